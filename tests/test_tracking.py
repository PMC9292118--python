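"""Streamline tractography: seeding, the three algorithms, invariants, sweeps."""

import numpy as np
import pytest

import myotract as mt
from myotract.tracking import sample_watson
from myotract.volumes import TensorVolume, matrices_to_tensors


def uniform_field(shape=(20, 20, 30), direction=(0, 0, 1.0), fa=0.3,
                  voxel=0.6):
    """Homogeneous unit-vector field + FA volume + matching tensors."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    v1 = np.broadcast_to(direction, shape + (3,)).copy()
    fa_vol = np.full(shape, fa)
    aff = np.eye(4)
    aff[:3, :3] = np.diag([voxel] * 3)
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel
    # tensors with v1 = direction, eigenvalues giving FA ~0.34
    lam = np.diag([12e-4, 8e-4, 6e-4])
    helper = np.array([1.0, 0, 0]) if abs(direction[0]) < 0.9 else np.array([0, 1.0, 0])
    e2 = np.cross(direction, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(direction, e2)
    basis = np.stack([direction, e2, e3], axis=1)
    mat = basis @ lam @ basis.T
    six = np.broadcast_to(matrices_to_tensors(mat), shape + (6,)).copy()
    tensors = TensorVolume(six, aff, np.ones(shape, bool))
    return v1, fa_vol, aff, tensors


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"fa_threshold": 1.5}, {"max_angle_deg": 0.0}, {"step_mm": -1.0},
        {"min_length_mm": 50.0, "max_length_mm": 40.0},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            mt.TrackingParams(**kwargs)


class TestSeeding:
    def test_cylinder_samples_inside_and_reproducible(self):
        region = mt.SeedRegion(kind="cylinder", center=(1, 2, 3),
                               axis=(0, 0, 1), radius=2.0, half_height=4.0)
        pts = mt.seed_points(region, 500, rng=9)
        assert region.contains(pts).all()
        assert np.array_equal(pts, mt.seed_points(region, 500, rng=9))

    def test_montecarlo_centroid_matches_region_center(self):
        region = mt.SeedRegion(kind="cylinder", center=(-2, 5, 1),
                               axis=(0, 0, 1), radius=3.0, half_height=6.0)
        n = 100_000
        pts = mt.seed_points(region, n, rng=1)
        # standard error: radial sd = r/2, height sd = h/sqrt(3)
        se = np.array([1.5, 1.5, 6 / np.sqrt(3)]) / np.sqrt(n)
        assert np.all(np.abs(pts.mean(axis=0) - region.center) < 3 * se)

    def test_mask_region_seeds_inside_mask(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        region = mt.SeedRegion(kind="mask", mask=mask, mask_affine=np.eye(4))
        pts = mt.seed_points(region, 200, rng=2)
        assert region.contains(pts).all()

    def test_empty_mask_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mt.SeedRegion(kind="mask", mask=np.zeros((4, 4, 4), bool),
                          mask_affine=np.eye(4))


class TestFact:
    def test_uniform_field_gives_straight_max_length_line(self):
        v1, fa, aff, _ = uniform_field(shape=(20, 20, 80))
        params = mt.TrackingParams(max_length_mm=20.0, step_mm=0.1)
        tg = mt.track_fact(v1, fa, aff, seeds=[(0.0, 0.0, 0.0)], params=params)
        assert len(tg) == 1
        sl = tg.streamlines[0]
        assert np.abs(sl[:, :2]).max() < 1e-9
        assert tg.lengths()[0] == pytest.approx(20.0, abs=0.2)

    def test_step_spacing_is_exact(self):
        v1, fa, aff, _ = uniform_field()
        params = mt.TrackingParams(max_length_mm=8.0)
        tg = mt.track_fact(v1, fa, aff, seeds=[(0.2, -0.1, 0.0)], params=params)
        gaps = np.linalg.norm(np.diff(tg.streamlines[0], axis=0), axis=1)
        assert np.abs(gaps - params.step_mm).max() < 1e-6

    def test_orthogonal_interface_terminates_streamline(self):
        shape = (20, 20, 40)
        v1, fa, aff, _ = uniform_field(shape=shape)
        v1[:, :, 20:] = (1.0, 0.0, 0.0)   # 90-degree discontinuity at z=0
        params = mt.TrackingParams(max_angle_deg=60.0, max_length_mm=30.0)
        tg = mt.track_fact(v1, fa, aff, seeds=[(0.0, 0.0, -5.0)], params=params)
        sl = tg.streamlines[0]
        # track stops at (or just into) the interface instead of turning
        assert sl[:, 2].max() < 0.7

    def test_low_fa_seed_yields_no_streamline(self):
        v1, fa, aff, _ = uniform_field(fa=0.05)
        tg = mt.track_fact(v1, fa, aff, seeds=[(0.0, 0.0, 0.0)],
                           params=mt.TrackingParams(fa_threshold=0.1))
        assert len(tg) == 0

    def test_circular_field_stays_on_seed_radius(self, default_spec, metrics):
        """Circumferential phantom fibers: vertices stay within one voxel of
        the seeded radius over a long arc."""
        params = mt.TrackingParams(max_length_mm=20.0)
        seed_r = 8.1
        tg = mt.track_fact(metrics, seeds=[(0.0, -seed_r, 0.0)], params=params)
        sl = tg.streamlines[0]
        radii = np.hypot(sl[:, 0], sl[:, 1])
        assert np.abs(radii - seed_r).max() < 0.6
        assert tg.lengths()[0] > 15.0

    def test_antipodal_symmetry(self, metrics):
        """Negating the whole eigenvector field leaves streamlines unchanged
        up to traversal direction (fiber orientations are axial)."""
        seeds = [(0.0, -8.1, 0.0), (0.0, -6.5, 1.0)]
        params = mt.TrackingParams(max_length_mm=10.0)
        tg1 = mt.track_fact(metrics.v1, metrics.fa, metrics.affine,
                            seeds=seeds, params=params)
        tg2 = mt.track_fact(-metrics.v1, metrics.fa, metrics.affine,
                            seeds=seeds, params=params)
        assert len(tg1) == len(tg2)
        for a, b in zip(tg1.streamlines, tg2.streamlines):
            assert np.allclose(a, b[::-1], atol=1e-9)


class TestDet:
    def test_matches_fact_on_homogeneous_field(self):
        v1, fa, aff, tensors = uniform_field(shape=(20, 20, 60))
        params = mt.TrackingParams(max_length_mm=15.0)
        seeds = [(0.3, -0.4, 0.0)]
        tg_f = mt.track_fact(v1, fa, aff, seeds=seeds, params=params)
        tg_d = mt.track_det(tensors, seeds, params)
        assert np.abs(tg_f.streamlines[0] - tg_d.streamlines[0]).max() < 0.6

    def test_smoother_than_fact_on_curved_field(self, fitted, metrics):
        """Interpolated tracking turns gradually; nearest-voxel tracking
        kinks at voxel boundaries: max turning angle strictly smaller."""
        from myotract.pathway import propagation_angle
        seeds = [(0.0, -8.1, 0.0)]
        params = mt.TrackingParams(max_length_mm=15.0)
        tg_f = mt.track_fact(metrics, seeds=seeds, params=params)
        tg_d = mt.track_det(fitted, seeds, params)
        max_f = max(propagation_angle(s).max() for s in tg_f.streamlines)
        max_d = max(propagation_angle(s).max() for s in tg_d.streamlines)
        assert max_d < max_f

    def test_interior_vertices_satisfy_termination_criteria(self, fitted):
        """Re-scan: every emitted vertex obeys the angle and FA rules."""
        from myotract.pathway import propagation_angle
        from myotract.tracking import _DetField
        params = mt.TrackingParams(max_length_mm=12.0)
        seeds = [(0.0, -8.1, z) for z in (-2.0, 0.0, 2.0)]
        tg = mt.track_det(fitted, seeds, params)
        field = _DetField(fitted)
        for sl in tg.streamlines:
            assert propagation_angle(sl).max() <= params.max_angle_deg + 1e-6
            _, fa, valid = field.query(sl[1:-1])
            assert np.all(fa[valid] >= params.fa_threshold)

    def test_helical_phantom_recovers_transmural_rule(self, default_spec,
                                                      fitted):
        """Streamline helix angles follow the linear transmural rule."""
        params = mt.TrackingParams(max_length_mm=10.0)
        depths = np.linspace(0.2, 0.8, 5)
        radii = default_spec.lv_inner_radius + depths * (
            default_spec.lv_outer_radius - default_spec.lv_inner_radius)
        seeds = [(0.0, -r, 0.0) for r in radii]
        tg = mt.track_det(fitted, seeds, params)
        assert len(tg) == len(seeds)
        worst = 0.0
        for sl in tg.streamlines:
            steps = np.diff(sl, axis=0)
            mid = 0.5 * (sl[:-1] + sl[1:])
            r = np.hypot(mid[:, 0], mid[:, 1])
            d = (r - default_spec.lv_inner_radius) / (
                default_spec.lv_outer_radius - default_spec.lv_inner_radius)
            ok = (d > 0.05) & (d < 0.95)
            circ = np.stack([-mid[:, 1] / r, mid[:, 0] / r], axis=1)
            ha = np.degrees(np.arctan2(
                steps[:, 2], np.sum(steps[:, :2] * circ, axis=1)))
            ha = np.where(ha > 90, ha - 180, np.where(ha < -90, ha + 180, ha))
            rule = default_spec.alpha_endo + (
                default_spec.alpha_epi - default_spec.alpha_endo) * d
            if ok.any():
                worst = max(worst, np.abs(np.abs(ha[ok]) - np.abs(rule[ok])).max())
        assert worst <= 3.0


class TestProb:
    def test_bit_identical_given_same_rng(self, fitted):
        params = mt.TrackingParams(max_length_mm=8.0)
        seeds = [(0.0, -8.1, 0.0), (0.0, -7.0, 1.0)]
        tg1 = mt.track_prob(fitted, seeds, params, rng=123)
        tg2 = mt.track_prob(fitted, seeds, params, rng=123)
        for a, b in zip(tg1.streamlines, tg2.streamlines):
            assert np.array_equal(a, b)

    def test_endpoint_spread_grows_as_concentration_drops(self):
        _, _, _, tensors = uniform_field(shape=(24, 24, 60))
        seeds = [(0.0, 0.0, 0.0)] * 200
        spreads = []
        for kappa0 in (2000.0, 200.0, 20.0):
            params = mt.TrackingParams(max_length_mm=10.0, step_mm=0.2,
                                       kappa0=kappa0)
            tg = mt.track_prob(tensors, seeds, params, rng=5)
            ends = np.array([s[-1] for s in tg.streamlines])
            spreads.append(ends[:, :2].std())
        assert spreads[0] < spreads[1] < spreads[2]

    def test_high_concentration_approaches_deterministic(self):
        _, _, _, tensors = uniform_field(shape=(24, 24, 60))
        params = mt.TrackingParams(max_length_mm=10.0, step_mm=0.2,
                                   kappa0=5e4)
        seeds = [(0.0, 0.0, 0.0)] * 50
        tg_p = mt.track_prob(tensors, seeds, params, rng=6)
        tg_d = mt.track_det(tensors, [(0.0, 0.0, 0.0)], params)
        end_d = tg_d.streamlines[0][-1]
        ends = np.array([s[-1] for s in tg_p.streamlines])
        assert np.linalg.norm(ends - end_d, axis=1).mean() < 0.5

    def test_bootstrap_requires_redundant_scheme(self, fitted, phantom,
                                                 default_spec):
        _, _, dwi = phantom
        with pytest.raises(ValueError, match="dispersion"):
            mt.track_prob(seeds=[(0, 0, 0)], mode="bootstrap", dwi=dwi,
                          scheme=default_spec.scheme())

    def test_bootstrap_mode_tracks_on_dense_scheme(self, default_spec):
        spec = mt.PhantomSpec(noise_sigma=20.0, seed=11)
        field, tensors, _ = mt.make_phantom(spec)
        scheme = mt.dense_scheme(15)
        dwi = mt.simulate_dwi(tensors, scheme, sigma=20.0, seed=11)
        params = mt.TrackingParams(max_length_mm=6.0, step_mm=0.2)
        tg = mt.track_prob(seeds=[(0.0, -8.1, 0.0)], params=params,
                           mode="bootstrap", dwi=dwi, scheme=scheme, rng=3)
        assert len(tg) == 1
        assert tg.lengths()[0] >= 1.0


class TestWatsonSampler:
    def test_concentration_controls_alignment(self):
        rng = np.random.default_rng(0)
        mu = np.tile([0.0, 0.0, 1.0], (4000, 1))
        for kappa, min_mean_t2 in [(0.0, 0.25), (20.0, 0.85), (500.0, 0.99)]:
            x = sample_watson(mu, np.full(len(mu), kappa), rng)
            t2 = (x @ np.array([0, 0, 1.0])) ** 2
            assert np.allclose(np.linalg.norm(x, axis=1), 1.0)
            assert t2.mean() > min_mean_t2
        # uniform case stays isotropic: mean t^2 = 1/3
        x = sample_watson(mu, np.zeros(len(mu)), rng)
        assert abs((x @ np.array([0, 0, 1.0]) ** 2).mean()) < 0.5


class TestSweep:
    def test_single_cell_equals_direct_call(self, fitted):
        seeds = [(0.0, -8.1, 0.0)]
        base = mt.TrackingParams(max_length_mm=10.0)
        results, table = mt.sweep({"max_angle_deg": [60.0]}, "det", fitted,
                                  seeds, base)
        direct = mt.track_det(fitted, seeds, base)
        (combo,) = results
        assert np.allclose(results[combo].streamlines[0],
                           direct.streamlines[0])
        assert table.loc[0, "n_streamlines"] == len(direct)

    def test_fa_threshold_never_lengthens_streamlines(self, fitted):
        """Raising the FA stop terminates tracks in lower-anisotropy
        regions earlier: mean length is non-increasing."""
        seeds = [(0.0, -r, 0.0) for r in np.linspace(6.0, 10.2, 8)]
        base = mt.TrackingParams(max_length_mm=20.0, step_mm=0.1)
        _, table = mt.sweep({"fa_threshold": [0.1, 0.15, 0.2, 0.25]},
                            "det", fitted, seeds, base)
        lengths = table.sort_values("fa_threshold")["mean_length_mm"].to_numpy()
        assert np.all(np.diff(lengths) <= 1e-9)

    def test_max_length_caps_are_hard(self, fitted):
        seeds = [(0.0, -8.1, 0.0)]
        base = mt.TrackingParams(step_mm=0.1)
        results, _ = mt.sweep({"max_length_mm": [10.0, 40.0]}, "det",
                              fitted, seeds, base)
        for (cap,), tg in results.items():
            assert tg.lengths().max() <= cap + 1e-6

    def test_empty_grid_rejected(self, fitted):
        with pytest.raises(ValueError, match="grid"):
            mt.sweep({}, "det", fitted, [(0, 0, 0)])
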