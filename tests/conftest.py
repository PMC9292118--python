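import numpy as np
import pytest

import myotract as mt


@pytest.fixture(scope="session")
def default_spec():
    return mt.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Standard two-ventricle phantom: (field, ground-truth tensors, DWI)."""
    return mt.make_phantom(default_spec)


@pytest.fixture(scope="session")
def fitted(default_spec, phantom):
    field, _tensors, dwi = phantom
    return mt.fit_dti(dwi, default_spec.scheme(), field.mask)


@pytest.fixture(scope="session")
def metrics(fitted):
    return mt.tensor_metrics(fitted)


def random_spd_tensors(rng, n, scale=1e-3):
    """Random SPD matrices as (n, 6) component rows (test oracle helper)."""
    a = rng.normal(size=(n, 3, 3))
    spd = a @ np.swapaxes(a, -1, -2) + 0.1 * np.eye(3)
    from myotract.volumes import matrices_to_tensors
    return matrices_to_tensors(spd * scale)


@pytest.fixture(scope="session")
def junction_rois():
    """Cylindrical ROI set around the junction bundle (at 90 deg).

    Seed R1 sits in the LV free wall at 150 deg; R2 at 210 deg is reachable
    without crossing the bundle; R4 at 30 deg lies on the far side of the
    long-axis bundle, so reaching it requires crossing the orthogonal
    fiber discontinuity.
    """
    def cyl(angle_deg, name, radius=1.5, half=10.0):
        a = np.deg2rad(angle_deg)
        return mt.SeedRegion(kind="cylinder",
                             center=(8.1 * np.cos(a), 8.1 * np.sin(a), 0.0),
                             axis=(0, 0, 1), radius=radius, half_height=half,
                             name=name)

    seed = mt.SeedRegion(kind="cylinder",
                         center=(8.1 * np.cos(np.deg2rad(150)),
                                 8.1 * np.sin(np.deg2rad(150)), 0.0),
                         axis=(0, 0, 1), radius=1.5, half_height=3.0, name="R1")
    return {"seed": seed, "free_wall": cyl(210, "R2"),
            "cross_bundle": cyl(30, "R4", radius=2.0)}
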