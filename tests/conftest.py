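"""Shared fixtures: small seeded phantoms sized for CPU test runs."""

import numpy as np
import pytest

from caroseg.phantom import PhantomSpec, StenosisSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """Compact isotropic phantom used by geometry-light tests."""
    return PhantomSpec(
        grid_shape=(48, 64, 64), spacing=(0.8, 0.7, 0.7), segment_length=16.0,
        noise_sd=5.0, seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


def quant_spec(percent: float, seed: int) -> PhantomSpec:
    """Measurement-friendly phantom: fine in-plane grid, long branches.

    Used wherever sub-voxel diameter accuracy matters (severe stenoses are
    thinner than a coarse voxel).
    """
    sten = (StenosisSpec("ICA", 18.0, 10.0, percent),) if percent > 0 else ()
    return PhantomSpec(
        grid_shape=(160, 160, 160), spacing=(0.5, 0.35, 0.35), segment_length=35.0,
        stenosis_list=sten, seed=seed,
    )


@pytest.fixture(scope="session")
def stenosed_phantom():
    """One 70% ICA stenosis phantom shared across stenosis tests."""
    return generate_phantom(quant_spec(70.0, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_cylinder_mask(shape=(40, 48, 48), spacing=(0.6, 0.5, 0.5), radius=3.0,
                       axis_rc=None):
    """Analytic axis-aligned cylinder along axis 0 (test oracle geometry)."""
    from caroseg.image import LumenLabel

    sp = np.asarray(spacing)
    if axis_rc is None:
        axis_rc = ((shape[1] - 1) / 2 * sp[1], (shape[2] - 1) / 2 * sp[2])
    rr = np.arange(shape[1]) * sp[1]
    cc = np.arange(shape[2]) * sp[2]
    d2 = (rr[:, None] - axis_rc[0]) ** 2 + (cc[None, :] - axis_rc[1]) ** 2
    disk = d2 <= radius**2
    mask = np.zeros(shape, np.uint8)
    mask[2:-2] = disk  # capped inside the grid so the skeleton is well defined
    return LumenLabel(np.ascontiguousarray(mask), spacing), axis_rc


def make_torus_mask(shape=(80, 80, 48), spacing=(0.5, 0.5, 0.5), big_radius=15.0,
                    tube_radius=3.0):
    """Quarter-torus tube of constant radius (curved-vessel oracle).

    The tube axis is the quarter circle of radius ``big_radius`` in the
    (axis0, axis1) plane centered at the grid point (c0, c1), swept through
    90 degrees; axis 2 is the torus axis direction.
    """
    from caroseg.image import LumenLabel

    sp = np.asarray(spacing)
    z = np.arange(shape[0]) * sp[0]
    y = np.arange(shape[1]) * sp[1]
    x = np.arange(shape[2]) * sp[2]
    c0, c1 = 6.0, 6.0
    cx = (shape[2] - 1) / 2 * sp[2]
    rho = np.sqrt((z[:, None] - c0) ** 2 + (y[None, :] - c1) ** 2)
    in_quadrant = (z[:, None] >= c0) & (y[None, :] >= c1)
    d2 = (rho - big_radius) ** 2
    mask = (
        (d2[:, :, None] + (x[None, None, :] - cx) ** 2 <= tube_radius**2)
        & in_quadrant[:, :, None]
    )
    return LumenLabel(mask.astype(np.uint8), spacing)


def _manifest_frame(n, grades, prefix, patients):
    import pandas as pd

    return pd.DataFrame({
        "lesion_id": [f"{prefix}{i:03d}" for i in range(n)],
        "patient_id": patients,
        "grade": grades,
    })


def study_style_manifests():
    """Synthetic manifests mirroring the study's printed per-cohort counts:
    train-val 372 patients / 545 lesions (3 mild, 206 moderate, 336 severe),
    test 50/96 (4, 20, 72), external 89/168 (6, 42, 120)."""

    def build(prefix, n_pat, grade_counts):
        grades = [g for g, c in zip(("mild", "moderate", "severe"), grade_counts)
                  for _ in range(c)]
        n = len(grades)
        patients = [f"{prefix}p{i % n_pat:03d}" for i in range(n)]
        return _manifest_frame(n, grades, prefix, patients)

    return {
        "train_val": build("tv", 372, (3, 206, 336)),
        "test": build("ts", 50, (4, 20, 72)),
        "external": build("ex", 89, (6, 42, 120)),
    }
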