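"""Synthetic bifurcating carotid phantoms with known stenosis geometry.

The generator emulates the data regime of black-blood neck MRI: a single
carotid tree (common carotid bifurcating into internal and external
branches) whose lumen occupies well under 0.1% of the image grid, voxelized
onto an anisotropic scanner-like grid, with a dark lumen inside a brighter
vessel-wall ring and additive Gaussian noise.  Focal stenoses are imposed as
smooth cosine-tapered radius reductions, so every phantom carries an exact
analytic ground truth (reference diameter, minimum lumen diameter, NASCET
percent, throat position and centerline) against which the measurement
pipeline can be validated.

Geometry convention: array axis 0 is the slice (superior-inferior) axis.
The common carotid artery (CCA) runs from the inferior grid boundary up to
the bifurcation; the internal (ICA) and external (ECA) branches continue
superiorly, splayed symmetrically in the row direction.  The ICA is given
the larger of the two distal radii.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .image import LumenLabel, VolumeImage

__all__ = [
    "StenosisSpec",
    "PhantomSpec",
    "GroundTruthRecord",
    "generate_phantom",
    "generate_cohort",
    "BRANCHES",
    "SCANNER_SPACINGS",
]

BRANCHES = ("CCA", "ICA", "ECA")

#: Scanner-style voxel spacings (slice, row, col) in mm used to tag cohort
#: phantoms, loosely following the three acquisition platforms' resolutions.
SCANNER_SPACINGS = {
    "ScI": (0.6, 0.6, 0.6),
    "ScII": (1.0, 0.8, 0.8),
    "ScIII": (1.0, 0.9, 0.9),
}


@dataclass(frozen=True)
class StenosisSpec:
    """A focal narrowing on one branch.

    ``target_percent`` is the NASCET percent diameter reduction at the
    throat; the radius profile tapers from the branch radius down to
    ``(1 - target_percent/100) * radius`` over ``length`` mm following a
    raised-cosine profile (smooth, analytic throat preserved).
    """

    branch: str
    center_arclength: float  # mm along the branch, measured from its origin
    length: float  # mm, full extent of the taper
    target_percent: float  # [0, 100)

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"branch must be one of {BRANCHES}, got {self.branch!r}")
        if not (0.0 <= self.target_percent < 100.0):
            raise ValueError("target_percent must lie in [0, 100)")
        if self.length <= 0:
            raise ValueError("stenosis length must be positive")

    def radius_factor(self, s: np.ndarray) -> np.ndarray:
        """Multiplicative radius factor at arc-lengths ``s`` (mm)."""
        s = np.asarray(s, dtype=float)
        u = (s - self.center_arclength) / self.length  # [-0.5, 0.5] inside
        inside = np.abs(u) <= 0.5
        f = np.ones_like(s)
        depth = self.target_percent / 100.0
        f[inside] = 1.0 - depth * 0.5 * (1.0 + np.cos(2.0 * np.pi * u[inside]))
        return f


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic carotid phantom."""

    grid_shape: tuple[int, int, int] = (192, 352, 352)
    spacing: tuple[float, float, float] = (0.59, 0.46, 0.46)
    cca_radius: float = 3.0  # mm
    ica_radius: float = 2.4
    eca_radius: float = 1.8
    segment_length: float = 50.0  # mm per branch
    bifurcation_angle: float = 50.0  # degrees between ICA and ECA
    stenosis_list: tuple[StenosisSpec, ...] = ()
    lumen_intensity: float = 30.0  # a.u.; dark lumen (black-blood contrast)
    wall_intensity: float = 180.0  # bright wall ring
    background_intensity: float = 100.0
    wall_thickness: float = 1.0  # mm
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "stenosis_list", tuple(self.stenosis_list))
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        for r in (self.cca_radius, self.ica_radius, self.eca_radius):
            if r <= 0:
                raise ValueError("radii must be positive")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for st in self.stenosis_list:
            lo = st.center_arclength - st.length / 2.0
            hi = st.center_arclength + st.length / 2.0
            if lo <= 0.0 or hi >= self.segment_length:
                raise ValueError(
                    f"stenosis on {st.branch} ([{lo:.1f}, {hi:.1f}] mm) must lie "
                    f"strictly inside the branch arc range (0, {self.segment_length})"
                )

    def branch_radius(self, branch: str) -> float:
        return {"CCA": self.cca_radius, "ICA": self.ica_radius, "ECA": self.eca_radius}[branch]


@dataclass
class GroundTruthRecord:
    """Analytic ground truth carried alongside each phantom."""

    true_percent: dict[str, float]  # per branch; 0 where no stenosis
    true_mld: float  # mm, diameter at the throat of the primary stenosis
    true_rvd: float  # mm, un-stenosed diameter of the stenosed branch
    throat_arclength: float  # mm along the stenosed branch; nan if none
    primary_branch: str  # branch carrying the primary (largest) stenosis
    centerline_points: dict[str, np.ndarray] = field(default_factory=dict)  # world mm

    @property
    def primary_percent(self) -> float:
        return self.true_percent[self.primary_branch]


def _branch_geometry(spec: PhantomSpec) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Return per-branch (origin point, unit direction) in world mm.

    All branches are parameterized by arc-length from the bifurcation for
    ICA/ECA, and *towards* the bifurcation for the CCA (the CCA origin is
    its inferior end so that arc-length increases superiorly along flow).
    """
    shape = np.asarray(spec.grid_shape, float)
    sp = np.asarray(spec.spacing, float)
    extent = shape * sp
    half_angle = np.deg2rad(spec.bifurcation_angle) / 2.0
    # Bifurcation sits mid-plane, with the CCA filling the inferior part.
    bif_z = spec.segment_length + spec.cca_radius + 1.0
    bif = np.array([bif_z, extent[1] / 2.0, extent[2] / 2.0])
    d_cca = np.array([-1.0, 0.0, 0.0])  # from bifurcation downwards
    d_ica = np.array([np.cos(half_angle), np.sin(half_angle), 0.0])
    d_eca = np.array([np.cos(half_angle), -np.sin(half_angle), 0.0])
    return {"CCA": (bif, d_cca), "ICA": (bif, d_ica), "ECA": (bif, d_eca)}


def _branch_samples(
    spec: PhantomSpec, branch: str, step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense centerline samples: arc-lengths, points (mm) and lumen radii."""
    bif, d = _branch_geometry(spec)[branch]
    s = np.arange(0.0, spec.segment_length + step / 2.0, step)
    pts = bif[None, :] + s[:, None] * d[None, :]
    r = np.full_like(s, spec.branch_radius(branch))
    for st in spec.stenosis_list:
        if st.branch == branch:
            r = r * st.radius_factor(s)
    return s, pts, r


def _paint_tube(
    mask: np.ndarray,
    points_mm: np.ndarray,
    radii_mm: np.ndarray,
    spacing: np.ndarray,
    check_bounds: bool = False,
) -> None:
    """Mark voxels whose center lies within ``r`` of any sample (in place).

    With a sample step well below the voxel size this union of balls
    voxelizes the analytic canal surface to sub-voxel accuracy.
    """
    shape = np.asarray(mask.shape)
    for p, r in zip(points_mm, radii_mm):
        if r <= 0:
            continue
        idx = p / spacing
        lo = np.maximum(np.ceil(idx - r / spacing - 1e-9).astype(int), 0)
        hi = np.minimum(np.floor(idx + r / spacing + 1e-9).astype(int), shape - 1)
        if check_bounds and (np.any(idx - r / spacing < -0.5) or np.any(idx + r / spacing > shape - 0.5)):
            raise ValueError("grid too small to contain the vessel tree")
        if np.any(lo > hi):
            continue
        zz = (np.arange(lo[0], hi[0] + 1) * spacing[0] - p[0]) ** 2
        yy = (np.arange(lo[1], hi[1] + 1) * spacing[1] - p[1]) ** 2
        xx = (np.arange(lo[2], hi[2] + 1) * spacing[2] - p[2]) ** 2
        d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
        sub = mask[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        sub |= d2 <= r * r


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeImage, LumenLabel, GroundTruthRecord]:
    """Generate one seeded phantom: image, lumen label and ground truth.

    The lumen mask is a single connected Y-shaped component.  The image is a
    three-level intensity model (background / wall ring / dark lumen) plus
    seeded Gaussian noise; identical specs give bit-identical outputs.
    """
    sp = np.asarray(spec.spacing, float)
    step = 0.25 * float(sp.min())
    lumen = np.zeros(spec.grid_shape, dtype=bool)
    wall = np.zeros(spec.grid_shape, dtype=bool)
    centerlines: dict[str, np.ndarray] = {}
    for branch in BRANCHES:
        s, pts, r = _branch_samples(spec, branch, step)
        _paint_tube(lumen, pts, r, sp, check_bounds=True)
        _paint_tube(wall, pts, r + spec.wall_thickness, sp)
        centerlines[branch] = pts[:: max(1, int(round(1.0 / step)))]  # ~1 mm apart
    wall &= ~lumen

    img = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float32)
    img[wall] = spec.wall_intensity
    img[lumen] = spec.lumen_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)

    true_percent = {b: 0.0 for b in BRANCHES}
    for st in spec.stenosis_list:
        true_percent[st.branch] = max(true_percent[st.branch], st.target_percent)
    primary = max(BRANCHES, key=lambda b: (true_percent[b], b == "ICA"))
    if true_percent[primary] > 0:
        throats = [
            st for st in spec.stenosis_list
            if st.branch == primary and st.target_percent == true_percent[primary]
        ]
        throat_s = throats[0].center_arclength
    else:
        primary = "ICA"
        throat_s = float("nan")
    rvd = 2.0 * spec.branch_radius(primary)
    mld = (1.0 - true_percent[primary] / 100.0) * rvd

    record = GroundTruthRecord(
        true_percent=true_percent,
        true_mld=mld,
        true_rvd=rvd,
        throat_arclength=throat_s,
        primary_branch=primary,
        centerline_points=centerlines,
    )
    vol = VolumeImage(img, spec.spacing)
    label = LumenLabel(lumen.astype(np.uint8), spec.spacing)
    return vol, label, record


# ---------------------------------------------------------------------------
# Cohorts


#: Grade mix of the study-style training-validation cohort
#: (mild : moderate : severe = 3 : 206 : 336).
DEFAULT_GRADE_MIX = (3 / 545, 206 / 545, 336 / 545)

#: Percent ranges sampled per grade.  Kept away from the 30/70 class
#: boundaries so that a cohort lesion's true grade is well defined at
#: voxelization tolerance.
_GRADE_RANGES = {"mild": (10.0, 28.0), "moderate": (33.0, 67.0), "severe": (72.0, 92.0)}


def _rounded_counts(n: int, mix: tuple[float, float, float]) -> dict[str, int]:
    """Largest-remainder rounding of grade proportions to integer counts."""
    mix_arr = np.asarray(mix, float)
    if mix_arr.min() < 0 or abs(mix_arr.sum() - 1.0) > 1e-9:
        raise ValueError("grade_mix must be non-negative and sum to 1")
    raw = mix_arr * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return dict(zip(("mild", "moderate", "severe"), counts.tolist()))


def default_cohort_spec(seed: int = 0) -> PhantomSpec:
    """Template for cohort phantoms: smaller grid, study-like geometry."""
    return PhantomSpec(grid_shape=(128, 144, 144), spacing=(0.6, 0.6, 0.6),
                       segment_length=35.0, seed=seed)


def generate_cohort(
    n_lesions: int,
    grade_mix: tuple[float, float, float] = DEFAULT_GRADE_MIX,
    seed: int = 0,
    out_dir=None,
    spec_template: PhantomSpec | None = None,
):
    """Generate a stratified phantom cohort and (optionally) write it out.

    Each lesion is one phantom with a single ICA stenosis whose NASCET
    percent is drawn from its grade's range; geometry (radii, angle,
    stenosis center/length) is jittered per lesion.  Returns a manifest
    DataFrame with columns lesion_id, image_path, label_path, grade,
    true_percent, scanner_tag, seed; when ``out_dir`` is None no files are
    written and the in-memory phantoms are returned alongside.
    """
    import pandas as pd

    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    counts = _rounded_counts(n_lesions, tuple(grade_mix))
    rng = np.random.default_rng(seed)
    grades = [g for g in ("mild", "moderate", "severe") for _ in range(counts[g])]

    template = spec_template or default_cohort_spec()
    records = []
    phantoms = []
    scanner_tags = sorted(SCANNER_SPACINGS)
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for i, grade in enumerate(grades):
        lo, hi = _GRADE_RANGES[grade]
        pct = float(rng.uniform(lo, hi))
        tag = scanner_tags[int(rng.integers(len(scanner_tags)))]
        jitter = rng.uniform(0.9, 1.1, size=4)
        L = template.segment_length
        center = float(rng.uniform(0.45, 0.6)) * L
        length = float(rng.uniform(8.0, 12.0))
        lesion_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            grid_shape=template.grid_shape,
            spacing=template.spacing,
            cca_radius=template.cca_radius * jitter[0],
            ica_radius=template.ica_radius * jitter[1],
            eca_radius=template.eca_radius * jitter[2],
            segment_length=L,
            bifurcation_angle=template.bifurcation_angle * jitter[3],
            stenosis_list=(StenosisSpec("ICA", center, length, pct),),
            noise_sd=template.noise_sd,
            seed=lesion_seed,
        )
        vol, label, truth = generate_phantom(spec)
        lesion_id = f"lesion_{i:03d}"
        row = {
            "lesion_id": lesion_id,
            "image_path": "",
            "label_path": "",
            "grade": grade,
            "true_percent": truth.primary_percent,
            "scanner_tag": tag,
            "seed": lesion_seed,
        }
        if out_dir is not None:
            from .io import write_volume, write_label

            img_path = out_dir / f"{lesion_id}_image.nii.gz"
            lab_path = out_dir / f"{lesion_id}_label.nii.gz"
            write_volume(vol, img_path)
            write_label(label, lab_path)
            row["image_path"] = str(img_path)
            row["label_path"] = str(lab_path)
        else:
            phantoms.append((vol, label, truth))
        records.append(row)

    manifest = pd.DataFrame.from_records(records)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest
    return manifest, phantoms


def file_checksum(path) -> str:
    """SHA-256 of a file, for determinism checks on written cohorts."""
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
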