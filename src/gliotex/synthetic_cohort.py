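"""Seeded synthetic glioma cohorts for end-to-end pipeline testing.

Real lower-grade-glioma MRI with genotype labels cannot be redistributed, so
this module generates cohorts with the statistical structure the analysis
assumes: two co-registered scalar channels (a T2-weighted B0-like channel and
an FA-like channel clipped to [0, 1]) at 2 mm isotropic spacing, ellipsoidal
whole-tumor masks, a mutant:wild-type imbalance near 77:23, larger mutant
tumors, and genotype-dependent within-tumor texture realized as Gaussian
random fields whose correlation length differs by genotype.  Every record is
reproducible bit-for-bit from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = ["CohortSpec", "PatientRecord", "sample_cohort",
           "generate_tumor_mask", "generate_textured_channel", "write_cohort"]

MUTANT = "mutant"
WILDTYPE = "wildtype"
CHANNELS = ("b0", "fa")

# Intensity scales of the two channels.  The B0 channel mimics a T2-weighted
# image (arbitrary units, tumor hyperintense); the FA channel lives in [0, 1]
# with reduced anisotropy inside tumor.  Absolute levels are free parameters
# of the generator — only relative (within-neighborhood) structure matters to
# the binarized descriptors downstream.
_CHANNEL_PARAMS = {
    "b0": {"background": 100.0, "tumor_offset": 40.0, "texture_amp": 15.0, "noise_scale": 1.0},
    "fa": {"background": 0.40, "tumor_offset": -0.10, "texture_amp": 0.08, "noise_scale": 0.01},
}

_MIN_RADIUS_VOXELS = 3.0
_MAX_AXIS_RATIO = 1.3
_CENTER_JITTER = 2.0  # voxels, per axis


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``texture_effect`` maps each channel to a ``(mutant, wildtype)`` pair of
    Gaussian smoothing scales in voxels: the correlation length of the
    within-tumor random field.  Setting the pair equal ablates the texture
    signal for that channel; setting ``mutant_size_mean == wild_size_mean``
    ablates the size signal.
    """

    n_patients: int = 79
    mutant_prob: float = 0.77
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    mutant_size_mean: float = 12.0
    wild_size_mean: float = 9.0
    size_sd: float = 2.0
    texture_effect: dict = field(
        default_factory=lambda: {"b0": (2.0, 0.5), "fa": (2.0, 0.5)}
    )
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 < self.mutant_prob < 1.0:
            raise ValueError("mutant_prob must lie strictly in (0, 1)")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacings must be positive")
        if any(g < 4 for g in self.grid_shape):
            raise ValueError("grid too small")
        if self.mutant_size_mean < self.wild_size_mean:
            raise ValueError("mutant_size_mean must be >= wild_size_mean")
        if self.size_sd <= 0 or self.noise_sd < 0:
            raise ValueError("size_sd must be positive and noise_sd non-negative")
        if set(self.texture_effect) != set(CHANNELS):
            raise ValueError(f"texture_effect must have keys {CHANNELS}")


@dataclass
class PatientRecord:
    patient_id: str
    genotype: str
    b0: np.ndarray
    fa: np.ndarray
    mask: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (self.b0.shape == self.fa.shape == self.mask.shape):
            raise ValueError(f"shape mismatch for patient {self.patient_id}")
        if self.mask.sum() < 1:
            raise ValueError(f"empty mask for patient {self.patient_id}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def generate_tumor_mask(
    radius_voxels: float,
    grid_shape: tuple[int, int, int],
    seed: int | np.random.Generator,
    patient_id: str = "<unknown>",
) -> np.ndarray:
    """Random axis-aligned ellipsoid mask of given equivalent-sphere radius.

    Axis ratios are drawn uniformly in [0.7, 1.3] and rescaled to unit
    geometric mean so the expected voxel count stays near the ideal sphere
    count (4/3)*pi*r^3; the center gets +-2 voxels of uniform jitter.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if radius_voxels < 1:
        raise ValueError(f"tumor radius {radius_voxels} < 1 voxel for patient {patient_id}")
    shape = np.asarray(grid_shape, dtype=int)
    ratios = rng.uniform(0.7, 1.3, size=3)
    ratios = ratios / np.prod(ratios) ** (1.0 / 3.0)
    jitter = rng.uniform(-_CENTER_JITTER, _CENTER_JITTER, size=3)
    center = (shape - 1) / 2.0 + jitter
    semi = ratios * radius_voxels
    if np.any(center - semi < 0) or np.any(center + semi > shape - 1):
        raise ValueError(
            f"grid {tuple(grid_shape)} too small for tumor of radius "
            f"{radius_voxels:.1f} voxels (patient {patient_id})"
        )
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij", sparse=True)
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = q <= 1.0
    if mask.sum() < 1:  # sub-voxel ellipsoid that missed every center
        ci = tuple(np.round(center).astype(int))
        mask[ci] = True
    return mask


def _smooth_unit_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """White noise smoothed to correlation length ``scale``, rescaled to unit SD."""
    f = rng.standard_normal(shape)
    if scale > 0:
        f = gaussian_filter(f, sigma=scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_textured_channel(
    mask: np.ndarray,
    genotype: str,
    channel: str,
    spec: CohortSpec,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One scalar channel: smooth background plus a genotype-textured tumor.

    Background is a broad centered Gaussian blob (brain-like base intensity)
    with iid voxel noise; inside the mask the intensity is a constant offset
    plus a unit-variance Gaussian random field whose smoothing scale depends
    on genotype and channel.  FA values are clipped to [0, 1].
    """
    if channel not in _CHANNEL_PARAMS:
        raise ValueError(f"unknown channel {channel!r}")
    if genotype not in (MUTANT, WILDTYPE):
        raise ValueError(f"unknown genotype {genotype!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = _CHANNEL_PARAMS[channel]
    shape = mask.shape
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij", sparse=True)
    center = [(s - 1) / 2.0 for s in shape]
    r2 = sum(((g - c) / (s / 3.0)) ** 2 for g, c, s in zip(grids, center, shape))
    base = p["background"] * np.exp(-0.5 * r2)
    vol = base + rng.standard_normal(shape) * (spec.noise_sd * p["noise_scale"])
    scale = spec.texture_effect[channel][0 if genotype == MUTANT else 1]
    texture = _smooth_unit_field(rng, shape, scale)
    inside = mask.astype(bool)
    vol[inside] = base[inside] + p["tumor_offset"] + p["texture_amp"] * texture[inside]
    if channel == "fa":
        vol = np.clip(vol, 0.0, 1.0)
    return vol


def sample_cohort(spec: CohortSpec, masks_only: bool = False) -> list[PatientRecord]:
    """Draw a full cohort; deterministic given ``spec.seed``.

    With ``masks_only`` the intensity channels are skipped (zeros), which
    leaves genotypes and masks bit-identical to a full draw — convenient for
    tumor-size statistics that do not need textures.
    """
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(spec.n_patients)
    records = []
    for i, ss in enumerate(streams):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(ss)
        genotype = MUTANT if rng.random() < spec.mutant_prob else WILDTYPE
        mean = spec.mutant_size_mean if genotype == MUTANT else spec.wild_size_mean
        radius = rng.normal(mean, spec.size_sd)
        while radius < _MIN_RADIUS_VOXELS:  # truncated normal by rejection
            radius = rng.normal(mean, spec.size_sd)
        mask = generate_tumor_mask(radius, spec.grid_shape, rng, patient_id=pid)
        if masks_only:
            b0 = np.zeros(spec.grid_shape)
            fa = np.zeros(spec.grid_shape)
        else:
            b0 = generate_textured_channel(mask, genotype, "b0", spec, rng)
            fa = generate_textured_channel(mask, genotype, "fa", spec, rng)
        records.append(
            PatientRecord(
                patient_id=pid, genotype=genotype, b0=b0, fa=fa, mask=mask,
                spacing_mm=spec.voxel_spacing_mm,
            )
        )
    return records


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> Path:
    """Write per-patient NIfTI files plus a cohort manifest CSV; returns manifest path."""
    from .volume_io import write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = {}
        for tag, arr in (("b0", rec.b0), ("fa", rec.fa), ("mask", rec.mask.astype(np.uint8))):
            path = out / f"{rec.patient_id}_{tag}.nii"
            write_volume(arr, rec.spacing_mm, path)
            paths[tag] = path.name
        rows.append(
            {"patient_id": rec.patient_id, "genotype": rec.genotype,
             "path_b0": paths["b0"], "path_fa": paths["fa"], "path_mask": paths["mask"]}
        )
    manifest = out / "cohort.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
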