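"""Rotation-invariant 3D local binary pattern descriptors.

For every voxel inside a tumor mask, intensities are sampled on spheres of
fixed physical radius around the voxel, binarized against the center
intensity, and the resulting binary function on the sphere is least-squares
projected onto real spherical harmonics.  The per-degree L2 norms of the
harmonic coefficients are invariant to rotations of the neighborhood and,
together with the Pearson kurtosis of the raw neighborhood intensities,
form the per-voxel texture descriptor.  Descriptors for several radii are
concatenated, so the default configuration (radii 1, 2, 3 mm, harmonic
degree 3) yields a 15-dimensional vector per voxel.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.special import sph_harm_y

__all__ = [
    "LbpConfig",
    "SphereSampling",
    "sphere_sample_directions",
    "real_sh_design",
    "build_sampling",
    "sample_neighborhood",
    "binarize",
    "fit_band_norms",
    "neighborhood_kurtosis",
    "voxel_descriptor",
    "extract_tumor_descriptors",
]


@dataclass(frozen=True)
class LbpConfig:
    """Configuration of the multi-radius spherical LBP descriptor.

    Parameters
    ----------
    radii_mm : strictly increasing physical radii of the sampling spheres.
    n_dirs : number of sphere sample directions shared by all radii; must be
        at least ``(max_degree + 1)**2`` so the harmonic fit is well posed.
    max_degree : highest spherical-harmonic degree retained in the fit.
    """

    radii_mm: tuple[float, ...] = (1.0, 2.0, 3.0)
    n_dirs: int = 64
    max_degree: int = 3

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii_mm)
        object.__setattr__(self, "radii_mm", radii)
        if any(r <= 0 for r in radii):
            raise ValueError("radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be strictly increasing")
        n_coef = (self.max_degree + 1) ** 2
        if self.n_dirs < n_coef:
            raise ValueError(
                f"n_dirs={self.n_dirs} < (L+1)^2={n_coef}: harmonic fit under-determined"
            )

    @property
    def descriptor_length(self) -> int:
        # per radius: one norm per degree 0..L plus the kurtosis
        return len(self.radii_mm) * (self.max_degree + 2)

    def fingerprint(self) -> str:
        payload = json.dumps(
            {"radii_mm": self.radii_mm, "n_dirs": self.n_dirs, "max_degree": self.max_degree},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def sphere_sample_directions(n_dirs: int) -> np.ndarray:
    """Deterministic near-uniform unit directions (Fibonacci spiral).

    Returns an ``(n_dirs, 3)`` array of unit vectors.  The spiral is fully
    deterministic and close to balanced: the mean direction is near zero and
    low-degree spherical harmonics are well conditioned on it.
    """
    if n_dirs < 4:
        raise ValueError("need at least 4 directions to support degree-1 harmonics")
    i = np.arange(n_dirs, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n_dirs
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def real_sh_design(directions: np.ndarray, max_degree: int) -> np.ndarray:
    """Design matrix of real orthonormal spherical harmonics.

    Rows are directions, columns run over ``(l, m)`` with ``l = 0..max_degree``
    and ``m = -l..l`` in that order.  The real basis is built from the complex
    harmonics Y_l^m in the standard way, so it is orthonormal on the sphere
    and per-degree coefficient norms are preserved under rotation.
    """
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    cols = []
    for l in range(max_degree + 1):
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                col = y.real
            elif m > 0:
                col = np.sqrt(2.0) * (-1.0) ** m * y.real
            else:
                col = np.sqrt(2.0) * (-1.0) ** m * y.imag
            cols.append(col)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SphereSampling:
    """Precomputed directions, harmonic design matrix and its pseudo-inverse."""

    directions: np.ndarray
    design: np.ndarray
    pseudo_inverse: np.ndarray
    max_degree: int
    degree_slices: tuple[slice, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-12:
            raise ValueError("directions must be unit vectors")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("rank-deficient harmonic design matrix")
        slices = []
        start = 0
        for l in range(self.max_degree + 1):
            slices.append(slice(start, start + 2 * l + 1))
            start += 2 * l + 1
        object.__setattr__(self, "degree_slices", tuple(slices))


def build_sampling(n_dirs: int, max_degree: int) -> SphereSampling:
    dirs = sphere_sample_directions(n_dirs)
    design = real_sh_design(dirs, max_degree)
    return SphereSampling(
        directions=dirs,
        design=design,
        pseudo_inverse=np.linalg.pinv(design),
        max_degree=max_degree,
    )


def _sample_points(
    volume: np.ndarray,
    centers_vox: np.ndarray,
    radius_mm: float,
    sampling: SphereSampling,
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    """Trilinear samples at ``center + radius * direction`` in world (mm) space.

    ``centers_vox`` is (n, 3) in voxel index coordinates.  Out-of-bounds
    sample points read the nearest in-bounds voxel (replicate padding).
    Returns an (n, n_dirs) array.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    offsets_vox = sampling.directions * radius_mm / spacing  # (n_dirs, 3)
    pts = centers_vox[:, None, :] + offsets_vox[None, :, :]  # (n, n_dirs, 3)
    coords = pts.reshape(-1, 3).T
    vals = map_coordinates(volume, coords, order=1, mode="nearest")
    return vals.reshape(len(centers_vox), -1)


def sample_neighborhood(
    volume: np.ndarray,
    center_voxel: tuple[int, int, int],
    radius_mm: float,
    sampling: SphereSampling,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Sphere-sample intensities around one voxel (world-coordinate radius)."""
    vol = np.asarray(volume, dtype=float)
    if not np.all(np.isfinite(vol)):
        raise ValueError("volume contains non-finite values")
    center = np.asarray(center_voxel, dtype=float)
    if np.any(center < 0) or np.any(center > np.asarray(vol.shape) - 1):
        raise ValueError("center voxel outside volume")
    return _sample_points(vol, center[None, :], radius_mm, sampling, spacing_mm)[0]


_REL_TIE_TOL = 1e-12


def binarize(intensities: np.ndarray, center_value: float) -> np.ndarray:
    """Threshold neighborhood intensities against the center voxel.

    A neighbor maps to 1 iff it is strictly more intense than the center;
    ties map to 0.  Values within a relative tolerance of 1e-12 count as
    ties so that interpolation round-off (e.g. on constant volumes) cannot
    flip bits.
    """
    tol = _REL_TIE_TOL * (1.0 + abs(center_value))
    return (np.asarray(intensities, dtype=float) > center_value + tol).astype(float)


def fit_band_norms(values: np.ndarray, sampling: SphereSampling) -> np.ndarray:
    """Per-degree L2 norms of the least-squares harmonic coefficients.

    ``values`` is the function on the sampling directions — normally the
    binarized neighborhood, but any real-valued samples are accepted (used
    directly when testing rotation invariance on band-limited functions).
    """
    v = np.asarray(values, dtype=float)
    if v.shape[-1] != sampling.pseudo_inverse.shape[1]:
        raise ValueError("value count does not match sampling directions")
    coef = v @ sampling.pseudo_inverse.T
    return np.stack(
        [np.linalg.norm(coef[..., sl], axis=-1) for sl in sampling.degree_slices], axis=-1
    )


def neighborhood_kurtosis(intensities: np.ndarray) -> float:
    """Population Pearson kurtosis m4 / m2**2 (not excess); 0 if degenerate."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intensities")
    return float(_kurtosis_rows(x[None, :])[0])


def _kurtosis_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    c = x - mean
    m2 = np.mean(c * c, axis=1)
    m4 = np.mean(c ** 4, axis=1)
    out = np.zeros(len(x))
    # a spread below round-off scale counts as zero variance
    ok = np.sqrt(m2) > _REL_TIE_TOL * (1.0 + np.abs(mean[:, 0]))
    out[ok] = m4[ok] / (m2[ok] ** 2)
    return out


def voxel_descriptor(
    volume: np.ndarray,
    center_voxel: tuple[int, int, int],
    config: LbpConfig,
    sampling: SphereSampling,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Full multi-radius descriptor for a single voxel.

    Layout per radius (in ``config.radii_mm`` order): band norms for degrees
    0..L, then the kurtosis of the raw neighborhood intensities.
    """
    vol = np.asarray(volume, dtype=float)
    center = np.asarray([center_voxel], dtype=float)
    return _descriptor_rows(vol, center, config, sampling, spacing_mm)[0]


def _descriptor_rows(
    volume: np.ndarray,
    centers_vox: np.ndarray,
    config: LbpConfig,
    sampling: SphereSampling,
    spacing_mm: tuple[float, float, float],
) -> np.ndarray:
    idx = np.round(centers_vox).astype(int)
    center_vals = volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    parts = []
    tol = _REL_TIE_TOL * (1.0 + np.abs(center_vals))
    for r in config.radii_mm:
        samples = _sample_points(volume, centers_vox, r, sampling, spacing_mm)
        bits = (samples > (center_vals + tol)[:, None]).astype(float)
        norms = fit_band_norms(bits, sampling)
        kurt = _kurtosis_rows(samples)
        parts.append(np.column_stack([norms, kurt]))
    return np.concatenate(parts, axis=1)


def extract_tumor_descriptors(
    volume: np.ndarray,
    mask: np.ndarray,
    config: LbpConfig,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sampling: SphereSampling | None = None,
    patient_id: str = "<unknown>",
) -> np.ndarray:
    """Descriptor matrix for all mask voxels, rows in lexicographic voxel order."""
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask).astype(bool)
    if vol.shape != msk.shape:
        raise ValueError(f"volume/mask shape mismatch for patient {patient_id}")
    if not np.all(np.isfinite(vol)):
        raise ValueError(f"non-finite voxel data for patient {patient_id}")
    centers = np.argwhere(msk).astype(float)  # argwhere is lexicographic
    if len(centers) == 0:
        raise ValueError(f"empty tumor mask for patient {patient_id}")
    if sampling is None:
        sampling = build_sampling(config.n_dirs, config.max_degree)
    return _descriptor_rows(vol, centers, config, sampling, spacing_mm)
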