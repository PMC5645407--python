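"""Learned texture patterns: a per-channel k-means codebook over voxel descriptors.

All training-cohort voxel descriptors of one channel are z-scored and
clustered with k-means (k = 50 by default); the centroids are the "learned
texture patterns".  Any tumor — training or validation — is then represented
by the relative occurrence of each pattern among its voxels.  Validation
descriptors never update the centroids or the standardizer.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

__all__ = ["TextureDictionary", "learn_dictionary", "assign", "histogram"]


@dataclass(frozen=True)
class TextureDictionary:
    channel: str
    k: int
    centroids: np.ndarray  # (k, d), in standardized space
    mean: np.ndarray  # per-dimension standardizer mean
    sd: np.ndarray  # per-dimension standardizer SD (zero-variance dims get 1)
    config_fingerprint: str

    def standardize(self, descriptors: np.ndarray) -> np.ndarray:
        return (np.asarray(descriptors, dtype=float) - self.mean) / self.sd

    def unstandardized_centroids(self) -> np.ndarray:
        return self.centroids * self.sd + self.mean

    def to_json(self, path: str | Path) -> None:
        """Lossless serialization (float64 arrays base64-encoded)."""
        payload = {
            "channel": self.channel,
            "k": self.k,
            "d": int(self.centroids.shape[1]),
            "config_fingerprint": self.config_fingerprint,
            "centroids": _enc(self.centroids),
            "mean": _enc(self.mean),
            "sd": _enc(self.sd),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TextureDictionary":
        p = json.loads(Path(path).read_text())
        d = p["d"]
        return cls(
            channel=p["channel"],
            k=p["k"],
            centroids=_dec(p["centroids"]).reshape(p["k"], d),
            mean=_dec(p["mean"]),
            sd=_dec(p["sd"]),
            config_fingerprint=p["config_fingerprint"],
        )


def _enc(a: np.ndarray) -> str:
    return base64.b64encode(np.ascontiguousarray(a, dtype="<f8").tobytes()).decode()


def _dec(s: str) -> np.ndarray:
    return np.frombuffer(base64.b64decode(s), dtype="<f8").copy()


def learn_dictionary(
    training_descriptors: np.ndarray,
    k: int = 50,
    seed: int = 0,
    channel: str = "b0",
    config_fingerprint: str = "",
) -> TextureDictionary:
    """Fit the standardizer and k-means codebook on stacked training descriptors.

    k-means++ initialization with 10 restarts, Lloyd iterations, relative
    inertia tolerance 1e-6, at most 300 iterations; the best-inertia run is
    kept.  Deterministic given the seed.
    """
    X = np.asarray(training_descriptors, dtype=float)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D matrix")
    bad = ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        raise ValueError(f"non-finite descriptors at rows {np.flatnonzero(bad)[:10].tolist()}")
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} descriptor rows, got {X.shape[0]}")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, algorithm="lloyd",
        tol=1e-6, max_iter=300, random_state=seed,
    ).fit(Z)
    return TextureDictionary(
        channel=channel, k=k, centroids=km.cluster_centers_.copy(),
        mean=mean, sd=sd, config_fingerprint=config_fingerprint,
    )


def assign(
    descriptors: np.ndarray,
    dictionary: TextureDictionary,
    config_fingerprint: str | None = None,
) -> np.ndarray:
    """Index of the nearest centroid (standardized Euclidean); ties take the lowest index."""
    if config_fingerprint is not None and config_fingerprint != dictionary.config_fingerprint:
        raise ValueError(
            "descriptor configuration does not match the dictionary "
            f"({config_fingerprint!r} vs {dictionary.config_fingerprint!r})"
        )
    Z = dictionary.standardize(descriptors)
    if Z.shape[1] != dictionary.centroids.shape[1]:
        raise ValueError("descriptor dimension does not match dictionary")
    # squared distances via expansion; argmin returns the lowest index on ties
    d2 = (
        np.sum(Z * Z, axis=1)[:, None]
        - 2.0 * Z @ dictionary.centroids.T
        + np.sum(dictionary.centroids ** 2, axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def histogram(indices: np.ndarray, k: int) -> np.ndarray:
    """Relative occurrence of each pattern among a tumor's voxels."""
    idx = np.asarray(indices)
    if idx.size == 0:
        raise ValueError("empty index list (empty tumor upstream)")
    if idx.min() < 0 or idx.max() >= k:
        raise ValueError("cluster index out of range")
    counts = np.bincount(idx, minlength=k).astype(float)
    return counts / counts.sum()
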