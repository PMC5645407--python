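"""Per-tumor feature rows (voxel count + two texture histograms) and the cohort split.

The default representation has 101 features: the mask voxel count plus the
relative occurrences of the 50 learned texture patterns in each of the B0
and FA channels.  Cohorts are split 3:1 into training and validation by
simple (label-blind) randomization, with the validation size rounded from
n/4 — 79 patients split into 59 training and 20 validation cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import lbp3d, texture_dictionary as td
from .synthetic_cohort import PatientRecord

__all__ = ["FeatureRow", "FeatureTable", "CohortSplit", "build_row",
           "split_cohort", "write_feature_table", "read_feature_table"]


@dataclass(frozen=True)
class FeatureRow:
    patient_id: str
    label: str
    voxel_count: int
    b0_freqs: np.ndarray
    fa_freqs: np.ndarray

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        for block in (self.b0_freqs, self.fa_freqs):
            if abs(block.sum() - 1.0) > 1e-9:
                raise ValueError("frequency block does not sum to 1")

    @property
    def features(self) -> np.ndarray:
        return np.concatenate([[float(self.voxel_count)], self.b0_freqs, self.fa_freqs])

    @property
    def n_features(self) -> int:
        return 1 + len(self.b0_freqs) + len(self.fa_freqs)


FeatureTable = list[FeatureRow]


@dataclass(frozen=True)
class CohortSplit:
    training_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.training_ids) & set(self.validation_ids):
            raise ValueError("training and validation ids overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"training_ids": list(self.training_ids),
             "validation_ids": list(self.validation_ids), "seed": self.seed}))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSplit":
        p = json.loads(Path(path).read_text())
        return cls(tuple(p["training_ids"]), tuple(p["validation_ids"]), p["seed"])


def build_row(
    patient: PatientRecord,
    dict_b0: td.TextureDictionary,
    dict_fa: td.TextureDictionary,
    config: lbp3d.LbpConfig,
    sampling: lbp3d.SphereSampling | None = None,
) -> FeatureRow:
    """Compute one patient's feature row from raw volumes via the dictionaries."""
    if sampling is None:
        sampling = lbp3d.build_sampling(config.n_dirs, config.max_degree)
    fp = config.fingerprint()
    freqs = {}
    for channel, volume, dic in (("b0", patient.b0, dict_b0), ("fa", patient.fa, dict_fa)):
        desc = lbp3d.extract_tumor_descriptors(
            volume, patient.mask, config, spacing_mm=patient.spacing_mm,
            sampling=sampling, patient_id=patient.patient_id,
        )
        idx = td.assign(desc, dic, config_fingerprint=fp)
        freqs[channel] = td.histogram(idx, dic.k)
    return FeatureRow(
        patient_id=patient.patient_id, label=patient.genotype,
        voxel_count=patient.voxel_count,
        b0_freqs=freqs["b0"], fa_freqs=freqs["fa"],
    )


def split_ids(ids: list[str], seed: int) -> CohortSplit:
    """Label-blind 3:1 partition of patient ids; validation size = round(n/4)."""
    n = len(ids)
    if n < 8:
        raise ValueError("need at least 8 patients for a 3:1 split")
    n_val = int(np.floor(n / 4.0 + 0.5))  # round half up
    rng = np.random.default_rng(seed)
    perm = rng.permutation(sorted(ids))
    return CohortSplit(
        training_ids=tuple(perm[n_val:].tolist()),
        validation_ids=tuple(perm[:n_val].tolist()),
        seed=seed,
    )


def split_cohort(rows: FeatureTable, seed: int) -> CohortSplit:
    return split_ids([r.patient_id for r in rows], seed)


def _header(k_b0: int, k_fa: int) -> list[str]:
    return (
        ["patient_id", "label", "voxel_count"]
        + [f"b0_f{i + 1:02d}" for i in range(k_b0)]
        + [f"fa_f{i + 1:02d}" for i in range(k_fa)]
    )


def write_feature_table(rows: FeatureTable, path: str | Path) -> None:
    if not rows:
        raise ValueError("no rows to write")
    k_b0 = len(rows[0].b0_freqs)
    k_fa = len(rows[0].fa_freqs)
    for i, r in enumerate(rows):
        if len(r.b0_freqs) != k_b0 or len(r.fa_freqs) != k_fa:
            raise ValueError(f"inconsistent row dimension at row {i} ({r.patient_id})")
    recs = [
        dict(zip(_header(k_b0, k_fa),
                 [r.patient_id, r.label, r.voxel_count, *r.b0_freqs, *r.fa_freqs]))
        for r in rows
    ]
    pd.DataFrame(recs).to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        fixed = ["patient_id", "label", "voxel_count"]
        if header[:3] != fixed:
            raise ValueError(f"malformed header at line 1: {header[:3]}")
        k_b0 = sum(c.startswith("b0_f") for c in header)
        k_fa = sum(c.startswith("fa_f") for c in header)
        if header != _header(k_b0, k_fa):
            raise ValueError("malformed header at line 1: unexpected column layout")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(",")
            if len(parts) != len(header):
                raise ValueError(
                    f"row length {len(parts)} != {len(header)} at line {lineno}")
            rows.append(FeatureRow(
                patient_id=parts[0], label=parts[1], voxel_count=int(parts[2]),
                b0_freqs=np.array([float(v) for v in parts[3:3 + k_b0]]),
                fa_freqs=np.array([float(v) for v in parts[3 + k_b0:]]),
            ))
    return rows
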