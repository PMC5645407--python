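"""Seeded, cached pipeline: simulate -> extract -> split -> learn-dict ->
featurize -> tune/train -> evaluate -> report.

Every stage reads its inputs from and writes its outputs to one run
directory; a stage whose outputs already exist is skipped, so a run is
restartable from any cached intermediate.  All randomness flows from the
named seeds in the configuration, and the run manifest records a SHA-256
hash of every artifact so end-to-end determinism is checkable byte for
byte.  The cohort split happens before dictionary learning: centroids,
standardizers and tuning only ever see training-cohort data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, feature_assembly as fa, lbp3d, neural_classifier as nc
from . import synthetic_cohort as sc
from . import texture_dictionary as td
from .volume_io import read_mask, read_volume

__all__ = ["PipelineConfig", "RunManifest", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "split", "learn_dict", "featurize",
          "train", "evaluate", "report")

FAST_TUNING = {"sizes": (2, 6), "decays": (1e-3, 1e-1)}
FAST_N_DIRS = 16
FAST_MAX_DICT_ROWS = 100_000


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str
    profile: str = "full"
    cohort: sc.CohortSpec = field(default_factory=sc.CohortSpec)
    lbp: lbp3d.LbpConfig = field(default_factory=lbp3d.LbpConfig)
    k: int = 50
    dict_seed: int = 0
    split_seed: int = 0
    tuning: nc.TuningGrid = field(default_factory=nc.TuningGrid)
    train_seed: int = 0
    max_dict_rows: int | None = None

    def __post_init__(self) -> None:
        if self.profile not in ("full", "fast"):
            raise ValueError("profile must be 'full' or 'fast'")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        cfg = dict(cfg)
        profile = cfg.get("profile", "full")
        cohort_kw = dict(cfg.get("cohort", {}))
        for key in ("grid_shape", "voxel_spacing_mm"):
            if key in cohort_kw:
                cohort_kw[key] = tuple(cohort_kw[key])
        if "texture_effect" in cohort_kw:
            cohort_kw["texture_effect"] = {
                ch: tuple(v) for ch, v in cohort_kw["texture_effect"].items()}
        lbp_kw = dict(cfg.get("lbp", {}))
        if "radii_mm" in lbp_kw:
            lbp_kw["radii_mm"] = tuple(lbp_kw["radii_mm"])
        tuning_kw = dict(cfg.get("tuning", {}))
        for key in ("sizes", "decays"):
            if key in tuning_kw:
                tuning_kw[key] = tuple(tuning_kw[key])
        max_rows = cfg.get("max_dict_rows")
        if profile == "fast":
            lbp_kw.setdefault("n_dirs", FAST_N_DIRS)
            tuning_kw.setdefault("sizes", FAST_TUNING["sizes"])
            tuning_kw.setdefault("decays", FAST_TUNING["decays"])
            if max_rows is None:
                max_rows = FAST_MAX_DICT_ROWS
        return cls(
            output_dir=str(cfg["output_dir"]),
            profile=profile,
            cohort=sc.CohortSpec(**cohort_kw),
            lbp=lbp3d.LbpConfig(**lbp_kw),
            k=int(cfg.get("k", 50)),
            dict_seed=int(cfg.get("dict_seed", 0)),
            split_seed=int(cfg.get("split_seed", 0)),
            tuning=nc.TuningGrid(**tuning_kw),
            train_seed=int(cfg.get("train_seed", 0)),
            max_dict_rows=max_rows,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def snapshot(self) -> dict:
        snap = asdict(self)
        snap["cohort"]["texture_effect"] = {
            ch: list(v) for ch, v in self.cohort.texture_effect.items()}
        return snap

    # --- paths -----------------------------------------------------------
    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    def path(self, name: str) -> Path:
        return self.out / name


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], seconds: float,
               cached: bool, extra: dict | None = None) -> None:
        self.stages[stage] = {
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(seconds, 3),
            "cached": cached,
            **(extra or {}),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "version": self.version, "stages": self.stages},
            indent=2, sort_keys=True))


# --- individual stages ----------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> list[Path]:
    cohort_dir = cfg.path("cohort")
    manifest = cohort_dir / "cohort.csv"
    if not manifest.exists():
        records = sc.sample_cohort(cfg.cohort)
        sc.write_cohort(records, cohort_dir)
    files = sorted(cohort_dir.glob("*.nii")) + [manifest]
    return files


def _load_cohort_table(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(cfg.path("cohort") / "cohort.csv")


def stage_extract(cfg: PipelineConfig) -> list[Path]:
    desc_dir = cfg.path("descriptors")
    desc_dir.mkdir(parents=True, exist_ok=True)
    sidecar = desc_dir / "lbp_config.json"
    table = _load_cohort_table(cfg)
    sampling = lbp3d.build_sampling(cfg.lbp.n_dirs, cfg.lbp.max_degree)
    outputs = []
    for _, row in table.iterrows():
        pid = row["patient_id"]
        out = desc_dir / f"{pid}.npz"
        outputs.append(out)
        if out.exists():
            continue
        mask, m_spacing = read_mask(cfg.path("cohort") / row["path_mask"])
        arrays = {}
        for channel in ("b0", "fa"):
            vol, spacing = read_volume(cfg.path("cohort") / row[f"path_{channel}"])
            if vol.shape != mask.shape or not np.allclose(spacing, m_spacing):
                raise ValueError(f"channel/mask geometry mismatch for patient {pid}")
            arrays[channel] = lbp3d.extract_tumor_descriptors(
                vol, mask, cfg.lbp, spacing_mm=spacing, sampling=sampling,
                patient_id=pid)
        np.savez_compressed(out, b0=arrays["b0"], fa=arrays["fa"])
    if not sidecar.exists():
        sidecar.write_text(json.dumps(
            {"fingerprint": cfg.lbp.fingerprint(),
             "radii_mm": list(cfg.lbp.radii_mm),
             "n_dirs": cfg.lbp.n_dirs, "max_degree": cfg.lbp.max_degree}))
    return outputs + [sidecar]


def stage_split(cfg: PipelineConfig) -> list[Path]:
    path = cfg.path("split.json")
    if not path.exists():
        ids = _load_cohort_table(cfg)["patient_id"].tolist()
        fa.split_ids(ids, cfg.split_seed).to_json(path)
    return [path]


def _descriptor_fingerprint(cfg: PipelineConfig) -> str:
    sidecar = cfg.path("descriptors") / "lbp_config.json"
    fp = json.loads(sidecar.read_text())["fingerprint"]
    if fp != cfg.lbp.fingerprint():
        raise ValueError("cached descriptors were computed with a different LBP config")
    return fp


def stage_learn_dict(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    split = fa.CohortSplit.from_json(cfg.path("split.json"))
    fp = _descriptor_fingerprint(cfg)
    outputs = []
    for channel in ("b0", "fa"):
        path = cfg.path(f"dict_{channel}.json")
        outputs.append(path)
        if path.exists():
            continue
        stacks = []
        for pid in split.training_ids:
            with np.load(cfg.path("descriptors") / f"{pid}.npz") as z:
                stacks.append(z[channel])
        X = np.vstack(stacks)
        if cfg.max_dict_rows is not None and len(X) > cfg.max_dict_rows:
            rng = np.random.default_rng(cfg.dict_seed)
            keep = rng.choice(len(X), size=cfg.max_dict_rows, replace=False)
            X = X[np.sort(keep)]
        dic = td.learn_dictionary(X, k=cfg.k, seed=cfg.dict_seed,
                                  channel=channel, config_fingerprint=fp)
        dic.to_json(path)
    return outputs, {"input_ids": list(split.training_ids)}


def stage_featurize(cfg: PipelineConfig) -> list[Path]:
    path = cfg.path("features.csv")
    if not path.exists():
        fp = _descriptor_fingerprint(cfg)
        dict_b0 = td.TextureDictionary.from_json(cfg.path("dict_b0.json"))
        dict_fa = td.TextureDictionary.from_json(cfg.path("dict_fa.json"))
        table = _load_cohort_table(cfg)
        rows = []
        for _, row in table.iterrows():
            pid = row["patient_id"]
            with np.load(cfg.path("descriptors") / f"{pid}.npz") as z:
                desc = {ch: z[ch] for ch in ("b0", "fa")}
            mask, _ = read_mask(cfg.path("cohort") / row["path_mask"])
            freqs = {
                ch: td.histogram(td.assign(desc[ch], dic, config_fingerprint=fp), cfg.k)
                for ch, dic in (("b0", dict_b0), ("fa", dict_fa))
            }
            rows.append(fa.FeatureRow(
                patient_id=pid, label=row["genotype"],
                voxel_count=int(mask.sum()),
                b0_freqs=freqs["b0"], fa_freqs=freqs["fa"]))
        fa.write_feature_table(rows, path)
    return [path]


def _split_rows(cfg: PipelineConfig):
    rows = fa.read_feature_table(cfg.path("features.csv"))
    split = fa.CohortSplit.from_json(cfg.path("split.json"))
    by_id = {r.patient_id: r for r in rows}
    train_rows = [by_id[i] for i in split.training_ids]
    val_rows = [by_id[i] for i in split.validation_ids]
    return train_rows, val_rows, split


def stage_train(cfg: PipelineConfig) -> tuple[list[Path], dict]:
    model_path = cfg.path("model.json")
    tuning_path = cfg.path("tuning.json")
    train_rows, _, split = _split_rows(cfg)
    if not (model_path.exists() and tuning_path.exists()):
        size, decay, acc = nc.grid_search(train_rows, cfg.tuning)
        model = nc.train(train_rows, size, decay, seed=cfg.train_seed)
        model.to_json(model_path, extra={
            "tuning": {"sizes": list(cfg.tuning.sizes), "decays": list(cfg.tuning.decays),
                       "resampling": f"{cfg.tuning.n_repeats}x stratified "
                                     f"{cfg.tuning.n_splits}-fold CV",
                       "seed": cfg.tuning.seed},
            "penalty": "L2 on connection weights, biases excluded",
        })
        tuning_path.write_text(json.dumps({
            "sizes": list(cfg.tuning.sizes), "decays": list(cfg.tuning.decays),
            "accuracy": acc.tolist(), "best_size": size, "best_decay": decay}))
    return [model_path, tuning_path], {"input_ids": list(split.training_ids)}


def _accuracy(labels, truth) -> float:
    return float(np.mean([a == b for a, b in zip(labels, truth)]))


def stage_evaluate(cfg: PipelineConfig) -> list[Path]:
    pred_path = cfg.path("predictions.csv")
    eval_path = cfg.path("evaluation.json")
    if not (pred_path.exists() and eval_path.exists()):
        model = nc.NetworkModel.from_json(cfg.path("model.json"))
        train_rows, val_rows, _ = _split_rows(cfg)
        metrics = {"size": model.size, "decay": model.decay}
        preds = []
        for name, rows in (("training", train_rows), ("validation", val_rows)):
            labels, probs = nc.predict_labels(model, rows)
            truth = [r.label for r in rows]
            y = np.array([t == "mutant" for t in truth])
            metrics[f"{name}_accuracy"] = _accuracy(labels, truth)
            metrics[f"{name}_auc"] = (
                cohort_stats.roc_auc(probs, y).auc if 0 < y.sum() < len(y) else None)
            for r, lab, p in zip(rows, labels, probs):
                preds.append({"cohort": name, "patient_id": r.patient_id,
                              "label": r.label, "predicted": lab,
                              "p_mutant": f"{p:.12g}"})
        # no-information-rate test in the validation cohort
        val_truth = np.array([r.label == "mutant" for r in val_rows])
        nir = max(val_truth.mean(), 1 - val_truth.mean())
        correct = int(round(metrics["validation_accuracy"] * len(val_rows)))
        metrics["no_information_rate"] = float(nir)
        metrics["nir_binomial_p"] = cohort_stats.binomial_exact_greater(
            correct, len(val_rows), nir)
        # tumor-size analyses on the full cohort
        all_rows = train_rows + val_rows
        sizes = np.array([r.voxel_count for r in all_rows], dtype=float)
        is_mut = np.array([r.label == "mutant" for r in all_rows])
        metrics["size_wilcoxon_p"] = (
            cohort_stats.wilcoxon_rank_sum(sizes[is_mut], sizes[~is_mut])
            if 0 < is_mut.sum() < len(is_mut) else None)
        for name, rows in (("training", train_rows), ("validation", val_rows)):
            xs = np.array([r.voxel_count for r in rows], dtype=float)
            ys = np.array([r.label == "mutant" for r in rows])
            if 0 < ys.sum() < len(ys):
                _, auc, _ = cohort_stats.logistic_univariate(xs, ys)
            else:
                auc = None
            metrics[f"size_only_{name}_auc"] = auc
        # genotype-by-cohort contingency (Table-1 style comparison)
        tab = [
            [int(sum(r.label == "mutant" for r in train_rows)),
             int(sum(r.label == "mutant" for r in val_rows))],
            [int(sum(r.label != "mutant" for r in train_rows)),
             int(sum(r.label != "mutant" for r in val_rows))],
        ]
        metrics["genotype_table"] = tab
        margins_ok = all(sum(r) > 0 for r in tab) and all(
            tab[0][j] + tab[1][j] > 0 for j in (0, 1))
        metrics["genotype_fisher_p"] = (
            cohort_stats.fisher_exact_2x2(tab) if margins_ok else None)
        pd.DataFrame(preds).to_csv(pred_path, index=False)
        eval_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
    return [pred_path, eval_path]


def stage_report(cfg: PipelineConfig) -> list[Path]:
    report_json = cfg.path("report.json")
    report_md = cfg.path("report.md")
    pca_csv = cfg.path("pca_scores.csv")
    importance_txt = cfg.path("importance.txt")
    outputs = [report_json, report_md, pca_csv, importance_txt]
    if all(p.exists() for p in outputs):
        return outputs
    metrics = json.loads(cfg.path("evaluation.json").read_text())
    model = nc.NetworkModel.from_json(cfg.path("model.json"))
    train_rows, val_rows, _ = _split_rows(cfg)
    names = nc.feature_names(cfg.k, cfg.k)
    imp = nc.garson_importance(model, names).sort_values(
        "importance_pct", ascending=False, ignore_index=True)
    top10 = imp.head(10)
    with open(importance_txt, "w") as fh:
        fh.write("Top 10 features by Garson importance\n")
        for _, r in top10.iterrows():
            fh.write(f"{r['feature']:>12s}  {r['importance_pct']:7.3f}%\n")
        fh.write("\nFull importance table\n")
        for _, r in imp.iterrows():
            fh.write(f"{r['feature']:>12s}  {r['importance_pct']:7.3f}%\n")
    # PCA of the top-10 features in the validation cohort
    top_idx = [names.index(f) for f in top10["feature"]]
    X = np.stack([r.features for r in val_rows])[:, top_idx]
    Xs = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
    n_comp = min(2, len(val_rows) - 1, Xs.shape[1])
    scores, frac = cohort_stats.pca_scores(Xs, n_comp)
    pca_df = pd.DataFrame({
        "patient_id": [r.patient_id for r in val_rows],
        "label": [r.label for r in val_rows],
        **{f"pc{i + 1}": scores[:, i] for i in range(n_comp)},
    })
    pca_df.to_csv(pca_csv, index=False, float_format="%.12g")
    report = {
        "metrics": metrics,
        "top10_features": top10.to_dict(orient="records"),
        "pca_explained_fraction": frac.tolist(),
    }
    report_json.write_text(json.dumps(report, indent=2, sort_keys=True))
    def fmt(key: str, spec: str = ".3f") -> str:
        v = metrics.get(key)
        return format(v, spec) if v is not None else "n/a"

    md = [
        "# Radiogenomic pipeline report", "",
        f"- Final network: {model.size} hidden units, decay {model.decay:g}",
        f"- Training accuracy: {fmt('training_accuracy')} (AUC {fmt('training_auc')})",
        f"- Validation accuracy: {fmt('validation_accuracy')} "
        f"(AUC {fmt('validation_auc')})",
        f"- No-information rate {fmt('no_information_rate')}; "
        f"exact binomial p = {fmt('nir_binomial_p', '.4g')}",
        f"- Tumor size, mutant vs wild type: rank-sum p = "
        f"{fmt('size_wilcoxon_p', '.4g')}",
        f"- Size-only logistic AUC: training {fmt('size_only_training_auc')}, "
        f"validation {fmt('size_only_validation_auc')}",
        f"- Genotype-by-cohort Fisher p = {fmt('genotype_fisher_p')}", "",
        "## Top 10 features (Garson importance)", "",
    ]
    md += [f"1. {r['feature']} ({r['importance_pct']:.2f}%)"
           for _, r in top10.iterrows()]
    report_md.write_text("\n".join(md) + "\n")
    return outputs


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, reusing cached outputs; returns the manifest."""
    from . import __version__

    config.out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)
    runners = {
        "simulate": stage_simulate, "extract": stage_extract, "split": stage_split,
        "learn_dict": stage_learn_dict, "featurize": stage_featurize,
        "train": stage_train, "evaluate": stage_evaluate, "report": stage_report,
    }
    for stage in STAGES:
        t0 = time.perf_counter()
        wall0 = time.time()
        try:
            result = runners[stage](config)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        if isinstance(result, tuple):
            outputs, extra = result
        else:
            outputs, extra = result, None
        dt = time.perf_counter() - t0
        cached = all(p.stat().st_mtime < wall0 for p in outputs)
        manifest.record(stage, outputs, dt, cached=cached, extra=extra)
        logger.info("stage %-10s %6.2fs  %d artifact(s)", stage, dt, len(outputs))
    manifest.to_json(config.path("manifest.json"))
    return manifest
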