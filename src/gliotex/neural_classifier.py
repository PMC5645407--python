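"""Single-hidden-layer neural network for genotype prediction.

The classifier is deliberately small: one hidden layer of logistic units and
a single logistic output neuron, trained by full-batch quasi-Newton
minimization of the cross-entropy with an L2 weight-decay penalty on all
connection weights (biases unpenalized).  The two tuning parameters — hidden
layer ``size`` and ``decay`` — are chosen by grid search with repeated
stratified cross-validation on the training cohort, and per-feature
relevance of the final network is summarized with Garson's algorithm.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import RepeatedStratifiedKFold

from .feature_assembly import FeatureRow, FeatureTable

__all__ = ["NetworkModel", "TuningGrid", "forward", "train",
           "grid_search", "predict_labels", "garson_importance", "feature_names"]

logger = logging.getLogger(__name__)

MUTANT = "mutant"

DEFAULT_SIZES = (2, 4, 6, 8, 10)
DEFAULT_DECAYS = (1e-4, 1e-3, 1e-2, 1e-1)


@dataclass(frozen=True)
class NetworkModel:
    """Trained network: input standardizer plus the two weight layers.

    ``W_hidden`` is ``(d + 1, size)`` with the bias in row 0; ``w_out`` has
    length ``size + 1`` with the bias first.
    """

    size: int
    decay: float
    input_mean: np.ndarray
    input_sd: np.ndarray
    W_hidden: np.ndarray
    w_out: np.ndarray
    train_seed: int
    converged: bool = True

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        payload = {
            "size": self.size, "decay": self.decay, "train_seed": self.train_seed,
            "converged": self.converged,
            "input_mean": self.input_mean.tolist(),
            "input_sd": self.input_sd.tolist(),
            "W_hidden": [[w.hex() for w in row] for row in self.W_hidden.astype(float)],
            "w_out": [w.hex() for w in self.w_out.astype(float)],
        }
        if extra:
            payload["metadata"] = extra
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkModel":
        p = json.loads(Path(path).read_text())
        return cls(
            size=p["size"], decay=p["decay"], train_seed=p["train_seed"],
            converged=p["converged"],
            input_mean=np.array(p["input_mean"]),
            input_sd=np.array(p["input_sd"]),
            W_hidden=np.array([[float.fromhex(w) for w in row] for row in p["W_hidden"]]),
            w_out=np.array([float.fromhex(w) for w in p["w_out"]]),
        )


@dataclass(frozen=True)
class TuningGrid:
    sizes: tuple[int, ...] = DEFAULT_SIZES
    decays: tuple[float, ...] = DEFAULT_DECAYS
    n_splits: int = 5
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sizes or not self.decays:
            raise ValueError("tuning grid must be non-empty")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _feature_matrix(rows: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([r.features for r in rows])
    y = np.array([1.0 if r.label == MUTANT else 0.0 for r in rows])
    return X, y


def _forward_logits(Xs: np.ndarray, W: np.ndarray, v: np.ndarray):
    H = _sigmoid(Xs @ W[1:] + W[0])
    z = H @ v[1:] + v[0]
    return H, z


def forward(model: NetworkModel, feature_row: FeatureRow | np.ndarray) -> float:
    """Probability of the mutant genotype for one feature row."""
    x = feature_row.features if isinstance(feature_row, FeatureRow) else np.asarray(feature_row, float)
    if x.shape[0] != model.input_mean.shape[0]:
        raise ValueError("feature dimension mismatch")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite features")
    xs = (x - model.input_mean) / model.input_sd
    _, z = _forward_logits(xs[None, :], model.W_hidden, model.w_out)
    return float(_sigmoid(z)[0])


def _loss_grad(theta, Xs, y, size, decay):
    d = Xs.shape[1]
    W = theta[: (d + 1) * size].reshape(d + 1, size)
    v = theta[(d + 1) * size:]
    H, z = _forward_logits(Xs, W, v)
    # cross-entropy via logaddexp for stability
    loss = np.sum(np.logaddexp(0.0, z) - y * z)
    loss += decay * (np.sum(W[1:] ** 2) + np.sum(v[1:] ** 2))
    dz = _sigmoid(z) - y  # (n,)
    gv = np.concatenate([[dz.sum()], H.T @ dz + 2.0 * decay * v[1:]])
    dH = dz[:, None] * v[None, 1:] * H * (1.0 - H)  # (n, size)
    gW = np.vstack([dH.sum(axis=0), Xs.T @ dH + 2.0 * decay * W[1:]])
    return loss, np.concatenate([gW.ravel(), gv])


def train(rows: FeatureTable, size: int, decay: float, seed: int = 0) -> NetworkModel:
    """Fit the network on the given rows.

    Standardizes inputs with the training rows' mean/SD (zero-variance
    features get SD 1), initializes all weights uniform(-0.5, 0.5) from the
    seed, and minimizes the penalized cross-entropy with L-BFGS (at most 500
    iterations, gradient tolerance 1e-6).  Non-convergence returns the best
    iterate with a logged warning.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    X, y = _feature_matrix(rows)
    if len(np.unique(y)) < 2:
        raise ValueError("training rows contain a single class")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    d = X.shape[1]
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-0.5, 0.5, size=(d + 1) * size + size + 1)
    res = minimize(
        _loss_grad, theta0, args=(Xs, y, size, decay), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "gtol": 1e-6, "ftol": 1e-12},
    )
    if not res.success and np.linalg.norm(res.jac, np.inf) > 1e-4:
        logger.warning("network training did not fully converge: %s", res.message)
    W = res.x[: (d + 1) * size].reshape(d + 1, size)
    v = res.x[(d + 1) * size:]
    return NetworkModel(
        size=size, decay=decay, input_mean=mean, input_sd=sd,
        W_hidden=W, w_out=v, train_seed=seed,
        converged=bool(res.success or np.linalg.norm(res.jac, np.inf) <= 1e-4),
    )


def predict_labels(model: NetworkModel, rows: FeatureTable, threshold: float = 0.5):
    """Predicted labels and mutant probabilities; ``p >= threshold`` → mutant."""
    probs = np.array([forward(model, r) for r in rows])
    labels = np.where(probs >= threshold, "mutant", "wildtype")
    return labels.tolist(), probs


def _fold_accuracy(train_rows, test_rows, size, decay, seed):
    model = train(train_rows, size, decay, seed=seed)
    labels, _ = predict_labels(model, test_rows)
    truth = [r.label for r in test_rows]
    return float(np.mean([a == b for a, b in zip(labels, truth)]))


def grid_search(rows: FeatureTable, grid: TuningGrid):
    """Pick (size, decay) by mean accuracy over repeated stratified 5-fold CV.

    Ties resolve to the smaller size, then the larger decay.  Returns the
    best size, best decay and the full accuracy table (sizes x decays).
    """
    y = np.array([1 if r.label == MUTANT else 0 for r in rows])
    if len(np.unique(y)) < 2:
        raise ValueError("grid search needs both classes")
    folds = None
    for attempt in range(10):
        cv = RepeatedStratifiedKFold(
            n_splits=grid.n_splits, n_repeats=grid.n_repeats,
            random_state=grid.seed + attempt)
        candidate = list(cv.split(np.zeros(len(rows)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in candidate):
            folds = candidate
            break
    if folds is None:
        raise ValueError("could not draw folds with both classes in every training fold")
    acc = np.zeros((len(grid.sizes), len(grid.decays)))
    for i, size in enumerate(grid.sizes):
        for j, decay in enumerate(grid.decays):
            scores = [
                _fold_accuracy(
                    [rows[t] for t in tr], [rows[t] for t in te], size, decay,
                    seed=grid.seed * 1000 + f_idx,
                )
                for f_idx, (tr, te) in enumerate(folds)
            ]
            acc[i, j] = float(np.mean(scores))
    # argmax with ties -> smaller size, then larger decay
    best = (0, 0)
    for i in range(len(grid.sizes)):
        for j in range(len(grid.decays)):
            bi, bj = best
            if acc[i, j] > acc[bi, bj] + 1e-12:
                best = (i, j)
            elif abs(acc[i, j] - acc[bi, bj]) <= 1e-12:
                if (grid.sizes[i], -grid.decays[j]) < (grid.sizes[bi], -grid.decays[bj]):
                    best = (i, j)
    return grid.sizes[best[0]], grid.decays[best[1]], acc


def garson_importance(model: NetworkModel, feature_names: list[str] | None = None):
    """Garson relative importance of each input, in percent (sums to 100).

    For input i with hidden-layer weights W (biases excluded) and output
    weights v:  Q_i = sum_j |W_ij| |v_j| / sum_k |W_kj|, normalized to 100%.
    """
    import pandas as pd

    W = np.abs(model.W_hidden[1:])  # (d, size)
    v = np.abs(model.w_out[1:])  # (size,)
    col = W.sum(axis=0)
    if np.all(col * v == 0):
        raise ValueError("all-zero hidden weights: importance undefined")
    contrib = W * v[None, :]
    nz = col > 0
    Q = (contrib[:, nz] / col[None, nz]).sum(axis=1)
    imp = 100.0 * Q / Q.sum()
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(W.shape[0])]
    return pd.DataFrame({"feature": feature_names, "importance_pct": imp})


def feature_names(k_b0: int = 50, k_fa: int = 50) -> list[str]:
    return (
        ["voxel_count"]
        + [f"b0_f{i + 1:02d}" for i in range(k_b0)]
        + [f"fa_f{i + 1:02d}" for i in range(k_fa)]
    )
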