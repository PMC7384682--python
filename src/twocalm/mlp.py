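"""A small MLP that classifies a sample pair as similar or dissimilar.

Architecture is fixed: 11 inputs (the cluster dimension d plus ten
p-values), one hidden layer of 20 tanh units, two softmax outputs read
as the posterior probabilities of "similar" and "dissimilar".  Training
minimises cross-entropy with full-batch Adam and early stopping on a
held-out split.  The network is written in plain numpy so its gradients
can be checked analytically against finite differences.

Feature vector per (dimension, resample) cell:

    (d, p1..p4)   KS/Wilcoxon p-values on density and curvature (per cell)
    (p5..p10)     directional mean-cross p-values on average density,
                  average curvature and Ripley K (per dimension,
                  broadcast across resamples)

Only d is standardised (z-score, parameters stored with the model);
p-values already live in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pipeline import ComparisonReport

__all__ = ["MLPModel", "build_feature_vectors", "train_mlp", "classify_pair", "save_model", "load_model"]

N_INPUT = 11
N_HIDDEN = 20
N_OUTPUT = 2
_SCHEMA = 1


def build_feature_vectors(report: ComparisonReport) -> np.ndarray:
    """L*M feature vectors (d, p1..p10) from a comparison report.

    p1..p4 come from the per-cell KD/WD/KC/WC matrices, p5..p10 from the
    per-dimension mean-cross curves broadcast across resamples.  Rows
    with any missing (nan) entry are dropped.
    """
    m = report.matrices
    if report.mean_cross_curves is None:
        raise ValueError("report lacks mean-cross curves (M=1 run); cannot build p5..p10")
    mc = report.mean_cross_curves
    for name in ("p5", "p6", "p7", "p8", "p9", "p10"):
        if name not in mc:
            raise ValueError(f"missing p-value family {name!r} in report")
    L, M = m.KD.shape
    d_col = np.repeat(report.grid.dims, M)
    cells = [m.KD.ravel(), m.WD.ravel(), m.KC.ravel(), m.WC.ravel()]
    broad = [np.repeat(mc[name], M) for name in ("p5", "p6", "p7", "p8", "p9", "p10")]
    X = np.column_stack([d_col] + cells + broad)
    X = X[np.isfinite(X).all(axis=1)]
    if len(X) == 0:
        raise ValueError("no complete feature vectors (all rows had missing values)")
    return X


@dataclass
class MLPModel:
    """Weights, standardisation parameters and training metadata."""

    W1: np.ndarray  # (11, 20)
    b1: np.ndarray  # (20,)
    W2: np.ndarray  # (20, 2)
    b2: np.ndarray  # (2,)
    d_mean: float
    d_std: float
    loss_curve: list = field(default_factory=list)
    seed: int = 0

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        Z = np.array(X, dtype=float)
        Z[:, 0] = (Z[:, 0] - self.d_mean) / self.d_std
        return Z

    def forward(self, X: np.ndarray, standardise: bool = True) -> np.ndarray:
        """Softmax posteriors, shape (n, 2); column 0 is P(similar)."""
        Z = self._standardise(X) if standardise else np.asarray(X, dtype=float)
        H = np.tanh(Z @ self.W1 + self.b1)
        logits = H @ self.W2 + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def _init_params(rng: np.random.Generator):
    W1 = rng.normal(0.0, np.sqrt(1.0 / N_INPUT), size=(N_INPUT, N_HIDDEN))
    b1 = np.zeros(N_HIDDEN)
    W2 = rng.normal(0.0, np.sqrt(1.0 / N_HIDDEN), size=(N_HIDDEN, N_OUTPUT))
    b2 = np.zeros(N_OUTPUT)
    return W1, b1, W2, b2


def loss_and_grad(params, X: np.ndarray, Y: np.ndarray):
    """Cross-entropy loss and analytic gradients (used by training and tests).

    ``params`` is (W1, b1, W2, b2); ``Y`` is one-hot (n, 2).  X is
    assumed already standardised.
    """
    W1, b1, W2, b2 = params
    n = len(X)
    H = np.tanh(X @ W1 + b1)
    logits = H @ W2 + b2
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    P = e / e.sum(axis=1, keepdims=True)
    loss = -np.sum(Y * np.log(np.clip(P, 1e-300, None))) / n
    dlogits = (P - Y) / n
    gW2 = H.T @ dlogits
    gb2 = dlogits.sum(axis=0)
    dH = dlogits @ W2.T
    dpre = dH * (1.0 - H**2)
    gW1 = X.T @ dpre
    gb1 = dpre.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def train_mlp(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    lr: float = 0.01,
    max_epochs: int = 2000,
    val_fraction: float = 0.2,
    patience: int = 100,
) -> MLPModel:
    """Train the 11-20-2 network on labelled feature vectors.

    ``y`` holds class indices (0 = similar, 1 = dissimilar) or one-hot
    rows.  Full-batch Adam with early stopping on a held-out split;
    reproducible given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.ndim == 2:
        y = y.argmax(axis=1)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training needs both classes present")
    if X.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT} features, got {X.shape[1]}")
    Y = np.eye(N_OUTPUT)[y.astype(int)]

    d_mean = float(X[:, 0].mean())
    d_std = float(X[:, 0].std()) or 1.0
    Z = X.copy()
    Z[:, 0] = (Z[:, 0] - d_mean) / d_std

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(Z))
    n_val = max(1, int(val_fraction * len(Z)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("not enough data to hold out a validation split")
    Ztr, Ytr = Z[tr_idx], Y[tr_idx]
    Zva, Yva = Z[val_idx], Y[val_idx]

    params = list(_init_params(rng))
    mom = [np.zeros_like(p) for p in params]
    vel = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_val = np.inf
    best_params = [p.copy() for p in params]
    since_best = 0
    loss_curve = []
    for t in range(1, max_epochs + 1):
        loss, grads = loss_and_grad(params, Ztr, Ytr)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at epoch {t}; loss trace: {loss_curve[-5:]}")
        for j, g in enumerate(grads):
            mom[j] = beta1 * mom[j] + (1 - beta1) * g
            vel[j] = beta2 * vel[j] + (1 - beta2) * g**2
            mhat = mom[j] / (1 - beta1**t)
            vhat = vel[j] / (1 - beta2**t)
            params[j] = params[j] - lr * mhat / (np.sqrt(vhat) + eps)
        val_loss, _ = loss_and_grad(params, Zva, Yva)
        loss_curve.append(float(val_loss))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    W1, b1, W2, b2 = best_params
    return MLPModel(W1=W1, b1=b1, W2=W2, b2=b2, d_mean=d_mean, d_std=d_std, loss_curve=loss_curve, seed=seed)


def classify_pair(model: MLPModel, vectors: np.ndarray, aggregate: str = "mean") -> float:
    """Posterior probability that the pair is similar.

    The per-vector softmax posteriors (first head) are aggregated over
    all L*M vectors by mean (default) or median.  Posteriors in
    (0.4, 0.6) are best treated as inconclusive: re-sample with more
    points before deciding.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.shape[1] != N_INPUT:
        raise ValueError(f"expected {N_INPUT}-dimensional vectors, got {vectors.shape[1]}")
    post = model.forward(vectors)[:, 0]
    if aggregate == "mean":
        return float(post.mean())
    if aggregate == "median":
        return float(np.median(post))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def save_model(model: MLPModel, path) -> None:
    """Serialise the model (architecture, standardisation, weights) as JSON."""
    doc = {
        "schema_version": _SCHEMA,
        "architecture": [N_INPUT, N_HIDDEN, N_OUTPUT],
        "activation": ["tanh", "softmax"],
        "d_mean": model.d_mean,
        "d_std": model.d_std,
        "seed": model.seed,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "loss_curve": model.loss_curve,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> MLPModel:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted model file {path}") from exc
    if not isinstance(doc, dict) or doc.get("schema_version") != _SCHEMA:
        raise ValueError(f"unsupported or corrupted model file {path}")
    if doc.get("architecture") != [N_INPUT, N_HIDDEN, N_OUTPUT]:
        raise ValueError("model architecture mismatch")
    return MLPModel(
        W1=np.array(doc["W1"]),
        b1=np.array(doc["b1"]),
        W2=np.array(doc["W2"]),
        b2=np.array(doc["b2"]),
        d_mean=doc["d_mean"],
        d_std=doc["d_std"],
        loss_curve=doc.get("loss_curve", []),
        seed=doc.get("seed", 0),
    )
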