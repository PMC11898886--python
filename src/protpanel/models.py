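"""Base decision models: hierarchical two-stage kNN and a linear two-layer net.

Both expose calibrated three-class posteriors P(y|x) over (healthy,
localized, metastatic), which the active-learning loop needs for
least-confidence querying.

The hierarchical model splits the problem: stage 1 votes healthy vs
non-healthy with a kNN on z-scored features; stage 2, trained only on
non-healthy labeled samples, votes localized vs metastatic.  The posterior
is the product of the two vote fractions, so P(localized) + P(metastatic)
= 1 - P(healthy) holds exactly.

The neural model is two affine layers with identity (linear) hidden
activation — the composed input->output map is itself affine — followed by
a normalized-exponential output so posteriors live on the simplex.  It is
trained from scratch by full-batch gradient descent on cross-entropy.

kNN distances use Euclidean metric on per-feature z-scores fitted on the
current labeled set; equidistant ties at the k-th neighbor resolve to the
smallest training-sample index, which makes every prediction deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GROUPS, PanelDefinition, default_panel

CLASS_INDEX = {g: i for i, g in enumerate(GROUPS)}


@dataclass(frozen=True)
class ClassPosterior:
    """Probabilities over (healthy, localized, metastatic)."""

    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (3,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"invalid posterior {p}")
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, 1.0))

    @property
    def predicted_class(self) -> str:
        # np.argmax takes the first maximum -> ties break by class order
        return GROUPS[int(np.argmax(self.probabilities))]

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())


# -- standardization ---------------------------------------------------------


@dataclass
class Standardizer:
    """Per-feature z-scoring fitted on the labeled set.

    Zero-variance features are dropped from the distance computation (with a
    warning) rather than dividing by zero.
    """

    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # boolean mask over features

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        kept = sd > 0
        if not kept.all():
            warnings.warn(
                f"dropping {int((~kept).sum())} zero-variance feature(s) "
                "from the distance",
                stacklevel=2,
            )
        if not kept.any():
            # all features degenerate: keep them unscaled so distances are 0
            kept = np.ones_like(kept)
            sd = np.ones_like(sd)
        return cls(mean=mean, sd=np.where(sd > 0, sd, 1.0), kept=kept)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        return Z[:, self.kept]


# -- kNN core ----------------------------------------------------------------


def _kneighbors(X_train: np.ndarray, x: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest training rows; ties by smallest index."""
    d2 = ((X_train - x) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(d2.size), d2))  # distance, then index
    return order[:k]


def _clip_odd(k: int, n: int, what: str) -> int:
    """Largest feasible odd k <= n, warning if clipped."""
    if k > n:
        k_new = n if n % 2 == 1 else n - 1
        k_new = max(k_new, 1)
        warnings.warn(f"{what}: k={k} exceeds {n} samples; clipped to {k_new}",
                      stacklevel=3)
        return k_new
    return k


# -- hierarchical kNN --------------------------------------------------------


@dataclass
class HierarchicalKnnModel:
    k1: int
    k2: int | None
    scaler: Standardizer
    X1: np.ndarray          # all labeled samples, z-scored
    healthy1: np.ndarray    # bool per row of X1
    X2: np.ndarray | None   # non-healthy labeled samples, z-scored
    localized2: np.ndarray | None
    feature_names: list[str] = field(default_factory=list)

    def predict(self, x: np.ndarray) -> ClassPosterior:
        x = np.asarray(x, dtype=float)
        if x.shape != (len(self.feature_names),):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {x.shape}"
            )
        z = self.scaler.transform(x[None, :])[0]
        nn1 = _kneighbors(self.X1, z, self.k1)
        p_healthy = float(self.healthy1[nn1].mean())
        if self.X2 is None or self.k2 is None:
            p_loc = 0.5 * (1.0 - p_healthy)
        else:
            nn2 = _kneighbors(self.X2, z, self.k2)
            p_loc = (1.0 - p_healthy) * float(self.localized2[nn2].mean())
        p_met = 1.0 - p_healthy - p_loc
        return ClassPosterior(np.array([p_healthy, p_loc, p_met]))

    def predict_table(self, X: np.ndarray) -> np.ndarray:
        return np.vstack([self.predict(row).probabilities for row in X])

    def to_dict(self) -> dict:
        return {
            "kind": "hierarchical_knn",
            "k1": self.k1,
            "k2": self.k2,
            "feature_names": self.feature_names,
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "sd": self.scaler.sd.tolist(),
                "kept": self.scaler.kept.tolist(),
            },
            "X1": self.X1.tolist(),
            "healthy1": self.healthy1.tolist(),
            "X2": None if self.X2 is None else self.X2.tolist(),
            "localized2": None if self.localized2 is None else self.localized2.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HierarchicalKnnModel":
        return cls(
            k1=d["k1"],
            k2=d["k2"],
            scaler=Standardizer(
                mean=np.array(d["scaler"]["mean"]),
                sd=np.array(d["scaler"]["sd"]),
                kept=np.array(d["scaler"]["kept"], dtype=bool),
            ),
            X1=np.array(d["X1"]),
            healthy1=np.array(d["healthy1"], dtype=bool),
            X2=None if d["X2"] is None else np.array(d["X2"]),
            localized2=None
            if d["localized2"] is None
            else np.array(d["localized2"], dtype=bool),
            feature_names=list(d["feature_names"]),
        )


def fit_hierarchical(
    labeled: pd.DataFrame, k: int = 5, panel: PanelDefinition | None = None
) -> HierarchicalKnnModel:
    """Fit both kNN stages on the labeled table.

    ``k`` must be odd (vote ties).  If k exceeds a stage's training size it
    is clipped down to the largest odd feasible value with a warning.  When
    fewer than two non-healthy classes are present, stage 2 is absent and
    the model splits the non-healthy mass uniformly.
    """
    panel = panel if panel is not None else default_panel()
    if len(labeled) == 0:
        raise ValueError("empty labeled set")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be odd and >= 1")
    X = labeled[panel.columns].to_numpy(float)
    groups = labeled["group"].to_numpy()
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    healthy = groups == "healthy"
    k1 = _clip_odd(k, len(Z), "stage 1")

    nonh = ~healthy
    if nonh.sum() > 0 and len(set(groups[nonh])) == 2:
        X2 = Z[nonh]
        localized2 = groups[nonh] == "localized"
        k2 = _clip_odd(k, len(X2), "stage 2")
    else:
        X2, localized2, k2 = None, None, None
    return HierarchicalKnnModel(
        k1=k1, k2=k2, scaler=scaler, X1=Z, healthy1=healthy,
        X2=X2, localized2=localized2, feature_names=panel.columns,
    )


# -- two-layer linear-activation network -------------------------------------


@dataclass
class NetHyper:
    hidden: int = 8
    learning_rate: float = 0.1
    epochs: int = 800
    init_scale: float = 0.1


@dataclass
class TwoLayerNetModel:
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    scaler: Standardizer
    hyper: NetHyper
    feature_names: list[str] = field(default_factory=list)

    def _logits(self, Z: np.ndarray) -> np.ndarray:
        return (Z @ self.W1 + self.b1) @ self.W2 + self.b2

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return _softmax(self._logits(self.scaler.transform(X)))

    def predict(self, x: np.ndarray) -> ClassPosterior:
        return ClassPosterior(self.predict_matrix(np.asarray(x)[None, :])[0])

    def predict_table(self, X: np.ndarray) -> np.ndarray:
        return self.predict_matrix(X)

    def to_dict(self) -> dict:
        return {
            "kind": "two_layer_nn",
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "W2": self.W2.tolist(), "b2": self.b2.tolist(),
            "feature_names": self.feature_names,
            "scaler": {
                "mean": self.scaler.mean.tolist(),
                "sd": self.scaler.sd.tolist(),
                "kept": self.scaler.kept.tolist(),
            },
            "hyper": {
                "hidden": self.hyper.hidden,
                "learning_rate": self.hyper.learning_rate,
                "epochs": self.hyper.epochs,
                "init_scale": self.hyper.init_scale,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoLayerNetModel":
        return cls(
            W1=np.array(d["W1"]), b1=np.array(d["b1"]),
            W2=np.array(d["W2"]), b2=np.array(d["b2"]),
            scaler=Standardizer(
                mean=np.array(d["scaler"]["mean"]),
                sd=np.array(d["scaler"]["sd"]),
                kept=np.array(d["scaler"]["kept"], dtype=bool),
            ),
            hyper=NetHyper(**d["hyper"]),
            feature_names=list(d["feature_names"]),
        )


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def fit_nn(
    labeled: pd.DataFrame,
    hyper: NetHyper | None = None,
    rng: np.random.Generator | None = None,
    panel: PanelDefinition | None = None,
) -> TwoLayerNetModel:
    """Train the linear two-layer net by full-batch gradient descent.

    Weights are initialized from ``rng`` (identical rng state + data gives
    identical weights).  With a single class in the labels, training is
    skipped and the output bias pins that class (degenerate limit).
    """
    panel = panel if panel is not None else default_panel()
    hyper = hyper if hyper is not None else NetHyper()
    rng = rng if rng is not None else np.random.default_rng(0)
    if len(labeled) == 0:
        raise ValueError("empty labeled set")

    X = labeled[panel.columns].to_numpy(float)
    groups = labeled["group"].to_numpy()
    scaler = Standardizer.fit(X)
    Z = scaler.transform(X)
    d = Z.shape[1]
    y = np.array([CLASS_INDEX[g] for g in groups])
    Y = np.eye(3)[y]

    W1 = rng.normal(0.0, hyper.init_scale, size=(d, hyper.hidden))
    b1 = np.zeros(hyper.hidden)
    W2 = rng.normal(0.0, hyper.init_scale, size=(hyper.hidden, 3))
    b2 = np.zeros(3)

    if len(set(groups)) == 1:
        # single-class degenerate limit: pin the class via the output bias
        W1[:], W2[:] = 0.0, 0.0
        b2 = np.where(np.arange(3) == y[0], 50.0, 0.0)
        return TwoLayerNetModel(W1, b1, W2, b2, scaler, hyper, panel.columns)

    n = len(Z)
    lr = hyper.learning_rate
    for _ in range(hyper.epochs):
        H = Z @ W1 + b1
        P = _softmax(H @ W2 + b2)
        G = (P - Y) / n                 # d(loss)/d(logits)
        gW2 = H.T @ G
        gb2 = G.sum(axis=0)
        GH = G @ W2.T
        gW1 = Z.T @ GH
        gb1 = GH.sum(axis=0)
        W1 -= lr * gW1
        b1 -= lr * gb1
        W2 -= lr * gW2
        b2 -= lr * gb2
        if not (np.isfinite(W1).all() and np.isfinite(W2).all()):
            raise FloatingPointError("non-finite weights during training "
                                     "(reduce learning_rate)")
    return TwoLayerNetModel(W1, b1, W2, b2, scaler, hyper, panel.columns)


# -- serialization -----------------------------------------------------------


def save_model(model, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh, sort_keys=True)


def load_model(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    if d["kind"] == "hierarchical_knn":
        return HierarchicalKnnModel.from_dict(d)
    if d["kind"] == "two_layer_nn":
        return TwoLayerNetModel.from_dict(d)
    raise ValueError(f"unknown model kind {d['kind']!r}")
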