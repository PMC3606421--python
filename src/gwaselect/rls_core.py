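"""Regularized least-squares (ridge / LS-SVM) training, prediction, and the
constant-time leave-one-out shortcut.

For a selected feature set S the RLS weights minimise
``||X_S^T w - y||^2 + lambda w^T w`` and have the closed forms

    w = (X_S X_S^T + lambda I)^-1 X_S y          (primal, |S| x |S| solve)
      = X_S (X_S^T X_S + lambda I)^-1 y          (dual,   m x m solve)

With G = (X_S^T X_S + lambda I)^-1, a = G y and d = diag(G), the LOO
prediction for example j is ``y_j - a_j / d_j`` — no retraining needed.
An explicit m-fold retraining oracle is provided for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg


#: smallest admissible diagonal entry of G, relative to 1/lambda; below this
#: the state has lost positive definiteness and is considered corrupt.
D_FLOOR_REL = 1e-12


class NumericalBreakdownError(RuntimeError):
    """diag(G) hit the numerical floor; the dual state is no longer trustworthy."""


@dataclass
class LinearPredictor:
    """Sparse linear model f(x) = sum_{i in S} w_i x_i.

    ``feature_indices`` are row indices into the full genotype matrix, in
    selection order; ``snp_ids`` carries the matching identifiers when known.
    ``has_bias`` marks a trailing constant feature appended by the caller.
    """

    feature_indices: list
    weights: np.ndarray
    lam: float
    snp_ids: list | None = None
    has_bias: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.feature_indices = [int(i) for i in self.feature_indices]
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.feature_indices):
            raise ValueError("one weight per selected feature required")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return predict(self, X)

    def to_json(self) -> str:
        return json.dumps(
            {
                "lambda": self.lam,
                "feature_indices": self.feature_indices,
                "snp_ids": self.snp_ids,
                "weights": self.weights.tolist(),
                "has_bias": self.has_bias,
                "provenance": self.provenance,
            },
            indent=2,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "LinearPredictor":
        doc = json.loads(text)
        return cls(
            feature_indices=doc["feature_indices"],
            weights=np.asarray(doc["weights"]),
            lam=doc["lambda"],
            snp_ids=doc.get("snp_ids"),
            has_bias=doc.get("has_bias", False),
            provenance=doc.get("provenance", {}),
        )

    @classmethod
    def load(cls, path) -> "LinearPredictor":
        return cls.from_json(Path(path).read_text())


@dataclass
class DualState:
    """Dual-space working quantities for RLS over a feature set S."""

    a: np.ndarray          # G y
    d: np.ndarray          # diag(G)
    lam: float
    S: list = field(default_factory=list)


def _check_inputs(X_S: np.ndarray, y: np.ndarray, lam: float) -> tuple:
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    X_S = np.asarray(X_S, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_S.ndim != 2:
        raise ValueError("X_S must be 2-D (|S| x m)")
    if not (np.isfinite(X_S).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in X_S or y")
    if X_S.shape[1] != y.shape[0]:
        raise ValueError(f"X_S has {X_S.shape[1]} columns but y has {y.shape[0]}")
    return X_S, y, float(lam)


def train_rls(X_S: np.ndarray, y: np.ndarray, lam: float = 1.0,
              feature_indices=None, mode: str = "auto") -> LinearPredictor:
    """Closed-form ridge solution over the selected features.

    Uses the primal |S| x |S| system when |S| <= m, otherwise the equivalent
    dual m x m system (``mode`` can force either; they agree to numerical
    tolerance).
    """
    X_S, y, lam = _check_inputs(X_S, y, lam)
    s, m = X_S.shape
    if feature_indices is None:
        feature_indices = list(range(s))
    if s == 0:
        return LinearPredictor([], np.empty(0), lam)
    if mode == "auto":
        mode = "primal" if s <= m else "dual"
    if mode == "primal":
        A = X_S @ X_S.T + lam * np.eye(s)
        w = scipy.linalg.solve(A, X_S @ y, assume_a="pos")
    elif mode == "dual":
        K = X_S.T @ X_S + lam * np.eye(m)
        w = X_S @ scipy.linalg.solve(K, y, assume_a="pos")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return LinearPredictor(list(feature_indices), w, lam)


def predict(p: LinearPredictor, X: np.ndarray) -> np.ndarray:
    """Score the columns of an (n_features, t) matrix; cost O(|S| t)."""
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_features x t)")
    if not p.feature_indices:
        return np.zeros(X.shape[1])
    idx = np.asarray(p.feature_indices)
    if idx.max() >= X.shape[0]:
        raise IndexError(
            f"predictor uses feature {idx.max()} but X has {X.shape[0]} rows"
        )
    return p.weights @ X[idx].astype(float)


def dual_state(X_S: np.ndarray, y: np.ndarray, lam: float = 1.0,
               S=None) -> DualState:
    """a = G y and d = diag(G) with G = (X_S^T X_S + lambda I)^-1.

    Forms G explicitly, which is fine at test scale (m x m); the selection
    algorithms maintain the same quantities incrementally instead.
    """
    X_S, y, lam = _check_inputs(X_S, y, lam)
    m = X_S.shape[1]
    if X_S.shape[0] == 0:
        return DualState(a=y / lam, d=np.full(m, 1.0 / lam), lam=lam, S=list(S or []))
    G = np.linalg.inv(X_S.T @ X_S + lam * np.eye(m))
    return DualState(a=G @ y, d=np.diag(G).copy(), lam=lam,
                     S=list(S) if S is not None else list(range(X_S.shape[0])))


def loo_predictions(state: DualState, y: np.ndarray) -> np.ndarray:
    """Leave-one-out predictions ``y_j - a_j / d_j`` in O(m) total."""
    y = np.asarray(y, dtype=float)
    floor = D_FLOOR_REL / state.lam
    if (state.d <= floor).any():
        raise NumericalBreakdownError(
            f"diag(G) fell below {floor:.3e}; state is numerically degenerate"
        )
    return y - state.a / state.d


def explicit_loo_oracle(X_S: np.ndarray, y: np.ndarray, lam: float = 1.0) -> np.ndarray:
    """LOO by m explicit retrainings — the slow reference the shortcut must match."""
    X_S, y, lam = _check_inputs(X_S, y, lam)
    m = X_S.shape[1]
    if m < 2:
        raise ValueError("need at least 2 examples for leave-one-out")
    out = np.empty(m)
    for j in range(m):
        keep = np.arange(m) != j
        p = train_rls(X_S[:, keep], y[keep], lam)
        out[j] = predict(p, X_S[:, [j]])[0]
    return out


def loo_mse(state: DualState, y: np.ndarray | None = None) -> float:
    """LOO mean squared error, mean_j (a_j / d_j)^2.

    Identical to mean((y - loo_predictions)^2); y is accepted for interface
    symmetry but the shortcut needs only a and d.
    """
    floor = D_FLOOR_REL / state.lam
    if (state.d <= floor).any():
        raise NumericalBreakdownError("diag(G) at numerical floor")
    r = state.a / state.d
    return float(np.mean(r * r))


def loo_rmse(state: DualState, y: np.ndarray | None = None) -> float:
    return float(np.sqrt(loo_mse(state, y)))


def append_bias_feature(X: np.ndarray, value: float = 1.0) -> np.ndarray:
    """Append a constant row so the ridge model can fit an intercept."""
    X = np.asarray(X, dtype=float)
    return np.vstack([X, np.full((1, X.shape[1]), value)])
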