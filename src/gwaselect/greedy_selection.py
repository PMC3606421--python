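"""Greedy forward feature selection for RLS with the leave-one-out criterion.

Three interchangeable engines:

* ``greedy_rls`` — the fast cached algorithm.  It maintains the dual vector
  a = G y, the diagonal d = diag(G) and the cache C = G X^T, and scores every
  candidate feature i through the rank-one (Sherman-Morrison-Woodbury) update

      u       = C[:, i] / (1 + X_i C[:, i])
      a~      = a - u (X_i a)
      d~_j    = d_j - u_j C[j, i]
      LOO-MSE = mean_j (a~_j / d~_j)^2

  so one selection step over all n candidates costs O(m n).

* ``greedy_rls_space_efficient`` — identical selections without storing the
  m x n cache.  After every commit the economy-size SVD X_S = U Sigma V^T is
  recomputed; any cache column is reconstructed on demand as
  c = V (Omega (V^T X_i^T)) + X_i^T / lambda with
  Omega = (Sigma^T Sigma + lambda I)^-1 - lambda^-1 I, in O(m r) time.
  Candidates are scanned in fixed-size feature blocks, so peak auxiliary
  float storage is O(m (r + constant)).

* ``naive_wrapper_oracle`` — the black-box wrapper: every candidate set is
  retrained from scratch and LOO is computed either by the dual shortcut or
  by m explicit retrainings.  Test-scale only; the other two must match it.

Ties are broken toward the smallest feature index everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rls_core import (
    D_FLOOR_REL,
    DualState,
    LinearPredictor,
    NumericalBreakdownError,
    dual_state,
    explicit_loo_oracle,
    loo_mse,
    train_rls,
)


@dataclass
class SelectionStep:
    step: int            # 1-based
    feature: int
    loo_mse: float


@dataclass
class SelectionTrace:
    """Ordered record of greedy steps: chosen feature and its LOO-MSE."""

    steps: list[SelectionStep] = field(default_factory=list)
    method: str = ""
    lam: float = 1.0
    seed: int | None = None

    def add(self, feature: int, mse: float) -> None:
        if not np.isfinite(mse):
            raise ValueError(f"non-finite LOO-MSE at step {len(self.steps) + 1}")
        self.steps.append(SelectionStep(len(self.steps) + 1, int(feature), float(mse)))

    @property
    def features(self) -> list[int]:
        return [s.feature for s in self.steps]

    @property
    def loo_mses(self) -> list[float]:
        return [s.loo_mse for s in self.steps]

    def to_frame(self, snp_ids=None, chrom=None, pos=None) -> pd.DataFrame:
        idx = self.features
        df = pd.DataFrame({"step": [s.step for s in self.steps],
                           "feature_index": idx,
                           "loo_mse": self.loo_mses})
        if snp_ids is not None:
            df.insert(2, "snp_id", [snp_ids[i] for i in idx])
        if chrom is not None:
            df["chrom"] = [chrom[i] for i in idx]
        if pos is not None:
            df["pos"] = [pos[i] for i in idx]
        return df

    def write_tsv(self, path, snp_ids=None, chrom=None, pos=None) -> None:
        self.to_frame(snp_ids, chrom, pos).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cached algorithm
# ---------------------------------------------------------------------------

@dataclass
class SelectionState:
    """Working set of the cached algorithm: S, a, d, C and the data matrix."""

    X: np.ndarray            # n x m, dense, no missing values
    y: np.ndarray
    lam: float
    S: list[int] = field(default_factory=list)
    a: np.ndarray = None
    d: np.ndarray = None
    C: np.ndarray = None     # m x n cache, C = G X^T
    Xf: np.ndarray = None    # float64 view/copy of X used by the hot loop

    @property
    def in_S(self) -> np.ndarray:
        mask = np.zeros(self.X.shape[0], dtype=bool)
        mask[self.S] = True
        return mask


def _validate_xy(X, y, lam):
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if X.ndim != 2 or X.shape[1] != y.shape[0]:
        raise ValueError("X must be n x m with one label per column")
    if np.issubdtype(X.dtype, np.signedinteger) and (X < 0).any():
        raise ValueError(
            "missing genotypes present; impute first (genotype_io.impute_missing)"
        )
    if not np.isfinite(np.asarray(X, dtype=float)).all():
        raise ValueError("non-finite entries in X; impute or clean first")
    return X, y, float(lam)


def init_selection(X: np.ndarray, y: np.ndarray, lam: float = 1.0) -> SelectionState:
    """Empty-set state: a = y/lambda, d = 1/lambda, C = X^T/lambda."""
    X, y, lam = _validate_xy(X, y, lam)
    m = X.shape[1]
    Xf = np.asarray(X, dtype=np.float64)
    return SelectionState(
        X=X, y=y, lam=lam, S=[],
        a=y / lam,
        d=np.full(m, 1.0 / lam),
        C=Xf.T / lam,
        Xf=Xf,
    )


def _candidate_mse_block(a, d, C_block, b, xa, lam):
    """Vectorised LOO-MSE for a block of candidate columns.

    C_block: m x B cache columns; b: B vector of X_i C[:, i]; xa: B vector
    of X_i a.  Returns (mse, min_d) per candidate.
    """
    t = 1.0 / (1.0 + b)
    num = a[:, None] - C_block * (t * xa)[None, :]
    den = d[:, None] - (C_block * C_block) * t[None, :]
    min_d = den.min(axis=0)
    floor = D_FLOOR_REL / lam
    bad = min_d <= floor
    if bad.any():
        den = np.where(den <= floor, np.nan, den)
    r = num / den
    mse = np.einsum("jb,jb->b", r, r) / a.shape[0]
    mse[bad] = np.nan
    return mse, min_d


def evaluate_candidate(state: SelectionState, i: int) -> float:
    """LOO-MSE of the model over S u {i}, without mutating the state."""
    n = state.X.shape[0]
    if not (0 <= i < n):
        raise IndexError(f"feature {i} out of range [0, {n})")
    if i in state.S:
        raise ValueError(f"feature {i} is already selected")
    x_i = state.Xf[i]
    c = state.C[:, i]
    b = float(x_i @ c)
    xa = float(x_i @ state.a)
    mse, min_d = _candidate_mse_block(
        state.a, state.d, c[:, None], np.array([b]), np.array([xa]), state.lam
    )
    if not np.isfinite(mse[0]):
        raise NumericalBreakdownError(
            f"candidate {i}: diag(G) update hit the numerical floor"
        )
    return float(mse[0])


def _scan_candidates(state: SelectionState) -> np.ndarray:
    """LOO-MSE for every candidate at once; selected features get +inf."""
    Xf = state.Xf
    C = state.C
    b = np.einsum("ij,ji->i", Xf, C)
    xa = Xf @ state.a
    mse, _ = _candidate_mse_block(state.a, state.d, C, b, xa, state.lam)
    mse = np.asarray(mse)
    if np.isnan(mse[~state.in_S]).any():
        raise NumericalBreakdownError("candidate update hit the numerical floor")
    mse[state.in_S] = np.inf
    return mse


def select_next(state: SelectionState) -> tuple[int, float]:
    """Best remaining candidate (argmin LOO-MSE, smallest index on ties)."""
    if len(state.S) >= state.X.shape[0]:
        raise ValueError("no candidate features remain")
    mse = _scan_candidates(state)
    best = int(np.argmin(mse))  # argmin returns the first (= smallest) index
    return best, float(mse[best])


def commit_feature(state: SelectionState, i: int) -> SelectionState:
    """Add feature i to S and update a, d and C in place (rank-one update)."""
    if i in state.S:
        raise ValueError(f"feature {i} is already selected")
    x_i = state.Xf[i]
    c = state.C[:, i].copy()
    u = c / (1.0 + x_i @ c)
    state.a -= u * (x_i @ state.a)
    state.d -= u * c
    floor = D_FLOOR_REL / state.lam
    if (state.d <= floor).any():
        raise NumericalBreakdownError(f"diag(G) degenerate after committing {i}")
    state.C -= np.outer(u, x_i @ state.C)
    state.S.append(int(i))
    return state


def _predictor_from_dual(S, a, X, lam, method, seed,
                         has_bias: bool = False) -> LinearPredictor:
    w = np.asarray(X, dtype=float)[S] @ a if S else np.empty(0)
    return LinearPredictor(
        list(S), w, lam, has_bias=has_bias,
        provenance={"selection_method": method, "seed": seed},
    )


def _with_bias(X: np.ndarray) -> np.ndarray:
    """Append a constant row of ones (the intercept-as-feature convention)."""
    ones = np.ones((1, X.shape[1]), dtype=X.dtype)
    return np.vstack([X, ones])


def greedy_rls(X: np.ndarray, y: np.ndarray, lam: float = 1.0, k: int = 10,
               seed: int | None = None,
               include_bias: bool = False) -> tuple[SelectionTrace, LinearPredictor]:
    """Select k features greedily by LOO-MSE; O(k m n) time, O(m n) cache.

    With ``include_bias`` a constant feature is appended and committed before
    selection starts, so the model carries an intercept while the k recorded
    picks are all genuine features.  The returned predictor then expects an
    augmented input (see :func:`gwaselect.rls_core.append_bias_feature`).
    """
    X = np.asarray(X)
    n = X.shape[0]
    if not (0 <= k <= n):
        raise ValueError(f"k={k} out of range for {n} features")
    Xw = _with_bias(X) if include_bias else X
    state = init_selection(Xw, y, lam)
    if include_bias:
        commit_feature(state, n)
    trace = SelectionTrace(method="greedy", lam=float(lam), seed=seed)
    for _ in range(k):
        i, mse = select_next(state)
        commit_feature(state, i)
        trace.add(i, mse)
    pred = _predictor_from_dual(state.S, state.a, Xw, float(lam), "greedy",
                                seed, has_bias=include_bias)
    return trace, pred


# ---------------------------------------------------------------------------
# Space-efficient algorithm
# ---------------------------------------------------------------------------

@dataclass
class SVDSelectionState:
    """SVD-backed state: S plus V, Sigma, Omega of the economy-size SVD of X_S."""

    S: list[int]
    V: np.ndarray        # m x r right singular vectors
    sigma: np.ndarray    # r nonzero singular values
    omega: np.ndarray    # diag of (Sigma^T Sigma + lam I)^-1 - lam^-1 I
    lam: float

    @property
    def r(self) -> int:
        return len(self.sigma)


class AllocationTracker:
    """Records peak live auxiliary float count inside the space-efficient scan."""

    def __init__(self) -> None:
        self.peak = 0

    def update(self, n_floats: int) -> None:
        self.peak = max(self.peak, int(n_floats))


def _svd_state(X, S, lam) -> SVDSelectionState:
    if not S:
        m = X.shape[1]
        return SVDSelectionState(S=list(S), V=np.empty((m, 0)),
                                 sigma=np.empty(0), omega=np.empty(0), lam=lam)
    Xs = np.asarray(X, dtype=float)[S]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xs.shape) * np.finfo(float).eps
    keep = s > tol
    s = s[keep]
    V = Vt[keep].T
    omega = 1.0 / (s * s + lam) - 1.0 / lam
    return SVDSelectionState(S=list(S), V=V, sigma=s, omega=omega, lam=lam)


def se_cache_column(state: SVDSelectionState, X: np.ndarray, i: int) -> np.ndarray:
    """Column i of C = G X^T reconstructed from the SVD in O(m r)."""
    n = X.shape[0]
    if not (0 <= i < n):
        raise IndexError(f"feature {i} out of range [0, {n})")
    x_i = np.asarray(X[i], dtype=float)
    if state.r == 0:
        return x_i / state.lam
    return state.V @ (state.omega * (state.V.T @ x_i)) + x_i / state.lam


def _se_dual(state: SVDSelectionState, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """a = G y and d = diag(G) from the SVD representation."""
    lam = state.lam
    if state.r == 0:
        return y / lam, np.full(y.shape[0], 1.0 / lam)
    a = state.V @ (state.omega * (state.V.T @ y)) + y / lam
    d = (state.V * state.V) @ state.omega + 1.0 / lam
    return a, d


def greedy_rls_space_efficient(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0, k: int = 10,
    seed: int | None = None, block_size: int = 64,
    alloc_tracker: AllocationTracker | None = None,
    include_bias: bool = False,
) -> tuple[SelectionTrace, LinearPredictor]:
    """Greedy LOO-MSE selection without the m x n cache.

    Recomputes the economy SVD of X_S after every commit and reconstructs
    cache columns on demand in fixed-size candidate blocks; auxiliary float
    storage stays O(m (r + block_size)) while X itself remains one byte per
    entry.  Selections match ``greedy_rls`` to floating-point tolerance.
    """
    X, y, lam = _validate_xy(X, y, lam)
    if include_bias:
        X = _with_bias(X)
    n, m = X.shape
    n_select = n - 1 if include_bias else n
    if not (0 <= k <= n_select):
        raise ValueError(f"k={k} out of range for {n_select} features")
    trace = SelectionTrace(method="space_efficient", lam=lam, seed=seed)
    state = _svd_state(X, [n - 1] if include_bias else [], lam)
    for _ in range(k):
        a, d = _se_dual(state, y)
        sel = np.zeros(n, dtype=bool)
        sel[state.S] = True
        best_i, best_mse = -1, np.inf
        for lo in range(0, n, block_size):
            hi = min(lo + block_size, n)
            Xb = np.asarray(X[lo:hi], dtype=float)  # B x m
            if state.r == 0:
                Cb = Xb.T / lam
            else:
                Cb = state.V @ (state.omega[:, None] * (state.V.T @ Xb.T)) + Xb.T / lam
            b = np.einsum("bm,mb->b", Xb, Cb)
            xa = Xb @ a
            mse, _ = _candidate_mse_block(a, d, Cb, b, xa, lam)
            if alloc_tracker is not None:
                B = hi - lo
                # live floats: V, a, d, Xb, Cb, b, xa, mse + the two m x B
                # temporaries inside the block evaluation
                alloc_tracker.update(
                    state.V.size + 2 * m + 4 * m * B + 3 * B
                )
            mse[sel[lo:hi]] = np.inf
            if np.isnan(mse).any():
                raise NumericalBreakdownError("candidate update hit numerical floor")
            j = int(np.argmin(mse))
            if mse[j] < best_mse:
                best_i, best_mse = lo + j, float(mse[j])
        state = _svd_state(X, state.S + [best_i], lam)
        trace.add(best_i, best_mse)
    a, _ = _se_dual(state, y)
    pred = _predictor_from_dual(state.S, a, X, lam, "space_efficient", seed,
                                has_bias=include_bias)
    return trace, pred


# ---------------------------------------------------------------------------
# Naive wrapper oracle
# ---------------------------------------------------------------------------

def naive_wrapper_oracle(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0, k: int = 5,
    loo: str = "shortcut", max_cost: int = 20_000_000,
    seed: int | None = None, include_bias: bool = False,
) -> tuple[SelectionTrace, LinearPredictor]:
    """Greedy wrapper with black-box retraining per candidate set (test oracle).

    ``loo='shortcut'`` computes each candidate's LOO via a fresh dual state and
    the a/d formula; ``loo='explicit'`` retrains m times per candidate.  Both
    must reproduce the fast algorithms.  Guarded by an n*m*k cost cap.
    """
    X, y, lam = _validate_xy(X, y, lam)
    if include_bias:
        X = _with_bias(X)
    n, m = X.shape
    n_select = n - 1 if include_bias else n
    if not (0 <= k <= n_select):
        raise ValueError(f"k={k} out of range for {n_select} features")
    cost = n * m * k * (m if loo == "explicit" else 1)
    if cost > max_cost:
        raise ValueError(
            f"naive oracle cost {cost} exceeds cap {max_cost}; use greedy_rls"
        )
    Xf = np.asarray(X, dtype=float)
    S: list[int] = [n - 1] if include_bias else []
    trace = SelectionTrace(method=f"naive_oracle[{loo}]", lam=lam, seed=seed)
    for _ in range(k):
        best_i, best_mse = -1, np.inf
        for i in range(n):
            if i in S:
                continue
            cand = S + [i]
            if loo == "shortcut":
                st = dual_state(Xf[cand], y, lam, S=cand)
                mse = loo_mse(st)
            elif loo == "explicit":
                preds = explicit_loo_oracle(Xf[cand], y, lam)
                mse = float(np.mean((y - preds) ** 2))
            else:
                raise ValueError(f"unknown loo mode {loo!r}")
            if mse < best_mse:  # strict: ties keep the smaller index
                best_i, best_mse = i, mse
        S.append(best_i)
        trace.add(best_i, best_mse)
    st = dual_state(Xf[S], y, lam, S=S) if S else None
    a = st.a if st is not None else np.zeros(m)
    pred = _predictor_from_dual(S, a, X, lam, f"naive_oracle[{loo}]", seed,
                                has_bias=include_bias)
    return trace, pred
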