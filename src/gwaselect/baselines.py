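"""Univariate filter and filter+wrapper hybrid selectors.

The filter ranks SNPs by the p-value of Fisher's exact test on the 3x2
genotype-by-status contingency table, the standard single-marker genotypic
association test.  The hybrid first keeps the 50 smallest-p SNPs and then
runs greedy RLS inside that shortlist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .genotype_io import MISSING
from .greedy_selection import LinearPredictor, SelectionTrace, greedy_rls


@dataclass
class GenotypeContingencyTable:
    """3x2 counts: rows = genotype 0/1/2, columns = (case, control)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 2):
            raise ValueError("contingency table must be 3x2")
        if (self.counts < 0).any():
            raise ValueError("negative cell counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def genotype_contingency(x_i: np.ndarray, y: np.ndarray) -> GenotypeContingencyTable:
    """Count (genotype, status) pairs, excluding missing genotypes."""
    x_i = np.asarray(x_i)
    y = np.asarray(y)
    obs = x_i != MISSING
    if not obs.any():
        raise ValueError("all genotypes missing for this SNP")
    g = x_i[obs].astype(np.int64)
    case = (y[obs] == 1)
    counts = np.zeros((3, 2), dtype=np.int64)
    for col, mask in ((0, case), (1, ~case)):
        counts[:, col] = np.bincount(g[mask], minlength=3)[:3]
    return GenotypeContingencyTable(counts)


def fisher_exact_3x2(table: GenotypeContingencyTable | np.ndarray,
                     max_total: int = 5000) -> float:
    """Exact conditional test on a 3x2 table (probability-ordering p-value).

    Enumerates every table with the observed margins (two free cells),
    accumulating the multivariate hypergeometric probability of tables no
    more probable than the observed one (relative tolerance 1e-7 on the
    comparison).  Log-gamma arithmetic throughout.  Tables with more than
    ``max_total`` observations fall back to the chi-square test with a
    warning.
    """
    if not isinstance(table, GenotypeContingencyTable):
        table = GenotypeContingencyTable(table)
    T = table.counts
    N = table.total
    if N == 0:
        raise ValueError("empty contingency table")
    if N > max_total:
        warnings.warn(
            f"table total {N} exceeds exact-test cap {max_total}; "
            "falling back to chi-square", RuntimeWarning,
        )
        keep = T.sum(axis=1) > 0
        if keep.sum() < 2 or (T.sum(axis=0) == 0).any():
            return 1.0
        return float(sps.chi2_contingency(T[keep])[1])

    r = T.sum(axis=1)       # genotype margins
    c0 = int(T[:, 0].sum())  # case margin
    lf = gammaln(np.arange(N + 1) + 1.0)  # log factorials

    def log_choose(n, k):
        return lf[n] - lf[k] - lf[n - k]

    # free cells: x0 = cases with genotype 0, x1 = cases with genotype 1
    x0 = np.arange(max(0, c0 - r[1] - r[2]), min(r[0], c0) + 1)
    logp_rows = []
    denom = log_choose(N, c0)
    for v0 in x0:
        x1 = np.arange(max(0, c0 - v0 - r[2]), min(r[1], c0 - v0) + 1)
        x2 = c0 - v0 - x1
        lp = (log_choose(r[0], v0) + log_choose(r[1], x1)
              + log_choose(r[2], x2) - denom)
        logp_rows.append(lp)
    logp = np.concatenate(logp_rows)
    lp_obs = (log_choose(r[0], T[0, 0]) + log_choose(r[1], T[1, 0])
              + log_choose(r[2], T[2, 0]) - denom)
    p = float(np.exp(logp[logp <= lp_obs + np.log1p(1e-7)]).sum())
    return min(1.0, p)


def filter_select(X: np.ndarray, y: np.ndarray, k: int,
                  max_total: int = 5000) -> tuple[np.ndarray, np.ndarray]:
    """Rank SNPs by ascending exact-test p-value; return (top-k order, all p).

    Ties rank the smaller feature index first.  P-values are computed on the
    supplied (training) data only — callers are responsible for passing the
    training fold, never the full dataset.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds feature count {n}")
    pvals = np.empty(n)
    for i in range(n):
        pvals[i] = fisher_exact_3x2(genotype_contingency(X[i], y), max_total)
    order = np.argsort(pvals, kind="stable")  # stable: ties keep index order
    return order[:k], pvals


def hybrid_select(
    X: np.ndarray, y: np.ndarray, lam: float = 1.0, k: int = 10,
    prefilter: int = 50, seed: int | None = None, max_total: int = 5000,
) -> tuple[SelectionTrace, LinearPredictor]:
    """P-value prefilter to ``prefilter`` SNPs, then greedy RLS for k of them.

    Reported indices refer to the original feature space.
    """
    X = np.asarray(X)
    n = X.shape[0]
    if not (k <= prefilter <= n):
        raise ValueError(f"need k <= prefilter <= n, got k={k}, "
                         f"prefilter={prefilter}, n={n}")
    shortlist, _ = filter_select(X, y, prefilter, max_total)
    shortlist = np.sort(shortlist)  # keep original index order inside the subset
    trace_sub, pred_sub = greedy_rls(X[shortlist], y, lam, k, seed=seed)
    trace = SelectionTrace(method="hybrid", lam=float(lam), seed=seed)
    for s in trace_sub.steps:
        trace.add(int(shortlist[s.feature]), s.loo_mse)
    pred = LinearPredictor(
        [int(shortlist[i]) for i in pred_sub.feature_indices],
        pred_sub.weights, float(lam),
        provenance={"selection_method": "hybrid", "prefilter": prefilter,
                    "seed": seed},
    )
    return trace, pred
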