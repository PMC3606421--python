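"""Nested cross-validation of the selection methods.

External stratified folds estimate generalization; the internal LOO-MSE
criterion drives selection inside each training fold only.  For every fold
and every k up to ``k_max`` a fresh RLS model on the first k selected
features is trained on the training fold and scored by AUC on the held-out
fold; curves are averaged pointwise over folds.  A label-permutation control
re-runs the identical protocol (same folds) on shuffled labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .baselines import filter_select, hybrid_select
from .genotype_io import GenotypeDataset
from .greedy_selection import greedy_rls, greedy_rls_space_efficient
from .rls_core import dual_state, loo_mse, predict, train_rls

METHODS = ("greedy", "space_efficient", "filter", "hybrid")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, midrank (Mann-Whitney) formulation.

    Probability that a random case outranks a random control, with tied
    scores counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == -1
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both a case and a control")
    r = rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def stratified_folds(labels: np.ndarray, n_folds: int = 3, seed: int = 0) -> np.ndarray:
    """Deterministic stratified partition; returns a fold id per sample."""
    labels = np.asarray(labels)
    for cls in (1, -1):
        if (labels == cls).sum() < n_folds:
            raise ValueError(f"class {cls:+d} has fewer than {n_folds} members")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_id = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_id[test_idx] = f
    return fold_id


@dataclass
class FoldResult:
    fold: int
    selected: list[int]
    auc_by_k: np.ndarray       # k = 1..k_max
    loo_mse_by_k: np.ndarray


@dataclass
class NestedCVResult:
    folds: list[FoldResult]
    mean_auc_by_k: np.ndarray
    method: str
    lam: float
    k_max: int
    seed: int
    permuted: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.folds:
            for k in range(1, self.k_max + 1):
                rows.append({"fold": fr.fold, "k": k,
                             "auc": fr.auc_by_k[k - 1],
                             "loo_mse": fr.loo_mse_by_k[k - 1]})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        peak_k = int(np.argmax(self.mean_auc_by_k)) + 1
        return {
            "method": self.method,
            "lambda": self.lam,
            "k_max": self.k_max,
            "seed": self.seed,
            "permuted": self.permuted,
            "peak_k": peak_k,
            "peak_auc": float(self.mean_auc_by_k[peak_k - 1]),
        }

    def write(self, tsv_path, json_path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        Path(json_path).write_text(json.dumps(self.summary(), indent=2))


def _select_on_training(X_tr, y_tr, method, lam, k_max, seed, prefilter):
    """Run the configured selector on training data only; return ordered
    feature list and per-k internal LOO-MSE (length k_max)."""
    if method == "greedy":
        trace, _ = greedy_rls(X_tr, y_tr, lam, k_max, seed=seed)
        return trace.features, np.asarray(trace.loo_mses)
    if method == "space_efficient":
        trace, _ = greedy_rls_space_efficient(X_tr, y_tr, lam, k_max, seed=seed)
        return trace.features, np.asarray(trace.loo_mses)
    if method == "filter":
        order, _ = filter_select(X_tr, y_tr, k_max)
        feats = [int(i) for i in order]
        mses = np.empty(k_max)
        Xf = np.asarray(X_tr, dtype=float)
        for k in range(1, k_max + 1):
            st = dual_state(Xf[feats[:k]], y_tr, lam)
            mses[k - 1] = loo_mse(st)
        return feats, mses
    if method == "hybrid":
        trace, _ = hybrid_select(X_tr, y_tr, lam, k_max,
                                 prefilter=max(prefilter, k_max), seed=seed)
        return trace.features, np.asarray(trace.loo_mses)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def nested_cv(
    ds: GenotypeDataset,
    method: str = "greedy",
    lam: float = 1.0,
    k_max: int = 50,
    n_folds: int = 3,
    seed: int = 0,
    prefilter: int = 50,
    fold_id: np.ndarray | None = None,
    y_override: np.ndarray | None = None,
) -> NestedCVResult:
    """External stratified CV around internal LOO-driven selection.

    Selection sees only the training two-thirds of each round; the held-out
    fold is used exclusively to score per-k AUC.  ``fold_id``/``y_override``
    exist so the permutation control can reuse identical splits.
    """
    if ds.has_missing():
        raise ValueError("dataset has missing genotypes; impute before nested_cv")
    y = ds.y if y_override is None else np.asarray(y_override, dtype=np.int8)
    if k_max > ds.n_snps:
        raise ValueError(f"k_max={k_max} exceeds {ds.n_snps} features")
    if fold_id is None:
        fold_id = stratified_folds(y, n_folds, seed)
    X = ds.X
    Xf = np.asarray(X, dtype=float)
    folds = []
    for f in range(n_folds):
        test = fold_id == f
        train = ~test
        feats, mses = _select_on_training(
            X[:, train], y[train], method, lam, k_max, seed, prefilter
        )
        aucs = np.empty(k_max)
        for k in range(1, k_max + 1):
            Sk = feats[:k]
            p = train_rls(Xf[Sk][:, train], y[train].astype(float), lam,
                          feature_indices=Sk)
            scores = predict(p, Xf[:, test])
            aucs[k - 1] = auc(scores, y[test])
        folds.append(FoldResult(fold=f, selected=list(feats),
                                auc_by_k=aucs, loo_mse_by_k=np.asarray(mses)))
    mean_auc = np.mean([fr.auc_by_k for fr in folds], axis=0)
    return NestedCVResult(folds=folds, mean_auc_by_k=mean_auc, method=method,
                          lam=float(lam), k_max=k_max, seed=seed,
                          permuted=y_override is not None)


def per_feature_auc(ds: GenotypeDataset, features=None) -> pd.DataFrame:
    """Discriminative power of each SNP alone, scored by its allele count.

    Raw counts can be anti-associated, so the oriented value
    max(AUC, 1 - AUC) is reported beside the raw AUC with a direction flag
    ("risk" when more minor alleles score toward cases, else "protective").
    """
    if features is None:
        features = range(ds.n_snps)
    rows = []
    for i in features:
        a = auc(ds.X[i].astype(float), ds.y)
        rows.append({
            "feature_index": int(i),
            "snp_id": ds.snp_ids[i],
            "auc_raw": a,
            "auc_oriented": max(a, 1.0 - a),
            "direction": "risk" if a >= 0.5 else "protective",
        })
    return pd.DataFrame(rows)


def permutation_control(
    ds: GenotypeDataset,
    method: str = "greedy",
    lam: float = 1.0,
    k_max: int = 50,
    seed: int = 0,
    n_folds: int = 3,
    prefilter: int = 50,
) -> NestedCVResult:
    """Re-run nested_cv with labels permuted once, on the identical splits.

    Folds are computed from the original labels so data and train/test
    partitions match the unpermuted experiment exactly; only the labels
    change.  Expected outcome: a flat random-level AUC curve.
    """
    fold_id = stratified_folds(ds.y, n_folds, seed)
    rng = np.random.default_rng([seed, 104729])
    y_perm = rng.permutation(ds.y)
    return nested_cv(ds, method=method, lam=lam, k_max=k_max, n_folds=n_folds,
                     seed=seed, prefilter=prefilter, fold_id=fold_id,
                     y_override=y_perm)
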