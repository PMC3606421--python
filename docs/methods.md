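# Methods

## Model and selection criterion

The classifier is regularized least-squares (RLS, equivalently ridge
regression or the LS-SVM) on minor-allele counts: for a selected SNP set S
the weights minimise ‖X_Sᵀw − y‖² + λwᵀw with y ∈ {±1}. Training has the
closed forms

    w = (X_S X_Sᵀ + λI)⁻¹ X_S y        (primal, |S|×|S| solve)
      = X_S (X_SᵀX_S + λI)⁻¹ y         (dual,   m×m solve)

and `train_rls` switches to whichever system is smaller (`|S| ≤ m` →
primal). All linear algebra is double precision regardless of the one-byte
genotype storage.

Selection is greedy forward search scored by leave-one-out mean squared
error. Writing G = (X_SᵀX_S + λI)⁻¹, a = Gy, d = diag(G), the LOO
prediction for sample j is y_j − a_j/d_j, so the criterion is
mean((a/d)²). G is symmetric positive definite, hence 0 < d_j ≤ 1/λ
always; with S empty, a = y/λ and d = 1/λ, every LOO prediction is 0 and
the criterion is exactly 1 — the natural baseline for ±1 labels.

Candidate evaluation uses the rank-one (Sherman–Morrison–Woodbury) update
through the cache C = GXᵀ:

    u = C[:,i] (1 + X_i C[:,i])⁻¹,  ã = a − u(X_i a),  d̃ = d − u ∘ C[:,i]

The denominator 1 + X_i C[:,i] = 1 + X_i G X_iᵀ ≥ 1, so the update never
divides by anything small; an all-zero candidate leaves a, d unchanged and
can therefore never strictly improve the criterion. MSE rather than RMSE is
minimised in the hot loop (the square root is monotone, so selections are
identical). Ties are broken toward the smallest feature index, which makes
all cross-engine equivalence checks index-exact.

## Space-efficient variant

The cached algorithm stores C (m×n float64), which dominates memory because
the genotypes themselves need only one byte per entry. The space-efficient
engine instead recomputes the economy-size SVD X_S = UΣVᵀ after every
commit (one SVD per selected feature, matching the method's published cost
model) and reconstructs any cache column on demand:

    G = VΩVᵀ + λ⁻¹I,  Ω = (ΣᵀΣ + λI)⁻¹ − λ⁻¹I,
    C[:,i] = V(Ω(VᵀX_iᵀ)) + λ⁻¹X_iᵀ            — O(mr) per column

Candidates are scanned in fixed-size blocks (default 64 columns), so peak
auxiliary float storage is O(m·(r + block)); an `AllocationTracker` hook
records the live-float peak and the test suite asserts the bound. Singular
values below `σ_max · max(dim) · eps` are treated as zero. Both engines are
required (by test) to produce identical index sequences and per-step errors
up to 1e-8.

## Intercept handling

The linear model f(x) = wᵀx_S has no bias term; when an intercept is
wanted it is realised as an extra constant-valued feature. The selection
engines accept `include_bias=True`, which appends a constant row and
commits it *before* the k counted picks. This matters in practice: without
an intercept, greedy selection on raw 0/1/2 counts spends early picks on
high-mean noise SNPs that act as intercept surrogates (their contribution
shifts predictions toward the label mean rather than discriminating). The
planted-recovery experiment therefore runs with the intercept feature; the
default remains off so the algebra matches the equations as written and the
engine-equivalence oracles stay minimal.

## Regularization

λ defaults to 1.0 and is never tuned internally: tuning would interleave
with selection and break the reproducibility of the traces. Callers can set
it per run. The verification suite exercises λ ∈ {0.1, 1, 10} and the
limit behaviour (λ → 1e8 drives a → y/λ and w → 0).

## Baselines

The filter ranks SNPs by Fisher's exact test on the 3×2 genotype-by-status
table. The p-value is the standard probability-ordering convention: all
tables with the observed margins (two free cells) are enumerated, and
tables no more probable than the observed one (relative tolerance 1e-7 on
the comparison) contribute to p. Log-gamma arithmetic keeps the
enumeration stable; above a configurable total-count cap (default 5,000,
enumeration being O(total²)) the chi-square test on the same table is used
with a warning. When one genotype row is empty the test reduces exactly to
the 2×2 hypergeometric tail (worked check: margins (4,4|4,4) give
p = 34/70). The hybrid selector keeps the 50 smallest-p SNPs (configurable)
and runs greedy RLS inside the shortlist, reporting original indices.

## Quality control

Order: samples with more than 5% missing genotypes are dropped first;
per-SNP statistics are then recomputed and SNPs are dropped that fail
Hardy-Weinberg equilibrium *in controls* (p < 1e-3), have MAF < 1%, or
exceed 5% missingness. Each dropped item records the first filter it
failed (HWE, then MAF, then missingness). The HWE test defaults to the
1-df chi-square goodness of fit — deterministic, fast, and adequate at the
loose 1e-3 threshold; an exact mid-p variant (enumeration of heterozygote
counts conditional on allele counts) is available via `method="exact"`.
Monomorphic SNPs return p = 1 by convention. QC is idempotent by
construction and tested as such.

Selection requires a dense matrix, so residual missing genotypes (≤5%
allowed by QC) are imputed afterwards — per-SNP mode by default, ties
toward the smaller genotype; mean-rounded and zero strategies exist. This
impute-then-select policy is this package's documented choice.

## Synthetic cohorts

The simulator draws per-SNP MAF uniformly (default 0.05–0.5; causal SNPs
from 0.2–0.5, i.e. common variants), genotypes i.i.d. Binomial(2, MAF)
(Hardy-Weinberg proportions, no linkage disequilibrium by default), and
labels from an additive logistic liability: logit P(case) = b₀ + Σ β_c X_c,
with b₀ solved by root-finding so the expected prevalence hits the target
(default 0.5, balanced case-control). A duplicate-pair mechanism copies a
causal column (optionally with flip noise) for redundancy experiments.
Scenario plus seed fixes every dataset bit for bit.

Preset conditions, frozen after one calibration run:

* `null` — n=1000, m=600, no causal SNPs.
* `strong_signal` — n=2000, m=600, 5 causal SNPs, per-allele log-odds
  0.8–1.5. With the intercept feature included, the first five greedy picks
  contain ≥4 of the 5 planted SNPs in 20/20 calibration seeds.
* `redundant_pair` — one causal SNP (β=1.5) duplicated columnwise.
* `weak_polygenic` — n=1000, m=1500, 50 causal SNPs at β=0.5. With 50
  causal variants an individual SNP's case-control correlation saturates
  near 0.14 whatever β is (each variant also inflates total liability
  variance), so individually-weak-but-jointly-predictive behaviour requires
  the larger cohort: calibration gave max single-SNP AUC 0.57–0.59 and a
  held-out 30-SNP model AUC 0.77–0.79.

What the simulator does **not** emulate: linkage disequilibrium structure,
population stratification, genotyping batch effects, and rare-variant
architectures. Passing tests therefore demonstrate algorithmic correctness
and the selection/evaluation protocol, not robustness to confounding in
real cohorts.

## Evaluation protocol

Nested cross-validation: the cohort is split into three stratified external
folds (delegated to scikit-learn's `StratifiedKFold`, shuffled,
seed-deterministic). Per round, selection runs only on the training
two-thirds with the internal LOO criterion; for every k up to k_max an RLS
model on the first k selected features is trained on the training fold and
scored by AUC on the held-out fold; curves are averaged pointwise over
folds. The reported "peak k" is the external-test AUC maximum — a report,
never fed back into selection. AUC uses the midrank (Mann–Whitney)
convention, ties counted half. Per-feature AUC scores the raw allele count
and reports max(AUC, 1−AUC) with a direction flag, since raw counts can be
anti-associated.

The permutation control permutes labels once and re-runs the identical
experiment on the identical splits (folds are computed from the original
labels and reused), so a flat 0.5 curve isolates leakage from genuine
signal. A separate leakage test deletes each round's test fold from the
dataset and verifies the selection is bit-identical.

## Numerical choices

* Degenerate diagonal entries (d̃ ≤ 1e-12/λ) raise a hard
  `NumericalBreakdownError` instead of being clamped — with λ > 0 they can
  only indicate corruption.
* Cross-engine tolerances: selected indices exact; per-step errors 1e-8;
  dense-reconstruction checks 1e-9.
* Internal LOO-MSE traces decrease monotonically in practice (the criterion
  overfits as k grows); this is observed, not asserted, since it is not a
  theorem.

## Problem sizes

The verification experiments run at deliberately desk-friendly sizes: LOO
shortcut on 200+ random problems (m ≤ 30, |S| ≤ 10), engine equivalence on
20 instances (n ≤ 40, m ≤ 30, k = 5), recovery and control experiments at
m = 600 with n = 1000–2000 SNPs, and the scaling probe at m = 500 with
n = 5,000 → 10,000. These sizes exercise every code path; the algorithms
themselves scale linearly in n and m by construction, and the wall-time
ratio reported by the acceptance script sits in the ~2–3× band expected
when doubling n (slightly above 2 because the m×n working set stops
fitting in cache).
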