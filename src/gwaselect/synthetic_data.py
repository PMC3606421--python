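"""Case-control GWAS simulator with planted causal SNPs.

Genotypes are independent SNPs in Hardy-Weinberg proportions: per SNP a
minor allele frequency is drawn uniformly from ``maf_range`` and genotypes
are Binomial(2, MAF) across samples.  Disease status follows an additive
logistic liability: logit P(case) = b0 + sum_c beta_c X_c, with the
intercept solved numerically so the expected prevalence matches the target.
Everything is bit-for-bit reproducible from the scenario seed.

Presets
-------
null            no causal SNPs — calibration of false-positive behaviour.
strong_signal   5 causal common SNPs (MAF 0.2-0.5) with per-allele log-odds
                0.8-1.5 — planted-recovery experiments.
redundant_pair  one strong causal SNP duplicated columnwise — exposes the
                filter's redundancy blindness vs the wrapper.
weak_polygenic  50 causal SNPs with per-allele log-odds 0.5 at m=1500 —
                individually near-random markers (each explains under 1% of
                liability variance) that combine into a predictive model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .genotype_io import GenotypeDataset

PRESETS = ("null", "strong_signal", "redundant_pair", "weak_polygenic")


@dataclass
class SimulationScenario:
    """Full description of one synthetic dataset; seed fixes it exactly."""

    n_snps: int = 1000
    m_samples: int = 600
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_range: tuple[float, float] | None = (0.2, 0.5)
    causal: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    betas: np.ndarray = field(default_factory=lambda: np.empty(0))
    prevalence: float = 0.5
    #: (source, target) pairs: target SNP column is overwritten with a copy
    #: of source, each entry flipped to a random genotype with prob flip_noise.
    duplicate_pairs: tuple = ()
    flip_noise: float = 0.0
    seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        self.causal = np.asarray(self.causal, dtype=int)
        self.betas = np.asarray(self.betas, dtype=float)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if len(self.causal) != len(self.betas):
            raise ValueError("one effect size per causal SNP required")
        if len(self.causal) and (self.causal.min() < 0
                                 or self.causal.max() >= self.n_snps):
            raise ValueError("causal index out of range")


def make_scenario(preset: str, **overrides) -> SimulationScenario:
    """Named study conditions; ``overrides`` replace any scenario field."""
    seed = overrides.pop("seed", 0)
    if preset == "null":
        sc = SimulationScenario(n_snps=1000, m_samples=600, seed=seed, name="null")
    elif preset == "strong_signal":
        sc = SimulationScenario(
            n_snps=2000, m_samples=600,
            causal=np.arange(5), betas=np.linspace(0.8, 1.5, 5),
            seed=seed, name="strong_signal",
        )
    elif preset == "redundant_pair":
        sc = SimulationScenario(
            n_snps=2000, m_samples=600,
            causal=np.array([0]), betas=np.array([1.5]),
            duplicate_pairs=((0, 1),),
            seed=seed, name="redundant_pair",
        )
    elif preset == "weak_polygenic":
        sc = SimulationScenario(
            n_snps=1000, m_samples=1500,
            causal=np.arange(50), betas=np.full(50, 0.5),
            seed=seed, name="weak_polygenic",
        )
    else:
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    return replace(sc, **overrides) if overrides else sc


def simulate_genotypes(scenario: SimulationScenario) -> np.ndarray:
    """(n_snps, m_samples) int8 matrix of Binomial(2, MAF) allele counts."""
    rng = np.random.default_rng([scenario.seed, 0])
    n, m = scenario.n_snps, scenario.m_samples
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, size=n)
    if scenario.causal_maf_range is not None and len(scenario.causal):
        clo, chi = scenario.causal_maf_range
        maf[scenario.causal] = rng.uniform(clo, chi, size=len(scenario.causal))
    X = rng.binomial(2, maf[:, None], size=(n, m)).astype(np.int8)
    for src, dst in scenario.duplicate_pairs:
        X[dst] = X[src]
        if scenario.flip_noise > 0:
            flip = rng.random(m) < scenario.flip_noise
            X[dst, flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.int8)
    return X


def simulate_phenotype(X: np.ndarray, scenario: SimulationScenario) -> np.ndarray:
    """Labels in {+1, -1} from the additive logistic liability model."""
    rng = np.random.default_rng([scenario.seed, 1])
    m = X.shape[1]
    if len(scenario.causal) and scenario.causal.max() >= X.shape[0]:
        raise ValueError("causal index out of range for this genotype matrix")
    if len(scenario.causal):
        liability = scenario.betas @ X[scenario.causal].astype(float)
    else:
        liability = np.zeros(m)

    def excess(b0):
        return expit(b0 + liability).mean() - scenario.prevalence

    b0 = brentq(excess, -50.0, 50.0)
    case = rng.random(m) < expit(b0 + liability)
    return np.where(case, 1, -1).astype(np.int8)


def simulate_dataset(scenario: SimulationScenario) -> GenotypeDataset:
    """Convenience wrapper producing a labelled GenotypeDataset with
    synthetic SNP metadata (all on chromosome 1, 1 kb spacing)."""
    X = simulate_genotypes(scenario)
    y = simulate_phenotype(X, scenario)
    n = scenario.n_snps
    width = len(str(n))
    return GenotypeDataset(
        X=X,
        snp_ids=np.array([f"snp{i:0{width}d}" for i in range(n)], dtype=object),
        sample_ids=np.array([f"sample{j}" for j in range(scenario.m_samples)],
                            dtype=object),
        y=y,
        chrom=np.full(n, "1", dtype=object),
        pos=np.arange(1, n + 1) * 1000,
    )
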