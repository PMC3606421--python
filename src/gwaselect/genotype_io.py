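"""Genotype data containers, PLINK binary / TSV readers and writers, and QC.

Genotypes are minor-allele counts stored one byte per entry (``int8``): 0 =
major-allele homozygote, 1 = heterozygote, 2 = minor-allele homozygote, and
``-1`` marks a missing call.  Case/control status is encoded +1 / -1.

Quality control mirrors the standard GWAS pipeline: per-sample missingness
first, then per-SNP Hardy-Weinberg equilibrium in controls, minor allele
frequency, and missingness filters.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

MISSING = np.int8(-1)

#: PLINK .bed 2-bit code -> minor allele count (01 = missing).
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
#: minor allele count (+1 so that -1 maps to slot 0) -> 2-bit code.
_BED_ENCODE = np.array([1, 3, 2, 0], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """The .bed file violates the PLINK binary layout."""


class LabelError(ValueError):
    """A phenotype/label value is outside the accepted encoding."""


AlleleStats = namedtuple("AlleleStats", ["snp", "sample_missing_rate"])


@dataclass
class GenotypeDataset:
    """A feature-by-example genotype matrix with labels and metadata.

    Parameters
    ----------
    X : (n_snps, n_samples) int8 array
        Minor-allele counts in {0, 1, 2}; -1 marks a missing genotype.
    snp_ids, sample_ids : arrays of str
        Unique identifiers for rows and columns of ``X``.
    y : (n_samples,) int8 array
        +1 for cases, -1 for controls.
    chrom, pos : per-SNP chromosome label and base-pair position.
    a1, a2 : per-SNP counted (minor) and other allele; synthesized as
        "A"/"B" when the source format carries no allele information.
    """

    X: np.ndarray
    snp_ids: np.ndarray
    sample_ids: np.ndarray
    y: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D (n_snps, n_samples) matrix")
        n, m = self.X.shape
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.chrom is None:
            self.chrom = np.zeros(n, dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
        if self.pos is None:
            self.pos = np.zeros(n, dtype=np.int64)
        else:
            self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.a1 is None:
            self.a1 = np.full(n, "A", dtype=object)
        else:
            self.a1 = np.asarray(self.a1, dtype=object)
        if self.a2 is None:
            self.a2 = np.full(n, "B", dtype=object)
        else:
            self.a2 = np.asarray(self.a2, dtype=object)
        self.validate()

    # -- basic facts ------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def snp_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos,
             "a1": self.a1, "a2": self.a2}
        )

    def validate(self) -> None:
        n, m = self.X.shape
        bad = ~np.isin(self.X, [-1, 0, 1, 2])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"genotype out of range at SNP row {i}, sample column {j}: "
                f"{int(self.X[i, j])} (expected 0, 1, 2 or missing)"
            )
        if len(self.y) != m:
            raise LabelError(f"{len(self.y)} labels for {m} samples")
        if not np.isin(self.y, [-1, 1]).all():
            raise LabelError("labels must be +1 (case) or -1 (control)")
        for name, ids, k in (("snp", self.snp_ids, n), ("sample", self.sample_ids, m)):
            if len(ids) != k:
                raise ValueError(f"{name}_ids length {len(ids)} != {k}")
            if len(set(ids)) != k:
                raise ValueError(f"duplicated {name} identifiers")

    def has_missing(self) -> bool:
        return bool((self.X == MISSING).any())

    def subset(self, snp_idx=None, sample_idx=None) -> "GenotypeDataset":
        """Return a new dataset restricted to the given row/column indices."""
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        sample_idx = (
            np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        )
        return GenotypeDataset(
            X=self.X[np.ix_(snp_idx, sample_idx)],
            snp_ids=self.snp_ids[snp_idx],
            sample_ids=self.sample_ids[sample_idx],
            y=self.y[sample_idx],
            chrom=self.chrom[snp_idx],
            pos=self.pos[snp_idx],
            a1=self.a1[snp_idx],
            a2=self.a2[snp_idx],
        )


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK .bed/.bim/.fam fileset (SNP-major mode only).

    The .bed payload packs four samples per byte, two bits each, least
    significant pair first; codes 00/10/11 are 2/1/0 copies of allele A1 and
    01 is missing.  The .fam phenotype column must be 1 (control) or 2 (case).
    """
    bed_path, bim_path, fam_path = Path(bed_path), Path(bim_path), Path(fam_path)
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(bim), len(fam)

    bad_pheno = ~fam["pheno"].isin([1, 2])
    if bad_pheno.any():
        off = fam.loc[bad_pheno, "iid"].iloc[0]
        raise LabelError(
            f"sample {off!r} has phenotype {fam.loc[bad_pheno, 'pheno'].iloc[0]!r}; "
            "expected 1 (control) or 2 (case)"
        )
    y = np.where(fam["pheno"].to_numpy() == 2, 1, -1).astype(np.int8)

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK .bed file)")
    if raw[2] == 0x00:
        raise PlinkFormatError(
            f"{bed_path}: individual-major .bed files are not supported"
        )
    if raw[2] != 0x01:
        raise PlinkFormatError(f"{bed_path}: unknown mode byte {raw[2]:#04x}")
    bytes_per_snp = (m + 3) // 4
    if len(raw) != 3 + bytes_per_snp * n:
        raise PlinkFormatError(
            f"{bed_path}: expected {3 + bytes_per_snp * n} bytes for "
            f"{n} SNPs x {m} samples, found {len(raw)} (truncated or corrupt)"
        )

    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n, bytes_per_snp)
    codes = np.empty((n, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):  # unpack 2-bit pairs, sample j lives at bit 2*(j % 4)
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    X = _BED_DECODE[codes[:, :m]]

    return GenotypeDataset(
        X=X,
        snp_ids=bim["snp_id"].to_numpy(dtype=object),
        sample_ids=fam["iid"].to_numpy(dtype=object),
        y=y,
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
    )


def write_plink_binary(ds: GenotypeDataset, prefix) -> tuple[Path, Path, Path]:
    """Write ``ds`` as <prefix>.bed/.bim/.fam (SNP-major); returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = ds.X.shape
    bytes_per_snp = (m + 3) // 4

    codes = np.zeros((n, bytes_per_snp * 4), dtype=np.uint8)
    codes[:, :m] = _BED_ENCODE[ds.X.astype(np.int16) + 1]
    # padding samples beyond m stay 00 (= genotype 2 code, ignored on read)
    packed = np.zeros((n, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)

    bed_path = prefix.with_suffix(".bed")
    bed_path.write_bytes(b"\x6c\x1b\x01" + packed.tobytes())

    bim = pd.DataFrame(
        {"chrom": ds.chrom, "snp_id": ds.snp_ids, "cm": 0, "pos": ds.pos,
         "a1": ds.a1, "a2": ds.a2}
    )
    bim_path = prefix.with_suffix(".bim")
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {"fid": ds.sample_ids, "iid": ds.sample_ids, "father": 0, "mother": 0,
         "sex": 0, "pheno": np.where(ds.y == 1, 2, 1)}
    )
    fam_path = prefix.with_suffix(".fam")
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_tsv(genotype_path, label_path) -> GenotypeDataset:
    """Read the plain-text dialect: a SNP-by-sample genotype table + label map.

    The genotype table is tab-separated with header ``snp_id\\t<sample ids>``
    and entries 0/1/2/NA; the label file maps sample id to case/control
    (accepted spellings: case, control, +1, 1, -1).
    """
    geno = pd.read_csv(genotype_path, sep="\t", dtype=str,
                       keep_default_na=False, na_values=[])
    if geno.shape[1] < 2:
        raise ValueError(f"{genotype_path}: need a snp_id column plus samples")
    snp_ids = geno.iloc[:, 0].to_numpy(dtype=object)
    if len(set(snp_ids)) != len(snp_ids):
        raise ValueError(f"{genotype_path}: duplicated SNP ids")
    sample_ids = np.asarray(geno.columns[1:], dtype=object)

    body = geno.iloc[:, 1:]
    if body.isna().any().any() or (body == "").any().any():
        raise ValueError(f"{genotype_path}: ragged rows (empty cells found)")
    allowed = {"0": 0, "1": 1, "2": 2, "NA": -1, "na": -1, ".": -1}
    X = np.empty(body.shape, dtype=np.int8)
    vals = body.to_numpy()
    for (i, j), v in np.ndenumerate(vals):
        v = v.strip()
        if v not in allowed:
            raise ValueError(
                f"{genotype_path}: invalid genotype {v!r} at SNP "
                f"{snp_ids[i]!r}, sample {sample_ids[j]!r}"
            )
        X[i, j] = allowed[v]

    labels = pd.read_csv(label_path, sep="\t", dtype=str,
                         keep_default_na=False, na_values=[])
    labels.columns = ["sample_id", "status"]
    lab_map = {}
    status_codes = {"case": 1, "control": -1, "+1": 1, "1": 1, "-1": -1}
    for _, row in labels.iterrows():
        s = row["status"].strip().lower()
        if s not in status_codes:
            raise LabelError(f"{label_path}: bad status {row['status']!r}")
        lab_map[row["sample_id"]] = status_codes[s]
    absent = [s for s in sample_ids if s not in lab_map]
    if absent:
        raise LabelError(f"samples missing from label file: {absent}")
    y = np.array([lab_map[s] for s in sample_ids], dtype=np.int8)
    return GenotypeDataset(X=X, snp_ids=snp_ids, sample_ids=sample_ids, y=y)


def write_tsv(ds: GenotypeDataset, genotype_path, label_path) -> None:
    body = np.where(ds.X == MISSING, "NA", ds.X.astype(str))
    table = pd.DataFrame(body, columns=list(ds.sample_ids))
    table.insert(0, "snp_id", ds.snp_ids)
    table.to_csv(genotype_path, sep="\t", index=False)
    labels = pd.DataFrame(
        {"sample_id": ds.sample_ids,
         "status": np.where(ds.y == 1, "case", "control")}
    )
    labels.to_csv(label_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Imputation and allele statistics
# ---------------------------------------------------------------------------

def impute_missing(ds: GenotypeDataset, strategy: str = "mode") -> GenotypeDataset:
    """Fill missing genotypes per SNP.

    ``mode``: most frequent genotype (ties toward the smaller count);
    ``mean-rounded``: non-missing mean, rounded half-up; ``zero``: 0.
    """
    if strategy not in {"mode", "mean-rounded", "zero"}:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if not ds.has_missing():
        return ds
    X = ds.X.copy()
    miss = X == MISSING
    all_missing = miss.all(axis=1)
    if all_missing.any():
        raise ValueError(
            f"cannot impute SNP(s) with every genotype missing: "
            f"{list(ds.snp_ids[all_missing])}"
        )
    rows = np.flatnonzero(miss.any(axis=1))
    for i in rows:
        obs = X[i][~miss[i]]
        if strategy == "mode":
            fill = int(np.bincount(obs, minlength=3).argmax())
        elif strategy == "mean-rounded":
            fill = int(min(2, math.floor(obs.mean() + 0.5)))
        else:
            fill = 0
        X[i, miss[i]] = fill
    return GenotypeDataset(
        X=X, snp_ids=ds.snp_ids, sample_ids=ds.sample_ids, y=ds.y,
        chrom=ds.chrom, pos=ds.pos, a1=ds.a1, a2=ds.a2,
    )


def allele_stats(ds: GenotypeDataset) -> AlleleStats:
    """Per-SNP minor allele frequency and missing rate, per-sample missing rate.

    MAF is min(f, 1-f) with f = (sum of non-missing counts) / (2 * #non-missing).
    A SNP with no non-missing calls gets missing_rate 1 and MAF NaN (flagged
    via ``maf_defined = False``).
    """
    nonmiss = ds.X != MISSING
    n_obs = nonmiss.sum(axis=1)
    counts = np.where(nonmiss, ds.X, 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = counts / (2.0 * n_obs)
    maf = np.minimum(f, 1.0 - f)
    maf_defined = n_obs > 0
    maf = np.where(maf_defined, maf, np.nan)
    snp = pd.DataFrame(
        {"snp_id": ds.snp_ids,
         "maf": maf,
         "missing_rate": 1.0 - n_obs / ds.n_samples,
         "maf_defined": maf_defined}
    )
    sample_missing = 1.0 - nonmiss.sum(axis=0) / ds.n_snps
    return AlleleStats(snp=snp, sample_missing_rate=sample_missing)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_test(n_hom_major: int, n_het: int, n_hom_minor: int,
             method: str = "chisq") -> float:
    """HWE goodness-of-fit p-value from genotype counts.

    ``chisq`` (default): 1-df chi-square against expected counts
    N(1-f)^2, 2Nf(1-f), Nf^2 where f is the minor allele frequency.
    ``exact``: mid-p exact test enumerating heterozygote counts conditional
    on the allele counts.  Monomorphic input returns 1 by convention.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    N = sum(counts)
    if N == 0:
        raise ValueError("HWE test needs at least one genotype")
    n_minor = n_het + 2 * n_hom_minor
    f = n_minor / (2.0 * N)
    if f == 0.0 or f == 1.0:
        return 1.0
    if method == "chisq":
        exp = np.array([N * (1 - f) ** 2, 2 * N * f * (1 - f), N * f ** 2])
        chi2 = float(((np.array(counts) - exp) ** 2 / exp).sum())
        return float(sps.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact_midp(N, n_minor, n_het)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact_midp(N: int, n_minor: int, het_obs: int) -> float:
    # het counts share the parity of the minor allele count
    hs = np.arange(n_minor % 2, min(n_minor, 2 * N - n_minor) + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = N - hs - hom_minor
    logp = (
        gammaln(N + 1) - gammaln(hom_major + 1) - gammaln(hs + 1)
        - gammaln(hom_minor + 1) + hs * math.log(2)
        + gammaln(n_minor + 1) + gammaln(2 * N - n_minor + 1) - gammaln(2 * N + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = p[hs == het_obs][0]
    lower = p[p < p_obs * (1 - 1e-12)].sum()
    equal = p[np.abs(p - p_obs) <= p_obs * 1e-12].sum()
    return float(min(1.0, lower + 0.5 * equal))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-SNP and per-sample filter decisions with first-triggered reasons."""

    snp: pd.DataFrame      # snp_id, maf, missing_rate, hwe_p, kept, reason
    sample: pd.DataFrame   # sample_id, missing_rate, kept, reason
    thresholds: dict = field(default_factory=dict)

    @property
    def n_snps_kept(self) -> int:
        return int(self.snp["kept"].sum())

    @property
    def n_samples_kept(self) -> int:
        return int(self.sample["kept"].sum())


def apply_qc(
    ds: GenotypeDataset,
    hwe_threshold: float = 1e-3,
    maf_threshold: float = 0.01,
    snp_missing_threshold: float = 0.05,
    sample_missing_threshold: float = 0.05,
    hwe_method: str = "chisq",
) -> tuple[GenotypeDataset, QCReport]:
    """Standard case-control QC: drop high-missingness samples, then SNPs
    failing HWE in controls (p < threshold), MAF, or missingness.

    Per-SNP statistics are recomputed after the sample filter.  Each dropped
    item records the first filter it failed (checked in the order HWE, MAF,
    missingness for SNPs).
    """
    st = allele_stats(ds)
    samp_miss = st.sample_missing_rate
    samp_kept = samp_miss <= sample_missing_threshold
    sample_report = pd.DataFrame(
        {"sample_id": ds.sample_ids, "missing_rate": samp_miss,
         "kept": samp_kept,
         "reason": np.where(samp_kept, "", "sample_missing_rate")}
    )
    if not samp_kept.any():
        raise ValueError("QC dropped every sample")
    kept_samples = np.flatnonzero(samp_kept)
    ds2 = ds.subset(sample_idx=kept_samples)

    st2 = allele_stats(ds2).snp
    controls = ds2.y == -1
    hwe_p = np.ones(ds2.n_snps)
    if controls.any():
        Xc = ds2.X[:, controls]
        obs = Xc != MISSING
        for i in range(ds2.n_snps):
            g = Xc[i][obs[i]]
            if g.size == 0:
                hwe_p[i] = 1.0
                continue
            c = np.bincount(g, minlength=3)
            hwe_p[i] = hwe_test(int(c[0]), int(c[1]), int(c[2]), method=hwe_method)

    maf = st2["maf"].to_numpy()
    snp_miss = st2["missing_rate"].to_numpy()
    reasons = np.full(ds2.n_snps, "", dtype=object)
    fail_hwe = hwe_p < hwe_threshold
    fail_maf = np.isnan(maf) | (maf < maf_threshold)
    fail_miss = snp_miss > snp_missing_threshold
    reasons[fail_miss] = "missing_rate"
    reasons[fail_maf] = "maf"
    reasons[fail_hwe] = "hwe"  # first-checked filter wins
    snp_kept = reasons == ""
    snp_report = pd.DataFrame(
        {"snp_id": ds2.snp_ids, "maf": maf, "missing_rate": snp_miss,
         "hwe_p": hwe_p, "kept": snp_kept, "reason": reasons}
    )
    if not snp_kept.any():
        raise ValueError("QC dropped every SNP")

    out = ds2.subset(snp_idx=np.flatnonzero(snp_kept))
    report = QCReport(
        snp=snp_report, sample=sample_report,
        thresholds={
            "hwe_threshold": hwe_threshold,
            "maf_threshold": maf_threshold,
            "snp_missing_threshold": snp_missing_threshold,
            "sample_missing_threshold": sample_missing_threshold,
        },
    )
    return out, report
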