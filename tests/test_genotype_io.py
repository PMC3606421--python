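"""PLINK binary / TSV IO, imputation, allele statistics, HWE and QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gwaselect.genotype_io import (
    MISSING,
    GenotypeDataset,
    LabelError,
    PlinkFormatError,
    allele_stats,
    apply_qc,
    hwe_test,
    impute_missing,
    read_plink_binary,
    read_tsv,
    write_plink_binary,
    write_tsv,
)


def make_dataset(X, y, **kw):
    X = np.asarray(X, dtype=np.int8)
    n, m = X.shape
    return GenotypeDataset(
        X=X,
        snp_ids=kw.pop("snp_ids", [f"rs{i}" for i in range(n)]),
        sample_ids=kw.pop("sample_ids", [f"s{j}" for j in range(m)]),
        y=np.asarray(y, dtype=np.int8),
        **kw,
    )


def random_dataset(seed, n=10, m=8, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing_rate:
        X[rng.random((n, m)) < missing_rate] = MISSING
    y = rng.choice([-1, 1], size=m).astype(np.int8)
    if np.all(y == y[0]):
        y[0] = -y[0]
    return make_dataset(X, y)


def write_fileset(tmp_path, name, bed_payload, bim_lines, fam_lines):
    bed = tmp_path / f"{name}.bed"
    bed.write_bytes(bed_payload)
    (tmp_path / f"{name}.bim").write_text("\n".join(bim_lines) + "\n")
    (tmp_path / f"{name}.fam").write_text("\n".join(fam_lines) + "\n")
    return bed, tmp_path / f"{name}.bim", tmp_path / f"{name}.fam"


class TestDatasetInvariants:
    def test_out_of_range_genotype_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            make_dataset([[0, 3]], [1, -1])

    def test_label_domain_enforced(self):
        with pytest.raises(LabelError):
            make_dataset([[0, 1]], [1, 0])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicated snp"):
            make_dataset([[0, 1], [1, 2]], [1, -1], snp_ids=["a", "a"])

    def test_one_byte_storage(self):
        ds = random_dataset(0)
        assert ds.X.dtype == np.int8


class TestPlinkBinary:
    def test_bad_magic_bytes(self, tmp_path):
        paths = write_fileset(tmp_path, "bad", b"\x00\x00\x01\x00",
                              ["1 rs1 0 100 A G"], ["f1 s1 0 0 0 1"])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink_binary(*paths)

    def test_individual_major_rejected(self, tmp_path):
        paths = write_fileset(tmp_path, "im", b"\x6c\x1b\x00\x00",
                              ["1 rs1 0 100 A G"], ["f1 s1 0 0 0 1"])
        with pytest.raises(PlinkFormatError, match="individual-major"):
            read_plink_binary(*paths)

    def test_truncated_payload(self, tmp_path):
        paths = write_fileset(tmp_path, "tr", b"\x6c\x1b\x01",
                              ["1 rs1 0 100 A G"], ["f1 s1 0 0 0 1"])
        with pytest.raises(PlinkFormatError, match="truncated|corrupt"):
            read_plink_binary(*paths)

    def test_handcrafted_byte_decodes_per_bit_layout(self, tmp_path):
        # byte 0b11_10_01_00: sample 1 owns the lowest bit pair
        payload = b"\x6c\x1b\x01" + bytes([0b11100100])
        paths = write_fileset(
            tmp_path, "hand", payload, ["1 rs1 0 100 A G"],
            [f"f{j} s{j} 0 0 0 {p}" for j, p in enumerate([2, 1, 2, 1], 1)],
        )
        ds = read_plink_binary(*paths)
        np.testing.assert_array_equal(ds.X[0], [2, MISSING, 1, 0])
        np.testing.assert_array_equal(ds.y, [1, -1, 1, -1])

    def test_padding_bits_ignored_for_five_samples(self, tmp_path):
        # 5 samples -> 2 bytes; second byte: sample 5 = code 10 (one copy),
        # padding bits set to garbage 1s that must be ignored
        payload = b"\x6c\x1b\x01" + bytes([0b11100100, 0b11111110])
        paths = write_fileset(
            tmp_path, "pad", payload, ["1 rs1 0 100 A G"],
            [f"f{j} s{j} 0 0 0 1" for j in range(1, 6)],
        )
        ds = read_plink_binary(*paths)
        assert ds.X.shape == (1, 5)
        np.testing.assert_array_equal(ds.X[0], [2, MISSING, 1, 0, 1])

    def test_bad_phenotype_names_sample(self, tmp_path):
        payload = b"\x6c\x1b\x01" + bytes([0b00000000])
        paths = write_fileset(tmp_path, "ph", payload, ["1 rs1 0 100 A G"],
                              ["f1 s1 0 0 0 9"])
        with pytest.raises(LabelError, match="s1"):
            read_plink_binary(*paths)

    @pytest.mark.parametrize("seed", range(3))
    def test_round_trip_identity(self, tmp_path, seed):
        ds = random_dataset(seed, n=7, m=9, missing_rate=0.15)
        write_plink_binary(ds, tmp_path / "rt")
        back = read_plink_binary(tmp_path / "rt.bed", tmp_path / "rt.bim",
                                 tmp_path / "rt.fam")
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)
        assert list(back.snp_ids) == list(ds.snp_ids)
        assert list(back.sample_ids) == list(ds.sample_ids)


class TestTsvDialect:
    def test_small_table(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "snp_id\ts1\ts2\ts3\nrs1\t0\t0\t0\nrs2\t0\t0\t0\n")
        (tmp_path / "l.tsv").write_text(
            "sample_id\tstatus\ns1\tcase\ns2\tcontrol\ns3\tcase\n")
        ds = read_tsv(tmp_path / "g.tsv", tmp_path / "l.tsv")
        np.testing.assert_array_equal(ds.X, 0)
        np.testing.assert_array_equal(ds.y, [1, -1, 1])

    def test_out_of_domain_entry_is_located(self, tmp_path):
        (tmp_path / "g.tsv").write_text("snp_id\ts1\ts2\nrs1\t0\t3\n")
        (tmp_path / "l.tsv").write_text("sample_id\tstatus\ns1\tcase\ns2\tcontrol\n")
        with pytest.raises(ValueError, match="rs1.*s2"):
            read_tsv(tmp_path / "g.tsv", tmp_path / "l.tsv")

    def test_missing_labels_listed(self, tmp_path):
        (tmp_path / "g.tsv").write_text("snp_id\ts1\ts2\nrs1\t0\t1\n")
        (tmp_path / "l.tsv").write_text("sample_id\tstatus\ns1\tcase\n")
        with pytest.raises(LabelError, match="s2"):
            read_tsv(tmp_path / "g.tsv", tmp_path / "l.tsv")

    def test_duplicate_snp_ids_rejected(self, tmp_path):
        (tmp_path / "g.tsv").write_text("snp_id\ts1\nrs1\t0\nrs1\t1\n")
        (tmp_path / "l.tsv").write_text("sample_id\tstatus\ns1\tcase\n")
        with pytest.raises(ValueError, match="duplicated"):
            read_tsv(tmp_path / "g.tsv", tmp_path / "l.tsv")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_identity(self, tmp_path, seed):
        ds = random_dataset(seed, n=10, m=8, missing_rate=0.2)
        write_tsv(ds, tmp_path / "g.tsv", tmp_path / "l.tsv")
        back = read_tsv(tmp_path / "g.tsv", tmp_path / "l.tsv")
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)


class TestImputation:
    def test_complete_data_returned_unchanged(self):
        ds = random_dataset(1)
        assert impute_missing(ds, "mode") is ds

    def test_mode_fill_is_most_frequent(self):
        ds = make_dataset([[0, 0, 1, MISSING]], [1, -1, 1, -1])
        out = impute_missing(ds, "mode")
        np.testing.assert_array_equal(out.X[0], [0, 0, 1, 0])

    def test_mode_tie_prefers_smaller_genotype(self):
        ds = make_dataset([[0, 0, 1, 1, MISSING]], [1, -1, 1, -1, 1])
        assert impute_missing(ds, "mode").X[0, 4] == 0

    def test_mean_rounded_hand_arithmetic(self):
        ds = make_dataset([[0, 1, 1, MISSING, 2]], [1, -1, 1, -1, 1])
        # mean of observed = 4/4 = 1
        assert impute_missing(ds, "mean-rounded").X[0, 3] == 1

    def test_all_missing_snp_is_an_error(self):
        ds = make_dataset([[MISSING, MISSING]], [1, -1])
        with pytest.raises(ValueError, match="rs0"):
            impute_missing(ds, "mode")


class TestAlleleStats:
    def test_definitional_counts(self):
        ds = make_dataset([[0, 1, 2, 2], [0, 0, 0, 0], [0, MISSING, MISSING, 2]],
                          [1, -1, 1, -1])
        st = allele_stats(ds)
        assert st.snp["maf"][0] == pytest.approx(3 / 8)
        assert st.snp["maf"][1] == 0.0
        assert st.snp["missing_rate"][2] == pytest.approx(0.5)
        assert st.snp["maf"][2] == pytest.approx(0.5)

    def test_fully_missing_snp_flagged(self):
        ds = make_dataset([[MISSING, MISSING], [0, 1]], [1, -1])
        st = allele_stats(ds)
        assert st.snp["missing_rate"][0] == 1.0
        assert not st.snp["maf_defined"][0]

    def test_maf_invariant_under_allele_swap(self):
        ds = random_dataset(7, n=12, m=20, missing_rate=0.1)
        swapped = make_dataset(
            np.where(ds.X == MISSING, MISSING, 2 - ds.X), ds.y
        )
        np.testing.assert_allclose(
            allele_stats(ds).snp["maf"], allele_stats(swapped).snp["maf"],
            atol=1e-12,
        )

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 8), m=st.integers(2, 12))
    def test_maf_swap_property(self, seed, n, m):
        ds = random_dataset(seed, n=n, m=m, missing_rate=0.2)
        swapped = make_dataset(np.where(ds.X == MISSING, MISSING, 2 - ds.X), ds.y)
        np.testing.assert_allclose(
            allele_stats(ds).snp["maf"], allele_stats(swapped).snp["maf"],
            atol=1e-12,
        )


class TestHWE:
    def test_exact_fit_gives_p_one(self):
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_convention(self):
        assert hwe_test(10, 0, 0) == 1.0
        assert hwe_test(0, 0, 7) == 1.0

    def test_chi_square_against_hand_computation(self):
        # counts (50, 20, 30): f = 0.4, expected (36, 48, 16)
        obs = np.array([50, 20, 30])
        exp = np.array([36.0, 48.0, 16.0])
        chi2 = float((((obs - exp) ** 2) / exp).sum())
        assert hwe_test(50, 20, 30) == pytest.approx(
            sps.chi2.sf(chi2, 1), abs=1e-10
        )

    def test_exact_midp_matches_exact_enumeration(self):
        from fractions import Fraction
        from math import comb
        N, counts = 20, (12, 6, 2)
        n_minor = counts[1] + 2 * counts[2]
        probs = {}
        for h in range(n_minor % 2, min(n_minor, 2 * N - n_minor) + 1, 2):
            hm = (n_minor - h) // 2
            hM = N - h - hm
            probs[h] = (Fraction(comb(N, hM) * comb(N - hM, h) * 2 ** h)
                        * Fraction(1))
        tot = sum(probs.values())
        p_obs = probs[counts[1]]
        midp = (sum(p for p in probs.values() if p < p_obs)
                + Fraction(1, 2) * sum(p for p in probs.values() if p == p_obs))
        assert hwe_test(*counts, method="exact") == pytest.approx(
            float(midp / tot), abs=1e-10
        )

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            hwe_test(-1, 0, 0)
        with pytest.raises(ValueError):
            hwe_test(0, 0, 0)


class TestQC:
    def test_clean_dataset_passes_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(20, 200)).astype(np.int8)
        y = np.tile([1, -1], 100).astype(np.int8)
        ds = make_dataset(X, y)
        out, report = apply_qc(ds)
        assert out.n_snps == 20 and out.n_samples == 200
        assert report.snp["kept"].all() and report.sample["kept"].all()

    def test_low_maf_snp_dropped_with_reason(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, size=(10, 400)).astype(np.int8)
        X[6] = 0
        X[6, :2] = 1  # maf = 2/800 = 0.0025 < 0.01
        y = np.tile([1, -1], 200).astype(np.int8)
        out, report = apply_qc(make_dataset(X, y))
        assert out.n_snps == 9
        dropped = report.snp[~report.snp["kept"]]
        assert list(dropped["snp_id"]) == ["rs6"]
        assert list(dropped["reason"]) == ["maf"]

    def test_bad_sample_dropped_before_snp_stats(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.4, size=(10, 60)).astype(np.int8)
        X[:6, 0] = MISSING  # sample 0 is 60% missing
        y = np.tile([1, -1], 30).astype(np.int8)
        out, report = apply_qc(make_dataset(X, y))
        assert not report.sample["kept"][0]
        assert report.sample["reason"][0] == "sample_missing_rate"
        # SNP missing rates must be computed after the drop: nothing left missing
        assert report.snp["missing_rate"].max() == 0.0
        assert out.n_samples == 59

    def test_hwe_failure_in_controls_detected(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.4, size=(5, 300)).astype(np.int8)
        y = np.tile([1, -1], 150).astype(np.int8)
        controls = y == -1
        # plant extreme heterozygote deficit in controls only
        X[2, controls] = np.where(np.arange(controls.sum()) % 2 == 0, 0, 2)
        out, report = apply_qc(make_dataset(X, y))
        assert report.snp["reason"][2] == "hwe"
        assert out.n_snps == 4

    def test_idempotent(self):
        ds = random_dataset(9, n=30, m=150, missing_rate=0.02)
        once, _ = apply_qc(ds)
        twice, rep = apply_qc(once)
        np.testing.assert_array_equal(once.X, twice.X)
        assert rep.snp["kept"].all() and rep.sample["kept"].all()

    def test_everything_dropped_is_explicit(self):
        ds = make_dataset([[0, 1, 0, 1]], [1, 1, -1, -1])  # maf 0.25 ok
        with pytest.raises(ValueError, match="every SNP"):
            apply_qc(ds, maf_threshold=0.6)
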