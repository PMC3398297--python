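"""Tests for dosage/VCF readers, the genome-wide scan loop, and result tables."""

import gzip
import math

import numpy as np
import pandas as pd
import pytest

from vqtlscan import (
    DosageMatrix,
    brown_forsythe_levene,
    hard_call,
    read_dosage_table,
    read_results,
    read_vcf_dosages,
    run_scan,
    svlm_test,
    write_dosage_table,
    write_results,
)


def _random_scan_fixture(rng, n_snps=20, n_samples=500, p=0.5):
    dose = rng.binomial(2, p, size=(n_snps, n_samples)).astype(float)
    dm = DosageMatrix(
        snp_ids=[f"rs{i}" for i in range(n_snps)],
        a1=["A"] * n_snps,
        a2=["G"] * n_snps,
        samples=[f"s{i}" for i in range(n_samples)],
        dose=dose,
    )
    pheno = pd.Series(rng.standard_normal(n_samples), index=dm.samples, name="y")
    return dm, pheno


class TestDosageTable:
    def test_roundtrip_parses_exact_values(self, dosage_file, small_dosage_matrix):
        dm = read_dosage_table(dosage_file)
        assert dm.snp_ids == ["rs1", "rs2"]
        assert dm.a1 == ["A", "C"] and dm.a2 == ["G", "T"]
        assert dm.samples == ["s1", "s2", "s3"]
        ref = small_dosage_matrix.dose
        assert np.array_equal(np.isnan(dm.dose), np.isnan(ref))
        assert np.allclose(dm.dose[np.isfinite(dm.dose)], ref[np.isfinite(ref)])

    def test_write_read_write_is_byte_identical(self, dosage_file, tmp_path):
        again = tmp_path / "again.txt"
        write_dosage_table(read_dosage_table(dosage_file), again)
        assert again.read_bytes() == dosage_file.read_bytes()

    def test_gzip_detected_by_suffix(self, small_dosage_matrix, tmp_path):
        path = tmp_path / "dose.txt.gz"
        write_dosage_table(small_dosage_matrix, path)
        with gzip.open(path, "rt") as fh:
            assert fh.readline().startswith("SNP A1 A2")
        dm = read_dosage_table(path)
        assert dm.n_snps == 2

    def test_out_of_range_dose_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("SNP A1 A2 s1 s2\nrs1 A G 0.5 2.4\n")
        with pytest.raises(ValueError, match=r"bad.txt:2.*rs1.*s2"):
            read_dosage_table(path)

    def test_ragged_row_and_duplicate_snp_rejected(self, tmp_path):
        path = tmp_path / "ragged.txt"
        path.write_text("SNP A1 A2 s1 s2\nrs1 A G 0.5\n")
        with pytest.raises(ValueError, match="ragged.txt:2"):
            read_dosage_table(path)
        path.write_text("SNP A1 A2 s1 s2\nrs1 A G 0 1\nrs1 C T 1 2\n")
        with pytest.raises(ValueError, match="duplicate SNP"):
            read_dosage_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "hdr.txt"
        path.write_text("ID REF ALT s1\nrs1 A G 0.5\n")
        with pytest.raises(ValueError, match="hdr.txt:1"):
            read_dosage_table(path)


class TestVcfDosages:
    def test_hand_authored_records(self, vcf_file):
        with pytest.warns(UserWarning):
            dm = read_vcf_dosages(vcf_file)
        # multi-allelic and GT-only records skipped
        assert dm.snp_ids == ["rs_ds", "rs_gp", "rs_both"]
        assert dm.samples == ["s1", "s2", "s3", "s4"]
        # DS copied through
        assert np.allclose(dm.dose[0], [0.12, 1.0, 1.9, 0.0])
        # GP -> P(het) + 2 P(hom-alt); worked example 0.18 + 2*0.01 = 0.20
        assert dm.dose[1, 0] == pytest.approx(0.20, abs=1e-9)
        assert np.allclose(dm.dose[1], [0.20, 1.0, 1.95, 0.0])
        # DS takes precedence over GP
        assert dm.dose[2, 0] == pytest.approx(1.37, abs=1e-9)
        # effect allele is ALT
        assert dm.a1 == ["G", "T", "A"] and dm.a2 == ["A", "C", "G"]

    def test_doses_within_range(self, vcf_file):
        with pytest.warns(UserWarning):
            dm = read_vcf_dosages(vcf_file)
        finite = dm.dose[np.isfinite(dm.dose)]
        assert finite.min() >= 0 and finite.max() <= 2


class TestRunScan:
    def test_scan_is_map_of_single_snp_test(self, rng):
        dm, pheno = _random_scan_fixture(rng)
        records = run_scan(dm, pheno, test="svlm")
        assert len(records) == dm.n_snps
        for i in (0, 7, 19):
            ref = svlm_test(pheno.to_numpy(), dm.dose[i])
            rec = records[i]
            assert rec.mean_beta == pytest.approx(ref.stage1_beta, rel=1e-12)
            assert rec.var_beta == pytest.approx(ref.stage2_beta, rel=1e-12)
            assert rec.var_p == pytest.approx(ref.stage2_p, rel=1e-12)
            assert rec.n_used == ref.n_used
            assert rec.status == "ok"  # groups ~125/250/125, all above 80

    def test_levene_route_hard_calls_then_tests(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=5)
        records = run_scan(dm, pheno, test="levene", max_distance=0.5)
        for i, rec in enumerate(records):
            g = hard_call(dm.dose[i], 0.5)
            ref = brown_forsythe_levene(pheno.to_numpy(), g)
            assert rec.var_p == pytest.approx(ref.p_value, rel=1e-12)
            assert math.isnan(rec.var_beta)
            assert rec.test_used == "levene"

    def test_eaf_matches_dose_mean(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=3)
        records = run_scan(dm, pheno)
        for i, rec in enumerate(records):
            assert rec.eaf == pytest.approx(dm.dose[i].mean() / 2, abs=1e-12)

    def test_monomorphic_snp_reported_not_fatal(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=3)
        dm.dose[1] = 2.0
        records = run_scan(dm, pheno)
        assert records[1].status == "monomorphic"
        assert math.isnan(records[1].var_p)
        assert records[1].eaf == 1.0
        assert records[0].status == "ok" and records[2].status == "ok"

    def test_low_group_count_flagged_but_reported(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=2, p=0.03)
        records = run_scan(dm, pheno)
        flagged = [r for r in records if r.status == "low_group_count"]
        assert flagged
        assert all(math.isfinite(r.var_p) for r in flagged)

    def test_row_and_sample_permutation_invariance(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=6, n_samples=120)
        base = run_scan(dm, pheno)
        row_order = rng.permutation(dm.n_snps)
        dm_rows = DosageMatrix(
            snp_ids=[dm.snp_ids[i] for i in row_order],
            a1=[dm.a1[i] for i in row_order],
            a2=[dm.a2[i] for i in row_order],
            samples=dm.samples,
            dose=dm.dose[row_order],
        )
        permuted = run_scan(dm_rows, pheno)
        assert [r.snp_id for r in permuted] == [dm.snp_ids[i] for i in row_order]
        by_id = {r.snp_id: r for r in base}
        for rec in permuted:
            assert rec == by_id[rec.snp_id]

        col_order = rng.permutation(dm.n_samples)
        dm_cols = DosageMatrix(
            snp_ids=dm.snp_ids,
            a1=dm.a1,
            a2=dm.a2,
            samples=[dm.samples[j] for j in col_order],
            dose=dm.dose[:, col_order],
        )
        # numeric fields agree to accumulation-order precision
        for got, ref in zip(run_scan(dm_cols, pheno), base):
            assert (got.snp_id, got.status, got.n_used) == (
                ref.snp_id,
                ref.status,
                ref.n_used,
            )
            for col in ("eaf", "mean_beta", "mean_se", "mean_p",
                        "var_beta", "var_se", "var_p"):
                assert getattr(got, col) == pytest.approx(
                    getattr(ref, col), rel=1e-9, abs=1e-12
                )

    def test_covariates_enter_stage1(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=2, n_samples=150)
        covar = pd.DataFrame(
            {"age": rng.uniform(30, 70, 150)}, index=dm.samples
        )
        rec = run_scan(dm, pheno, covar)[0]
        ref = svlm_test(pheno.to_numpy(), dm.dose[0], covar.to_numpy())
        assert rec.mean_beta == pytest.approx(ref.stage1_beta, rel=1e-12)
        assert rec.var_p == pytest.approx(ref.stage2_p, rel=1e-12)

    def test_tests_agree_on_monomorphic_for_integral_dosages(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=4, n_samples=100)
        dm.dose[2] = 0.0
        svlm_status = [r.status for r in run_scan(dm, pheno, test="svlm")]
        lev_status = [r.status for r in run_scan(dm, pheno, test="levene")]
        assert [s == "monomorphic" for s in svlm_status] == [
            s == "monomorphic" for s in lev_status
        ]

    def test_small_intersection_rejected(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=2, n_samples=30)
        with pytest.raises(ValueError, match="intersection"):
            run_scan(dm, pheno.iloc[:5])

    def test_null_scan_rejection_rate_near_alpha(self, rng):
        dm, pheno = _random_scan_fixture(rng, n_snps=2000, n_samples=500, p=0.3)
        records = run_scan(dm, pheno)
        pvals = np.array([r.var_p for r in records if math.isfinite(r.var_p)])
        frac = (pvals <= 0.05).mean()
        se = math.sqrt(0.05 * 0.95 / pvals.size)
        assert abs(frac - 0.05) < 3 * se


class TestResultsTable:
    def test_written_file_shape_and_roundtrip(self, rng, tmp_path):
        dm, pheno = _random_scan_fixture(rng, n_snps=3)
        dm.dose[1] = 1.0  # monomorphic row
        records = run_scan(dm, pheno)
        out = tmp_path / "scan.tsv"
        write_results(records, out)
        lines = out.read_text().splitlines()
        assert len(lines) == 4  # header + 3 records
        df = read_results(out)
        assert list(df["snp_id"]) == [r.snp_id for r in records]
        # numeric fields survive at printed precision
        for i, rec in enumerate(records):
            for col in ("eaf", "mean_beta", "var_p"):
                written = df[col][i]
                orig = getattr(rec, col)
                if math.isnan(orig):
                    assert math.isnan(written)
                else:
                    assert written == pytest.approx(orig, rel=1e-5)
        # monomorphic row: NA statistics, populated id and eaf
        assert math.isnan(df["var_p"][1]) and math.isnan(df["mean_beta"][1])
        assert df["snp_id"][1] == "rs1" and df["eaf"][1] == 0.5

    def test_pvalues_in_scientific_notation(self, rng, tmp_path):
        dm, pheno = _random_scan_fixture(rng, n_snps=1)
        out = tmp_path / "scan.tsv"
        write_results(run_scan(dm, pheno), out)
        header, row = out.read_text().splitlines()
        var_p = row.split("\t")[header.split("\t").index("var_p")]
        assert "e" in var_p  # 6-digit scientific notation

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_results([], tmp_path / "x.tsv")
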