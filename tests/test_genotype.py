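"""Genotype IO, per-SNP statistics, QC rules, and kinship."""

import numpy as np
import pandas as pd
import pytest

from metagwas import (
    DataFormatError,
    GenotypeMatrix,
    ModelError,
    SimConfig,
    apply_qc,
    compute_kinship,
    compute_snp_stats,
    read_genotypes,
    simulate_genotypes,
    write_genotypes,
)

from conftest import make_genotypes


class TestTsvRoundTrip:
    def test_small_matrix_round_trips_with_missing(self, tmp_path):
        G = make_genotypes([[0, 1], [2, np.nan], [1, 0]])
        path = tmp_path / "g.tsv"
        write_genotypes(G, path)
        G2 = read_genotypes(path)
        assert G2.dosage.shape == (3, 2)
        assert np.isnan(G2.dosage).sum() == 1
        np.testing.assert_array_equal(
            np.nan_to_num(G.dosage, nan=-1), np.nan_to_num(G2.dosage, nan=-1)
        )
        assert G2.accession_ids == G.accession_ids
        assert G2.snp_ids == G.snp_ids

    def test_bad_dosage_token_names_row_and_accession(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "snp_id\tchrom\tpos\tallele1\tallele2\tA1\tA2\n"
            "S1\tChr1\t100\tA\tG\t0\t3\n"
        )
        with pytest.raises(DataFormatError, match="'3'.*A2|A2.*'3'"):
            read_genotypes(path)

    def test_duplicate_snp_ids_rejected(self):
        snp_map = pd.DataFrame(
            {
                "snp_id": ["S1", "S1"],
                "chrom": ["Chr1", "Chr1"],
                "pos": [1, 2],
                "allele1": ["A", "A"],
                "allele2": ["G", "G"],
            }
        )
        with pytest.raises(DataFormatError, match="duplicate SNP ids"):
            GenotypeMatrix(np.zeros((2, 2)), ["A1", "A2"], snp_map)


class TestVcf:
    def test_gt_codes_map_to_dosages(self, tmp_path):
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA1\tA2\tA3\n"
            "Chr1\t100\tS1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "Chr1\t200\tS2\tC\tT\t.\t.\t.\tGT\t./.\t0/0\t0/1\n"
            "Chr1\t300\tS3\tC\tT,G\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
        )
        G = read_genotypes(vcf)
        assert G.snp_ids == ["S1", "S2"]  # multi-allelic S3 dropped
        np.testing.assert_array_equal(G.dosage[:, 0], [0, 1, 2])
        assert np.isnan(G.dosage[0, 1])
        np.testing.assert_array_equal(G.dosage[1:, 1], [0, 1])


class TestSnpStats:
    @pytest.mark.parametrize(
        "column, call_rate, maf, het",
        [
            ([0, 0, 1, 2], 1.0, 0.375, 0.25),
            ([2, 2, 2, 2], 1.0, 0.0, 0.0),
            ([0, np.nan, np.nan, np.nan], 0.25, 0.0, 0.0),
        ],
    )
    def test_hand_counted_columns(self, column, call_rate, maf, het):
        G = make_genotypes(np.array(column, dtype=float).reshape(-1, 1))
        stats = compute_snp_stats(G)
        assert stats["call_rate"].iloc[0] == pytest.approx(call_rate)
        assert stats["maf"].iloc[0] == pytest.approx(maf)
        assert stats["het_rate"].iloc[0] == pytest.approx(het)

    def test_all_missing_snp_flagged_not_zeroed(self):
        G = make_genotypes(np.full((3, 1), np.nan))
        stats = compute_snp_stats(G)
        assert bool(stats["all_missing"].iloc[0])
        assert np.isnan(stats["maf"].iloc[0])
        assert np.isnan(stats["het_rate"].iloc[0])


class TestApplyQc:
    def test_hand_filter_keeps_only_the_clean_snp(self, toy_qc_genotypes):
        filtered, report = apply_qc(toy_qc_genotypes, het_max=0.15)
        assert filtered.snp_ids == ["S4"]
        assert report.n_input == 4
        assert report.n_output == 1
        # input = output + failing at least one rule
        assert report.n_input == report.n_output + report.n_removed
        assert report.n_fail_het == 2  # S1 and S3
        assert report.n_fail_maf == 1  # S2
        assert report.n_fail_call_rate == 1  # S3
        assert report.n_fail_multiple == 1  # S3 fails two rules

    def test_vacuous_thresholds_keep_everything(self, toy_qc_genotypes):
        filtered, report = apply_qc(toy_qc_genotypes, call_rate_min=0.0,
                                    maf_min=0.0, het_max=1.0)
        assert filtered.snp_ids == toy_qc_genotypes.snp_ids
        assert report.n_removed == 0

    def test_call_rate_boundary_is_strict(self):
        # call rate exactly 0.80 must be removed ("greater than" semantics)
        col = [0, 2, 0, 2, np.nan]
        G = make_genotypes(np.array(col, dtype=float).reshape(-1, 1))
        stats = compute_snp_stats(G)
        assert stats["call_rate"].iloc[0] == pytest.approx(0.80)
        filtered, _ = apply_qc(G, call_rate_min=0.80, maf_min=0.0, het_max=1.0)
        assert filtered.n_snps == 0

    def test_idempotent(self, toy_qc_genotypes):
        once, _ = apply_qc(toy_qc_genotypes, het_max=0.15)
        twice, report = apply_qc(once, het_max=0.15)
        assert report.n_removed == 0
        assert twice.snp_ids == once.snp_ids

    def test_removing_everything_warns(self, toy_qc_genotypes):
        with pytest.warns(UserWarning, match="every SNP"):
            filtered, _ = apply_qc(toy_qc_genotypes, maf_min=0.6)
        assert filtered.n_snps == 0


class TestKinship:
    def test_single_snp_hand_calculation(self):
        # one SNP, f=0.5, dosages (0, 2): Z=(-1, 1), denominator 0.5
        G = make_genotypes([[0], [2]])
        K = compute_kinship(G)
        np.testing.assert_allclose(K.values, [[2, -2], [-2, 2]])

    def test_identical_rows_have_equal_relationship(self):
        G = make_genotypes([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        K = compute_kinship(G)
        assert K.values[0, 0] == pytest.approx(K.values[0, 1])
        assert K.values[0, 1] == pytest.approx(K.values[1, 1])

    def test_monomorphic_matrix_raises(self):
        with pytest.raises(ModelError, match="monomorphic"):
            compute_kinship(make_genotypes([[2, 2], [2, 2]]))

    def test_hwe_diagonal_near_one(self):
        cfg = SimConfig(n_accessions=200, n_snps=2000, genotype_missing_rate=0.0,
                        seed=7)
        G = simulate_genotypes(cfg)
        K = compute_kinship(G)
        assert np.diag(K.values).mean() == pytest.approx(1.0, abs=0.1)

    def test_invariant_to_snp_and_accession_permutation(self, rng):
        cfg = SimConfig(n_accessions=30, n_snps=60, genotype_missing_rate=0.05,
                        seed=11)
        G = simulate_genotypes(cfg)
        K = compute_kinship(G)
        perm_snps = rng.permutation(G.n_snps)
        # map positions do not enter the GRM: rebuild with permuted columns
        Gs = make_genotypes(G.dosage[:, perm_snps],
                            accession_ids=G.accession_ids)
        np.testing.assert_allclose(compute_kinship(Gs).values, K.values,
                                   atol=1e-10)
        acc_perm = list(rng.permutation(G.accession_ids))
        Ka = compute_kinship(G.subset_accessions(acc_perm))
        order = [acc_perm.index(a) for a in G.accession_ids]
        np.testing.assert_allclose(Ka.values[np.ix_(order, order)], K.values,
                                   atol=1e-10)

    def test_centered_rows_sum_to_zero_after_imputation(self):
        cfg = SimConfig(n_accessions=50, n_snps=40, genotype_missing_rate=0.1,
                        seed=3)
        G = simulate_genotypes(cfg)
        dos = G.dosage
        called = ~np.isnan(dos)
        freq = np.nansum(dos, axis=0) / (2 * called.sum(axis=0))
        Z = np.where(called, dos, 2 * freq) - 2 * freq
        np.testing.assert_allclose(Z.sum(axis=0), 0.0, atol=1e-9)
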