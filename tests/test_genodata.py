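"""Genotype / trio / gene-set I-O, LD pruning, pseudo-controls, balancing."""

import numpy as np
import pandas as pd
import pytest

from episgsea import genodata
from episgsea.genodata import (
    MISSING,
    GeneSetCollection,
    GenotypeDataset,
    ParseError,
    TrioDataset,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# genotype table round-trips
# ---------------------------------------------------------------------------


class TestGenotypeTable:
    def test_round_trip_identity(self, tmp_path):
        ds = make_dataset(seed=1, n=7, p=4, missing_frac=0.2)
        path = tmp_path / "geno.tsv"
        genodata.write_genotype_table(ds, path)
        assert genodata.read_genotype_table(path) == ds

    def test_small_table_values(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text(
            "sample_id\trs1\trs2\tphenotype\n"
            "a\t0\t2\t1\n"
            "b\t1\tNA\t0\n"
        )
        ds = genodata.read_genotype_table(path)
        assert ds.genotypes.tolist() == [[0, 2], [1, MISSING]]
        assert ds.phenotype.tolist() == [1, 0]

    def test_duplicate_rsid_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs1\trs1\tphenotype\na\t0\t1\t1\n")
        with pytest.raises(ParseError, match="rs1"):
            genodata.read_genotype_table(path)

    def test_bad_token_names_row_and_column(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\trs1\trs2\tphenotype\na\t0\t3\t1\nb\t0\t1\t0\n")
        with pytest.raises(ParseError, match=r"'a'.*'rs2'"):
            genodata.read_genotype_table(path)

    def test_empty_dataset_header_only(self, tmp_path):
        ds = GenotypeDataset([], ["rs1"], np.empty((0, 1), dtype=np.int8), np.empty(0))
        path = tmp_path / "empty.tsv"
        genodata.write_genotype_table(ds, path)
        assert path.read_text().strip() == "sample_id\trs1\tphenotype"

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError, match="sample row 0, SNP column 1"):
            GenotypeDataset(["a"], ["rs1", "rs2"], [[0, 5]], [1])


class TestGmtRnkBed:
    def test_gmt_dedups_members(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\tB\tA\n")
        coll = genodata.read_gmt(path)
        assert coll.sets == {"S1": {"A", "B"}}

    def test_gmt_duplicate_name_and_short_line(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\td\tA\nS1\td\tB\n")
        with pytest.raises(ParseError, match="duplicate"):
            genodata.read_gmt(path)
        path.write_text("S1\tdesc-only\n")
        with pytest.raises(ParseError, match=":1"):
            genodata.read_gmt(path)

    def test_gmt_empty_file_and_round_trip(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("")
        assert len(genodata.read_gmt(path)) == 0
        coll = GeneSetCollection({"A": {"x", "y"}, "B": {"z"}}, {"A": "d1", "B": ""})
        genodata.write_gmt(coll, path)
        back = genodata.read_gmt(path)
        assert back.sets == coll.sets

    def test_rnk_round_trip_sorted_desc(self, tmp_path):
        path = tmp_path / "r.rnk"
        genodata.write_rnk(pd.Series({"A": 2.0, "B": 1.0, "C": 3.5}), path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("C\t") and lines[-1].startswith("B\t")
        back = genodata.read_rnk(path)
        assert back["A"] == 2.0 and len(back) == 3

    def test_rnk_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "r.rnk"
        path.write_text("A\t1.0\nA\t2.0\n")
        with pytest.raises(ParseError, match="duplicate"):
            genodata.read_rnk(path)

    def test_gene_table_round_trip_and_validation(self, tmp_path):
        table = genodata.GeneTable(["g1", "g2"], ["1", "X"], [100, 5], [200, 50])
        path = tmp_path / "genes.bed"
        genodata.write_gene_table(table, path)
        back = genodata.read_gene_table(path)
        assert back.symbols == ["g1", "g2"]
        assert back.start.tolist() == [100, 5]
        with pytest.raises(ValueError, match="start must be < end"):
            genodata.GeneTable(["g"], ["1"], [10], [10])


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


class TestLdPrune:
    def test_identical_columns_one_removed(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=50)
        geno = np.column_stack([col, col, rng.integers(0, 3, size=50)]).astype(np.int8)
        ds = GenotypeDataset(
            [f"s{i}" for i in range(50)], ["a", "b", "c"], geno,
            np.zeros(50, dtype=np.int8),
        )
        pruned = genodata.ld_prune(ds, r2_max=0.2, window=3, step=1)
        assert pruned.snp_ids == ["a", "c"]  # earlier member of the pair kept

    def test_independent_columns_survive(self):
        ds = make_dataset(seed=3, n=500, p=30)
        pruned = genodata.ld_prune(ds, r2_max=0.2, window=10, step=2)
        assert pruned.snp_ids == ds.snp_ids
        # no surviving within-window pair exceeds the threshold
        frame = pd.DataFrame(pruned.genotypes.astype(float))
        r2 = frame.corr().to_numpy() ** 2
        np.fill_diagonal(r2, 0)
        assert r2.max() <= 0.2

    def test_toy_matrix_matches_hand_r2(self):
        # 8 samples x 3 SNPs; SNPs a and b strongly correlated, c independent
        geno = np.array(
            [[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 1],
             [1, 1, 2], [2, 2, 0], [0, 1, 0], [2, 2, 2]], dtype=np.int8
        )
        ds = GenotypeDataset(
            [f"s{i}" for i in range(8)], ["a", "b", "c"], geno,
            np.zeros(8, dtype=np.int8),
        )
        # brute-force pairwise r^2 on the toy matrix
        r2 = pd.DataFrame(geno.astype(float)).corr().to_numpy() ** 2
        assert r2[0, 1] > 0.2 and r2[0, 2] <= 0.2 and r2[1, 2] <= 0.2
        pruned = genodata.ld_prune(ds, r2_max=0.2, window=3, step=1)
        assert pruned.snp_ids == ["a", "c"]

    def test_survivors_subset_in_order(self):
        ds = make_dataset(seed=4, n=100, p=40)
        pruned = genodata.ld_prune(ds, r2_max=0.05, window=8, step=3)
        kept = [s for s in ds.snp_ids if s in set(pruned.snp_ids)]
        assert pruned.snp_ids == kept

    def test_parameter_validation(self):
        ds = make_dataset(seed=5, n=10, p=4)
        with pytest.raises(ValueError):
            genodata.ld_prune(ds, r2_max=1.5)
        with pytest.raises(ValueError):
            genodata.ld_prune(ds, window=1)


# ---------------------------------------------------------------------------
# pseudo-controls
# ---------------------------------------------------------------------------


def random_trios(seed, n_trios=50, n_snps=8):
    """Mendelian-consistent trios: child alleles drawn from parental ones."""
    rng = np.random.default_rng(seed)
    pat = rng.integers(0, 2, size=(2, n_trios, n_snps))  # paternal haplotypes
    mat = rng.integers(0, 2, size=(2, n_trios, n_snps))
    father = pat.sum(axis=0)
    mother = mat.sum(axis=0)
    child = pat[rng.integers(0, 2, size=(n_trios, n_snps)), np.arange(n_trios)[:, None],
                np.arange(n_snps)[None, :]] + \
        mat[rng.integers(0, 2, size=(n_trios, n_snps)), np.arange(n_trios)[:, None],
            np.arange(n_snps)[None, :]]
    return TrioDataset(
        [f"t{i}" for i in range(n_trios)], [f"rs{j}" for j in range(n_snps)],
        father.astype(np.int8), mother.astype(np.int8), child.astype(np.int8),
    )


class TestPseudoControls:
    @pytest.mark.parametrize(
        "f,m,c,expected",
        [(1, 1, 2, 0), (2, 2, 2, 2), (0, 2, 1, 1)],
    )
    def test_untransmitted_alleles(self, f, m, c, expected):
        trios = TrioDataset(["t"], ["rs1"], [[f]], [[m]], [[c]])
        out = genodata.make_pseudo_controls(trios)
        assert out.genotypes[1, 0] == expected
        assert out.phenotype.tolist() == [1, 0]

    def test_mendelian_error_becomes_missing(self, caplog):
        trios = TrioDataset(["t"], ["rs1"], [[0]], [[0]], [[2]])
        with caplog.at_level("WARNING"):
            out = genodata.make_pseudo_controls(trios)
        assert out.genotypes[1, 0] == MISSING
        assert "Mendelian" in caplog.text

    def test_sum_invariant_on_random_trios(self):
        trios = random_trios(seed=11, n_trios=200, n_snps=10)
        out = genodata.make_pseudo_controls(trios)
        total = out.genotypes[0::2].astype(int) + out.genotypes[1::2].astype(int)
        assert np.array_equal(total, trios.father.astype(int) + trios.mother)

    def test_all_missing_trio_dropped_and_missing_propagates(self):
        father = np.array([[MISSING, 1], [MISSING, MISSING]], dtype=np.int8)
        mother = np.array([[1, 1], [MISSING, MISSING]], dtype=np.int8)
        child = np.array([[1, 1], [MISSING, MISSING]], dtype=np.int8)
        trios = TrioDataset(["t1", "t2"], ["rs1", "rs2"], father, mother, child)
        out = genodata.make_pseudo_controls(trios)
        assert out.n_samples == 2  # t2 dropped
        assert out.genotypes[1, 0] == MISSING  # missing father -> missing pseudo

    def test_trio_table_round_trip(self, tmp_path):
        trios = random_trios(seed=12, n_trios=5, n_snps=3)
        path = tmp_path / "trios.tsv"
        genodata.write_trio_table(trios, path)
        back = genodata.read_trio_table(path)
        assert back.trio_ids == trios.trio_ids
        assert np.array_equal(back.child, trios.child)


# ---------------------------------------------------------------------------
# control balancing
# ---------------------------------------------------------------------------


class TestBalanceControls:
    def test_downsamples_to_case_count(self):
        rng = np.random.default_rng(0)
        n_cases, n_controls = 30, 120
        geno = rng.integers(0, 3, size=(150, 4)).astype(np.int8)
        pheno = np.r_[np.ones(n_cases), np.zeros(n_controls)].astype(np.int8)
        ds = GenotypeDataset([f"s{i}" for i in range(150)], list("abcd"), geno, pheno)
        out = genodata.balance_controls(ds, seed=9)
        assert out.n_samples == 60
        assert (out.phenotype == 1).sum() == 30
        # every case row kept bit-exactly
        assert np.array_equal(out.genotypes[out.phenotype == 1], geno[:n_cases])

    def test_already_balanced_unchanged(self):
        ds = make_dataset(seed=2, n=20, p=3)
        assert genodata.balance_controls(ds, seed=1) == ds

    def test_deterministic_given_seed(self):
        ds = make_dataset(seed=6, n=40, p=3, balanced=False)
        a = genodata.balance_controls(ds, seed=5)
        b = genodata.balance_controls(ds, seed=5)
        assert a == b

    def test_too_few_controls(self):
        ds = GenotypeDataset(["a", "b"], ["r"], [[0], [1]], [1, 1])
        with pytest.raises(ValueError, match="balance"):
            genodata.balance_controls(ds, seed=0)
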