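import numpy as np
import pandas as pd
import pytest

from cdpop.genotypes import (
    AlleleFrequencies,
    GenotypeMatrix,
    GenotypeParseError,
    KinshipMatrix,
    compute_allele_frequencies,
    filter_individuals,
    filter_markers,
    impute_missing,
    kinship_network_edges,
    read_genotypes,
    vanraden_kinship,
    write_genotypes,
)

NA = np.nan


def make_G(values, fam=None, ids=None, loci=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"i{k}" for k in range(values.shape[0])]
    loci = loci or [f"l{k}" for k in range(values.shape[1])]
    return GenotypeMatrix(ids, loci, values, family_of=fam)


class TestGenotypeMatrix:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            make_G([[0.0, 1.5]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(["a", "a"], ["l1"], np.zeros((2, 1)))

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            GenotypeMatrix(["a"], ["l1", "l2"], np.zeros((1, 1)))


class TestTableIO:
    def test_write_read_roundtrip(self, tmp_path):
        G = make_G([[1, 0, NA], [0, 1, 0.5]])
        path = tmp_path / "geno.tsv"
        write_genotypes(G, path)
        back = read_genotypes(path, format="table")
        assert back.individual_ids == G.individual_ids
        assert back.locus_ids == G.locus_ids
        np.testing.assert_array_equal(back.values, G.values)

    def test_comma_dialect_is_sniffed(self, tmp_path):
        path = tmp_path / "geno.csv"
        path.write_text("id,l1,l2\na,1,0\nb,0,1\n")
        G = read_genotypes(path)
        np.testing.assert_array_equal(G.values, [[1, 0], [0, 1]])

    def test_malformed_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text("id\tl1\tl2\na\t1\t0\nb\t0\t0.7\n")
        with pytest.raises(GenotypeParseError, match="'b'.*'l2'"):
            read_genotypes(path)

    def test_unparseable_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text("id\tl1\na\txx\n")
        with pytest.raises(GenotypeParseError, match="'a'.*'l1'"):
            read_genotypes(path)

    def test_duplicate_individual_id_rejected(self, tmp_path):
        path = tmp_path / "geno.tsv"
        path.write_text("id\tl1\na\t1\na\t0\n")
        with pytest.raises(GenotypeParseError, match="duplicate"):
            read_genotypes(path)


VCF_HEADER = (
    '##fileformat=VCFv4.2\n'
    '##contig=<ID=1>\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
)


class TestVcfIO:
    def test_gt_to_dosage_conversion(self, tmp_path):
        path = tmp_path / "calls.vcf"
        path.write_text(
            VCF_HEADER
            + "1\t100\tm1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\n"
            + "1\t200\tm2\tA\tT\t.\tPASS\t.\tGT\t1/1\t./.\n"
        )
        G = read_genotypes(path, format="vcf")
        assert G.individual_ids == ["s1", "s2"]
        assert G.locus_ids == ["m1", "m2"]
        np.testing.assert_array_equal(G.values, [[0.0, 1.0], [0.5, NA]])

    def test_multiallelic_record_is_named(self, tmp_path):
        path = tmp_path / "calls.vcf"
        path.write_text(
            VCF_HEADER + "1\t300\tm3\tA\tC,T\t.\tPASS\t.\tGT\t0/1\t1/2\n"
        )
        with pytest.raises(GenotypeParseError, match="1:300"):
            read_genotypes(path, format="vcf")


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "column, expected",
        [((1, 0, 1, 0.5), 0.625), ((1, 1), 1.0), ((0, NA, 1), 0.5)],
    )
    def test_mean_dosage_is_frequency(self, column, expected):
        G = make_G(np.asarray(column, dtype=float).reshape(-1, 1))
        freqs = compute_allele_frequencies(G)
        assert freqs.p[0] == pytest.approx(expected)

    def test_subset_selects_frequency_source(self):
        G = make_G([[1], [1], [0], [0]])
        freqs = compute_allele_frequencies(G, subset=["i0", "i1"], source="panel")
        assert freqs.p[0] == 1.0
        assert freqs.source == "panel"

    def test_all_missing_locus_raises(self):
        G = make_G([[NA], [NA]])
        with pytest.raises(ValueError, match="l0"):
            compute_allele_frequencies(G)


class TestFilters:
    def test_maf_threshold_is_strict(self):
        G = make_G(np.tile([[0.0], [1.0]], (1, 3)), loci=["l1", "l2", "l3"])
        freqs = AlleleFrequencies(["l1", "l2", "l3"], [0.005, 0.5, 1.0])
        out = filter_markers(G, freqs, maf_min=0.01, max_marker_missing=1.0)
        assert out.locus_ids == ["l2"]

    def test_no_thresholds_keeps_everything(self):
        vals = np.array([[1, 0, 0.5], [0, 1, NA]])
        G = make_G(vals)
        freqs = compute_allele_frequencies(G)
        out = filter_markers(G, freqs, maf_min=0.0, max_marker_missing=1.0)
        assert out.locus_ids == G.locus_ids

    def test_marker_missingness_rule(self):
        # 3 of 10 values missing at a 10% ceiling -> locus dropped
        col = np.array([NA, NA, NA, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        G = make_G(np.column_stack([col, np.tile([0.0, 1.0], 5)]))
        freqs = AlleleFrequencies(["l0", "l1"], [0.5, 0.5])
        out = filter_markers(G, freqs, maf_min=0.0, max_marker_missing=0.10)
        assert out.locus_ids == ["l1"]

    def test_individual_missingness_rule(self):
        vals = np.ones((3, 10))
        vals[0, :2] = NA  # 20% missing at a 10% ceiling -> dropped
        G = make_G(vals)
        out = filter_individuals(G, max_indiv_missing=0.10)
        assert out.individual_ids == ["i1", "i2"]

    def test_phenotype_requirement(self):
        G = make_G(np.ones((3, 2)))
        phen = pd.Series([1.0, 2.0], index=["i0", "i2"])
        out = filter_individuals(G, 1.0, require_phenotype=phen)
        assert out.individual_ids == ["i0", "i2"]

    def test_threshold_one_is_identity(self):
        G = make_G([[NA, 1], [0, 1]])
        out = filter_individuals(G, max_indiv_missing=1.0)
        assert out.individual_ids == G.individual_ids

    def test_empty_result_raises(self):
        G = make_G([[NA, NA]])
        with pytest.raises(ValueError, match="no individuals"):
            filter_individuals(G, max_indiv_missing=0.5)


class TestImputation:
    def test_group_mean_fills_missing(self):
        G = make_G(
            [[NA], [1], [0], [1]],
            fam={"i0": "A", "i1": "A", "i2": "A", "i3": "B"},
        )
        out = impute_missing(G)
        assert out.values[0, 0] == pytest.approx(0.5)  # mean of (1, 0) in A
        assert not np.isnan(out.values).any()

    def test_no_missing_is_identity(self):
        G = make_G([[1, 0], [0, 1]], fam={"i0": "A", "i1": "A"})
        out = impute_missing(G)
        np.testing.assert_array_equal(out.values, G.values)

    def test_fully_missing_group_falls_back_to_global_mean(self):
        G = make_G(
            [[NA], [NA], [1], [0], [0], [0]],
            fam={f"i{k}": ("A" if k < 2 else "B") for k in range(6)},
        )
        out = impute_missing(G)
        assert out.values[0, 0] == pytest.approx(0.25)  # global mean of (1,0,0,0)

    def test_unlabelled_individual_raises(self):
        G = make_G([[NA], [1]], fam={"i0": "A"})
        with pytest.raises(ValueError, match="i1"):
            impute_missing(G)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.0, 0.5, 1.0, NA], size=(8, 6), p=[0.3, 0.2, 0.3, 0.2])
        vals[:, (np.isnan(vals).all(axis=0))] = 0.0  # keep loci observable
        fam = {f"i{k}": ("A" if k < 4 else "B") for k in range(8)}
        G = make_G(vals, fam=fam)
        perm = list(rng.permutation(G.individual_ids))
        direct = impute_missing(G).subset(individuals=perm)
        permuted = impute_missing(G.subset(individuals=perm))
        np.testing.assert_allclose(direct.values, permuted.values)


class TestVanRaden:
    def test_hand_worked_two_individuals(self):
        G = make_G([[1, 0], [0, 1]])
        freqs = AlleleFrequencies(["l0", "l1"], [0.5, 0.5], "external")
        K = vanraden_kinship(G, freqs)
        np.testing.assert_allclose(K.K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_single_individual(self):
        G = make_G([[1, 1]])
        freqs = AlleleFrequencies(["l0", "l1"], [0.5, 0.5], "external")
        np.testing.assert_allclose(vanraden_kinship(G, freqs).K, [[1.0]])

    def test_monomorphic_frequency_source_raises(self):
        G = make_G([[1, 0], [0, 1]])
        freqs = AlleleFrequencies(["l0", "l1"], [0.0, 1.0])
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_kinship(G, freqs)

    def test_missing_values_rejected(self):
        G = make_G([[NA, 0], [0, 1]])
        freqs = AlleleFrequencies(["l0", "l1"], [0.5, 0.5])
        with pytest.raises(ValueError, match="impute"):
            vanraden_kinship(G, freqs)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(11)
        vals = rng.choice([0.0, 0.5, 1.0], size=(10, 20))
        G = make_G(vals)
        freqs = compute_allele_frequencies(G)
        K = vanraden_kinship(G, freqs).K
        D = np.sum(freqs.p * (1 - freqs.p))
        naive = np.empty((10, 10))
        for i in range(10):
            for j in range(10):
                naive[i, j] = np.sum(
                    (vals[i] - freqs.p) * (vals[j] - freqs.p)
                ) / D
        np.testing.assert_allclose(K, naive, atol=1e-12)

    def test_self_frequencies_center_rows(self, genotype_pool, kinship_pool):
        row_sums = kinship_pool.K.sum(axis=1)
        assert np.abs(row_sums).max() < 1e-10
        assert kinship_pool.K.diagonal().min() >= 0.0


class TestNetworkEdges:
    def test_threshold_and_order(self):
        K = KinshipMatrix(
            ["b", "a", "c"],
            np.array([[1.0, 0.25, 0.10], [0.25, 1.0, 0.30], [0.10, 0.30, 1.0]]),
        )
        assert kinship_network_edges(K, 0.2) == [("a", "b"), ("a", "c")]

    def test_single_edge_above_threshold(self):
        K = KinshipMatrix(["1", "2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert kinship_network_edges(K, 0.4) == [("1", "2")]

    def test_high_threshold_gives_no_edges(self):
        K = KinshipMatrix(["1", "2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert kinship_network_edges(K, 0.5) == []
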