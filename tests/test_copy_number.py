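"""Gene classification, copy counting, normalization, ratio and z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fishcnv import copy_number as cn
from fishcnv.copy_number import GeneCountTable


def cosmic_frame(rows):
    return pd.DataFrame(rows, columns=["gene", "role", "tier", "somatic", "germline"])


class TestClassify:
    def test_pure_roles(self):
        df = cosmic_frame(
            [
                ("TP53", "TSG", 1, 1, 1),
                ("KRAS", "oncogene", 1, 1, 0),
                ("ALK", "fusion", 1, 1, 0),
            ]
        )
        cls, tallies, unclassified = cn.classify_cosmic(df)
        assert [c.bucket for c in cls] == ["pure_tsg", "pure_og", "pure_fusion"]
        assert tallies["pure_tsg"] == tallies["pure_og"] == tallies["pure_fusion"] == 1
        assert unclassified == []

    def test_mixed_fusion_excluded_from_pure(self):
        df = cosmic_frame([("BCR", "oncogene, fusion", 1, 1, 0)])
        cls, tallies, _ = cn.classify_cosmic(df)
        assert cls[0].bucket == "og_fusion"
        assert cn.gene_subset(cls, cn.ROLE_OG) == []
        assert cn.gene_subset(cls, cn.ROLE_OG, include_fusion_mixed=True) == ["BCR"]

    def test_both_roles_excluded_from_both_tallies(self):
        df = cosmic_frame([("NOTCH1", "TSG, oncogene", 1, 1, 0)])
        cls, tallies, _ = cn.classify_cosmic(df)
        assert tallies["both"] == 1
        assert cn.gene_subset(cls, cn.ROLE_TSG) == []
        assert cn.gene_subset(cls, cn.ROLE_OG) == []

    def test_all_three_roles_bucket(self):
        df = cosmic_frame([("X1", "TSG, oncogene, fusion", 2, 1, 0)])
        _, tallies, _ = cn.classify_cosmic(df)
        assert tallies["all"] == 1

    def test_unrecognized_role_goes_to_unclassified(self):
        df = cosmic_frame([("ODD", "mystery", 1, 1, 0), ("TP53", "TSG", 1, 1, 0)])
        cls, tallies, unclassified = cn.classify_cosmic(df)
        assert unclassified == ["ODD"]
        assert tallies["unclassified"] == 1
        assert len(cls) == 1  # ODD kept out of classified list, not silently dropped

    def test_buckets_partition(self):
        roles = ["TSG", "oncogene", "fusion", "TSG, oncogene", "TSG, fusion",
                 "oncogene, fusion", "TSG, oncogene, fusion"]
        df = cosmic_frame([(f"G{i}", r, 1, 1, 0) for i, r in enumerate(roles)] * 3)
        cls, tallies, unclassified = cn.classify_cosmic(df)
        assert sum(tallies.values()) == len(df)
        assert len(cls) + len(unclassified) == len(df)

    def test_tier1_subset_within_tier12(self):
        df = cosmic_frame([(f"G{i}", "TSG", 1 + i % 2, 1, 0) for i in range(10)])
        cls, _, _ = cn.classify_cosmic(df)
        t1 = set(cn.gene_subset(cls, cn.ROLE_TSG, tier_max=1))
        t12 = set(cn.gene_subset(cls, cn.ROLE_TSG, tier_max=2))
        assert t1 <= t12 and len(t1) == 5 and len(t12) == 10

    def test_gatekeeper_annotation(self):
        df = cosmic_frame([("TP53", "TSG", 1, 1, 0), ("BRCA2", "TSG", 1, 0, 1)])
        cls, _, _ = cn.classify_cosmic(df, {"TP53": "gatekeeper", "BRCA2": "caretaker"})
        by_gene = {c.gene_symbol: c.tsg_class for c in cls}
        assert by_gene == {"TP53": "gatekeeper", "BRCA2": "caretaker"}
        assert cn.gene_subset(cls, cn.ROLE_TSG, tsg_class="gatekeeper") == ["TP53"]


class TestCountsFromGeneTrees:
    def test_direct(self):
        table = cn.counts_from_gene_trees({"G1": "(a_2:1,b_1:1);"}, ["a", "b", "c"])
        assert table.counts.loc["G1"].tolist() == [2, 1, 0]
        assert table.found.loc["G1"].tolist() == [True, True, False]

    def test_empty_gene_map(self):
        table = cn.counts_from_gene_trees({}, ["a", "b"])
        assert table.counts.shape == (0, 2)

    def test_empty_species_error(self):
        with pytest.raises(ValueError, match="species"):
            cn.counts_from_gene_trees({"G1": "(a_1:1,b_1:1);"}, [])

    def test_simulator_roundtrip(self, small_study):
        """Counts re-extracted from emitted CAFE trees equal the table."""
        table = cn.counts_from_gene_trees(small_study.gene_trees, small_study.count_table.species)
        src = small_study.count_table
        for gene in table.genes:
            # gene trees only encode found species; counts agree there
            found = src.found.loc[gene]
            assert (table.found.loc[gene] == found).all()
            assert (table.counts.loc[gene][found] == src.counts.loc[gene][found]).all()


class TestCountsFromOrthologRecords:
    def test_dedup_and_confidence(self):
        rec = pd.DataFrame(
            [("G1", "a", "x", 1), ("G1", "a", "x", 1), ("G1", "a", "y", 1), ("G1", "a", "z", 0)],
            columns=["gene", "species", "ortholog_id", "confidence"],
        )
        table = cn.counts_from_ortholog_records(rec)
        assert table.counts.loc["G1", "a"] == 2
        assert bool(table.found.loc["G1", "a"])

    def test_missing_vs_found_zero(self):
        rec = pd.DataFrame(
            [("G1", "a", "x", 1), ("G1", "b", "w", 0)],
            columns=["gene", "species", "ortholog_id", "confidence"],
        )
        table = cn.counts_from_ortholog_records(rec, species=["a", "b", "c"])
        assert table.counts.loc["G1", "b"] == 0 and bool(table.found.loc["G1", "b"])
        assert not bool(table.found.loc["G1", "c"])  # no record at all: missing

    def test_agreement_with_gene_trees(self, small_study):
        """Both count encodings of the same ground truth agree."""
        src = small_study.count_table
        rows = []
        for gene in src.genes:
            for sp in src.species:
                if not src.found.loc[gene, sp]:
                    continue
                for i in range(int(src.counts.loc[gene, sp])):
                    rows.append((gene, sp, f"{gene}_{sp}_{i}", 1))
                if src.counts.loc[gene, sp] == 0:
                    rows.append((gene, sp, f"{gene}_{sp}_none", 0))
        rec = pd.DataFrame(rows, columns=["gene", "species", "ortholog_id", "confidence"])
        table = cn.counts_from_ortholog_records(rec, species=src.species, genes=src.genes)
        assert table.counts.equals(src.counts)
        assert table.found.equals(src.found)


def make_table(counts, found=None):
    counts = pd.DataFrame(counts).T
    found = counts.notna() if found is None else pd.DataFrame(found).T
    return GeneCountTable(counts=counts.fillna(0).astype(int), found=found.astype(bool))


class TestNormalize:
    def test_constant_counts(self):
        table = make_table({"G1": {"a": 2, "b": 2}, "G2": {"a": 2, "b": 2}})
        norm = cn.normalize_counts(table, ["G1", "G2"])
        assert norm.tolist() == [2.0, 2.0]

    def test_missing_gene_excluded_from_denominator(self):
        table = make_table(
            {"G1": {"a": 2}, "G2": {"a": 1}, "G3": {"a": 7}},
            found={"G1": {"a": True}, "G2": {"a": True}, "G3": {"a": False}},
        )
        norm = cn.normalize_counts(table, ["G1", "G2", "G3"])
        assert norm["a"] == pytest.approx(1.5)

    def test_disjoint_subset_error(self):
        table = make_table({"G1": {"a": 2}})
        with pytest.raises(ValueError, match="disjoint"):
            cn.normalize_counts(table, ["NOPE"])

    def test_bounded_by_observed_counts(self, small_study):
        table = small_study.count_table
        genes = table.genes[:20]
        norm = cn.normalize_counts(table, genes)
        sub = table.counts.loc[genes].where(table.found.loc[genes])
        assert (norm >= sub.min().reindex(norm.index) - 1e-12).all()
        assert (norm <= sub.max().reindex(norm.index) + 1e-12).all()


class TestRatioAndZscore:
    @pytest.mark.parametrize("tsg,og,expected", [(2.0, 2.0, 1.0), (1.8, 2.0, 0.9)])
    def test_ratio_examples(self, tsg, og, expected):
        assert cn.tsg_og_ratio(tsg, og) == pytest.approx(expected)

    def test_ratio_undefined_for_zero_og(self):
        with pytest.raises(ValueError, match="ratio"):
            cn.tsg_og_ratio(1.0, 0.0)

    def test_ratio_wgd_invariance(self):
        """Doubling every count of a species doubles norms, not the ratio."""
        tsg = pd.Series({"a": 1.8, "wgd": 3.6})
        og = pd.Series({"a": 2.0, "wgd": 4.0})
        ratio = cn.tsg_og_ratio(tsg, og)
        assert ratio["a"] == pytest.approx(ratio["wgd"], abs=1e-12)

    def test_zscore_symmetric_case(self):
        z = cn.zscore(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_zscore_moments(self, rng):
        z = cn.zscore(pd.Series(rng.normal(5, 3, 40)))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_zscore_constant_error(self):
        with pytest.raises(ValueError, match="constant"):
            cn.zscore(pd.Series([2.0, 2.0, 2.0]))

    @given(
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_zscore_affine_invariance(self, a, b):
        x = pd.Series([0.4, 1.9, 3.1, 7.7, 2.2])
        z1, z2 = cn.zscore(x), cn.zscore(a * x + b)
        assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestTableIO:
    def test_tsv_roundtrip(self, tmp_path, small_study):
        table = small_study.count_table
        table.to_tsv(tmp_path / "c.tsv", tmp_path / "f.tsv")
        back = GeneCountTable.from_tsv(tmp_path / "c.tsv", tmp_path / "f.tsv")
        assert back.counts.equals(table.counts)
        assert back.found.equals(table.found)
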