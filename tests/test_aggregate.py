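"""Aggregation by taxon / function / taxon-specific function, and export."""

import numpy as np
import pandas as pd
import pytest

import metapept as mp
from metapept.errors import ConfigurationError, UsageError

from conftest import (annotated_from_records, assert_matches_oracle,
                      brute_force_aggregate)


def tiny_annotated(tax_values, func_sets, values, mode="labeled",
                   samples=("S1",)):
    """Hand-built AnnotatedTable: one taxon value and one category per row."""
    n = len(values)
    features = pd.DataFrame({
        "feature_id": [f"PEP{i}K" for i in range(n)],
        "sequence": [f"PEP{i}K" for i in range(n)],
    })
    features["master_accessions"] = [[] for _ in range(n)]
    for c in ("confidence", "quan_info", "marker", "description",
              "raw_sequence"):
        features[c] = ""
    qt = mp.QuantTable(level="peptide", features=features,
                       abundances=pd.DataFrame(
                           np.asarray(values, dtype=float),
                           columns=list(samples)))
    tax = pd.DataFrame({"family": tax_values}) \
        if tax_values is not None else None
    func = pd.DataFrame({"KEGG_Pathway": [frozenset(s) for s in func_sets]}) \
        if func_sets is not None else None
    return mp.AnnotatedTable(base=qt, tax_columns=tax, func_columns=func,
                             unassigned_mode=mode)


class TestAggregateByTaxon:
    def test_family_sums(self):
        at = tiny_annotated(
            ["Lachnospiraceae", "Lachnospiraceae", "Bacteroidaceae"],
            None, [[10], [5], [2]])
        agg = mp.aggregate_by_taxon(at, "family")
        frame = agg.to_frame()
        assert dict(zip(frame["family"], frame["S1"])) == \
            {"Bacteroidaceae": 2.0, "Lachnospiraceae": 15.0}

    def test_unique_annotations_permute_the_input(self):
        at = tiny_annotated(["B", "A", "C"], None, [[1], [2], [3]])
        frame = mp.aggregate_by_taxon(at, "family").to_frame()
        assert frame["family"].tolist() == ["A", "B", "C"]  # lexicographic
        assert frame["S1"].tolist() == [2.0, 1.0, 3.0]

    def test_empty_mode_drops_unannotated(self):
        at = tiny_annotated(["A", None], None, [[1], [2]], mode="empty")
        frame = mp.aggregate_by_taxon(at, "family").to_frame()
        assert frame["family"].tolist() == ["A"]

    def test_labeled_mode_groups_unassigned(self):
        at = tiny_annotated(["A", None], None, [[1], [2]], mode="labeled")
        frame = mp.aggregate_by_taxon(at, "family").to_frame()
        assert dict(zip(frame["family"], frame["S1"])) == \
            {"A": 1.0, "unassigned": 2.0}

    def test_absent_rank_is_usage_error(self):
        at = tiny_annotated(["A"], None, [[1]])
        with pytest.raises(UsageError, match="genus"):
            mp.aggregate_by_taxon(at, "genus")

    @pytest.mark.parametrize("rank", ["family", "genus", "species", "lca"])
    def test_matches_brute_force(self, scenario, rank):
        sc, _ = scenario
        at = annotated_from_records(sc)
        assert_matches_oracle(mp.aggregate_by_taxon(at, rank),
                              brute_force_aggregate(at, rank=rank))


class TestAggregateByFunction:
    def test_multivalued_feature_contributes_fully_to_each_group(self):
        at = tiny_annotated(None, [{"ko00010", "ko00020"}], [[8]])
        frame = mp.aggregate_by_function(at, "KEGG_Pathway").to_frame()
        assert frame["S1"].tolist() == [8.0, 8.0]

    def test_fractional_split_option(self):
        at = tiny_annotated(None, [{"ko00010", "ko00020"}], [[8]])
        frame = mp.aggregate_by_function(at, "KEGG_Pathway",
                                         fractional=True).to_frame()
        assert frame["S1"].tolist() == [4.0, 4.0]

    def test_single_valued_data_conserves_sample_totals(self):
        at = tiny_annotated(None, [{"a"}, {"b"}, {"a"}],
                            [[1, 2], [3, 4], [5, 6]], samples=("S1", "S2"))
        frame = mp.aggregate_by_function(at, "KEGG_Pathway").to_frame()
        assert frame["S1"].sum() == 9 and frame["S2"].sum() == 12

    @pytest.mark.parametrize("category", ["KEGG_Pathway", "KEGG_ko", "EC",
                                          "COG_category"])
    def test_matches_brute_force(self, scenario, category):
        sc, _ = scenario
        at = annotated_from_records(sc)
        assert_matches_oracle(mp.aggregate_by_function(at, category),
                              brute_force_aggregate(at, category=category))


class TestAggregateTaxonFunction:
    def test_cross_expansion(self):
        at = tiny_annotated(["Lachnospiraceae"], [{"ko00010", "ko00020"}],
                            [[4]])
        frame = mp.aggregate_taxon_function(at, "family",
                                            "KEGG_Pathway").to_frame()
        assert frame.columns.tolist()[:2] == ["family", "KEGG_Pathway"]
        assert frame["S1"].tolist() == [4.0, 4.0]
        assert set(frame["KEGG_Pathway"]) == {"ko00010", "ko00020"}

    def test_marginal_over_functions_reproduces_taxon_table(self):
        """On single-valued data the pair table sums back to the taxon table."""
        at = tiny_annotated(["A", "A", "B"], [{"x"}, {"y"}, {"x"}],
                            [[1], [2], [4]])
        pair = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway") \
            .to_frame()
        marginal = pair.groupby("family")["S1"].sum()
        taxon = mp.aggregate_by_taxon(at, "family").to_frame()
        assert marginal.tolist() == taxon["S1"].tolist()

    def test_matches_brute_force(self, scenario):
        sc, _ = scenario
        at = annotated_from_records(sc)
        agg = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway")
        assert_matches_oracle(
            agg, brute_force_aggregate(at, rank="family",
                                       category="KEGG_Pathway"))

    def test_invariant_to_input_row_order(self, scenario):
        sc, _ = scenario
        at = annotated_from_records(sc)
        order = np.random.default_rng(0).permutation(at.base.n_features)
        shuffled = mp.AnnotatedTable(
            base=mp.QuantTable(
                level=at.base.level,
                features=at.base.features.iloc[order].reset_index(drop=True),
                abundances=at.base.abundances.iloc[order]
                .reset_index(drop=True)),
            tax_columns=at.tax_columns.iloc[order].reset_index(drop=True),
            func_columns=at.func_columns.iloc[order].reset_index(drop=True),
            unassigned_mode=at.unassigned_mode)
        a = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway")
        b = mp.aggregate_taxon_function(shuffled, "family", "KEGG_Pathway")
        assert a.keys.equals(b.keys)
        assert np.allclose(a.sums.to_numpy(), b.sums.to_numpy())


class TestFeatureCounts:
    def test_contributing_features_per_sample(self):
        at = tiny_annotated(["A", "A"], None,
                            [[1, np.nan], [2, np.nan]], samples=("S1", "S2"))
        counts = mp.feature_counts(at, rank="family")
        assert counts.loc[0, "S1"] == 2 and counts.loc[0, "S2"] == 0

    def test_zero_count_implies_zero_sum(self, scenario):
        sc, _ = scenario
        at = annotated_from_records(sc)
        agg = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway")
        zero = agg.counts.to_numpy() == 0
        assert (agg.sums.to_numpy()[zero] == 0).all()

    def test_counts_bounded_by_group_size(self, scenario):
        sc, _ = scenario
        at = annotated_from_records(sc)
        agg = mp.aggregate_by_taxon(at, "family")
        sizes = {}
        for value in at.tax_columns["family"]:
            sizes[value] = sizes.get(value, 0) + 1
        for key, row in zip(agg.keys["family"],
                            agg.counts.itertuples(index=False)):
            assert max(row) <= sizes[key]

    def test_replaced_zeros_do_not_count_as_measured(self):
        at = tiny_annotated(["A"], None, [[np.nan, 3]], samples=("S1", "S2"))
        at.base.abundances = at.base.abundances.fillna(0.0)
        at.base.zeros_replaced = True
        counts = mp.feature_counts(at, rank="family")
        assert counts.loc[0, "S1"] == 0 and counts.loc[0, "S2"] == 1


class TestConservation:
    def test_labeled_single_valued_totals_conserved(self):
        """With one annotation per feature and labeled mode, per-sample
        aggregated totals equal the input totals."""
        sc = mp.generate_scenario(seed=6, multi_annotation_rate=0.0,
                                  multi_master_rate=0.0)
        at = annotated_from_records(sc)
        input_totals = at.base.abundances.sum(skipna=True).to_numpy()
        for rank in ("family", "genus"):
            frame = mp.aggregate_by_taxon(at, rank).to_frame()
            np.testing.assert_allclose(
                frame[at.base.sample_ids].sum().to_numpy(), input_totals,
                rtol=1e-9)
        for category in ("KEGG_Pathway", "KEGG_ko"):
            frame = mp.aggregate_by_function(at, category).to_frame()
            np.testing.assert_allclose(
                frame[at.base.sample_ids].sum().to_numpy(), input_totals,
                rtol=1e-9)


class TestExport:
    def test_pair_output_headers_include_pathway_name(self, tmp_path,
                                                      scenario):
        sc, paths = scenario
        at = annotated_from_records(sc)
        agg = mp.aggregate_taxon_function(at, "family", "KEGG_Pathway")
        names = mp.kegg_names(set(map(str, agg.keys["KEGG_Pathway"])) -
                              {"unassigned"}, paths["kegg_mapping"])
        agg = mp.add_kegg_names(agg, names, "KEGG_Pathway")
        out = tmp_path / "pair.tsv"
        mp.write_output(agg, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[:3] == ["family", "KEGG_Pathway", "Pathway name"]

    def test_write_read_round_trip(self, tmp_path, scenario):
        sc, _ = scenario
        at = annotated_from_records(sc)
        agg = mp.aggregate_by_taxon(at, "family")
        out = tmp_path / "t.tsv"
        mp.write_output(agg, out)
        back = pd.read_csv(out, sep="\t")
        np.testing.assert_allclose(back[at.base.sample_ids].to_numpy(),
                                   agg.sums.to_numpy(), rtol=1e-9)

    def test_empty_table_writes_header_only(self, tmp_path):
        at = tiny_annotated([None], None, [[1]], mode="empty")
        agg = mp.aggregate_by_taxon(at, "family")
        out = tmp_path / "empty.tsv"
        mp.write_output(agg, out)
        lines = out.read_text().splitlines()
        assert lines == ["family\tS1"]


class TestRenameReorder:
    def agg(self):
        at = tiny_annotated(["A", "B"], None, [[1, 2], [3, 4]],
                            samples=("F1", "F2"))
        return mp.aggregate_by_taxon(at, "family")

    def test_rename_and_reverse(self):
        out = mp.rename_reorder(self.agg(), {"F1": "Patient01"},
                                ["F2", "Patient01"])
        assert out.sample_ids == ["F2", "Patient01"]
        assert out.sums["Patient01"].tolist() == [1.0, 3.0]
        assert out.keys.equals(self.agg().keys)

    def test_identity_is_identity(self):
        agg = self.agg()
        out = mp.rename_reorder(agg, {}, ["F1", "F2"])
        assert out.sums.equals(agg.sums)

    def test_permutation_then_inverse_restores(self):
        agg = self.agg()
        out = mp.rename_reorder(mp.rename_reorder(agg, {}, ["F2", "F1"]),
                                {}, ["F1", "F2"])
        assert out.sums.equals(agg.sums)

    def test_unknown_column_and_bad_permutation_rejected(self):
        with pytest.raises(ConfigurationError, match="F9"):
            mp.rename_reorder(self.agg(), {"F9": "X"}, None)
        with pytest.raises(ConfigurationError, match="permutation"):
            mp.rename_reorder(self.agg(), {}, ["F1", "F1"])

    def test_file_mode_moves_values_with_columns(self, tmp_path):
        agg = self.agg()
        path = tmp_path / "t.tsv"
        mp.write_output(agg, path)
        frame = mp.rename_reorder(str(path), {"F1": "Patient01"},
                                  ["F2", "Patient01"])
        assert frame.columns.tolist() == ["family", "F2", "Patient01"]
        back = pd.read_csv(path, sep="\t")
        assert back["Patient01"].tolist() == [1.0, 3.0]
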