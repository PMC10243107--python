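"""Shared fixtures and the independent brute-force aggregation oracle."""

import numpy as np
import pandas as pd
import pytest

import metapept as mp


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """A mid-sized synthetic scenario written to disk once per session."""
    sc = mp.generate_scenario(seed=11)
    directory = tmp_path_factory.mktemp("scenario")
    paths = mp.write_scenario(sc, directory)
    return sc, paths


@pytest.fixture(scope="session")
def walkthrough_files(tmp_path_factory):
    """The walkthrough-shaped scenario (markers, confidence tiers, pathways)."""
    sc = mp.walkthrough_scenario(seed=23)
    directory = tmp_path_factory.mktemp("walkthrough")
    paths = mp.write_scenario(sc, directory)
    return sc, paths


def quant_from_records(sc):
    """Build a peptide-level QuantTable straight from generator records,
    bypassing file serialization."""
    features = pd.DataFrame({
        "feature_id": [p["sequence"] for p in sc.peptides],
        "sequence": [p["sequence"] for p in sc.peptides],
    })
    features["master_accessions"] = [list(p["masters"]) for p in sc.peptides]
    features["confidence"] = [p["confidence"] for p in sc.peptides]
    features["quan_info"] = [p["quan_info"] for p in sc.peptides]
    features["marker"] = [p["marker"] for p in sc.peptides]
    features["description"] = ""
    features["raw_sequence"] = features["sequence"]
    abundances = pd.DataFrame(
        [[np.nan if v is None else v for v in p["abundances"]]
         for p in sc.peptides],
        columns=sc.samples, dtype=float)
    return mp.QuantTable(level="peptide", features=features,
                         abundances=abundances)


def annotations_from_records(sc):
    """TaxAnnotation / FuncAnnotation lists straight from generator records."""
    tax = [
        mp.TaxAnnotation(
            peptide=p["sequence"],
            ranks={"lca": p["lca"],
                   **{r: p["lineage"][r] for r in p["lineage"]}})
        for p in sc.peptides if p["tax_annotated"]
    ]
    func = [
        mp.FuncAnnotation(query=pr["accession"],
                          categories=dict(pr["functions"]))
        for pr in sc.proteins if pr["annotated"]
    ]
    return tax, func


def annotated_from_records(sc, mode="labeled"):
    qt = quant_from_records(sc)
    tax, func = annotations_from_records(sc)
    at = mp.join_taxonomy(qt, tax, mode=mode)
    return mp.join_function(at, func, basis="protein", mode=mode)


def psm_table_from_records(sc):
    """PSM-level QuantTable straight from the generator's (seq, sample) draws."""
    n = len(sc.psms)
    features = pd.DataFrame({
        "feature_id": [f"psm_{i:06d}" for i in range(n)],
        "sequence": [seq for seq, _ in sc.psms],
    })
    features["master_accessions"] = [[] for _ in range(n)]
    for c in ("confidence", "quan_info", "marker", "description",
              "raw_sequence"):
        features[c] = ""
    features["sample"] = [s for _, s in sc.psms]
    onehot = pd.DataFrame(0.0, index=range(n), columns=sc.samples)
    for i, (_, s) in enumerate(sc.psms):
        onehot.loc[i, s] = 1.0
    return mp.QuantTable(level="psm", features=features, abundances=onehot)


def brute_force_aggregate(at, rank=None, category=None):
    """Plain-python expand -> group -> sum reference, independent of the
    package's aggregation code.

    Returns ``{key_tuple: (sums_list, counts_list)}`` over the samples of
    ``at.base``; missing cells contribute nothing to sums; counts tally
    features with a measured (non-missing, and positive when zeros were
    substituted upstream) value.
    """
    samples = at.base.sample_ids
    result = {}
    for i in range(at.base.n_features):
        tax_keys = [()]
        if rank is not None:
            value = at.tax_columns.iloc[i][rank]
            if value is None or (isinstance(value, float) and np.isnan(value)):
                tax_keys = [("unassigned",)] \
                    if at.unassigned_mode == "labeled" else []
            else:
                tax_keys = [(str(value),)]
        keys = tax_keys
        if category is not None:
            codes = at.func_columns.iloc[i][category]
            if not codes:
                codes = {"unassigned"} if at.unassigned_mode == "labeled" \
                    else set()
            keys = [t + (c,) for t in tax_keys for c in sorted(codes)]
        for key in keys:
            if key not in result:
                result[key] = ([0.0] * len(samples), [0] * len(samples))
            for j, sample in enumerate(samples):
                value = at.base.abundances.iloc[i][sample]
                if not np.isnan(value):
                    result[key][0][j] += value
                    measured = value > 0 if at.base.zeros_replaced else True
                    if measured:
                        result[key][1][j] += 1
    return result


def assert_matches_oracle(agg_table, oracle, rel=1e-9):
    """Cell-for-cell comparison of an AggregatedTable with the oracle dict."""
    frame = agg_table.to_frame()
    keys = [tuple(row) for row in
            agg_table.keys[agg_table.key_columns].itertuples(index=False)]
    assert sorted(keys) == sorted(oracle), \
        f"group keys differ: {sorted(set(keys) ^ set(oracle))}"
    samples = agg_table.sample_ids
    for key, row_sums, row_counts in zip(
            keys, agg_table.sums.itertuples(index=False),
            agg_table.counts.itertuples(index=False)):
        expected_sums, expected_counts = oracle[key]
        for got, want in zip(row_sums, expected_sums):
            assert got == pytest.approx(want, rel=rel, abs=1e-12)
        assert list(row_counts) == expected_counts
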