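"""Abundance aggregation over taxonomic / functional annotation keys.

Aggregation sums, for each sample, the abundances of all features sharing
the same annotation value: one taxon per row, one function code per row, or
one (taxon, function) pair per row.  A feature with k codes in a functional
category contributes its full abundance to each of the k groups (documented
double counting; a fractional split is available but off by default).  A
companion counts table records how many features actually contributed a
measured value per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import CATEGORIES, RANKS, UNASSIGNED, AnnotatedTable
from .errors import ConfigurationError, UsageError


@dataclass
class AggregationSpec:
    """Which aggregation outputs to produce and how to decorate them."""

    tax_levels: set[str] = field(default_factory=set)
    func_levels: set[str] = field(default_factory=set)
    pairs: set[tuple[str, str]] = field(default_factory=set)
    retrieve_kegg_names: bool = False
    emit_counts: bool = False
    prefix: str = ""
    suffix: str = ""

    def __post_init__(self) -> None:
        bad = set(self.tax_levels) - set(RANKS)
        if bad:
            raise ConfigurationError(f"unknown taxonomy ranks: {sorted(bad)}")
        bad = set(self.func_levels) - set(CATEGORIES)
        if bad:
            raise ConfigurationError(f"unknown functional categories: {sorted(bad)}")
        for rank, cat in self.pairs:
            if rank not in RANKS or cat not in CATEGORIES:
                raise ConfigurationError(f"invalid (rank, category) pair "
                                         f"({rank!r}, {cat!r})")


@dataclass
class AggregatedTable:
    """One row per annotation key with summed abundances per sample.

    ``keys`` holds the 1 or 2 key columns (plus an optional name column added
    by KEGG enrichment); ``sums`` and the optional ``counts`` are group x
    sample matrices aligned with ``keys``.
    """

    keys: pd.DataFrame
    sums: pd.DataFrame
    counts: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.sums.columns]

    @property
    def key_columns(self) -> list[str]:
        return [str(c) for c in self.keys.columns]

    def to_frame(self, with_counts: bool = False) -> pd.DataFrame:
        """Flat DataFrame: key columns first, then per-sample columns."""
        matrix = self.counts if with_counts else self.sums
        return pd.concat(
            [self.keys.reset_index(drop=True), matrix.reset_index(drop=True)],
            axis=1,
        )


def _tax_keys(at: AnnotatedTable, rank: str) -> list[list[str]]:
    """Per-feature taxonomy keys (0 or 1 entry, per unassigned mode)."""
    if at.tax_columns is None or rank not in at.tax_columns.columns:
        raise UsageError(f"taxonomy rank column {rank!r} not present; "
                         "join a taxonomy input first")
    keys = []
    for value in at.tax_columns[rank]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            keys.append([UNASSIGNED] if at.unassigned_mode == "labeled" else [])
        else:
            keys.append([str(value)])
    return keys


def _func_keys(at: AnnotatedTable, category: str) -> list[list[str]]:
    """Per-feature function keys (k entries for k codes, per mode)."""
    if at.func_columns is None or category not in at.func_columns.columns:
        raise UsageError(f"functional category column {category!r} not present; "
                         "join a functional input first")
    keys = []
    for codes in at.func_columns[category]:
        if not codes:
            keys.append([UNASSIGNED] if at.unassigned_mode == "labeled" else [])
        else:
            keys.append(sorted(codes))
    return keys


def _measured_mask(at: AnnotatedTable) -> np.ndarray:
    """Which cells count as measured for the companion counts table.

    Non-missing always; when zero replacement ran upstream, replaced zeros
    were never measured, so zeros are excluded then.
    """
    values = at.base.abundances.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    if at.base.zeros_replaced:
        mask &= values > 0
    return mask


def _aggregate(at: AnnotatedTable, keys_per_feature: list[list[tuple]],
               key_names: list[str], fractional: bool = False
               ) -> AggregatedTable:
    """Shared expand -> group -> sum core for all three aggregations."""
    samples = at.base.sample_ids
    values = at.base.abundances.to_numpy(dtype=float)
    filled = np.nan_to_num(values, nan=0.0)  # missing contributes nothing
    measured = _measured_mask(at)

    sums: dict[tuple, np.ndarray] = {}
    counts: dict[tuple, np.ndarray] = {}
    for i, feature_keys in enumerate(keys_per_feature):
        if not feature_keys:
            continue
        weight = 1.0 / len(feature_keys) if fractional else 1.0
        for key in feature_keys:
            if key not in sums:
                sums[key] = np.zeros(len(samples))
                counts[key] = np.zeros(len(samples), dtype=int)
            sums[key] += filled[i] * weight
            counts[key] += measured[i]

    ordered = sorted(sums)
    keys_df = pd.DataFrame(ordered, columns=key_names, dtype=object)
    sums_df = pd.DataFrame([sums[k] for k in ordered] or
                           np.empty((0, len(samples))), columns=samples)
    counts_df = pd.DataFrame([counts[k] for k in ordered] or
                             np.empty((0, len(samples)), dtype=int),
                             columns=samples).astype(int)
    return AggregatedTable(keys=keys_df, sums=sums_df, counts=counts_df)


def aggregate_by_taxon(at: AnnotatedTable, rank: str) -> AggregatedTable:
    """Sum abundances over features sharing the same taxon at ``rank``.

    Features with a missing annotation are excluded in ``empty`` mode and
    grouped under ``"unassigned"`` in ``labeled`` mode.
    """
    keys = [[(k,) for k in ks] for ks in _tax_keys(at, rank)]
    return _aggregate(at, keys, [rank])


def aggregate_by_function(at: AnnotatedTable, category: str,
                          fractional: bool = False) -> AggregatedTable:
    """Sum abundances over features sharing a code in ``category``.

    Multi-valued cells expand: a feature with k codes contributes its full
    abundance to each of the k groups unless ``fractional=True`` splits it
    evenly.
    """
    keys = [[(k,) for k in ks] for ks in _func_keys(at, category)]
    return _aggregate(at, keys, [category], fractional=fractional)


def aggregate_taxon_function(at: AnnotatedTable, rank: str, category: str,
                             fractional: bool = False) -> AggregatedTable:
    """Sum abundances over (taxon, function code) pairs.

    The group key crosses the feature's taxon at ``rank`` with each of its
    codes in ``category``; key columns are named after the rank and the
    category verbatim.
    """
    tax = _tax_keys(at, rank)
    func = _func_keys(at, category)
    keys = [[(t, f) for t in ts for f in fs] for ts, fs in zip(tax, func)]
    return _aggregate(at, keys, [rank, category], fractional=fractional)


def feature_counts(at: AnnotatedTable, rank: str | None = None,
                   category: str | None = None) -> pd.DataFrame:
    """Counts matrix for the matching aggregation (same grouping args).

    ``counts[g][j]`` is the number of features in group g with a measured
    abundance in sample j.
    """
    if rank is not None and category is not None:
        agg = aggregate_taxon_function(at, rank, category)
    elif rank is not None:
        agg = aggregate_by_taxon(at, rank)
    elif category is not None:
        agg = aggregate_by_function(at, category)
    else:
        raise UsageError("feature_counts needs a rank and/or a category")
    return agg.to_frame(with_counts=True)


def add_kegg_names(agg: AggregatedTable, names: dict[str, str],
                   category: str) -> AggregatedTable:
    """Insert a name column right after a KEGG key column.

    The column header follows the category: ``KEGG_Pathway`` gets
    ``"Pathway name"``, ``KEGG_ko`` gets ``"KO name"``, and so on.  Ids
    absent from the mapping get empty text.
    """
    header = {
        "KEGG_ko": "KO name",
        "KEGG_Pathway": "Pathway name",
        "KEGG_Module": "Module name",
        "KEGG_Reaction": "Reaction name",
    }.get(category)
    if header is None or category not in agg.keys.columns:
        raise UsageError(f"no KEGG key column for category {category!r}")
    keys = agg.keys.copy()
    position = list(keys.columns).index(category) + 1
    keys.insert(position, header,
                [names.get(str(c), "") for c in keys[category]])
    return AggregatedTable(keys=keys, sums=agg.sums, counts=agg.counts)


# -- export --------------------------------------------------------------

def decorated_name(stem: str, prefix: str = "", suffix: str = "",
                   fmt: str = "tsv") -> str:
    ext = {"xlsx": ".xlsx", "txt": ".txt", "tsv": ".tsv"}[fmt]
    return f"{prefix}{stem}{suffix}{ext}"


def write_output(table, path, fmt: str | None = None,
                 with_counts: bool = False) -> None:
    """Write an aggregated or annotated table to xlsx / txt / tsv.

    Key columns come first, then per-sample columns in order; text formats
    are tab-separated UTF-8 with ``.`` decimals.  An empty table produces a
    header-only file.
    """
    p = str(path)
    if fmt is None:
        fmt = "xlsx" if p.endswith(".xlsx") else "tsv"
    if fmt not in ("xlsx", "txt", "tsv"):
        raise ConfigurationError(f"unknown output format {fmt!r}")

    if isinstance(table, AggregatedTable):
        df = table.to_frame(with_counts=with_counts)
    elif isinstance(table, AnnotatedTable):
        parts = [table.base.features[["feature_id", "sequence"]].copy()]
        parts[0]["master_accessions"] = [
            ";".join(m) for m in table.base.features["master_accessions"]
        ]
        if table.tax_columns is not None:
            parts.append(table.tax_columns)
        if table.func_columns is not None:
            func = table.func_columns.apply(
                lambda col: [",".join(sorted(v)) for v in col])
            parts.append(func)
        parts.append(table.base.abundances)
        df = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    elif isinstance(table, pd.DataFrame):
        df = table
    else:
        raise UsageError(f"cannot export object of type {type(table).__name__}")

    try:
        if fmt == "xlsx":
            df.to_excel(p, index=False)
        else:
            df.to_csv(p, sep="\t", index=False, encoding="utf-8")
    except OSError as exc:
        raise OSError(f"failed writing output to {p}: {exc}") from exc


def rename_reorder(table, renames: dict[str, str] | None = None,
                   order: list[str] | None = None):
    """Rename and/or reorder the sample columns of an output table.

    Accepts an :class:`AggregatedTable` (returns a new one) or a path to a
    previously written tsv/txt/xlsx file (rewrites it in place and returns
    the DataFrame).  Key columns are untouched; ``order`` must be a
    permutation of the (renamed) sample columns.
    """
    renames = renames or {}

    if isinstance(table, AggregatedTable):
        for old in renames:
            if old not in table.sums.columns:
                raise ConfigurationError(f"unknown sample column {old!r}")
        sums = table.sums.rename(columns=renames)
        counts = table.counts.rename(columns=renames) \
            if table.counts is not None else None
        if order is not None:
            if sorted(order) != sorted(map(str, sums.columns)):
                raise ConfigurationError(
                    "order is not a permutation of the sample columns"
                )
            sums = sums[order]
            counts = counts[order] if counts is not None else None
        return AggregatedTable(keys=table.keys.copy(), sums=sums, counts=counts)

    # file path: sample columns are whatever rename/order refer to; the
    # remaining columns are keys and keep their leading positions
    p = str(table)
    df = pd.read_excel(p) if p.endswith(".xlsx") else pd.read_csv(p, sep="\t")
    df.columns = [str(c) for c in df.columns]
    for old in renames:
        if old not in df.columns:
            raise ConfigurationError(f"unknown sample column {old!r}")
    df = df.rename(columns=renames)
    if order is not None:
        missing = [c for c in order if c not in df.columns]
        if missing:
            raise ConfigurationError(f"unknown columns in order: {missing}")
        if len(set(order)) != len(order):
            raise ConfigurationError("order contains duplicate columns")
        keys = [c for c in df.columns if c not in set(order)]
        df = df[keys + list(order)]
    if p.endswith(".xlsx"):
        df.to_excel(p, index=False)
    else:
        df.to_csv(p, sep="\t", index=False)
    return df
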