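"""Taxonomic and functional annotation parsing and joining.

Taxonomic annotations follow the Unipept export layout: one row per peptide
with its lowest common ancestor (LCA) and the named ranks.  Functional
annotations follow the eggNOG-mapper export layout: one row per query
(protein accession or peptide) with multi-valued category cells.  Both can
also come from generic key/value tables.

Joins are peptide-keyed for taxonomy and either peptide- or protein-keyed
(through master protein accessions) for function; they never change
abundance values or row count of the base table.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import ConfigurationError, FormatError, UsageError
from .quant_io import QuantTable, canonicalize_sequence

logger = logging.getLogger("metapept")

#: taxonomy rank vocabulary, LCA first, then root-to-leaf.  "kingdom" is
#: present in some Unipept exports between superkingdom and phylum; it is
#: accepted when present.
RANKS = ("lca", "superkingdom", "kingdom", "phylum", "class", "order",
         "family", "genus", "species")

#: functional category vocabulary (eggNOG-mapper column names)
CATEGORIES = ("COG_category", "GOs", "EC", "CAZy", "KEGG_ko", "KEGG_Pathway",
              "KEGG_Module", "KEGG_Reaction")

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxAnnotation:
    """Per-peptide ranked taxonomy record (LCA plus named ranks).

    ``ranks`` maps each name in :data:`RANKS` to a taxon name, or ``None``
    when the LCA is above that rank.
    """

    peptide: str
    ranks: dict  # rank name -> str | None

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError("taxonomy record with empty peptide")
        unknown = set(self.ranks) - set(RANKS)
        if unknown:
            raise FormatError(f"unknown taxonomy ranks: {sorted(unknown)}")


@dataclass(frozen=True)
class FuncAnnotation:
    """Per-query multi-valued functional record over the 8 categories.

    ``categories`` maps each name in :data:`CATEGORIES` to a (possibly
    empty) frozenset of annotation codes; the ``-`` placeholder is never
    stored.
    """

    query: str
    categories: dict  # category name -> frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise FormatError(f"unknown functional categories: {sorted(unknown)}")
        for cat, codes in self.categories.items():
            for code in codes:
                if not code or code != code.strip() or code == "-":
                    raise FormatError(
                        f"invalid code {code!r} in category {cat}"
                    )


@dataclass(frozen=True)
class GenericAnnotation:
    """One row of a generic key -> multi-valued-columns annotation table."""

    key: str
    values: dict  # column name -> frozenset[str]


@dataclass
class AnnotatedTable:
    """A QuantTable joined with taxonomy and/or function columns.

    ``tax_columns`` has one column per rank (values ``str`` or ``None``);
    ``func_columns`` one column per category (values ``frozenset[str]``).
    In ``labeled`` mode no cell is missing: unmatched features carry the
    literal ``"unassigned"`` instead.
    """

    base: QuantTable
    tax_columns: pd.DataFrame | None = None
    func_columns: pd.DataFrame | None = None
    unassigned_mode: str = "empty"

    def __post_init__(self) -> None:
        if self.unassigned_mode not in ("empty", "labeled"):
            raise ConfigurationError(
                f"unassigned_mode must be 'empty' or 'labeled', "
                f"got {self.unassigned_mode!r}"
            )
        for df in (self.tax_columns, self.func_columns):
            if df is not None and len(df) != self.base.n_features:
                raise UsageError("annotation columns must match base row count")


# -- parsing -------------------------------------------------------------

def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_unipept(path) -> list[TaxAnnotation]:
    """Parse a Unipept-style peptide taxonomy export (csv or tsv).

    The delimiter is auto-detected from the header.  Empty rank cells become
    missing; peptides are canonicalized exactly as in quant_io.  Duplicate
    peptide rows keep the first occurrence (a warning reports the count).
    """
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = [h.strip().lower() for h in (reader.fieldnames or [])]
        if "peptide" not in header:
            raise FormatError(f"{path}: no 'peptide' column in header")
        canon_fields = {h: h.strip().lower() for h in (reader.fieldnames or [])}
        records: list[TaxAnnotation] = []
        seen: set[str] = set()
        duplicates = 0
        for row in reader:
            low = {canon_fields[k]: (v or "").strip() for k, v in row.items()
                   if k is not None}
            pep = canonicalize_sequence(low["peptide"])
            if not pep:
                continue
            if pep in seen:
                duplicates += 1
                continue
            seen.add(pep)
            ranks = {r: (low.get(r) or None) for r in RANKS if r in low}
            records.append(TaxAnnotation(peptide=pep, ranks=ranks))
    if duplicates:
        logger.warning("%s: %d duplicate peptide rows ignored (first kept)",
                       path, duplicates)
    return records


def _split_codes(cell: str, category: str, *, strip_ko_prefix: bool,
                 drop_map_duplicates: bool) -> frozenset[str]:
    text = (cell or "").strip()
    if text in ("", "-"):
        return frozenset()
    if category == "COG_category":
        # eggNOG writes multi-letter COG cells without separators ("EG")
        letters = {c for c in text.replace(",", "").replace(" ", "") if c != "-"}
        return frozenset(letters)
    tokens = [t.strip() for t in text.split(",") if t.strip() and t.strip() != "-"]
    if category == "KEGG_ko" and strip_ko_prefix:
        tokens = [t[3:] if t.startswith("ko:") else t for t in tokens]
    codes = set(tokens)
    if category == "KEGG_Pathway" and drop_map_duplicates:
        # each pathway appears as both koNNNNN and mapNNNNN; keep ko, drop
        # the map duplicate (a map-only entry is kept)
        ko_numbers = {t[2:] for t in codes if t.startswith("ko")}
        codes = {t for t in codes
                 if not (t.startswith("map") and t[3:] in ko_numbers)}
    return frozenset(codes)


def read_eggnog(path, *, strip_ko_prefix: bool = True,
                drop_map_duplicates: bool = True) -> list[FuncAnnotation]:
    """Parse an eggNOG-mapper annotations export (tab-separated).

    Leading ``##`` comment lines are skipped; the header row must begin with
    ``#query``.  ``-`` cells become empty sets; comma-separated multi-values
    are split (COG category cells split into single letters).
    """
    with open(path, encoding="utf-8") as fh:
        header = None
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if header is None:
                if line.startswith("##") or not line.strip():
                    continue
                if line.startswith("#query"):
                    header = line.lstrip("#").split("\t")
                    header[0] = "query"
                    continue
                raise FormatError(f"{path}: expected a '#query' header row")
            if line.startswith("##") or not line.strip():
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise FormatError(f"{path}: expected a '#query' header row")

    col_index = {name: i for i, name in enumerate(header)}
    records = []
    seen: set[str] = set()
    duplicates = 0
    for cells in rows:
        query = cells[col_index["query"]].strip()
        if not query:
            continue
        if query in seen:
            duplicates += 1
            continue
        seen.add(query)
        cats = {}
        for cat in CATEGORIES:
            idx = col_index.get(cat)
            cell = cells[idx] if idx is not None and idx < len(cells) else ""
            cats[cat] = _split_codes(cell, cat, strip_ko_prefix=strip_ko_prefix,
                                     drop_map_duplicates=drop_map_duplicates)
        records.append(FuncAnnotation(query=query, categories=cats))
    if duplicates:
        logger.warning("%s: %d duplicate query rows ignored (first kept)",
                       path, duplicates)
    return records


def read_generic_annotation(path, key_column: str, value_columns: list[str],
                            delimiters: tuple[str, ...] = (";", ",")
                            ) -> list[GenericAnnotation]:
    """Parse a generic annotation table (tsv/csv/xlsx); caller names columns.

    Multi-valued cells split on the first configured delimiter found in the
    cell (default ``;`` then ``,``).
    """
    p = str(path)
    if p.endswith((".xlsx", ".xlsm")):
        df = pd.read_excel(p, dtype=object)
    else:
        with open(p, encoding="utf-8") as fh:
            delim = _sniff_delimiter(fh.readline())
        df = pd.read_csv(p, sep=delim, dtype=object, keep_default_na=False,
                         na_values=[], engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in [key_column, *value_columns] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: columns not found: {missing}")

    def split(cell) -> frozenset[str]:
        text = str(cell or "").strip()
        if text in ("", "-", "nan"):
            return frozenset()
        for d in delimiters:
            if d in text:
                return frozenset(t.strip() for t in text.split(d) if t.strip())
        return frozenset({text})

    records = []
    seen: set[str] = set()
    duplicates = 0
    for _, row in df.iterrows():
        key = str(row[key_column]).strip()
        if not key:
            continue
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        records.append(GenericAnnotation(
            key=key, values={c: split(row[c]) for c in value_columns}))
    if duplicates:
        logger.warning("%s: %d duplicate key rows ignored (first kept)",
                       path, duplicates)
    return records


def generic_to_taxonomy(records: list[GenericAnnotation]) -> list[TaxAnnotation]:
    """Interpret generic records as taxonomy (columns must be rank names);
    multi-valued cells keep their lexicographically first value."""
    out = []
    for rec in records:
        ranks = {}
        for col, values in rec.values.items():
            if col not in RANKS:
                raise FormatError(f"column {col!r} is not a taxonomy rank")
            ranks[col] = min(values) if values else None
        out.append(TaxAnnotation(peptide=canonicalize_sequence(rec.key),
                                 ranks=ranks))
    return out


def generic_to_function(records: list[GenericAnnotation]) -> list[FuncAnnotation]:
    """Interpret generic records as function (columns must be category names)."""
    out = []
    for rec in records:
        cats = {}
        for col, values in rec.values.items():
            if col not in CATEGORIES:
                raise FormatError(f"column {col!r} is not a functional category")
            cats[col] = frozenset(values)
        out.append(FuncAnnotation(query=rec.key, categories=cats))
    return out


# -- joining -------------------------------------------------------------

def _as_annotated(qt) -> AnnotatedTable:
    if isinstance(qt, AnnotatedTable):
        return qt
    return AnnotatedTable(base=qt)


def join_taxonomy(qt, tax: list[TaxAnnotation], mode: str = "empty",
                  equate_il: bool = False) -> AnnotatedTable:
    """Left-join taxonomy onto a peptide-level table by canonical sequence.

    ``equate_il=True`` maps I to L on both sides before matching (mirrors
    Unipept's "equate I and L" option).  Unmatched features get missing rank
    cells (``mode="empty"``) or the literal ``"unassigned"`` at every rank
    (``mode="labeled"``); in labeled mode ranks above a peptide's LCA are
    labeled too, so no cell stays missing.
    """
    at = _as_annotated(qt)
    base = at.base
    if base.level not in ("peptide", "psm"):
        raise UsageError("taxonomy is peptide-keyed; protein-level table given")

    def key(seq: str) -> str:
        return seq.replace("I", "L") if equate_il else seq

    index = {}
    for rec in tax:
        index.setdefault(key(rec.peptide), rec)

    ranks_present = sorted(
        {r for rec in tax for r in rec.ranks}, key=RANKS.index
    ) or list(RANKS)
    columns: dict[str, list] = {r: [] for r in ranks_present}
    for seq in base.features["sequence"]:
        rec = index.get(key(seq))
        for r in ranks_present:
            value = rec.ranks.get(r) if rec is not None else None
            if value is None and mode == "labeled":
                value = UNASSIGNED
            columns[r].append(value)
    tax_df = pd.DataFrame(columns, index=range(base.n_features))
    return replace(at, tax_columns=tax_df, unassigned_mode=mode)


def join_function(qt, func: list[FuncAnnotation], basis: str = "protein",
                  mode: str = "empty") -> AnnotatedTable:
    """Join functional annotations onto the table.

    ``basis="peptide"`` joins on canonical sequence; ``basis="protein"``
    propagates each feature's master protein annotations, taking the
    deduplicated union over all its master accessions (protein-level tables
    join on their own accession).  Unmatched features get empty sets
    (``mode="empty"``) or the singleton ``{"unassigned"}`` per category
    (``mode="labeled"``).
    """
    if basis not in ("protein", "peptide"):
        raise ConfigurationError(f"basis must be 'protein' or 'peptide', got {basis!r}")
    at = _as_annotated(qt)
    base = at.base

    index = {rec.query: rec for rec in func}
    cats_present = sorted(
        {c for rec in func for c in rec.categories}, key=CATEGORIES.index
    ) or list(CATEGORIES)

    if basis == "protein":
        keys_per_feature = [list(m) for m in base.features["master_accessions"]]
        if base.level != "protein" and not any(keys_per_feature):
            raise UsageError(
                "basis='protein' requires master protein accessions, "
                "but none are populated"
            )
    else:
        if base.level == "protein":
            raise UsageError("basis='peptide' on a protein-level table")
        keys_per_feature = [[s] for s in base.features["sequence"]]

    columns: dict[str, list] = {c: [] for c in cats_present}
    for keys in keys_per_feature:
        matched = [index[k] for k in keys if k in index]
        for c in cats_present:
            codes: set[str] = set()
            for rec in matched:
                codes |= rec.categories.get(c, frozenset())
            if not codes and mode == "labeled":
                codes = {UNASSIGNED}
            columns[c].append(frozenset(codes))
    func_df = pd.DataFrame(
        {c: pd.Series(columns[c], dtype=object) for c in cats_present},
        index=range(base.n_features),
    )
    return replace(at, func_columns=func_df, unassigned_mode=mode)


# -- KEGG names ----------------------------------------------------------

def read_kegg_mapping(path) -> dict[str, str]:
    """Read a two-column id<TAB>name mapping file."""
    mapping = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def _kegg_fetch_online(ids: set[str]) -> dict[str, str]:
    """Query the public KEGG REST `list` endpoint for id names.

    Never called from tests; retried once, and any remaining failure is
    raised rather than returning silent partial output.
    """
    from urllib.request import urlopen

    names: dict[str, str] = {}
    databases = {"K": "ko", "k": "pathway", "m": "pathway", "M": "module",
                 "R": "reaction"}
    dbs = {databases.get(i[0]) for i in ids if i and databases.get(i[0])}
    for db in sorted(dbs):
        url = f"https://rest.kegg.jp/list/{db}"
        last_error = None
        for _ in range(2):
            try:
                with urlopen(url, timeout=30) as resp:
                    text = resp.read().decode("utf-8")
                break
            except Exception as exc:  # pragma: no cover - network only
                last_error = exc
        else:  # pragma: no cover - network only
            raise ConfigurationError(f"KEGG fetch failed for {url}: {last_error}")
        for line in text.splitlines():
            parts = line.split("\t")
            if len(parts) >= 2:
                ident = parts[0].split(":")[-1]
                names[ident] = parts[1]
    return {i: names.get(i, names.get(i.replace("ko", "map", 1), ""))
            for i in ids}


def kegg_names(ids: set[str], mapping_path=None, online: bool = False
               ) -> dict[str, str]:
    """Resolve KEGG ids to human-readable names.

    Offline mode reads a two-column tsv mapping; online mode queries the
    KEGG REST API and caches results into the mapping file.  Ids without a
    name map to empty text (a warning reports how many).
    """
    if mapping_path is None and not online:
        raise ConfigurationError(
            "kegg_names needs a mapping file or online=True"
        )
    mapping: dict[str, str] = {}
    if mapping_path is not None:
        try:
            mapping = read_kegg_mapping(mapping_path)
        except FileNotFoundError:
            if not online:
                raise ConfigurationError(
                    f"KEGG mapping file not found: {mapping_path}"
                )
    result = {i: mapping.get(i, "") for i in ids}
    unresolved = {i for i, n in result.items() if not n}
    if unresolved and online:
        fetched = _kegg_fetch_online(unresolved)
        result.update({i: n for i, n in fetched.items() if n})
        if mapping_path is not None:  # cache for future offline runs
            mapping.update({i: n for i, n in fetched.items() if n})
            with open(mapping_path, "w", encoding="utf-8") as fh:
                for i in sorted(mapping):
                    fh.write(f"{i}\t{mapping[i]}\n")
        unresolved = {i for i, n in result.items() if not n}
    if unresolved:
        logger.warning("%d KEGG ids without a name in the mapping",
                       len(unresolved))
    return result
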