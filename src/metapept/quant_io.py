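"""Readers for identification/quantification tables.

Three dialects are supported and all land in the same in-memory
representation, :class:`QuantTable`:

* Proteome Discoverer-style exports (xlsx or tab-separated text) at the
  protein, peptide or PSM level;
* mzTab 1.0 files (PRT / PEP / PSM sections, via :mod:`pyteomics.mztab`);
* generic tabular files where the caller names the id and abundance columns.

Missing abundances are kept as NaN throughout; replacing them with zeros is
an explicit preprocessing step, never a side effect of reading.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError, ValueParseError

LEVELS = ("protein", "peptide", "psm")

#: per-feature auxiliary columns every QuantTable carries (text, "" when absent)
META_COLUMNS = ("confidence", "quan_info", "marker", "description", "raw_sequence")

# Proteome Discoverer dialect defaults.  Header text varies between PD
# versions, so every entry can be overridden through ``column_map``.
PD_COLUMN_MAP = {
    "sequence": ("Annotated Sequence", "Sequence"),
    "accession": ("Accession",),
    "confidence": ("Confidence",),
    "quan_info": ("Quan Info",),
    "marker": ("Marker",),
    "master_accessions": ("Master Protein Accessions",),
    "description": ("Description",),
    "spectrum_file": ("Spectrum File",),
}

#: abundance column header prefixes, tried in order (longest first)
PD_ABUNDANCE_PREFIXES = (
    "Abundances (Normalized):",
    "Abundance:",
)

_FLANK_LEADING = re.compile(r"^\[[^\]]*\]\.")
_FLANK_TRAILING = re.compile(r"\.\[[^\]]*\]$")
_BRACKETED = re.compile(r"\[[^\]]*\]|\([^)]*\)")
_NUMERIC = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def canonicalize_sequence(raw: str) -> str:
    """Reduce a peptide sequence to bare uppercase residues.

    Strips bracketed flanking residues (``[K].PEPTIDE.[D]``), removes
    bracketed/parenthesized modification annotations and lowercase
    modification tags, and uppercases what remains.  The result contains
    only the characters A-Z.
    """
    s = str(raw).strip()
    s = _FLANK_LEADING.sub("", s)
    s = _FLANK_TRAILING.sub("", s)
    s = _BRACKETED.sub("", s)
    return "".join(c for c in s if "A" <= c <= "Z")


def parse_abundance(cell, row_index: int) -> float:
    """Parse one abundance cell; '' / None / NaN -> NaN, else a float >= 0.

    Only the ``.`` decimal separator is accepted; thousands separators and
    any other non-numeric content raise :class:`ValueParseError` naming the
    row.
    """
    if cell is None:
        return math.nan
    if isinstance(cell, float):
        if math.isnan(cell):
            return math.nan
        return float(cell)
    if isinstance(cell, (int, np.integer, np.floating)):
        return float(cell)
    text = str(cell).strip()
    if text == "" or text.lower() in ("nan", "null", "na"):
        return math.nan
    if not _NUMERIC.match(text):
        raise ValueParseError(
            f"row {row_index}: abundance cell {cell!r} is not a plain decimal number"
        )
    return float(text)


@dataclass
class QuantTable:
    """Features x samples abundance matrix with per-feature metadata.

    Parameters
    ----------
    level
        ``"protein"``, ``"peptide"`` or ``"psm"``.
    features
        One row per feature with columns ``feature_id``, ``sequence``,
        ``master_accessions`` (list of accessions, possibly empty) and the
        text columns in :data:`META_COLUMNS`.  At PSM level an additional
        ``sample`` column records the run/sample each PSM belongs to.
    abundances
        Float DataFrame, columns are the sample ids in order; NaN marks a
        missing (not-measured) value.
    zeros_replaced
        True once missing values have been replaced by zeros; downstream
        feature counting then treats zeros as not measured.
    """

    level: str
    features: pd.DataFrame
    abundances: pd.DataFrame
    zeros_replaced: bool = False

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise UsageError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if len(self.features) != len(self.abundances):
            raise UsageError(
                f"feature rows ({len(self.features)}) != abundance rows "
                f"({len(self.abundances)})"
            )
        if len(set(self.abundances.columns)) != len(self.abundances.columns):
            raise FormatError("duplicate sample ids in abundance columns")
        if self.level in ("protein", "peptide"):
            dup = self.features["feature_id"][self.features["feature_id"].duplicated()]
            if len(dup):
                raise FormatError(
                    f"duplicate feature_id at {self.level} level: {dup.iloc[0]!r}"
                )
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueParseError("negative abundance value in table")
        self.features = self.features.reset_index(drop=True)
        self.abundances = self.abundances.reset_index(drop=True).astype(float)

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.abundances.columns]

    @property
    def n_features(self) -> int:
        return len(self.features)

    def copy(self) -> "QuantTable":
        return replace(
            self, features=self.features.copy(), abundances=self.abundances.copy()
        )

    def subset(self, mask) -> "QuantTable":
        """Row-subsetting helper used by the filters; values untouched."""
        return replace(
            self,
            features=self.features.loc[mask].reset_index(drop=True),
            abundances=self.abundances.loc[mask].reset_index(drop=True),
        )


def _empty_meta(n: int) -> dict:
    return {c: [""] * n for c in META_COLUMNS}


def _read_tabular(path, *, dtype=str) -> pd.DataFrame:
    """Read xlsx or tab-separated text into an all-string DataFrame."""
    p = str(path)
    if p.endswith((".xlsx", ".xlsm")):
        df = pd.read_excel(p, dtype=object)
    else:
        df = pd.read_csv(p, sep="\t", dtype=object, keep_default_na=False,
                         na_values=[], engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _pd_resolve(df: pd.DataFrame, key: str, column_map: dict | None) -> str | None:
    candidates = ()
    if column_map and key in column_map:
        cand = column_map[key]
        candidates = (cand,) if isinstance(cand, str) else tuple(cand)
    else:
        candidates = PD_COLUMN_MAP.get(key, ())
    for name in candidates:
        if name in df.columns:
            return name
    return None


def _pd_abundance_columns(df: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Auto-detect abundance columns; return (column names, sample labels)."""
    cols, labels = [], []
    for c in df.columns:
        for prefix in PD_ABUNDANCE_PREFIXES:
            if c.startswith(prefix):
                cols.append(c)
                labels.append(c[len(prefix):].strip())
                break
    return cols, labels


def _abundance_frame(df: pd.DataFrame, cols: list[str], labels: list[str]) -> pd.DataFrame:
    data = {}
    for col, label in zip(cols, labels):
        data[label] = [parse_abundance(v, i) for i, v in enumerate(df[col])]
    return pd.DataFrame(data, dtype=float)


def _split_masters(cell) -> list[str]:
    if cell is None:
        return []
    text = str(cell).strip()
    if not text or text.lower() == "nan":
        return []
    return [t.strip() for t in text.split(";") if t.strip()]


def read_pd_export(path, level: str, column_map: dict | None = None) -> QuantTable:
    """Read a Proteome Discoverer export (xlsx or tab-separated text).

    Abundance columns are auto-detected by their ``Abundance`` header prefix;
    the sample label is the remainder of the header.  Empty cells read as
    missing, never as zero.
    """
    if level not in LEVELS:
        raise UsageError(f"unknown level {level!r}")
    df = _read_tabular(path)

    ab_cols, sample_labels = _pd_abundance_columns(df)
    if level != "psm" and not ab_cols:
        raise FormatError(
            f"{path}: no abundance columns found (headers with prefix "
            f"{PD_ABUNDANCE_PREFIXES})"
        )

    n = len(df)
    meta = _empty_meta(n)
    for key in ("confidence", "quan_info", "marker", "description"):
        col = _pd_resolve(df, key, column_map)
        if col is not None:
            meta[key] = [str(v).strip() if v is not None else "" for v in df[col]]

    if level == "protein":
        acc_col = _pd_resolve(df, "accession", column_map)
        if acc_col is None:
            raise FormatError(f"{path}: mandatory column 'Accession' not found")
        feature_id = [str(v).strip() for v in df[acc_col]]
        sequence = [""] * n
        masters = [[fid] for fid in feature_id]
    else:
        seq_col = _pd_resolve(df, "sequence", column_map)
        if seq_col is None:
            raise FormatError(
                f"{path}: mandatory sequence column not found "
                f"(tried {PD_COLUMN_MAP['sequence']})"
            )
        raw = [str(v).strip() for v in df[seq_col]]
        meta["raw_sequence"] = raw
        sequence = [canonicalize_sequence(r) for r in raw]
        m_col = _pd_resolve(df, "master_accessions", column_map)
        masters = [_split_masters(v) for v in df[m_col]] if m_col else [[] for _ in raw]
        feature_id = list(sequence) if level == "peptide" else [
            f"psm_{i:06d}" for i in range(n)
        ]

    features = pd.DataFrame({"feature_id": feature_id, "sequence": sequence})
    features["master_accessions"] = masters
    for k, v in meta.items():
        features[k] = v

    if level == "psm":
        sf_col = _pd_resolve(df, "spectrum_file", column_map)
        if sf_col is None:
            raise FormatError(
                f"{path}: PSM input requires a 'Spectrum File' column for "
                "per-sample assignment"
            )
        samples = [str(v).strip() for v in df[sf_col]]
        for i, s in enumerate(samples):
            if not s or s.lower() == "nan":
                raise FormatError(f"{path}: PSM row {i} has no sample assignment")
        features["sample"] = samples
        sample_ids = sorted(set(samples))
        onehot = pd.DataFrame(0.0, index=range(n), columns=sample_ids)
        for i, s in enumerate(samples):
            onehot.loc[i, s] = 1.0
        return QuantTable(level="psm", features=features, abundances=onehot)

    abundances = _abundance_frame(df, ab_cols, sample_labels)
    return QuantTable(level=level, features=features, abundances=abundances)


def read_generic(path, level: str, id_column: str,
                 abundance_columns: list[str]) -> QuantTable:
    """Read any tab-separated or xlsx table; the caller names the columns.

    ``abundance_columns`` order defines the sample order; sample ids are the
    column headers verbatim.
    """
    if level not in LEVELS:
        raise UsageError(f"unknown level {level!r}")
    df = _read_tabular(path)
    if id_column not in df.columns:
        raise FormatError(f"{path}: id column {id_column!r} not found")
    missing = [c for c in abundance_columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: abundance columns not found: {missing}")
    if not abundance_columns:
        raise FormatError(f"{path}: no abundance columns requested")

    n = len(df)
    ids = [str(v).strip() for v in df[id_column]]
    features = pd.DataFrame({"feature_id": ids})
    if level == "protein":
        features["sequence"] = [""] * n
        features["master_accessions"] = [[i] for i in ids]
    else:
        features["feature_id"] = [canonicalize_sequence(i) for i in ids] \
            if level == "peptide" else [f"psm_{i:06d}" for i in range(n)]
        features["sequence"] = [canonicalize_sequence(i) for i in ids]
        features["master_accessions"] = [[] for _ in range(n)]
    for k, v in _empty_meta(n).items():
        features[k] = v
    features["raw_sequence"] = ids if level != "protein" else [""] * n

    abundances = _abundance_frame(df, list(abundance_columns),
                                  [str(c) for c in abundance_columns])
    return QuantTable(level=level, features=features, abundances=abundances)


# -- mzTab ---------------------------------------------------------------

def _mztab_study_variables(meta: dict) -> list[tuple[int, str]]:
    """Ordered (index, label) of declared study variables.

    pyteomics exposes MTD as flat keys like ``study_variable[1]-description``.
    """
    out = {}
    for key, value in meta.items():
        m = re.match(r"study_variable\[(\d+)\]-description$", str(key))
        if m:
            out[int(m.group(1))] = str(value)
        else:
            m = re.match(r"study_variable\[(\d+)\]-", str(key))
            if m:
                out.setdefault(int(m.group(1)), f"study_variable[{m.group(1)}]")
    return sorted(out.items())


def _msrun_to_sample(meta: dict, sv: list[tuple[int, str]]) -> dict[int, str]:
    """Map ms_run index -> study-variable label via assay declarations."""
    assay_run: dict[int, int] = {}
    for key, value in meta.items():
        m = re.match(r"assay\[(\d+)\]-ms_run_ref$", str(key))
        if m:
            r = re.search(r"ms_run\[(\d+)\]", str(value))
            if r:
                assay_run[int(m.group(1))] = int(r.group(1))
    labels = dict(sv)
    run_sample: dict[int, str] = {}
    for key, value in meta.items():
        m = re.match(r"study_variable\[(\d+)\]-assay_refs$", str(key))
        if not m:
            continue
        sv_idx = int(m.group(1))
        for a in re.finditer(r"assay\[(\d+)\]", str(value)):
            aidx = int(a.group(1))
            if aidx in assay_run and sv_idx in labels:
                run_sample[assay_run[aidx]] = labels[sv_idx]
    return run_sample


def read_mztab(path, level: str) -> QuantTable:
    """Read an mzTab 1.0 file at the requested level.

    Protein level reads the PRT section (``protein_abundance_study_variable[n]``
    columns), peptide level the PEP section, PSM level the PSM section with
    sample assignment derived from ``spectra_ref`` through the MTD
    ms_run/assay/study_variable declarations.  ``null`` cells become missing.
    """
    from pyteomics import mztab

    if level not in LEVELS:
        raise UsageError(f"unknown level {level!r}")
    tab = mztab.MzTab(str(path))
    meta = tab.metadata
    sv = _mztab_study_variables(meta)

    if level in ("protein", "peptide"):
        section = tab.protein_table if level == "protein" else tab.peptide_table
        if section is None or len(section) == 0:
            raise FormatError(
                f"{path}: requested {'PRT' if level == 'protein' else 'PEP'} "
                "section absent or empty"
            )
        prefix = ("protein" if level == "protein" else "peptide") \
            + "_abundance_study_variable"
        ab_cols = []
        for idx, label in sv:
            col = f"{prefix}[{idx}]"
            if col in section.columns:
                ab_cols.append((col, label))
        for c in section.columns:
            m = re.match(re.escape(prefix) + r"\[(\d+)\]$", str(c))
            if m and int(m.group(1)) not in dict(sv):
                raise FormatError(
                    f"{path}: column {c} references an undeclared study variable"
                )
        if not ab_cols:
            raise FormatError(f"{path}: no {prefix}[n] abundance columns found")

        n = len(section)
        if level == "protein":
            ids = [str(v) for v in section["accession"]]
            seqs = [""] * n
            masters = [[i] for i in ids]
        else:
            raw = [str(v) for v in section["sequence"]]
            seqs = [canonicalize_sequence(r) for r in raw]
            ids = list(seqs)
            masters = [
                [] if (str(a) in ("", "null", "nan")) else [str(a)]
                for a in section.get("accession", [""] * n)
            ]
        features = pd.DataFrame({"feature_id": ids, "sequence": seqs})
        features["master_accessions"] = masters
        for k, v in _empty_meta(n).items():
            features[k] = v
        if level == "peptide":
            features["raw_sequence"] = [str(v) for v in section["sequence"]]
        ab = pd.DataFrame({
            label: [parse_abundance(v, i)
                    for i, v in enumerate(section[col])]
            for col, label in ab_cols
        }, dtype=float)
        if len(ids) != len(set(ids)):
            # PEP sections may repeat a sequence (charge states); collapse by
            # summing study-variable abundances so peptide ids stay unique.
            ab["_seq"] = ids
            grouped = ab.groupby("_seq", sort=False)
            summed = grouped.sum(min_count=1)
            keep = features.drop_duplicates("feature_id").set_index("feature_id")
            keep = keep.loc[summed.index].reset_index()
            return QuantTable(level=level, features=keep,
                              abundances=summed.reset_index(drop=True))
        return QuantTable(level=level, features=features, abundances=ab)

    # PSM level
    section = tab.spectrum_match_table
    if section is None or len(section) == 0:
        raise FormatError(f"{path}: requested PSM section absent or empty")
    run_sample = _msrun_to_sample(meta, sv)
    n = len(section)
    raw = [str(v) for v in section["sequence"]]
    seqs = [canonicalize_sequence(r) for r in raw]
    samples = []
    for i, ref in enumerate(section["spectra_ref"]):
        m = re.search(r"ms_run\[(\d+)\]", str(ref))
        if not m:
            raise FormatError(f"{path}: PSM row {i} has no ms_run in spectra_ref")
        run = int(m.group(1))
        if run not in run_sample:
            # no study-variable mapping declared: fall back to the run itself
            samples.append(f"ms_run[{run}]")
        else:
            samples.append(run_sample[run])
    features = pd.DataFrame({
        "feature_id": [f"psm_{i:06d}" for i in range(n)],
        "sequence": seqs,
    })
    features["master_accessions"] = [
        [] if (str(a) in ("", "null", "nan")) else [str(a)]
        for a in section.get("accession", [""] * n)
    ]
    for k, v in _empty_meta(n).items():
        features[k] = v
    features["raw_sequence"] = raw
    features["sample"] = samples
    sample_ids = [label for _, label in sv] if sv else sorted(set(samples))
    for s in samples:
        if s not in sample_ids:
            sample_ids.append(s)
    onehot = pd.DataFrame(0.0, index=range(n), columns=sample_ids)
    for i, s in enumerate(samples):
        onehot.loc[i, s] = 1.0
    return QuantTable(level="psm", features=features, abundances=onehot)


# -- writing -------------------------------------------------------------

def write_table(qt: QuantTable, path, fmt: str | None = None) -> None:
    """Write a QuantTable in the PD-style dialect so it round-trips through
    :func:`read_pd_export`.  Missing values are written as empty cells."""
    p = str(path)
    if fmt is None:
        fmt = "xlsx" if p.endswith(".xlsx") else "txt"
    df = pd.DataFrame()
    if qt.level == "protein":
        df["Accession"] = qt.features["feature_id"]
    else:
        raw = qt.features["raw_sequence"]
        df["Sequence"] = [
            r if r else s for r, s in zip(raw, qt.features["sequence"])
        ]
    df["Confidence"] = qt.features["confidence"]
    df["Quan Info"] = qt.features["quan_info"]
    df["Marker"] = qt.features["marker"]
    df["Description"] = qt.features["description"]
    df["Master Protein Accessions"] = [
        ";".join(m) for m in qt.features["master_accessions"]
    ]
    if qt.level == "psm":
        df["Spectrum File"] = qt.features["sample"]
    else:
        for s in qt.sample_ids:
            df[f"Abundance: {s}"] = qt.abundances[s]
    if fmt == "xlsx":
        df.to_excel(p, index=False)
    else:
        df.to_csv(p, sep="\t", index=False)
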