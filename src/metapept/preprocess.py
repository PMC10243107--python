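"""Feature filtering, missing-value handling, renormalization, PSM collapse.

The pipeline order is fixed: metadata filters, then valid-value filter, then
PSM collapse (for PSM-level input), then optional zero replacement, then
optional renormalization.  Zeros introduced by :func:`replace_missing` count
as valid values only if :func:`filter_valid_values` runs afterwards, which
the fixed order prevents; the CLI enforces the order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, NormalizationError, UsageError
from .quant_io import META_COLUMNS, QuantTable


@dataclass
class FilterSpec:
    """Declarative description of the preprocessing choices.

    Each keep-set applies to the metadata column of the same name; an unset
    (None) keep-set skips that criterion.  ``min_valid`` / ``min_valid_pct``
    are mutually exclusive; the percentage converts to a count with ceiling
    ("at least X%" semantics).
    """

    confidence_keep: set[str] | None = None
    quan_info_keep: set[str] | None = None
    marker_keep: set[str] | None = None
    min_valid: int | None = None
    min_valid_pct: float | None = None
    replace_missing_with_zero: bool = False
    renormalize: bool = False

    def __post_init__(self) -> None:
        if self.min_valid is not None and self.min_valid_pct is not None:
            raise ConfigurationError(
                "min_valid and min_valid_pct are mutually exclusive"
            )
        if self.min_valid is not None and self.min_valid < 0:
            raise ConfigurationError("min_valid must be >= 0")
        if self.min_valid_pct is not None and not (0 <= self.min_valid_pct <= 100):
            raise ConfigurationError("min_valid_pct must be in [0, 100]")

    def min_valid_count(self, n_samples: int) -> int | None:
        if self.min_valid is not None:
            if self.min_valid > n_samples:
                raise ConfigurationError(
                    f"min_valid={self.min_valid} exceeds sample count {n_samples}"
                )
            return self.min_valid
        if self.min_valid_pct is not None:
            return math.ceil(self.min_valid_pct / 100.0 * n_samples)
        return None


_META_FILTERS = ("confidence", "quan_info", "marker")


def apply_meta_filters(qt: QuantTable, spec: FilterSpec) -> QuantTable:
    """Keep rows whose metadata values are in every configured keep-set.

    Criteria with an unset keep-set are skipped; row order is preserved and
    surviving rows are value-identical to their inputs.
    """
    mask = pd.Series(True, index=qt.features.index)
    for column in _META_FILTERS:
        keep = getattr(spec, f"{column}_keep")
        if keep is None:
            continue
        if column not in qt.features.columns:
            raise ConfigurationError(
                f"cannot filter on metadata column {column!r}: absent from input"
            )
        values = qt.features[column].astype(str)
        if (values == "").all():
            raise ConfigurationError(
                f"cannot filter on metadata column {column!r}: "
                "input carries no values for it"
            )
        mask &= values.isin(set(keep))
    return qt.subset(mask)


def filter_valid_values(qt: QuantTable, spec: FilterSpec) -> QuantTable:
    """Keep rows with at least the requested number of non-missing abundances."""
    threshold = spec.min_valid_count(len(qt.sample_ids))
    if threshold is None:
        raise ConfigurationError(
            "filter_valid_values requires min_valid or min_valid_pct"
        )
    counts = qt.abundances.notna().sum(axis=1)
    return qt.subset(counts >= threshold)


def replace_missing(qt: QuantTable) -> QuantTable:
    """Replace every missing abundance with 0.0 (idempotent).

    Marks the table so feature counting downstream treats zeros as
    not-measured.
    """
    out = qt.copy()
    out.abundances = out.abundances.fillna(0.0)
    out.zeros_replaced = True
    return out


def renormalize(qt: QuantTable) -> QuantTable:
    """Total-sum normalization across samples.

    Each sample column is scaled so that its sum of non-missing values equals
    T, the mean of the per-sample sums; within-sample ratios are unchanged
    and the output stays on the input scale.
    """
    sums = qt.abundances.sum(axis=0, skipna=True)
    for sample, s in sums.items():
        if not (s > 0):
            raise NormalizationError(
                f"sample {sample!r} has no positive abundance to normalize on"
            )
    target = float(sums.mean())
    out = qt.copy()
    out.abundances = qt.abundances / sums * target
    return out


def collapse_psms(qt: QuantTable) -> QuantTable:
    """Collapse a PSM-level table into per-peptide PSM counts.

    One output row per distinct canonical sequence; cell (i, j) is the
    number of PSM rows with that sequence assigned to sample j (0, not
    missing, when none).  Master accessions are the union over collapsed
    rows, first-seen order.
    """
    if qt.level != "psm":
        raise UsageError("collapse_psms requires a psm-level table")
    if "sample" not in qt.features.columns:
        raise FormatError("psm table lacks per-row sample assignment")
    for i, s in enumerate(qt.features["sample"]):
        if not str(s).strip() or str(s).lower() == "nan":
            raise FormatError(f"PSM row {i} has no sample assignment")

    samples = qt.sample_ids
    order: list[str] = []
    masters: dict[str, list[str]] = {}
    meta: dict[str, dict[str, str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for i in range(qt.n_features):
        seq = qt.features.at[i, "sequence"]
        if seq not in counts:
            order.append(seq)
            counts[seq] = {s: 0 for s in samples}
            masters[seq] = []
            meta[seq] = {c: "" for c in META_COLUMNS}
        counts[seq][qt.features.at[i, "sample"]] += 1
        for acc in qt.features.at[i, "master_accessions"]:
            if acc not in masters[seq]:
                masters[seq].append(acc)
        for c in META_COLUMNS:
            if not meta[seq][c]:
                meta[seq][c] = qt.features.at[i, c]

    features = pd.DataFrame({"feature_id": order, "sequence": order})
    features["master_accessions"] = [masters[s] for s in order]
    for c in META_COLUMNS:
        features[c] = [meta[s][c] for s in order]
    abundances = pd.DataFrame(
        [[float(counts[seq][s]) for s in samples] for seq in order],
        columns=samples, dtype=float,
    )
    return QuantTable(level="peptide", features=features, abundances=abundances)
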