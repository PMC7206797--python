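"""Inclusion filtering, minimum-value imputation and log transforms.

Stage order in the standard pipeline is filter -> impute -> log2.  A
protein is retained when it was quantified (nonzero reporter abundance)
in at least ``min_per_group`` replicates of *both* groups, or when it is
present in every replicate of one group, absent from every replicate of
the other, and carries a high protein-FDR confidence grade (the
"exclusive" rule for proteins unique to one purification strategy).
Remaining zeros are imputed as the lowest nonzero abundance of the
retained matrix, after which values are log2 transformed.

The row-geometric-mean form (``log2(abundance / row geomean)``) is a
per-protein relative abundance used for reporting and bar plots, not
for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AbundanceTable, GroupDesign

__all__ = [
    "InclusionReport",
    "filter_by_replicate_coverage",
    "impute_missing",
    "log2_transform",
    "row_geomean_normalize",
    "column_total_normalize",
]


@dataclass
class InclusionReport:
    """Outcome of replicate-coverage filtering.

    ``kept`` and ``dropped`` partition the input accessions; ``dropped``
    maps accession -> reason code (``low_coverage`` or
    ``low_confidence_exclusive``).  ``exclusive`` is the subset of
    ``kept`` admitted through the all-present/all-absent rule.
    """

    kept: set[str] = field(default_factory=set)
    dropped: dict[str, str] = field(default_factory=dict)
    exclusive: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kept & set(self.dropped):
            raise ValueError("kept and dropped overlap")
        if not self.exclusive <= self.kept:
            raise ValueError("exclusive proteins must be kept")

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def filter_by_replicate_coverage(
    table: AbundanceTable, design: GroupDesign, min_per_group: int = 3
) -> tuple[AbundanceTable, InclusionReport]:
    """Apply the replicate-coverage inclusion rule.

    Keep a protein iff it has nonzero abundance in at least
    ``min_per_group`` replicates of both groups, or is nonzero in all
    replicates of one group and zero in all of the other *and* has
    ``high`` confidence (flagged exclusive).  Output preserves the input
    protein order.
    """
    if table.scale != "raw":
        raise ValueError(f"coverage filter requires a raw-scale table, got {table.scale}")
    design.validate_against(table)
    groups = (design.reference, design.comparison)
    sample_sets = {g: design.samples(g) for g in groups}
    for g, samples in sample_sets.items():
        if min_per_group > len(samples):
            raise ValueError(
                f"min_per_group={min_per_group} exceeds size of group "
                f"{g!r} ({len(samples)} samples)"
            )
    report = InclusionReport()
    keep_order: list[str] = []
    nonzero = table.data > 0
    for acc in table.data.index:
        counts = {g: int(nonzero.loc[acc, s].sum()) for g, s in sample_sets.items()}
        sizes = {g: len(s) for g, s in sample_sets.items()}
        covered = all(counts[g] >= min_per_group for g in groups)
        exclusive_pattern = any(
            counts[g] == sizes[g] and counts[other] == 0
            for g, other in ((groups[0], groups[1]), (groups[1], groups[0]))
        )
        if covered:
            report.kept.add(acc)
            keep_order.append(acc)
        elif exclusive_pattern:
            if table.confidence[acc] == "high":
                report.kept.add(acc)
                report.exclusive.add(acc)
                keep_order.append(acc)
            else:
                report.dropped[acc] = "low_confidence_exclusive"
        else:
            report.dropped[acc] = "low_coverage"
    return table.subset(keep_order), report


def impute_missing(table: AbundanceTable, floor: float | None = None) -> AbundanceTable:
    """Replace zeros with the lowest nonzero abundance of the matrix.

    The global minimum is taken over the table as given (by default the
    pipeline applies this after filtering, so "the dataset" is the
    retained matrix; pass ``floor`` to impute with a minimum computed
    over a larger matrix, e.g. the unfiltered one).  Nonzero values are
    untouched; the result has ``scale="imputed"`` and the operation is
    idempotent.
    """
    if table.scale != "raw":
        raise ValueError(f"imputation requires a raw-scale table, got {table.scale}")
    values = table.data.to_numpy(dtype=float)
    if floor is None:
        nonzero = values[values > 0]
        if nonzero.size == 0:
            raise ValueError("cannot impute an all-zero matrix")
        floor = nonzero.min()
    elif floor <= 0:
        raise ValueError("imputation floor must be positive")
    out = np.where(values > 0, values, floor)
    return table.with_values(out, scale="imputed")


def log2_transform(table: AbundanceTable) -> AbundanceTable:
    """log2 of a strictly positive (imputed) table."""
    if table.scale != "imputed":
        raise ValueError(f"log2 transform requires an imputed table, got {table.scale}")
    values = table.data.to_numpy(dtype=float)
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive abundance for protein {table.data.index[i]!r}, "
            f"sample {table.data.columns[j]!r}"
        )
    return table.with_values(np.log2(values), scale="log2")


def row_geomean_normalize(table: AbundanceTable) -> AbundanceTable:
    """Per-protein relative abundance: log2(value / row geometric mean).

    Each output row sums to zero in log2 space, and the result is
    invariant to rescaling a protein's raw row by any positive constant.
    """
    if table.scale != "imputed":
        raise ValueError(
            f"row-geomean normalization requires an imputed table, got {table.scale}"
        )
    values = table.data.to_numpy(dtype=float)
    if (values <= 0).any():
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(
            f"non-positive abundance for protein {table.data.index[i]!r}, "
            f"sample {table.data.columns[j]!r}"
        )
    logv = np.log2(values)
    centered = logv - logv.mean(axis=1, keepdims=True)
    return table.with_values(centered, scale="log2")


def column_total_normalize(table: AbundanceTable) -> AbundanceTable:
    """Optional equal-column-sum scaling of a raw table.

    Scales every sample so that its total abundance equals the mean
    column total.  Off by default: reporter abundances exported by
    search engines are normally already channel-normalized.
    """
    if table.scale != "raw":
        raise ValueError(f"column normalization requires a raw table, got {table.scale}")
    values = table.data.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cannot normalize a sample with zero total abundance")
    scaled = values * (totals.mean() / totals)
    return table.with_values(scaled, scale="raw")
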