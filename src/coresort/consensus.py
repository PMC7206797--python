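"""Percentile ranking and consensus high-abundance core-protein calling.

A protein belongs to the consensus core when its group-mean log2
abundance sits at or above a percentile threshold in *both* purification
strategies.  Percentiles use the midpoint-rank convention
``100 * (rank - 0.5) / N`` with average ranks for ties, which is
symmetric (mean percentile is always 50) and robust to ties; membership
therefore depends only on the ordering of abundances, not their scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, GroupDesign, MarkerReference

__all__ = [
    "percentile_rank",
    "abundance_ranks",
    "consensus_core",
    "ConsensusSet",
    "top_marker_selection",
    "threshold_grid",
]


def percentile_rank(values) -> np.ndarray:
    """Midpoint-rank percentiles: ``100 * (rank - 0.5) / N``, average-rank ties."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    ranks = stats.rankdata(values, method="average")
    return 100.0 * (ranks - 0.5) / values.size


def abundance_ranks(table: AbundanceTable, design: GroupDesign) -> pd.DataFrame:
    """Group-mean log2 abundance and within-group percentile per protein."""
    if table.scale != "log2":
        raise ValueError(f"ranking expects a log2 table, got {table.scale}")
    design.validate_against(table)
    out = pd.DataFrame(index=table.data.index)
    out.index.name = "accession"
    out["symbol"] = table.symbols
    for group in (design.reference, design.comparison):
        means = table.data[design.samples(group)].mean(axis=1)
        out[f"mean_{group}"] = means
        out[f"percentile_{group}"] = percentile_rank(means.to_numpy())
    return out


@dataclass
class ConsensusSet:
    """Proteins above the abundance-percentile threshold in both groups.

    ``members`` is ordered by the smaller of the two group percentiles,
    descending (ties broken by accession for stability); ``ranks`` keeps
    the per-group means/percentiles for every analyzed protein.
    """

    members: list[str]
    threshold_percentile: float
    ranks: pd.DataFrame

    def __len__(self) -> int:
        return len(self.members)

    def member_table(self) -> pd.DataFrame:
        table = self.ranks.loc[self.members].copy()
        pct_cols = [c for c in table.columns if c.startswith("percentile_")]
        table["min_percentile"] = table[pct_cols].min(axis=1)
        return table


def consensus_core(
    table: AbundanceTable, design: GroupDesign, threshold: float = 90.0
) -> ConsensusSet:
    """Call the consensus high-abundance core at a percentile threshold.

    Membership requires percentile >= threshold in both groups, so the
    call is invariant to any strictly increasing transformation of the
    abundances and nested: raising the threshold never adds members.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold percentile must lie in (0, 100)")
    ranks = abundance_ranks(table, design)
    pct_cols = [f"percentile_{g}" for g in (design.reference, design.comparison)]
    min_pct = ranks[pct_cols].min(axis=1)
    members_frame = ranks[min_pct >= threshold].assign(_min=min_pct[min_pct >= threshold])
    # sort by accession first so that the stable sort breaks ties deterministically
    order = members_frame.sort_index().sort_values(
        by="_min", ascending=False, kind="mergesort"
    )
    return ConsensusSet(list(order.index), threshold, ranks)


def top_marker_selection(
    core: ConsensusSet, reference: MarkerReference, cell_type: str = "microglia"
) -> pd.DataFrame:
    """Core members whose reference label matches ``cell_type``.

    Returns the member table restricted to matching symbols, keeping the
    core's consensus-abundance ordering.  The result depends only on
    set membership and ranks, so it is stable under permutations of the
    underlying input rows.
    """
    table = core.member_table()
    mask = [reference.label(s) == cell_type for s in table["symbol"]]
    return table[np.array(mask, dtype=bool)] if len(table) else table


def threshold_grid(
    table: AbundanceTable,
    design: GroupDesign,
    thresholds=tuple(range(50, 100, 5)),
) -> pd.DataFrame:
    """Consensus-set size over a grid of percentile thresholds.

    Calibration utility for locating a target core-set size empirically
    when the threshold convention behind a published count is unknown.
    """
    ranks = abundance_ranks(table, design)
    pct_cols = [f"percentile_{g}" for g in (design.reference, design.comparison)]
    min_pct = ranks[pct_cols].min(axis=1).to_numpy()
    rows = [
        {"threshold": float(t), "n_members": int((min_pct >= t).sum())}
        for t in thresholds
    ]
    return pd.DataFrame(rows)
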