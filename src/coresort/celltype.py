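"""Cell-type marker enrichment of differential results.

Each tested protein is annotated with the cell type its gene symbol
carries in a marker reference (``none`` when unmatched).  Significant
proteins are tallied per cell type and direction, and over-representation
of each cell type within the increased and decreased lists is scored
with a one-tailed Fisher exact (hypergeometric upper-tail) test against
the background of all quantified proteins, BH-corrected across the
cell-type x direction family.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_fdr
from .io import CELL_TYPES, MarkerReference

__all__ = [
    "annotate_celltype",
    "celltype_overlap_counts",
    "fisher_onetailed",
    "reference_concordance",
]

#: Display label for unassigned proteins, matching summary-table convention.
NO_CELL_TYPE = "No cell-type"

_ORDER = ["microglia", "neuron", "astrocyte", "oligodendrocyte", "endothelial"]


def annotate_celltype(
    results: pd.DataFrame, reference: MarkerReference
) -> pd.DataFrame:
    """Add a ``cell_type`` column to a differential-results frame.

    Unmatched symbols get ``none``.  The annotation is a pure row-wise
    lookup, so it is independent of row order.
    """
    if "symbol" not in results.columns:
        raise ValueError("results frame needs a 'symbol' column")
    out = results.copy()
    out["cell_type"] = [reference.label(s) for s in out["symbol"]]
    return out


def fisher_onetailed(
    overlap: int, list_size: int, category_size: int, background_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    ``overlap`` successes drawing ``list_size`` items from a background
    of ``background_size`` containing ``category_size`` category
    members; equivalent to a one-tailed Fisher exact test for
    over-representation.
    """
    if not 0 <= overlap <= min(list_size, category_size):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, list={list_size}, "
            f"category={category_size}"
        )
    if max(list_size, category_size) > background_size:
        raise ValueError("list and category must fit inside the background")
    return float(stats.hypergeom.sf(overlap - 1, background_size, category_size, list_size))


def celltype_overlap_counts(
    annotated: pd.DataFrame,
    alpha: float = 0.05,
    test: bool = True,
) -> pd.DataFrame:
    """Summary-table-style counts with per-direction Fisher enrichment.

    Parameters
    ----------
    annotated
        Differential-results frame carrying ``direction`` and
        ``cell_type`` columns (see :func:`annotate_celltype`).  All rows
        form the test background; only rows with
        ``direction != 'unchanged'`` (the p < alpha set) are counted.
    alpha
        Recorded for provenance only; significance was already decided
        by the differential stage.
    test
        Compute Fisher p and BH q per cell type x direction.  The
        "No cell-type" row is reported but never tested.

    Returns a frame indexed by display label with columns
    ``n_increased, pct_increased, n_decreased, pct_decreased, n_total``
    plus (when ``test``) ``fisher_p_increased/decreased`` and
    ``fdr_q_increased/decreased``.
    """
    for col in ("direction", "cell_type"):
        if col not in annotated.columns:
            raise ValueError(f"annotated frame needs a {col!r} column")
    background_n = len(annotated)
    sig = annotated[annotated["direction"] != "unchanged"]
    labels = [c for c in _ORDER if (annotated["cell_type"] == c).any()]
    rows = {}
    for label in [NO_CELL_TYPE, *labels]:
        key = "none" if label == NO_CELL_TYPE else label
        members = annotated["cell_type"] == key
        sig_members = sig[sig["cell_type"] == key]
        n_inc = int((sig_members["direction"] == "increased").sum())
        n_dec = int((sig_members["direction"] == "decreased").sum())
        total = n_inc + n_dec
        rows[label] = {
            "n_increased": n_inc,
            "pct_increased": 100.0 * n_inc / total if total else 0.0,
            "n_decreased": n_dec,
            "pct_decreased": 100.0 * n_dec / total if total else 0.0,
            "n_total": total,
            "_category_size": int(members.sum()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_type"
    if test:
        n_inc_list = int((sig["direction"] == "increased").sum())
        n_dec_list = int((sig["direction"] == "decreased").sum())
        pvals: dict[tuple[str, str], float] = {}
        for label in labels:
            cat = int(out.loc[label, "_category_size"])
            pvals[(label, "increased")] = fisher_onetailed(
                int(out.loc[label, "n_increased"]), n_inc_list, cat, background_n
            )
            pvals[(label, "decreased")] = fisher_onetailed(
                int(out.loc[label, "n_decreased"]), n_dec_list, cat, background_n
            )
        keys = list(pvals)
        qvals = dict(zip(keys, bh_fdr([pvals[k] for k in keys]))) if keys else {}
        for direction in ("increased", "decreased"):
            out[f"fisher_p_{direction}"] = [
                pvals.get((label, direction), np.nan) for label in out.index
            ]
            out[f"fdr_q_{direction}"] = [
                qvals.get((label, direction), np.nan) for label in out.index
            ]
    return out.drop(columns="_category_size")


def reference_concordance(
    ref_a: MarkerReference, ref_b: MarkerReference
) -> pd.DataFrame:
    """Per-cell-type Venn counts between two marker references.

    For every cell-type label (``none`` excluded) reports the number of
    symbols exclusive to each reference and shared by both.
    """
    labels = sorted((set(ref_a.mapping.values()) | set(ref_b.mapping.values())) - {"none"})
    rows = {}
    for label in labels:
        sa = ref_a.symbols_for(label)
        sb = ref_b.symbols_for(label)
        rows[label] = {
            "n_a": len(sa),
            "n_b": len(sb),
            "a_only": len(sa - sb),
            "b_only": len(sb - sa),
            "shared": len(sa & sb),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cell_type"
    return out
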