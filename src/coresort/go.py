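"""GO-term over-representation with a hypergeometric Z-score.

Given an input symbol list (here: significantly differentially enriched
or depleted proteins with at least a two-fold change), a background of
all quantified symbols, and flat GMT gene sets, each term is scored
with:

* the one-tailed Fisher exact p (hypergeometric upper tail), and
* the normal approximation of that tail,
  ``z = (r - nR/N) / sqrt(n (R/N)(1 - R/N)(1 - (n-1)/(N-1)))``,

where N is the background size, R the term size within the background,
n the input-list size and r the observed overlap.  A term passes at
``z > 1.96`` and ``p < 0.05`` with at least ``min_genes`` background
members — the two criteria agree because 1.96 is the two-sided normal
5% point.  Terms are first intersected with the background; ontology
graph traversal and term pruning are out of scope (flat sets only).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .celltype import fisher_onetailed
from .differential import bh_fdr
from .io import GeneSetCollection

__all__ = ["go_zscore", "go_enrichment"]


def go_zscore(r: int, n: int, R: int, N: int) -> float:
    """Hypergeometric-moment normal approximation of term over-representation.

    Mean ``nR/N`` and variance ``n (R/N)(1-R/N)(N-n)/(N-1)`` are the
    exact first two moments of the hypergeometric overlap count.
    """
    if N < 2:
        raise ValueError("background must have at least 2 symbols")
    if not (0 <= r <= min(n, R) and n <= N and R <= N):
        raise ValueError(
            f"inconsistent counts r={r}, n={n}, R={R}, N={N}"
        )
    p = R / N
    variance = n * p * (1.0 - p) * (1.0 - (n - 1) / (N - 1))
    if variance <= 0.0:
        raise ValueError(
            f"degenerate configuration (R={R}, n={n}, N={N}): zero variance"
        )
    return (r - n * p) / math.sqrt(variance)


def go_enrichment(
    input_list: set[str],
    background: set[str],
    sets: GeneSetCollection,
    min_genes: int = 5,
    alpha: float = 0.05,
    z_threshold: float = 1.96,
    bh: bool = False,
) -> pd.DataFrame:
    """Score every gene set against an input list.

    Terms are intersected with the background before testing and
    skipped when fewer than ``min_genes`` background symbols remain.
    Results are sorted by Z-score descending.  ``bh`` adds a BH-adjusted
    q column (off by default; the pass criterion uses the unadjusted p).
    """
    input_list = {s.upper() for s in input_list}
    background = {s.upper() for s in background}
    if not background:
        raise ValueError("background symbol set is empty")
    if not input_list <= background:
        extra = sorted(input_list - background)[:5]
        raise ValueError(f"input symbols missing from background, e.g. {extra}")
    N = len(background)
    n = len(input_list)
    rows = []
    for term, (name, members) in sets.items():
        in_background = members & background
        R = len(in_background)
        if R < min_genes:
            continue
        r = len(in_background & input_list)
        zscore = go_zscore(r, n, R, N) if 0 < R < N and n < N else np.nan
        pvalue = fisher_onetailed(r, n, R, N)
        rows.append(
            {
                "term": term,
                "name": name,
                "R": R,
                "n": n,
                "r": r,
                "expected": n * R / N,
                "zscore": zscore,
                "fisher_p": pvalue,
                "passes": bool(
                    pvalue < alpha and np.isfinite(zscore) and zscore > z_threshold
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "name", "R", "n", "r", "expected", "zscore", "fisher_p", "passes",
        ],
    )
    if len(out):
        out = out.sort_values("zscore", ascending=False, kind="mergesort").reset_index(
            drop=True
        )
        if bh:
            out["fdr_q"] = bh_fdr(out["fisher_p"].to_numpy())
    elif bh:
        out["fdr_q"] = []
    return out
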