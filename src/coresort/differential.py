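"""Per-protein two-group differential enrichment.

The model is deliberately simple: for every protein an unpaired
two-sample t-test on log2 abundances between the comparison and the
reference group, Benjamini-Hochberg correction across proteins, and a
volcano-style classification.  ``log2fc`` is oriented comparison minus
reference, so positive values mean higher abundance in the comparison
(FACS-like) group.

The entry point follows the statsmodels idiom:

>>> model = DifferentialEnrichment(table_log2, design)
>>> res = model.fit()
>>> res.counts["n_significant"]
...

Degenerate comparisons (both groups constant after imputation) are kept
rather than erroring: equal constants give t=0, p=1; unequal constants
give p=0 with a ``degenerate`` flag so downstream consumers can treat
them cautiously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceTable, GroupDesign, MarkerReference

__all__ = [
    "TTestResult",
    "two_sample_ttest",
    "bh_fdr",
    "DifferentialEnrichment",
    "DifferentialEnrichmentResults",
    "volcano_table",
]


class TTestResult(NamedTuple):
    tstat: float
    df: float
    pvalue: float
    degenerate: bool = False


def two_sample_ttest(
    a: np.ndarray, b: np.ndarray, flavor: str = "student"
) -> TTestResult:
    """Unpaired two-sample t-test of ``b`` versus ``a`` (t > 0 when mean(b) > mean(a)).

    ``student`` pools variances (df = n_a + n_b - 2); ``welch`` uses the
    Satterthwaite approximation.  Two-sided p-value from the t
    distribution.  Zero-variance inputs are handled explicitly: equal
    constant vectors give (0, df, 1); unequal constant vectors give
    p = 0 with the ``degenerate`` flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in t-test input")
    if flavor not in ("student", "welch"):
        raise ValueError(f"flavor must be 'student' or 'welch', got {flavor!r}")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = b.mean() - a.mean()
    if va == 0.0 and vb == 0.0:
        df = float(na + nb - 2)
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=False)
        return TTestResult(np.sign(diff) * np.inf, df, 0.0, degenerate=True)
    if flavor == "student":
        df = float(na + nb - 2)
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    tstat = diff / se
    pvalue = 2.0 * stats.t.sf(abs(tstat), df)
    return TTestResult(float(tstat), float(df), float(min(pvalue, 1.0)))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class DifferentialEnrichment:
    """Two-group differential-enrichment model over a log2 abundance table.

    Parameters
    ----------
    table
        Filtered, imputed, log2-scale :class:`~coresort.io.AbundanceTable`.
    design
        Two-group :class:`~coresort.io.GroupDesign`; fold changes are
        ``comparison - reference``.
    flavor
        ``student`` (pooled variance, default) or ``welch``.
    """

    def __init__(
        self,
        table: AbundanceTable,
        design: GroupDesign,
        flavor: str = "student",
    ) -> None:
        if table.scale != "log2":
            raise ValueError(
                f"differential enrichment expects a log2 table, got {table.scale}"
            )
        design.validate_against(table)
        if flavor not in ("student", "welch"):
            raise ValueError(f"flavor must be 'student' or 'welch', got {flavor!r}")
        self.table = table
        self.design = design
        self.flavor = flavor

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        design: GroupDesign,
        symbols: pd.Series | None = None,
        flavor: str = "student",
    ) -> "DifferentialEnrichment":
        """Build from a plain accession-indexed log2 DataFrame."""
        if symbols is None:
            symbols = pd.Series(list(data.index), index=data.index)
        table = AbundanceTable(data, symbols, scale="log2")
        return cls(table, design, flavor=flavor)

    def fit(
        self,
        alpha: float = 0.05,
        fold_log2: float = 1.0,
        alpha_inclusive: bool = False,
    ) -> "DifferentialEnrichmentResults":
        """Run the per-protein tests and classify the volcano.

        ``alpha`` is the unadjusted significance threshold (strict
        ``p < alpha`` unless ``alpha_inclusive``), ``fold_log2`` the
        absolute log2 fold-change bound for the >= 2^fold classification
        (which also requires significance).
        """
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        ref = self.design.samples(self.design.reference)
        comp = self.design.samples(self.design.comparison)
        a = self.table.data[ref].to_numpy(dtype=float)
        b = self.table.data[comp].to_numpy(dtype=float)
        rows = []
        for i in range(a.shape[0]):
            res = two_sample_ttest(a[i], b[i], flavor=self.flavor)
            rows.append(res)
        log2fc = b.mean(axis=1) - a.mean(axis=1)
        pvalues = np.array([r.pvalue for r in rows])
        qvalues = bh_fdr(pvalues)
        significant = pvalues <= alpha if alpha_inclusive else pvalues < alpha
        direction = np.where(
            ~significant,
            "unchanged",
            np.where(log2fc > 0, "increased", np.where(log2fc < 0, "decreased", "unchanged")),
        )
        fold2 = significant & (np.abs(log2fc) >= fold_log2) & (direction != "unchanged")
        frame = pd.DataFrame(
            {
                "accession": self.table.accessions,
                "symbol": [self.table.symbols[acc] for acc in self.table.accessions],
                "log2fc": log2fc,
                "tstat": [r.tstat for r in rows],
                "df": [r.df for r in rows],
                "pvalue": pvalues,
                "qvalue": qvalues,
                "direction": direction,
                "fold2": fold2,
                "degenerate": [r.degenerate for r in rows],
            }
        )
        return DifferentialEnrichmentResults(self, frame, alpha, fold_log2)


@dataclass
class DifferentialEnrichmentResults:
    """Fitted per-protein results plus volcano-style summaries."""

    model: DifferentialEnrichment
    frame: pd.DataFrame
    alpha: float
    fold_log2: float

    @property
    def counts(self) -> dict[str, int]:
        f = self.frame
        return {
            "n_proteins": len(f),
            "n_significant": int((f["direction"] != "unchanged").sum()),
            "n_fdr": int((f["qvalue"] < self.alpha).sum()),
            "n_increased": int((f["direction"] == "increased").sum()),
            "n_decreased": int((f["direction"] == "decreased").sum()),
            "n_fold2_increased": int((f["fold2"] & (f["direction"] == "increased")).sum()),
            "n_fold2_decreased": int((f["fold2"] & (f["direction"] == "decreased")).sum()),
        }

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != "unchanged"]

    def input_symbols(self, direction: str = "both", fold2_only: bool = True) -> set[str]:
        """Symbol sets for over-representation input lists.

        Defaults to the significant AND >= 2^fold_log2 definition used
        for GO input lists; ``direction`` selects increased, decreased
        or both.
        """
        f = self.frame
        mask = f["fold2"] if fold2_only else (f["direction"] != "unchanged")
        if direction in ("increased", "decreased"):
            mask = mask & (f["direction"] == direction)
        elif direction != "both":
            raise ValueError("direction must be 'increased', 'decreased' or 'both'")
        return set(f.loc[mask, "symbol"])

    def background_symbols(self) -> set[str]:
        return set(self.frame["symbol"])

    def summary(self) -> str:
        """Plain-text summary table in the statsmodels spirit."""
        c = self.counts
        design = self.model.design
        lines = [
            "Differential enrichment (unpaired t-test, "
            f"{self.model.flavor} flavor)",
            "=" * 64,
            f"Comparison: {design.comparison} vs {design.reference} "
            f"(log2FC = {design.comparison} - {design.reference})",
            f"Proteins tested:                {c['n_proteins']:>6}",
            f"Significant (p < {self.alpha:g}):        {c['n_significant']:>6}",
            f"Significant (BH FDR < {self.alpha:g}):   {c['n_fdr']:>6}",
            f"  increased in {design.comparison:<12}   {c['n_increased']:>6}",
            f"  decreased in {design.comparison:<12}   {c['n_decreased']:>6}",
            f"  >= {2 ** self.fold_log2:.0f}-fold increased:         {c['n_fold2_increased']:>6}",
            f"  >= {2 ** self.fold_log2:.0f}-fold decreased:         {c['n_fold2_decreased']:>6}",
            "=" * 64,
        ]
        return "\n".join(lines)

    def volcano_table(self, reference: MarkerReference | None = None) -> pd.DataFrame:
        """Export table for volcano plotting (one row per tested protein)."""
        return volcano_table(self.frame, reference)

    def plot_volcano(self, ax=None, reference: MarkerReference | None = None):
        """Volcano scatter (requires matplotlib)."""
        import matplotlib.pyplot as plt

        table = self.volcano_table(reference)
        if ax is None:
            _, ax = plt.subplots()
        colors = table["direction"].map(
            {"increased": "tab:orange", "decreased": "tab:blue", "unchanged": "0.7"}
        )
        ax.scatter(table["log2fc"], table["neg_log10_p"], s=8, c=colors, lw=0)
        ax.axhline(-np.log10(self.alpha), ls=":", c="k", lw=0.8)
        for x in (-self.fold_log2, self.fold_log2):
            ax.axvline(x, ls=":", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        return ax


def volcano_table(
    frame: pd.DataFrame, reference: MarkerReference | None = None
) -> pd.DataFrame:
    """Columns needed to draw a volcano: log2fc, -log10 p, classification.

    p-values of exactly 0 (degenerate comparisons) map to +inf on the
    -log10 axis; a cell-type column is added when a marker reference is
    supplied.
    """
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(frame["pvalue"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "accession": frame["accession"],
            "symbol": frame["symbol"],
            "log2fc": frame["log2fc"],
            "neg_log10_p": neg_log10_p,
            "direction": frame["direction"],
            "fold2": frame["fold2"],
        }
    )
    if reference is not None:
        out["cell_type"] = [reference.label(s) for s in out["symbol"]]
    return out
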