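"""Synthetic sorted-cell proteomes with known ground truth.

The generator emulates the contamination structure of sorted-cell
proteomics: each brain cell type has a log2 expression profile in which
its marker proteins are enriched by a fixed effect, and each observed
sample is a purity-weighted *linear-intensity* mixture of those
profiles.  Reporter intensities add physically across co-isolated
material, so debris carried into an enriched preparation contributes
its cell types' intensities in proportion to the mixing weights.  A
gentler-purity group (MACS-like, cellular debris from neurons,
astrocytes and oligodendrocytes) and a high-purity group (FACS-like)
therefore differ by closed-form expected log2 fold changes:

    E[log2fc] = log2(sum_c w_comp_c 2^profile_c)
              - log2(sum_c w_ref_c  2^profile_c)

On top of the mixture, samples receive multiplicative log-normal
reporter noise and abundance-dependent missingness with logistic
probability decreasing in log2 abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AbundanceTable, GroupDesign, MarkerReference

__all__ = [
    "SimulationConfig",
    "generate_profiles",
    "mix_samples",
    "simulate_experiment",
]

_CELL_TYPES = ("microglia", "neuron", "astrocyte", "oligodendrocyte", "endothelial")
_PREFIX = {
    "microglia": "MGL",
    "neuron": "NEU",
    "astrocyte": "AST",
    "oligodendrocyte": "OLG",
    "endothelial": "END",
    "shared": "SHR",
}


def _default_fractions() -> dict[str, float]:
    return {
        "microglia": 0.08,
        "neuron": 0.08,
        "astrocyte": 0.08,
        "oligodendrocyte": 0.08,
        "endothelial": 0.04,
    }


def _default_compositions() -> dict[str, dict[str, float]]:
    # MACS-like retains acellular debris from other cell types; FACS-like
    # gates it out almost completely.
    return {
        "MACS": {
            "microglia": 0.85,
            "neuron": 0.07,
            "astrocyte": 0.045,
            "oligodendrocyte": 0.03,
            "endothelial": 0.005,
        },
        "FACS": {
            "microglia": 0.97,
            "neuron": 0.01,
            "astrocyte": 0.01,
            "oligodendrocyte": 0.005,
            "endothelial": 0.005,
        },
    }


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 2 groups x 5 replicates, ~1800 proteins.

    Parameters
    ----------
    n_proteins
        Total simulated proteins; those not assigned as markers form a
        shared pool expressed equally in every cell type.
    celltype_fractions
        Fraction of proteins assigned as markers of each cell type
        (must sum to <= 1).
    marker_log2_enrichment
        log2 enrichment of a marker in its own cell type versus all
        others.
    group_compositions
        Per group, cell-type mixing weights summing to 1; the first
        group listed is the reference (MACS-like).
    n_replicates
        Samples per group.
    noise_sigma
        Standard deviation (log2 units) of multiplicative reporter noise.
    dropout_midpoint, dropout_slope
        Logistic missingness on log2 abundance: at the midpoint a value
        is missing with probability 0.5, decreasing with abundance at
        the given slope.  A non-positive slope disables dropout.
    baseline_mean, baseline_sd
        Normal distribution of baseline log2 abundance per protein.
    seed
        Default RNG seed used when none is passed explicitly.
    """

    n_proteins: int = 1791
    celltype_fractions: dict[str, float] = field(default_factory=_default_fractions)
    marker_log2_enrichment: float = 3.0
    group_compositions: dict[str, dict[str, float]] = field(
        default_factory=_default_compositions
    )
    n_replicates: int = 5
    noise_sigma: float = 0.3
    dropout_midpoint: float = 4.0
    dropout_slope: float = 1.0
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be at least 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        fracs = self.celltype_fractions
        if any(not 0 <= f <= 1 for f in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("celltype_fractions must lie in [0,1] and sum to <= 1")
        unknown = set(fracs) - set(_CELL_TYPES)
        if unknown:
            raise ValueError(f"unknown cell types in fractions: {sorted(unknown)}")
        if len(self.group_compositions) != 2:
            raise ValueError("exactly two groups are required")
        for group, weights in self.group_compositions.items():
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixing weights of group {group!r} must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative mixing weight in group {group!r}")
            unknown = set(weights) - set(_CELL_TYPES)
            if unknown:
                raise ValueError(
                    f"unknown cell types in group {group!r}: {sorted(unknown)}"
                )

    @property
    def groups(self) -> tuple[str, str]:
        ref, comp = self.group_compositions
        return ref, comp

    def null(self) -> "SimulationConfig":
        """Copy with identical compositions in both groups (no true effects)."""
        ref, comp = self.groups
        compositions = {
            ref: dict(self.group_compositions[ref]),
            comp: dict(self.group_compositions[ref]),
        }
        return replace(self, group_compositions=compositions)


def generate_profiles(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cell-type log2 expression profiles plus truth assignment.

    Every protein draws a baseline log2 abundance from
    N(baseline_mean, baseline_sd), equal across cell types; markers add
    ``marker_log2_enrichment`` in their own cell type only.  Returns the
    proteins x cell-types profile matrix and a Series giving each
    protein's assigned cell type (``shared`` for the unassigned pool).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    counts = {c: int(round(f * n)) for c, f in config.celltype_fractions.items()}
    if sum(counts.values()) > n:
        raise ValueError("celltype fractions allocate more proteins than available")
    assignment: list[str] = []
    for cell_type in _CELL_TYPES:
        assignment += [cell_type] * counts.get(cell_type, 0)
    assignment += ["shared"] * (n - len(assignment))
    tally: dict[str, int] = {}
    accessions = []
    for cell_type in assignment:
        tally[cell_type] = tally.get(cell_type, 0) + 1
        accessions.append(f"{_PREFIX[cell_type]}{tally[cell_type]:04d}")
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    profiles = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(_CELL_TYPES))),
        index=accessions,
        columns=list(_CELL_TYPES),
    )
    for i, cell_type in enumerate(assignment):
        if cell_type != "shared":
            profiles.iloc[i, profiles.columns.get_loc(cell_type)] += (
                config.marker_log2_enrichment
            )
    truth = pd.Series(assignment, index=accessions, name="cell_type")
    return profiles, truth


def _expected_intensity(profiles: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    linear = np.power(2.0, profiles.to_numpy(dtype=float))
    w = np.array([weights.get(c, 0.0) for c in profiles.columns])
    return linear @ w


def mix_samples(
    profiles: pd.DataFrame,
    truth: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Mix cell-type profiles into noisy replicate samples.

    Each sample's noise-free intensity is the weighted sum of linear
    intensities ``sum_c w_c 2^profile_c``; multiplicative log-normal
    noise (sigma in log2 units) and logistic dropout are applied on top,
    with dropped-out values stored as 0.  Returns a raw-scale
    :class:`AbundanceTable` (confidence ``high`` throughout) plus the
    per-protein truth frame with the closed-form expected log2fc.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref, comp = config.groups
    expected = {
        g: _expected_intensity(profiles, config.group_compositions[g])
        for g in (ref, comp)
    }
    n = len(profiles)
    columns: dict[str, np.ndarray] = {}
    for group in (ref, comp):
        for rep in range(1, config.n_replicates + 1):
            signal = expected[group].copy()
            if config.noise_sigma > 0:
                signal = signal * np.power(
                    2.0, rng.normal(0.0, config.noise_sigma, size=n)
                )
            if config.dropout_slope > 0:
                p_missing = expit(
                    -(np.log2(signal) - config.dropout_midpoint) * config.dropout_slope
                )
                signal = np.where(rng.random(n) < p_missing, 0.0, signal)
            columns[f"{group}_{rep}"] = signal
    data = pd.DataFrame(columns, index=profiles.index)
    symbols = pd.Series(list(profiles.index), index=profiles.index)
    confidence = pd.Series("high", index=profiles.index)
    table = AbundanceTable(data, symbols, confidence, scale="raw")
    truth_frame = pd.DataFrame(
        {
            "cell_type": truth,
            "is_marker": truth != "shared",
            "expected_log2fc": np.log2(expected[comp]) - np.log2(expected[ref]),
        },
        index=profiles.index,
    )
    truth_frame.index.name = "accession"
    return table, truth_frame


def simulate_experiment(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[AbundanceTable, GroupDesign, MarkerReference, pd.DataFrame]:
    """Complete pipeline-ready dataset: table, design, marker truth, truth frame.

    Fully reproducible from ``seed`` (falls back to ``config.seed``).
    The returned marker reference assigns exactly the simulated marker
    proteins to their true cell types.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    profiles, truth = generate_profiles(config, rng)
    table, truth_frame = mix_samples(profiles, truth, config, rng)
    ref, comp = config.groups
    assignment = {s: s.rsplit("_", 1)[0] for s in table.samples}
    design = GroupDesign(assignment, ref, comp)
    mapping = {
        acc: cell_type
        for acc, cell_type in truth.items()
        if cell_type != "shared"
    }
    reference = MarkerReference(mapping, provenance="synthetic truth")
    return table, design, reference, truth_frame
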