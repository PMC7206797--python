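"""End-to-end orchestration: preprocess -> DE -> cell type -> consensus -> GO.

Every stage writes a TSV under the configured output directory and a
JSON run report collects the headline numbers (inclusion counts, DE
counts, cell-type tables, consensus size, GO table sizes) together with
input checksums and every parameter, so a run is reproducible from the
report alone.  Outputs carry no timestamps: identical config + inputs
give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .celltype import annotate_celltype, celltype_overlap_counts, reference_concordance
from .consensus import consensus_core, threshold_grid, top_marker_selection
from .differential import DifferentialEnrichment
from .go import go_enrichment
from .io import (
    read_abundance_table,
    read_gene_sets,
    read_group_design,
    read_marker_reference,
    write_abundance_table,
    write_table,
)
from .preprocess import (
    column_total_normalize,
    filter_by_replicate_coverage,
    impute_missing,
    log2_transform,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    abundance: str
    design: str
    outdir: str
    marker_references: list[str] = field(default_factory=list)
    gene_sets: str | None = None
    reference_group: str | None = None
    min_per_group: int = 3
    impute_scope: str = "filtered"  # or "full"
    column_normalize: str = "none"  # or "total"
    alpha: float = 0.05
    alpha_inclusive: bool = False
    fold_log2: float = 1.0
    flavor: str = "student"
    threshold_percentile: float = 90.0
    min_genes: int = 5

    def __post_init__(self) -> None:
        if self.impute_scope not in ("filtered", "full"):
            raise ValueError("impute_scope must be 'filtered' or 'full'")
        if self.column_normalize not in ("none", "total"):
            raise ValueError("column_normalize must be 'none' or 'total'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _StageContext()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run report (also written
    to ``<outdir>/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "coresort": __version__,
        "parameters": asdict(config),
        "inputs": {"abundance": _sha256(config.abundance), "design": _sha256(config.design)},
    }
    for path in config.marker_references:
        report["inputs"][Path(path).name] = _sha256(path)
    if config.gene_sets:
        report["inputs"][Path(config.gene_sets).name] = _sha256(config.gene_sets)

    with _stage("preprocess"):
        table = read_abundance_table(config.abundance)
        design = read_group_design(config.design, reference=config.reference_group)
        if config.column_normalize == "total":
            table = column_total_normalize(table)
        full_min = None
        if config.impute_scope == "full":
            values = table.data.to_numpy()
            positive = values[values > 0]
            full_min = float(positive.min()) if positive.size else None
        filtered, inclusion = filter_by_replicate_coverage(
            table, design, min_per_group=config.min_per_group
        )
        imputed = impute_missing(filtered, floor=full_min)
        logged = log2_transform(imputed)
        write_abundance_table(
            logged,
            outdir / "abundance_log2.tsv",
            params={"min_per_group": config.min_per_group, "impute_scope": config.impute_scope},
        )
        inclusion_rows = [
            {"accession": acc, "status": "kept", "reason": "exclusive" if acc in inclusion.exclusive else "covered"}
            for acc in sorted(inclusion.kept)
        ] + [
            {"accession": acc, "status": "dropped", "reason": reason}
            for acc, reason in sorted(inclusion.dropped.items())
        ]
        write_table(pd.DataFrame(inclusion_rows), outdir / "inclusion_report.tsv")
        report["preprocess"] = {
            "n_input": table.shape[0],
            "n_kept": inclusion.n_kept,
            "n_dropped": inclusion.n_dropped,
            "n_exclusive": len(inclusion.exclusive),
        }

    with _stage("de"):
        model = DifferentialEnrichment(logged, design, flavor=config.flavor)
        results = model.fit(
            alpha=config.alpha,
            fold_log2=config.fold_log2,
            alpha_inclusive=config.alpha_inclusive,
        )
        write_table(
            results.frame,
            outdir / "differential.tsv",
            params={"alpha": config.alpha, "flavor": config.flavor},
        )
        report["de"] = results.counts

    references = {
        Path(p).name: read_marker_reference(p) for p in config.marker_references
    }
    if references:
        with _stage("celltype"):
            report["celltype"] = {}
            annotated_first = None
            for name, reference in references.items():
                annotated = annotate_celltype(results.frame, reference)
                if annotated_first is None:
                    annotated_first = annotated
                overlap = celltype_overlap_counts(annotated, alpha=config.alpha)
                stem = Path(name).stem
                write_table(
                    overlap.reset_index(), outdir / f"celltype_{stem}.tsv"
                )
                report["celltype"][name] = {
                    row: {
                        "n_increased": int(overlap.loc[row, "n_increased"]),
                        "n_decreased": int(overlap.loc[row, "n_decreased"]),
                        "n_total": int(overlap.loc[row, "n_total"]),
                    }
                    for row in overlap.index
                }
            write_table(
                results.volcano_table(next(iter(references.values()))),
                outdir / "volcano.tsv",
            )
            if len(references) >= 2:
                names = list(references)
                concordance = reference_concordance(
                    references[names[0]], references[names[1]]
                )
                write_table(concordance.reset_index(), outdir / "concordance.tsv")
                report["concordance"] = {
                    row: {k: int(v) for k, v in concordance.loc[row].items()}
                    for row in concordance.index
                }
    else:
        with _stage("volcano"):
            write_table(results.volcano_table(), outdir / "volcano.tsv")

    with _stage("consensus"):
        core = consensus_core(
            logged, design, threshold=config.threshold_percentile
        )
        write_table(
            core.member_table().reset_index(),
            outdir / "consensus_members.tsv",
            params={"threshold_percentile": config.threshold_percentile},
        )
        grid = threshold_grid(logged, design)
        write_table(grid, outdir / "consensus_grid.tsv")
        report["consensus"] = {
            "threshold_percentile": config.threshold_percentile,
            "n_members": len(core),
            "grid": {str(row.threshold): int(row.n_members) for row in grid.itertuples()},
        }
        if references:
            first = next(iter(references.values()))
            top = top_marker_selection(core, first)
            write_table(top.reset_index(), outdir / "consensus_top_markers.tsv")
            report["consensus"]["n_top_markers"] = len(top)

    if config.gene_sets:
        with _stage("go"):
            sets = read_gene_sets(config.gene_sets)
            background = results.background_symbols()
            report["go"] = {}
            for direction in ("increased", "decreased"):
                input_list = results.input_symbols(direction=direction)
                if not input_list:
                    report["go"][direction] = {"n_input": 0, "n_terms": 0, "n_passing": 0}
                    continue
                enriched = go_enrichment(
                    input_list, background, sets, min_genes=config.min_genes
                )
                write_table(enriched, outdir / f"go_{direction}.tsv")
                report["go"][direction] = {
                    "n_input": len(input_list),
                    "n_terms": len(enriched),
                    "n_passing": int(enriched["passes"].sum()) if len(enriched) else 0,
                }

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
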