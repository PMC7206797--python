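"""Domain containers and text-format readers/writers.

The pipeline operates on four kinds of inputs, all plain text:

* a wide protein-by-sample reporter-abundance table (TSV/CSV) with
  ``accession``, ``symbol``, optional ``confidence`` columns followed by
  one column per sample;
* a two-column sample/group design file (CSV or TSV);
* a cell-type marker reference mapping gene symbols to the brain cell
  type in which they are most enriched (two-column table or GMT);
* gene-set collections in standard GMT.

Gene symbols are uppercased at ingest everywhere so that mouse-style
(``Msn``) and human-style (``MSN``) symbols compare equal.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "CONFIDENCE_LEVELS",
    "AbundanceTable",
    "GroupDesign",
    "MarkerReference",
    "GeneSetCollection",
    "read_abundance_table",
    "write_abundance_table",
    "read_group_design",
    "read_marker_reference",
    "read_gene_sets",
    "write_table",
]

#: Closed set of cell-type labels used by the marker references.
CELL_TYPES = frozenset(
    {"microglia", "neuron", "astrocyte", "oligodendrocyte", "endothelial", "none"}
)

#: Search-engine protein FDR confidence grades.
CONFIDENCE_LEVELS = frozenset({"high", "medium", "low", "unknown"})

_SCALES = ("raw", "imputed", "log2")


@dataclass(frozen=True)
class ProteinId:
    """Identity of one protein group: accession, symbol, search confidence."""

    accession: str
    symbol: str
    confidence: str = "unknown"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError(f"empty symbol for accession {self.accession!r}")
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(
                f"confidence {self.confidence!r} not in {sorted(CONFIDENCE_LEVELS)}"
            )


class AbundanceTable:
    """Protein x sample reporter-abundance matrix with identity metadata.

    Parameters
    ----------
    data
        DataFrame of non-negative abundances, indexed by accession with
        one column per sample.  A value of 0 means "not quantified"
        (only meaningful while ``scale == "raw"``).
    symbols
        Series mapping accession -> uppercased gene symbol.
    confidence
        Series mapping accession -> protein FDR confidence grade.
        Defaults to ``"unknown"`` for every protein.
    scale
        One of ``raw`` (zeros encode missing), ``imputed`` (strictly
        positive linear intensities) or ``log2``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        symbols: pd.Series,
        confidence: pd.Series | None = None,
        scale: str = "raw",
    ) -> None:
        if scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {scale!r}")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise ValueError(f"duplicate accession {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample name {dup!r}")
        values = data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance matrix contains non-finite values")
        if scale in ("raw", "imputed") and (values < 0).any():
            raise ValueError(f"negative abundance in a {scale}-scale table")
        if scale == "imputed" and (values == 0).any():
            raise ValueError("imputed-scale table must not contain zeros")
        symbols = symbols.reindex(data.index)
        if symbols.isna().any() or (symbols == "").any():
            missing = symbols.index[symbols.isna() | (symbols == "")][0]
            raise ValueError(f"missing symbol for accession {missing!r}")
        if confidence is None:
            confidence = pd.Series("unknown", index=data.index)
        confidence = confidence.reindex(data.index).fillna("unknown")
        bad = set(confidence.unique()) - CONFIDENCE_LEVELS
        if bad:
            raise ValueError(f"unknown confidence grade(s) {sorted(bad)}")
        self.data = data.astype(float)
        self.symbols = symbols.str.upper()
        self.confidence = confidence
        self.scale = scale

    # -- basic protocol -------------------------------------------------
    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, m = self.shape
        return f"<AbundanceTable {n} proteins x {m} samples, scale={self.scale}>"

    def protein_ids(self) -> list[ProteinId]:
        return [
            ProteinId(acc, self.symbols[acc], self.confidence[acc])
            for acc in self.data.index
        ]

    def subset(self, accessions: Iterable[str]) -> "AbundanceTable":
        """Row subset preserving the original protein order."""
        keep = [a for a in self.data.index if a in set(accessions)]
        return AbundanceTable(
            self.data.loc[keep],
            self.symbols.loc[keep],
            self.confidence.loc[keep],
            scale=self.scale,
        )

    def with_values(self, values: np.ndarray, scale: str) -> "AbundanceTable":
        """New table with the same identities but a replaced matrix."""
        data = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return AbundanceTable(data, self.symbols, self.confidence, scale=scale)


@dataclass(frozen=True)
class GroupDesign:
    """Sample -> group assignment for a two-group comparison.

    ``reference`` is the baseline group (MACS-like in the motivating
    design) and ``comparison`` the group whose enrichment is reported
    (FACS-like); log2 fold changes are comparison minus reference.
    """

    assignment: Mapping[str, str]
    reference: str
    comparison: str

    def __post_init__(self) -> None:
        groups = set(self.assignment.values())
        if groups != {self.reference, self.comparison}:
            raise ValueError(
                f"design groups {sorted(groups)} do not match "
                f"({self.reference!r}, {self.comparison!r})"
            )
        for label in (self.reference, self.comparison):
            if len(self.samples(label)) < 2:
                raise ValueError(f"group {label!r} has fewer than 2 samples")

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]

    def validate_against(self, table: AbundanceTable) -> None:
        missing = [s for s in table.samples if s not in self.assignment]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")

    def swapped(self) -> "GroupDesign":
        return GroupDesign(dict(self.assignment), self.comparison, self.reference)


@dataclass
class MarkerReference:
    """Gene symbol -> cell-type label mapping with provenance.

    Symbols claimed by more than one cell type are resolved to ``none``;
    ``n_conflicts`` records how many were demoted this way.
    """

    mapping: dict[str, str]
    provenance: str = ""
    n_conflicts: int = 0

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - CELL_TYPES
        if bad:
            raise ValueError(
                f"unrecognized cell-type label(s) {sorted(bad)}; "
                f"allowed: {sorted(CELL_TYPES)}"
            )
        self.mapping = {s.upper(): c for s, c in self.mapping.items()}

    def label(self, symbol: str) -> str:
        return self.mapping.get(symbol.upper(), "none")

    def symbols_for(self, cell_type: str) -> frozenset[str]:
        return frozenset(s for s, c in self.mapping.items() if c == cell_type)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms or similar): term id -> (name, symbols)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_COLUMNS = ("accession", "symbol", "confidence")


def _infer_sep(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_directives(path: Path) -> dict[str, str]:
    """Parse ``# key=value`` comment lines at the top of a file."""
    directives: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                directives[key.strip()] = value.strip()
    return directives


def read_abundance_table(
    path: str | Path, dialect: str | None = None, scale: str | None = None
) -> AbundanceTable:
    """Read a wide abundance table.

    The file must have a header row with ``accession``, ``symbol``,
    optionally ``confidence``, followed by one column per sample.
    Leading ``#`` comment lines may carry a ``# scale=...`` directive;
    the explicit ``scale`` argument overrides it (default ``raw``).
    Blank cells and literal zeros are both stored as 0 ("not
    quantified") on the raw scale.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    if scale is None:
        scale = _read_directives(path).get("scale", "raw")
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    for required in ("accession", "symbol"):
        if required not in lower:
            raise ValueError(f"{path}: missing required column {required!r}")
    sample_cols = [c for c in df.columns if c.lower() not in _META_COLUMNS]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    accessions = df[lower["accession"]].astype(str).str.strip()
    if accessions.duplicated().any():
        dup = accessions[accessions.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate accession {dup!r}")
    values = np.zeros((len(df), len(sample_cols)))
    for j, col in enumerate(sample_cols):
        raw = df[col]
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                values[i, j] = 0.0
                continue
            text = str(cell).strip()
            if text == "" or text.lower() in ("na", "nan"):
                values[i, j] = 0.0
                continue
            try:
                values[i, j] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric abundance {text!r} at row "
                    f"{accessions.iloc[i]!r}, column {col!r}"
                ) from None
    data = pd.DataFrame(values, index=accessions.values, columns=sample_cols)
    symbols = pd.Series(
        df[lower["symbol"]].astype(str).str.strip().values, index=accessions.values
    )
    confidence = None
    if "confidence" in lower:
        confidence = pd.Series(
            df[lower["confidence"]].fillna("unknown").astype(str).str.strip().str.lower().values,
            index=accessions.values,
        )
    return AbundanceTable(data, symbols, confidence, scale=scale)


def write_abundance_table(
    table: AbundanceTable,
    path: str | Path,
    dialect: str | None = None,
    params: Mapping[str, object] | None = None,
) -> None:
    """Write a table in the reader's own dialect (round-trip safe).

    Floats are serialized with :func:`repr` so every value survives a
    write/read cycle bit-exactly.  A ``# scale=`` directive plus any
    extra ``params`` are recorded as header comments.
    """
    path = Path(path)
    sep = _infer_sep(path, dialect)
    header = {"scale": table.scale}
    if params:
        header.update({str(k): v for k, v in params.items()})
    buf = _io.StringIO()
    for key, value in header.items():
        buf.write(f"# {key}={value}\n")
    cols = ["accession", "symbol", "confidence", *table.samples]
    buf.write(sep.join(cols) + "\n")
    for acc in table.data.index:
        row = [acc, table.symbols[acc], table.confidence[acc]]
        row += [repr(float(v)) for v in table.data.loc[acc]]
        buf.write(sep.join(row) + "\n")
    path.write_text(buf.getvalue())


def read_group_design(
    path: str | Path, reference: str | None = None
) -> GroupDesign:
    """Read a two-column sample,group design file (CSV or TSV).

    ``reference`` names the baseline group; by default the group of the
    first sample listed is the reference.
    """
    path = Path(path)
    sep = _infer_sep(path, None)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design file needs 'sample' and 'group' columns")
    assignment = {
        str(s).strip(): str(g).strip() for s, g in zip(df["sample"], df["group"])
    }
    groups = list(dict.fromkeys(assignment.values()))
    if len(groups) != 2:
        raise ValueError(f"{path}: expected exactly 2 groups, found {groups}")
    if reference is None:
        reference = groups[0]
    if reference not in groups:
        raise ValueError(f"{path}: reference group {reference!r} not in {groups}")
    comparison = next(g for g in groups if g != reference)
    return GroupDesign(assignment, reference, comparison)


def _marker_from_pairs(
    pairs: Iterable[tuple[str, str]], provenance: str
) -> MarkerReference:
    seen: dict[str, str] = {}
    conflicted: set[str] = set()
    for symbol, cell_type in pairs:
        symbol = symbol.strip().upper()
        cell_type = cell_type.strip().lower()
        if cell_type not in CELL_TYPES:
            raise ValueError(
                f"unrecognized cell-type label {cell_type!r}; "
                f"allowed: {sorted(CELL_TYPES)}"
            )
        if symbol in seen and seen[symbol] != cell_type:
            conflicted.add(symbol)
        else:
            seen[symbol] = cell_type
    for symbol in conflicted:
        seen[symbol] = "none"
    if conflicted:
        warnings.warn(
            f"{len(conflicted)} symbol(s) assigned to multiple cell types; "
            "reassigned to 'none'",
            stacklevel=3,
        )
    return MarkerReference(seen, provenance=provenance, n_conflicts=len(conflicted))


def read_marker_reference(path: str | Path, provenance: str | None = None) -> MarkerReference:
    """Read a marker reference from a two-column table or a GMT file.

    In GMT form each set name must be a cell-type label and its members
    the marker symbols.  Symbols claimed by more than one cell type are
    demoted to ``none`` (conflict count kept on the returned object);
    the demotion is independent of input row order.
    """
    path = Path(path)
    provenance = provenance if provenance is not None else path.name
    pairs: list[tuple[str, str]] = []
    if path.suffix.lower() == ".gmt":
        for record in _iter_gmt(path):
            term, _, members = record
            for symbol in members:
                pairs.append((symbol, term))
    else:
        sep = _infer_sep(path, None)
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
        df.columns = [c.strip().lower() for c in df.columns]
        if not {"symbol", "cell_type"} <= set(df.columns):
            # headerless two-column fallback
            df = pd.read_csv(
                path, sep=sep, comment="#", dtype=str, header=None,
                names=["symbol", "cell_type"],
            )
        pairs = [
            (str(s), str(c)) for s, c in zip(df["symbol"], df["cell_type"])
        ]
    return _marker_from_pairs(pairs, provenance)


def _iter_gmt(path: Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} field(s); "
                    "GMT requires term, description and at least one symbol"
                )
            term, description, *symbols = fields
            members = [s.strip().upper() for s in symbols if s.strip()]
            yield term.strip(), description.strip(), members


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file into a :class:`GeneSetCollection`.

    Symbols are uppercased; duplicates within a set collapse.  An empty
    file yields an empty collection.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for term, description, members in _iter_gmt(Path(path)):
        if term in sets:
            raise ValueError(f"{path}: duplicate term {term!r}")
        sets[term] = (description, frozenset(members))
    return GeneSetCollection(sets)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    """Write a stage-output DataFrame as TSV with ``# key=value`` header comments."""
    from . import __version__

    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# coresort={__version__}\n")
    for key, value in (params or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(buf.getvalue())
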