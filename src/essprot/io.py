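"""Readers and writers for the four input kinds and the derived artifacts.

All inputs are plain tab-separated text:

* PPI network: two-column edge list (BioGRID-style exports; extra columns
  ignored, ``#`` comments allowed).
* Gene expression: one header row of time-point labels, one row per protein.
* Subcellular localization: ``protein<TAB>term`` pairs (COMPARTMENTS-style).
* Essential-protein labels: one protein ID per line (DEG/OGEE-style).

Protein identity is exact string equality; the canonical node order used for
every matrix and tie-break in the package is lexicographic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StaticPPINetwork",
    "ExpressionMatrix",
    "LocalizationTable",
    "LabelSet",
    "AlignedDataset",
    "ParseError",
    "read_ppi_edge_list",
    "read_expression_matrix",
    "read_localization_table",
    "read_label_list",
    "align_dataset",
    "write_ppi_edge_list",
    "write_expression_matrix",
    "write_localization_table",
    "write_label_list",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_predictions",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the unordered pair (u, v) in its canonical (sorted) form."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class StaticPPINetwork:
    """Undirected simple graph of protein IDs (no self-loops, no duplicates)."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if u > v:
                raise ValueError(f"edge ({u!r}, {v!r}) not in canonical order")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u!r}, {v!r}) has endpoint outside node set")

    @property
    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Proteins x time-points matrix of nonnegative expression levels."""

    proteins: tuple[str, ...]
    timepoints: tuple[str, ...]
    values: np.ndarray  # shape (len(proteins), len(timepoints))

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.proteins), len(self.timepoints)):
            raise ValueError("expression matrix shape mismatch")
        object.__setattr__(self, "values", vals)

    def row(self, protein: str) -> np.ndarray:
        return self.values[self.proteins.index(protein)]

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)


@dataclass(frozen=True)
class LocalizationTable:
    """Unique (protein, localization term) annotation pairs."""

    records: frozenset[tuple[str, str]]

    def terms_of(self, protein: str) -> set[str]:
        return {t for p, t in self.records if p == protein}


@dataclass(frozen=True)
class LabelSet:
    """The set of proteins experimentally known to be essential."""

    essential: frozenset[str]


@dataclass(frozen=True)
class AlignedDataset:
    """The four inputs restricted to one node universe (the PPI network).

    ``labels`` is a binary vector over ``network.sorted_nodes``.
    """

    network: StaticPPINetwork
    expression: ExpressionMatrix
    localization: LocalizationTable
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        if lab.shape != (len(self.network.nodes),):
            raise ValueError("label vector length must equal node count")
        if not np.isin(lab, [0, 1]).all():
            raise ValueError("labels must be binary")
        object.__setattr__(self, "labels", lab)

    @property
    def nodes(self) -> list[str]:
        return self.network.sorted_nodes


def _lines(source: IO[str] | Iterable[str]) -> Iterable[tuple[int, str]]:
    for i, raw in enumerate(source, start=1):
        yield i, raw.rstrip("\n")


def read_ppi_edge_list(source: IO[str] | Iterable[str], comment_prefix: str = "#") -> StaticPPINetwork:
    """Parse a two-column edge list into a simple undirected graph.

    Self-loops are dropped; ``(a, b)`` and ``(b, a)`` collapse to one edge;
    columns beyond the first two are ignored. An empty edge set is an error.
    """
    edges: set[tuple[str, str]] = set()
    n_loops = 0
    n_dups = 0
    for lineno, line in _lines(source):
        if not line.strip() or (comment_prefix and line.startswith(comment_prefix)):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected at least 2 fields, got {line!r}")
        u, v = fields[0], fields[1]
        if u == v:
            n_loops += 1
            continue
        e = canonical_edge(u, v)
        if e in edges:
            n_dups += 1
        edges.add(e)
    if not edges:
        raise ParseError("edge list contains no usable edges")
    if n_loops or n_dups:
        logger.info("dropped %d self-loops and %d duplicate edges", n_loops, n_dups)
    nodes = frozenset(x for e in edges for x in e)
    return StaticPPINetwork(nodes=nodes, edges=frozenset(edges))


def read_expression_matrix(source: IO[str] | Iterable[str]) -> ExpressionMatrix:
    """Parse a TSV with one header row of time labels and one row per protein."""
    it = _lines(source)
    try:
        _, header = next(it)
    except StopIteration:
        raise ParseError("expression file is empty") from None
    timepoints = tuple(header.split("\t") if "\t" in header else header.split())
    if not timepoints:
        raise ParseError("expression header has no timepoint labels")
    proteins: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in it:
        if not line.strip():
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != len(timepoints) + 1:
            raise ParseError(
                f"line {lineno}: expected {len(timepoints) + 1} fields, got {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise ParseError(f"line {lineno}: duplicate protein row {pid!r}")
        seen.add(pid)
        try:
            vals = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric expression value") from exc
        if not all(np.isfinite(vals)):
            raise ParseError(f"line {lineno}: non-finite expression value")
        proteins.append(pid)
        rows.append(vals)
    return ExpressionMatrix(
        proteins=tuple(proteins),
        timepoints=timepoints,
        values=np.asarray(rows, dtype=float).reshape(len(proteins), len(timepoints)),
    )


def read_localization_table(source: IO[str] | Iterable[str]) -> LocalizationTable:
    """Parse protein -> localization-term pairs; duplicate pairs collapse."""
    records: set[tuple[str, str]] = set()
    for lineno, line in _lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected 2 columns, got {line!r}")
        records.add((fields[0], fields[1].strip()))
    if not records:
        warnings.warn("localization table is empty", stacklevel=2)
    return LocalizationTable(records=frozenset(records))


def read_label_list(source: IO[str] | Iterable[str]) -> LabelSet:
    """Parse a one-ID-per-line essential-protein list; blank lines ignored."""
    ids = {line.strip() for _, line in _lines(source) if line.strip()}
    if not ids:
        warnings.warn("label list is empty", stacklevel=2)
    return LabelSet(essential=frozenset(ids))


def align_dataset(
    network: StaticPPINetwork,
    expression: ExpressionMatrix,
    localization: LocalizationTable,
    labels: LabelSet,
) -> AlignedDataset:
    """Restrict all inputs to the PPI node universe.

    Expression rows, localization records and labels for IDs not in the
    network are dropped (with a logged count). Nodes without expression rows
    are retained — the dynamic-network stage treats them as always active.
    """
    nodes = set(network.nodes)
    order = network.sorted_nodes

    keep = [i for i, p in enumerate(expression.proteins) if p in nodes]
    n_expr_dropped = len(expression.proteins) - len(keep)
    expr = ExpressionMatrix(
        proteins=tuple(expression.proteins[i] for i in keep),
        timepoints=expression.timepoints,
        values=expression.values[keep] if keep else np.empty((0, expression.n_timepoints)),
    )

    loc_records = frozenset(r for r in localization.records if r[0] in nodes)
    n_loc_dropped = len(localization.records) - len(loc_records)

    essential = labels.essential & nodes
    n_lab_dropped = len(labels.essential) - len(essential)
    if n_expr_dropped or n_loc_dropped or n_lab_dropped:
        logger.info(
            "alignment dropped %d expression rows, %d localization records, %d labels",
            n_expr_dropped,
            n_loc_dropped,
            n_lab_dropped,
        )
    if not essential:
        raise ValueError("no positive labels remain after alignment to the network")
    y = np.array([1 if p in essential else 0 for p in order], dtype=int)
    return AlignedDataset(
        network=network,
        expression=expr,
        localization=LocalizationTable(records=loc_records),
        labels=y,
    )


# ---------------------------------------------------------------------------
# writers (and the readers needed to round-trip pipeline artifacts)

def write_ppi_edge_list(network: StaticPPINetwork, sink: IO[str]) -> None:
    for u, v in sorted(network.edges):
        sink.write(f"{u}\t{v}\n")


def write_expression_matrix(expr: ExpressionMatrix, sink: IO[str]) -> None:
    sink.write("\t".join(expr.timepoints) + "\n")
    for pid, row in zip(expr.proteins, expr.values):
        sink.write(pid + "\t" + "\t".join(format(x, ".10g") for x in row) + "\n")


def write_localization_table(table: LocalizationTable, sink: IO[str]) -> None:
    for p, t in sorted(table.records):
        sink.write(f"{p}\t{t}\n")


def write_label_list(labels: LabelSet, sink: IO[str]) -> None:
    for p in sorted(labels.essential):
        sink.write(p + "\n")


def write_feature_matrix(
    proteins: Sequence[str], columns: Sequence[str], values: np.ndarray, sink: IO[str]
) -> None:
    """Write a feature matrix as TSV with a header row, proteins as rows."""
    values = np.asarray(values)
    if values.shape != (len(proteins), len(columns)):
        raise ValueError("feature matrix shape mismatch")
    sink.write("protein\t" + "\t".join(columns) + "\n")
    for pid, row in zip(proteins, values):
        sink.write(pid + "\t" + "\t".join(format(x, ".10g") for x in row) + "\n")


def read_feature_matrix(source: IO[str]) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(source, sep="\t", header=0, dtype={0: str})
    proteins = df.iloc[:, 0].tolist()
    columns = df.columns[1:].tolist()
    return proteins, columns, df.iloc[:, 1:].to_numpy(dtype=float)


def write_predictions(
    proteins: Sequence[str], scores: np.ndarray, labels: np.ndarray, sink: IO[str]
) -> None:
    sink.write("protein\tscore\tlabel\n")
    for pid, s, l in zip(proteins, scores, labels):
        sink.write(f"{pid}\t{s:.6f}\t{int(l)}\n")
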