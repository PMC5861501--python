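"""Core containers and plain-text I/O for time-course network inference.

The central object is :class:`TimeCourseDataset`: an ordered gene list plus
one expression block per experimental replicate, each block a ``T_r x P``
matrix of time points by genes.  Replicate boundaries matter downstream —
a time-lagged regression pair must never span two replicates — so the
loaders keep blocks separate instead of flattening them.

File dialects (all tab- or comma-separated text):

* expression tables — header row of gene names, one row per time point
  (``rows_are_timepoints``), replicates separated by blank lines or given
  as an explicit block-size list; or the transposed layout
  (``rows_are_genes``) with one row per gene and one column per time point.
* gold standards — DREAM-challenge style ``regulator<TAB>target[<TAB>label]``
  with label in {0,1}; a missing label column means every listed edge is a
  positive.
* ranked edge lists — ``regulator<TAB>target<TAB>score`` sorted by
  descending score; scores are printed with 17 significant digits so a
  write/read round trip is bit-faithful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none"}


class DataFormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class TimeCourseDataset:
    """Gene names plus per-replicate time-point x gene expression blocks.

    Parameters
    ----------
    gene_names
        Ordered list of ``P`` unique gene identifiers.
    replicates
        List of ``n`` arrays, each of shape ``(T_r, P)`` with ``T_r >= 2``.
        Column order matches ``gene_names`` in every block.
    time_labels
        Optional per-replicate time stamps (one sequence per replicate).
    """

    gene_names: list[str]
    replicates: list[np.ndarray]
    time_labels: list[Sequence[float]] | None = None

    def __post_init__(self) -> None:
        self.gene_names = [str(g) for g in self.gene_names]
        if len(set(self.gene_names)) != len(self.gene_names):
            dupes = sorted({g for g in self.gene_names if self.gene_names.count(g) > 1})
            raise DataFormatError(f"duplicate gene names: {dupes}")
        if not self.replicates:
            raise DataFormatError("dataset has no replicate blocks")
        p = len(self.gene_names)
        blocks = []
        for r, block in enumerate(self.replicates):
            arr = np.asarray(block, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != p:
                raise DataFormatError(
                    f"replicate {r}: expected shape (T_r, {p}), got {arr.shape}"
                )
            if arr.shape[0] < 2:
                raise DataFormatError(
                    f"replicate {r} has {arr.shape[0]} time point(s); need at least 2"
                )
            if not np.all(np.isfinite(arr)):
                t, g = np.argwhere(~np.isfinite(arr))[0]
                raise DataFormatError(
                    f"non-finite value in replicate {r}, time point {t}, "
                    f"gene {self.gene_names[g]}"
                )
            blocks.append(arr)
        self.replicates = blocks
        if self.time_labels is not None and len(self.time_labels) != len(blocks):
            raise DataFormatError("time_labels must have one entry per replicate")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_lagged_pairs(self) -> int:
        """Total number of (t, t+1) sample pairs across replicates."""
        return sum(block.shape[0] - 1 for block in self.replicates)

    def pooled(self) -> np.ndarray:
        """All replicate blocks stacked row-wise into one matrix."""
        return np.vstack(self.replicates)


@dataclass
class EdgeSet:
    """Directed edges as ordered (regulator_index, target_index) pairs.

    ``negatives`` is ``None`` when the source listed only positives (the
    DREAM convention: every unlisted ordered pair is then a negative), and
    an explicit set when the gold standard carried 0-labelled rows.
    """

    positives: set[tuple[int, int]]
    negatives: set[tuple[int, int]] | None = None
    n_genes: int | None = None

    def __post_init__(self) -> None:
        self.positives = {(int(i), int(j)) for i, j in self.positives}
        if any(i == j for i, j in self.positives):
            raise DataFormatError("self-edges are not allowed in an edge set")
        if self.negatives is not None:
            self.negatives = {(int(i), int(j)) for i, j in self.negatives}
            if any(i == j for i, j in self.negatives):
                raise DataFormatError("self-edges are not allowed in an edge set")
            overlap = self.positives & self.negatives
            if overlap:
                raise DataFormatError(f"edges labelled both 0 and 1: {sorted(overlap)}")
        if self.n_genes is not None:
            all_edges = self.positives | (self.negatives or set())
            for i, j in all_edges:
                if not (0 <= i < self.n_genes and 0 <= j < self.n_genes):
                    raise DataFormatError(
                        f"edge ({i}, {j}) out of range for {self.n_genes} genes"
                    )


@dataclass
class WeightedAdjacency:
    """P x P matrix of regulatory interaction scores.

    ``scores[i, j]`` quantifies the evidence that gene ``i`` regulates gene
    ``j``.  The diagonal is structurally zero — self-regulation is never
    scored — and every entry is finite and non-negative.
    """

    scores: np.ndarray
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.gene_names = [str(g) for g in self.gene_names]
        p = len(self.gene_names)
        if self.scores.shape != (p, p):
            raise DataFormatError(
                f"score matrix shape {self.scores.shape} does not match {p} genes"
            )
        if not np.all(np.isfinite(self.scores)):
            raise DataFormatError("score matrix contains non-finite values")
        if np.any(self.scores < 0):
            raise DataFormatError("score matrix contains negative values")
        if np.any(np.diagonal(self.scores) != 0):
            raise DataFormatError("diagonal of the score matrix must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def ranked_edges(self) -> list[tuple[int, int, float]]:
        """Off-diagonal entries sorted by descending score.

        Ties are broken by (regulator index, target index) ascending so the
        ordering is reproducible.
        """
        p = self.n_genes
        edges = [
            (i, j, float(self.scores[i, j]))
            for i in range(p)
            for j in range(p)
            if i != j
        ]
        edges.sort(key=lambda e: (-e[2], e[0], e[1]))
        return edges


# ---------------------------------------------------------------------------
# readers / writers


def _detect_sep(line: str) -> str:
    return "\t" if "\t" in line else ","


def _parse_cell(token: str, row_desc: str, col_desc: str) -> float:
    token = token.strip()
    if token.lower() in _NA_TOKENS:
        raise DataFormatError(f"missing value at {row_desc}, {col_desc}")
    try:
        value = float(token)
    except ValueError as exc:
        raise DataFormatError(
            f"cannot parse value {token!r} at {row_desc}, {col_desc}"
        ) from exc
    if not math.isfinite(value):
        raise DataFormatError(f"non-finite value at {row_desc}, {col_desc}")
    return value


def read_expression_table(
    path: str | Path,
    layout: str = "rows_are_timepoints",
    replicate_sizes: Sequence[int] | None = None,
    sep: str | None = None,
) -> TimeCourseDataset:
    """Load a TSV/CSV expression table into a :class:`TimeCourseDataset`.

    Parameters
    ----------
    layout
        ``rows_are_timepoints`` — header row of gene names, one data row per
        time point; blank lines separate replicate blocks.
        ``rows_are_genes`` — header row of time labels, first column gene
        names, one row per gene.
    replicate_sizes
        Explicit block sizes along the time axis.  Mutually exclusive with
        blank-line separation.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not any(line.strip() for line in lines):
        raise DataFormatError(f"{path}: empty file")
    first = next(line for line in lines if line.strip())
    if sep is None:
        sep = _detect_sep(first)

    if layout == "rows_are_timepoints":
        gene_names, blocks = _parse_timepoint_rows(lines, sep)
    elif layout == "rows_are_genes":
        gene_names, blocks = _parse_gene_rows(lines, sep)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if replicate_sizes is not None:
        if len(blocks) != 1:
            raise DataFormatError(
                "replicate_sizes cannot be combined with blank-line separated blocks"
            )
        total = blocks[0].shape[0]
        sizes = [int(s) for s in replicate_sizes]
        if sum(sizes) != total:
            raise DataFormatError(
                f"replicate sizes {sizes} do not sum to {total} time points"
            )
        bounds = np.cumsum([0] + sizes)
        blocks = [blocks[0][a:b] for a, b in zip(bounds[:-1], bounds[1:])]

    return TimeCourseDataset(gene_names=gene_names, replicates=blocks)


def _parse_timepoint_rows(
    lines: list[str], sep: str
) -> tuple[list[str], list[np.ndarray]]:
    header_idx = next(i for i, line in enumerate(lines) if line.strip())
    gene_names = [c.strip() for c in lines[header_idx].split(sep)]
    if len(set(gene_names)) != len(gene_names):
        raise DataFormatError("duplicate gene names in header")
    p = len(gene_names)

    blocks: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        cells = line.split(sep)
        if len(cells) != p:
            raise DataFormatError(
                f"line {lineno}: expected {p} columns, found {len(cells)}"
            )
        current.append(
            [
                _parse_cell(tok, f"line {lineno}", f"gene {gene_names[k]}")
                for k, tok in enumerate(cells)
            ]
        )
    if current:
        blocks.append(current)
    if not blocks:
        raise DataFormatError("no data rows found")
    return gene_names, [np.asarray(b, dtype=float) for b in blocks]


def _parse_gene_rows(lines: list[str], sep: str) -> tuple[list[str], list[np.ndarray]]:
    body = [line for line in lines if line.strip()]
    if len(body) != sum(1 for line in lines if line.strip()):  # pragma: no cover
        pass
    header = body[0].split(sep)
    n_time = len(header) - 1
    if n_time < 2:
        raise DataFormatError("rows_are_genes layout needs at least 2 time columns")
    gene_names: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(body[1:], start=2):
        cells = line.split(sep)
        if len(cells) != n_time + 1:
            raise DataFormatError(
                f"line {lineno}: expected {n_time + 1} columns, found {len(cells)}"
            )
        name = cells[0].strip()
        gene_names.append(name)
        rows.append(
            [
                _parse_cell(tok, f"gene {name}", f"time column {k + 1}")
                for k, tok in enumerate(cells[1:])
            ]
        )
    if len(set(gene_names)) != len(gene_names):
        raise DataFormatError("duplicate gene names in first column")
    matrix = np.asarray(rows, dtype=float).T  # -> time points x genes
    return gene_names, [matrix]


def write_expression_table(
    dataset: TimeCourseDataset,
    path: str | Path,
    layout: str = "rows_are_timepoints",
    sep: str = "\t",
) -> None:
    """Write a dataset in a dialect :func:`read_expression_table` accepts.

    ``rows_are_timepoints`` separates replicates with blank lines;
    ``rows_are_genes`` requires a single replicate.
    """
    path = Path(path)
    lines: list[str] = []
    if layout == "rows_are_timepoints":
        lines.append(sep.join(dataset.gene_names))
        for r, block in enumerate(dataset.replicates):
            if r > 0:
                lines.append("")
            for row in block:
                lines.append(sep.join(f"{v:.17g}" for v in row))
    elif layout == "rows_are_genes":
        if dataset.n_replicates != 1:
            raise DataFormatError("rows_are_genes layout supports a single replicate")
        block = dataset.replicates[0]
        lines.append(sep.join(["gene"] + [f"t{t}" for t in range(block.shape[0])]))
        for g, name in enumerate(dataset.gene_names):
            lines.append(sep.join([name] + [f"{v:.17g}" for v in block[:, g]]))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    path.write_text("\n".join(lines) + "\n")


_GOLD_HEADER_TOKENS = {"regulator", "source", "tf", "from"}


def read_gold_standard(path: str | Path, gene_names: Sequence[str]) -> EdgeSet:
    """Load a DREAM-style 2- or 3-column gold-standard edge list.

    Rows are ``regulator<TAB>target[<TAB>label]`` with label in {0,1}.
    Without a label column every listed edge is a positive.  Self-edges are
    dropped with a logged warning; unknown gene names are an error.
    """
    path = Path(path)
    name_to_idx = {str(g): i for i, g in enumerate(gene_names)}
    positives: set[tuple[int, int]] = set()
    negatives: set[tuple[int, int]] = set()
    saw_label_column = False

    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        sep = _detect_sep(line)
        cells = [c.strip() for c in line.split(sep)]
        if lineno == 1 and cells[0].lower() in _GOLD_HEADER_TOKENS:
            continue
        if len(cells) not in (2, 3):
            raise DataFormatError(
                f"{path} line {lineno}: expected 2 or 3 columns, found {len(cells)}"
            )
        reg, tgt = cells[0], cells[1]
        for name in (reg, tgt):
            if name not in name_to_idx:
                raise DataFormatError(f"{path} line {lineno}: unknown gene {name!r}")
        i, j = name_to_idx[reg], name_to_idx[tgt]
        if len(cells) == 3:
            saw_label_column = True
            if cells[2] not in ("0", "1"):
                raise DataFormatError(
                    f"{path} line {lineno}: label must be 0 or 1, got {cells[2]!r}"
                )
            label = int(cells[2])
        else:
            label = 1
        if i == j:
            logger.warning("%s line %d: dropping self-edge %s -> %s", path, lineno, reg, tgt)
            continue
        (positives if label == 1 else negatives).add((i, j))

    return EdgeSet(
        positives=positives,
        negatives=negatives if saw_label_column else None,
        n_genes=len(gene_names),
    )


def write_gold_standard(
    edges: EdgeSet, gene_names: Sequence[str], path: str | Path
) -> None:
    """Write an edge set in the 3-column labelled gold-standard dialect."""
    path = Path(path)
    lines = ["regulator\ttarget\tlabel"]
    for i, j in sorted(edges.positives):
        lines.append(f"{gene_names[i]}\t{gene_names[j]}\t1")
    for i, j in sorted(edges.negatives or set()):
        lines.append(f"{gene_names[i]}\t{gene_names[j]}\t0")
    path.write_text("\n".join(lines) + "\n")


def write_ranked_edge_list(
    W: WeightedAdjacency, path: str | Path, max_edges: int | None = None
) -> None:
    """Write off-diagonal scores as ``regulator<TAB>target<TAB>score``.

    Rows are sorted by descending score with (regulator, target) index
    tie-breaks; scores carry 17 significant digits so re-reading them
    reproduces the matrix exactly.
    """
    path = Path(path)
    edges = W.ranked_edges()
    if max_edges is not None:
        edges = edges[: int(max_edges)]
    lines = [
        f"{W.gene_names[i]}\t{W.gene_names[j]}\t{score:.17g}" for i, j, score in edges
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_ranked_edge_list(
    path: str | Path, gene_names: Sequence[str]
) -> WeightedAdjacency:
    """Read a ranked edge list back into a :class:`WeightedAdjacency`.

    Pairs absent from the file get score 0.
    """
    path = Path(path)
    name_to_idx = {str(g): i for i, g in enumerate(gene_names)}
    p = len(gene_names)
    scores = np.zeros((p, p))
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 3:
            raise DataFormatError(
                f"{path} line {lineno}: expected 3 columns, found {len(cells)}"
            )
        reg, tgt, score = cells
        for name in (reg, tgt):
            if name not in name_to_idx:
                raise DataFormatError(f"{path} line {lineno}: unknown gene {name!r}")
        scores[name_to_idx[reg], name_to_idx[tgt]] = _parse_cell(
            score, f"line {lineno}", "score"
        )
    return WeightedAdjacency(scores=scores, gene_names=list(gene_names))
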