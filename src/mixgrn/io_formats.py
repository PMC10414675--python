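"""Reading/writing of DREAM5-dialect files and problem assembly.

File dialects (all plain TSV):

* expression table — header row of gene identifiers, one body row per
  sample/chip (samples x genes);
* regulator list — one TF identifier per line;
* gold standard — ``tf<TAB>target<TAB>{0,1}``;
* ranked predictions — ``tf<TAB>target<TAB>score``, descending, truncated
  to the top 100,000 edges by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: decimal places used when serializing edge scores
SCORE_DECIMALS = 6
#: default prediction-list truncation (DREAM5 convention)
DEFAULT_EDGE_LIMIT = 100_000


class FormatError(ValueError):
    """Malformed input file (ragged rows, bad cells, bad labels)."""


class ValidationError(ValueError):
    """Structurally valid file violating a dataset invariant."""


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with identifiers."""

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("expression matrix must be 2-D")
        if self.matrix.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]


@dataclass
class RegulatorSet:
    """Ordered TF identifiers resolved against an expression dataset."""

    tf_ids: list[str]
    column_index_map: dict[str, int]

    @property
    def p(self) -> int:
        return len(self.tf_ids)


@dataclass
class RegressionProblem:
    """Assembled multivariate regression: Y = XB + E.

    ``X`` holds the TF columns (n x p), ``Y`` the target-gene columns
    (n x s).  When the target set includes the TFs themselves (the default
    on the file-based path), ``tf_position_in_targets`` maps each TF to its
    column in ``Y`` — required by the precision-pruned master-regulator
    call.
    """

    X: np.ndarray
    Y: np.ndarray
    tf_ids: list[str]
    target_ids: list[str]
    tf_position_in_targets: dict[str, int] = field(default_factory=dict)
    standardized: bool = False

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def s(self) -> int:
        return self.Y.shape[1]


@dataclass
class GoldStandard:
    """Labeled TF -> target pairs defining the evaluation universe."""

    labels: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for pair, lab in self.labels.items():
            if lab not in (0, 1):
                raise ValidationError(f"label for {pair} not in {{0,1}}: {lab}")
        loops = [p for p in self.labels if p[0] == p[1]]
        if loops:
            logger.warning("gold standard contains %d self-loop pairs", len(loops))
        self.self_loops = set(loops)

    @property
    def universe(self) -> set[tuple[str, str]]:
        return set(self.labels)

    @property
    def positives(self) -> set[tuple[str, str]]:
        return {p for p, lab in self.labels.items() if lab == 1}

    @property
    def n_positives(self) -> int:
        return sum(self.labels.values())


def read_expression_table(path, transpose: bool = False) -> ExpressionDataset:
    """Load a DREAM5-style expression TSV (header = gene ids, rows = samples).

    ``transpose=True`` accepts genes-as-rows dumps (first column then holds
    gene ids and the header holds sample ids).
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header and at least one data row")
    header = lines[0].split("\t")
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if transpose:
            if len(cells) != len(header) + 1 and len(cells) != len(header):
                raise FormatError(f"{path}:{lineno}: ragged row ({len(cells)} cells)")
        elif len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, "
                f"expected {len(header)})"
            )
        rows.append(cells)
    if transpose:
        gene_ids = [r[0] for r in rows]
        body = [r[1:] for r in rows]
        sample_ids = header if len(header) == len(body[0]) else header[1:]
        values = _parse_body(body, path)
        return ExpressionDataset(values.T, gene_ids, list(sample_ids))
    values = _parse_body(rows, path)
    sample_ids = [f"S{i + 1}" for i in range(values.shape[0])]
    return ExpressionDataset(values, list(header), sample_ids)


def _parse_body(rows: list[list[str]], path) -> np.ndarray:
    try:
        values = np.array([[float(c) for c in r] for r in rows], dtype=float)
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric cell: {e}") from e
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite value in expression body")
    return values


def write_expression_table(dataset: ExpressionDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(dataset.gene_ids) + "\n")
        for row in dataset.matrix:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_regulator_list(path, dataset: ExpressionDataset) -> RegulatorSet:
    """Load TF identifiers and resolve them against ``dataset`` columns."""
    path = Path(path)
    tf_ids = [ln.strip() for ln in path.open() if ln.strip()]
    if not tf_ids:
        raise ValidationError(f"{path}: empty regulator list")
    if len(set(tf_ids)) != len(tf_ids):
        raise ValidationError(f"{path}: duplicate TF identifiers")
    index = {g: i for i, g in enumerate(dataset.gene_ids)}
    missing = [t for t in tf_ids if t not in index]
    if missing:
        raise ValidationError(
            f"{path}: {len(missing)} TFs absent from expression data: "
            f"{missing[:10]}"
        )
    return RegulatorSet(tf_ids, {t: index[t] for t in tf_ids})


def read_gold_standard(path) -> GoldStandard:
    """Load a 3-column gold standard TSV (tf, target, 0/1 label)."""
    path = Path(path)
    labels: dict[tuple[str, str], int] = {}
    for lineno, ln in enumerate(path.open(), start=1):
        if not ln.strip():
            continue
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        tf, tg, lab_str = cells
        try:
            lab = int(lab_str)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: bad label {lab_str!r}") from e
        if lab not in (0, 1):
            raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {lab}")
        if (tf, tg) in labels:
            if labels[(tf, tg)] != lab:
                raise ValidationError(
                    f"{path}:{lineno}: pair ({tf}, {tg}) listed with "
                    "conflicting labels"
                )
            continue
        labels[(tf, tg)] = lab
    if not labels:
        raise ValidationError(f"{path}: empty gold standard")
    gs = GoldStandard(labels)
    logger.info("gold standard: %d pairs, %d positives", len(labels), gs.n_positives)
    return gs


def center_and_scale(
    dataset: ExpressionDataset, on_constant: str = "drop"
) -> ExpressionDataset:
    """Standardize every gene column to mean 0 and sample sd 1 (n-1).

    Constant columns have undefined scale; they are dropped with a warning
    by default, or rejected with ``on_constant="error"``.
    """
    M = dataset.matrix
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1) if dataset.n > 1 else np.zeros(dataset.n_genes)
    constant = sd <= 0
    if constant.any():
        names = [g for g, c in zip(dataset.gene_ids, constant) if c]
        if on_constant == "error":
            raise ValidationError(f"constant gene columns: {names[:10]}")
        warnings.warn(
            f"dropping {len(names)} constant gene column(s): {names[:5]}",
            stacklevel=2,
        )
        keep = ~constant
        M, mean, sd = M[:, keep], mean[keep], sd[keep]
        gene_ids = [g for g, k in zip(dataset.gene_ids, keep) if k]
    else:
        gene_ids = list(dataset.gene_ids)
    Z = (M - mean) / sd
    return ExpressionDataset(Z, gene_ids, list(dataset.sample_ids), standardized=True)


def build_problem(dataset: ExpressionDataset, tfs: RegulatorSet) -> RegressionProblem:
    """Assemble X (TF columns) and Y (all gene columns, TFs included)."""
    cols = [tfs.column_index_map[t] for t in tfs.tf_ids]
    X = dataset.matrix[:, cols].copy()
    Y = dataset.matrix.copy()
    tf_pos = {t: dataset.gene_ids.index(t) for t in tfs.tf_ids}
    return RegressionProblem(
        X=X,
        Y=Y,
        tf_ids=list(tfs.tf_ids),
        target_ids=list(dataset.gene_ids),
        tf_position_in_targets=tf_pos,
        standardized=dataset.standardized,
    )


def write_ranked_edges(edges, path, limit: int = DEFAULT_EDGE_LIMIT) -> None:
    """Write the top ``limit`` ranked edges as a DREAM5 prediction TSV."""
    records = edges.records
    scores = [r[2] for r in records]
    if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
        raise RuntimeError("ranked edge list must be sorted by descending score")
    path = Path(path)
    with path.open("w") as fh:
        for tf, tg, score in records[:limit]:
            fh.write(f"{tf}\t{tg}\t{score:.{SCORE_DECIMALS}f}\n")


def read_ranked_edges(path):
    """Read a prediction TSV back into a RankedEdgeList."""
    from .network import RankedEdgeList

    path = Path(path)
    records = []
    for lineno, ln in enumerate(path.open(), start=1):
        if not ln.strip():
            continue
        cells = ln.rstrip("\n").split("\t")
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            records.append((cells[0], cells[1], float(cells[2])))
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: bad score {cells[2]!r}") from e
    return RankedEdgeList(records)
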