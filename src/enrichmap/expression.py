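"""Expression-matrix I/O, gene scoring, and heat-map data extraction.

The enrichment map sits downstream of a gene-scoring step: genes are
ranked by differential expression between two sample classes and the
ranking is fed to an enrichment method.  This module provides the two
scoring statistics commonly used for that step — the two-sample t
statistic (Welch form) and the ratio of class means — plus extraction
of the expression submatrix underlying any gene-set, the data behind
the heat-map view.

Formats are the GSEA companions: GCT for matrices (two-line preamble,
then Name/Description plus one column per sample), CLS for two-class
sample labels, RNK for ranked gene scores.  Plain headered TSV is
accepted as a fallback for both the matrix and the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .genesets import GeneSet

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_cls",
    "write_gct",
    "write_cls",
    "write_rnk",
    "score_genes_ttest",
    "score_genes_ratio",
    "heatmap_data",
    "HeatmapData",
]

VAR_FLOOR = 1e-8  # keeps t finite for (near-)constant genes


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix with optional two-class sample labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    classes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in expression matrix")
        if self.classes is not None:
            missing = [s for s in self.sample_ids if s not in self.classes]
            if missing:
                raise ValueError(f"samples without class label: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def class_columns(self, label: str) -> list[int]:
        if self.classes is None:
            raise ValueError("expression matrix has no class labels")
        return [i for i, s in enumerate(self.sample_ids) if self.classes[s] == label]

    def class_labels(self) -> list[str]:
        """Distinct labels in order of first appearance along the samples."""
        if self.classes is None:
            return []
        seen: list[str] = []
        for s in self.sample_ids:
            lab = self.classes[s]
            if lab not in seen:
                seen.append(lab)
        return seen


def _read_gct(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    with path.open("r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if not version.startswith("#1."):
            raise ValueError(f"{path}: not a GCT file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ValueError(f"{path}: malformed GCT dimension line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    sample_ids = [str(c) for c in df.columns[2:]]
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    if values.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: GCT preamble declares {n_genes}x{n_samples} but body "
            f"is {values.shape[0]}x{values.shape[1]}"
        )
    return gene_ids, sample_ids, values


def _read_matrix_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return (
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        df.to_numpy(dtype=float),
    )


def read_cls(path: str | PathLike[str], sample_ids: list[str]) -> dict[str, str]:
    """Parse a CLS file into a sample -> class-label mapping.

    CLS layout: line 1 ``<n_samples> <n_classes> 1``; line 2
    ``# label1 label2``; line 3 one label (or class index) per sample,
    in matrix column order.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text(encoding="utf-8").splitlines()
             if ln.strip()]
    if len(lines) < 3:
        raise ValueError(f"{path}: CLS file needs 3 non-empty lines")
    header = lines[0].split()
    n_samples = int(header[0])
    if n_samples != len(sample_ids):
        raise ValueError(
            f"{path}: CLS declares {n_samples} samples but matrix has "
            f"{len(sample_ids)}"
        )
    names = lines[1].lstrip("#").split()
    assignments = lines[2].split()
    if len(assignments) != n_samples:
        raise ValueError(
            f"{path}: CLS assignment line has {len(assignments)} entries, "
            f"expected {n_samples}"
        )
    classes = {}
    for sid, token in zip(sample_ids, assignments):
        if token in names:
            classes[sid] = token
        else:
            # numeric class indices referring to the declared names
            classes[sid] = names[int(token)]
    return classes


def _read_classes_tsv(path: Path, sample_ids: list[str]) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: class TSV must have exactly 2 columns")
    classes = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in sample_ids if s not in classes]
    if missing:
        raise ValueError(f"{path}: no class label for sample(s) {missing}")
    return {s: classes[s] for s in sample_ids}


def read_expression(
    matrix_path: str | PathLike[str],
    class_path: str | PathLike[str] | None = None,
) -> ExpressionMatrix:
    """Read a GCT or headered-TSV matrix, optionally with CLS/TSV labels.

    GCT is detected by its ``#1.x`` first line; anything else is parsed
    as a TSV whose first column holds gene ids and remaining columns
    hold samples.  ``class_path`` may be a CLS file or a two-column
    (sample, label) TSV.
    """
    matrix_path = Path(matrix_path)
    first = matrix_path.open("r", encoding="utf-8").readline()
    if first.startswith("#1."):
        gene_ids, sample_ids, values = _read_gct(matrix_path)
    else:
        gene_ids, sample_ids, values = _read_matrix_tsv(matrix_path)

    classes = None
    if class_path is not None:
        class_path = Path(class_path)
        head = class_path.open("r", encoding="utf-8").readline().split()
        looks_cls = len(head) == 3 and all(t.isdigit() for t in head)
        if looks_cls:
            classes = read_cls(class_path, sample_ids)
        else:
            classes = _read_classes_tsv(class_path, sample_ids)
    return ExpressionMatrix(gene_ids, sample_ids, values, classes)


def write_gct(expr: ExpressionMatrix, path: str | PathLike[str]) -> None:
    """Write the matrix as GCT (descriptions left empty)."""
    df = pd.DataFrame(expr.values, columns=expr.sample_ids)
    df.insert(0, "Description", "na")
    df.insert(0, "NAME", expr.gene_ids)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#1.2\n")
        fh.write(f"{len(expr.gene_ids)}\t{len(expr.sample_ids)}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_cls(expr: ExpressionMatrix, path: str | PathLike[str]) -> None:
    """Write the sample class labels as CLS."""
    if expr.classes is None:
        raise ValueError("expression matrix has no class labels to write")
    labels = expr.class_labels()
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(expr.sample_ids)} {len(labels)} 1\n")
        fh.write("# " + " ".join(labels) + "\n")
        fh.write(" ".join(expr.classes[s] for s in expr.sample_ids) + "\n")


def write_rnk(ranking: pd.DataFrame, path: str | PathLike[str]) -> None:
    """Write a ranked gene list as RNK (``gene<TAB>score``, no header)."""
    ranking[["gene", "score"]].to_csv(path, sep="\t", index=False, header=False)


def _class_matrices(
    expr: ExpressionMatrix, class_case: str, class_control: str
) -> tuple[np.ndarray, np.ndarray]:
    case_cols = expr.class_columns(class_case)
    control_cols = expr.class_columns(class_control)
    if not case_cols or not control_cols:
        raise ValueError(
            f"classes {class_case!r}/{class_control!r} not found among samples"
        )
    return expr.values[:, case_cols], expr.values[:, control_cols]


def _ranked(expr: ExpressionMatrix, scores: np.ndarray, keep: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"gene": expr.gene_ids, "score": scores})[keep]
    # stable sort; ties broken by gene id ascending for determinism
    df = df.sort_values("gene", kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )
    return df.reset_index(drop=True)


def score_genes_ttest(
    expr: ExpressionMatrix,
    class_case: str,
    class_control: str,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample t statistic, case vs control, ranked descending.

    The Welch (unequal-variance) form is the default; ``pooled=True``
    switches to the pooled-variance Student form.  Per-class variances
    are floored at ``VAR_FLOOR`` so constant genes yield finite
    statistics.  Positive scores mean higher expression in the case
    class.  Requires at least two samples per class.
    """
    case, control = _class_matrices(expr, class_case, class_control)
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"t statistic needs >= 2 samples per class, got {n1} and {n2}"
        )
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = np.maximum(case.var(axis=1, ddof=1), VAR_FLOOR)
    v2 = np.maximum(control.var(axis=1, ddof=1), VAR_FLOOR)
    if pooled:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
    t = (m1 - m2) / se
    return _ranked(expr, t, np.ones(len(t), dtype=bool))


def score_genes_ratio(
    expr: ExpressionMatrix,
    class_case: str,
    class_control: str,
) -> pd.DataFrame:
    """Per-gene ratio of class means, case / control, ranked descending.

    Values are used on the scale given (for log2 signals the ratio of
    log means, matching the plain reading of "ratio of class means").
    Genes with a zero control mean have no defined ratio; they are
    excluded with a warning.
    """
    case, control = _class_matrices(expr, class_case, class_control)
    if case.shape[1] < 1 or control.shape[1] < 1:
        raise ValueError("ratio of class means needs >= 1 sample per class")
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    keep = m2 != 0.0
    if not keep.all():
        bad = [g for g, ok in zip(expr.gene_ids, keep) if not ok]
        warnings.warn(
            f"{len(bad)} gene(s) with zero control mean excluded from the "
            f"ratio ranking: {bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(keep, m1 / np.where(keep, m2, 1.0), np.nan)
    return _ranked(expr, ratio, keep)


@dataclass
class HeatmapData:
    """The expression submatrix underlying one gene-set.

    ``frame`` holds genes (rows, ordered by descending t statistic when
    two-class labels allow scoring, otherwise matrix order) by samples
    (columns grouped by class, input order within a class).
    ``missing`` lists set genes absent from the matrix.
    """

    set_id: str
    frame: pd.DataFrame
    missing: list[str]
    normalization: str

    def to_tsv(self, path: str | PathLike[str]) -> None:
        self.frame.to_csv(path, sep="\t", index_label="gene")


def heatmap_data(
    gene_set: GeneSet,
    expr: ExpressionMatrix,
    normalization: str = "none",
) -> HeatmapData:
    """Extract and normalise the submatrix for one gene-set.

    Rows are the set's genes present in the matrix (absent genes are
    reported, never fabricated).  Normalisation modes: ``none``,
    ``row_zscore`` (per-row mean 0 / variance 1; constant rows become
    all-zero) and ``log2``.
    """
    if normalization not in ("none", "row_zscore", "log2"):
        raise ValueError(f"unknown normalization {normalization!r}")
    index = {g: i for i, g in enumerate(expr.gene_ids)}
    present = [g for g in expr.gene_ids if g in gene_set.genes]
    missing = sorted(gene_set.genes - set(present))
    if not present:
        raise ValueError(
            f"no gene of set {gene_set.set_id!r} is present in the matrix"
        )

    # row order: descending t when a two-class scoring is possible
    labels = expr.class_labels()
    order = present
    col_order = list(expr.sample_ids)
    if len(labels) == 2:
        case, control = labels
        try:
            ranking = score_genes_ttest(expr, case, control)
            rank_pos = {g: i for i, g in enumerate(ranking["gene"])}
            order = sorted(present, key=lambda g: rank_pos[g])
        except ValueError:
            pass  # fewer than 2 samples in a class: keep matrix order
        col_order = [s for lab in labels for s in expr.sample_ids
                     if expr.classes[s] == lab]

    rows = np.array([index[g] for g in order])
    cols = np.array([expr.sample_ids.index(s) for s in col_order])
    sub = expr.values[np.ix_(rows, cols)].astype(float)

    if normalization == "row_zscore":
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, keepdims=True)
        sub = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    elif normalization == "log2":
        if (sub <= 0).any():
            warnings.warn(
                "non-positive values encountered in log2 normalization",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            sub = np.log2(sub)

    frame = pd.DataFrame(sub, index=order, columns=col_order)
    return HeatmapData(
        set_id=gene_set.set_id,
        frame=frame,
        missing=missing,
        normalization=normalization,
    )
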