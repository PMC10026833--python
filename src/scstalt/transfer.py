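"""Assign query cells to kernel stages by maximal cosine similarity.

Each query cell's expression over the k kernel genes is compared against all
m kernel stage columns; the cell is labeled with the stage (and its grid
pseudotime) of highest cosine similarity S(j). Cosine similarity is invariant
to positive rescaling of either vector, so library-size-like per-cell scaling
never changes an assignment — the property that makes this transfer robust
where Euclidean nearest-stage matching is not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeneMismatchError, UndefinedSimilarityError, ValidationError
from .io import ExpressionMatrix
from .kernel import KernelProfile

logger = logging.getLogger(__name__)


@dataclass
class QueryProfile:
    """Query expression restricted and reordered to the kernel's k genes."""

    genes: np.ndarray
    E: np.ndarray  # k x n
    cell_ids: np.ndarray
    overlap_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.E = np.asarray(self.E, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.E.shape != (len(self.genes), len(self.cell_ids)):
            raise ValidationError("query profile shape does not match genes x cells")
        if not np.all(np.isfinite(self.E)):
            raise ValidationError("query profile contains non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.E.shape[1]


@dataclass
class TransferResult:
    """One query cell's assignment: stage, pseudotime, similarity, cutoff flag."""

    cell_id: str
    stage_index: int  # 1-based stage in [1, m]
    pseudotime: float
    similarity: float
    passed_cutoff: bool


def cosine_similarity(A, B) -> float:
    """cos(theta) = A.B / (||A|| ||B||); undefined for zero-norm vectors."""
    A = np.asarray(A, dtype=float).ravel()
    B = np.asarray(B, dtype=float).ravel()
    if A.shape != B.shape:
        raise ValidationError(f"vector lengths differ: {A.shape[0]} vs {B.shape[0]}")
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise UndefinedSimilarityError("cosine similarity undefined for zero-norm vector")
    return float(A @ B / (na * nb))


def align_genes(
    query_expr: ExpressionMatrix,
    kernel: KernelProfile,
    min_overlap: float = 0.8,
) -> QueryProfile:
    """Restrict and reorder the query matrix to the kernel's gene panel.

    Kernel genes absent from the query are imputed as zero (logged); if the
    overlap fraction falls below ``min_overlap`` a
    :class:`~scstalt.errors.GeneMismatchError` is raised instead.
    """
    index = {g: i for i, g in enumerate(query_expr.gene_ids)}
    present = [g in index for g in kernel.genes]
    overlap = float(np.mean(present))
    if overlap < min_overlap:
        raise GeneMismatchError(
            f"query covers only {overlap:.1%} of {kernel.k} kernel genes "
            f"(minimum {min_overlap:.1%})"
        )
    missing = [g for g, ok in zip(kernel.genes, present) if not ok]
    if missing:
        logger.warning(
            "%d/%d kernel genes missing from query, imputed as 0: %s%s",
            len(missing),
            kernel.k,
            missing[:5],
            "..." if len(missing) > 5 else "",
        )
    E = np.zeros((kernel.k, query_expr.n_cells))
    for row, (g, ok) in enumerate(zip(kernel.genes, present)):
        if ok:
            E[row] = query_expr.values[index[g]]
    return QueryProfile(kernel.genes, E, query_expr.cell_ids, overlap_fraction=overlap)


def similarity_matrix(query: QueryProfile, kernel: KernelProfile) -> np.ndarray:
    """n x m matrix of cosine similarities CS(E[j], R[i]) for all cells x stages."""
    if query.E.shape[0] != kernel.R.shape[0] or not np.array_equal(query.genes, kernel.genes):
        raise ValidationError("query and kernel gene panels do not match")
    qn = np.linalg.norm(query.E, axis=0)
    rn = np.linalg.norm(kernel.R, axis=0)
    if np.any(qn == 0):
        bad = list(query.cell_ids[qn == 0][:10])
        raise UndefinedSimilarityError(f"query cells with zero-norm expression: {bad}")
    if np.any(rn == 0):
        bad = list(np.flatnonzero(rn == 0)[:10] + 1)
        raise UndefinedSimilarityError(f"kernel stages with zero-norm profile: {bad}")
    S = (query.E / qn).T @ (kernel.R / rn)
    return np.clip(S, -1.0, 1.0)


def transfer_labels(
    query: QueryProfile,
    kernel: KernelProfile,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Label every query cell with its argmax-similarity kernel stage.

    Ties are broken toward the earliest stage (and logged). Returns a
    DataFrame with columns cell_id, stage_index (1-based), pseudotime (the
    stage-grid value), similarity (S(j)) and passed_cutoff; when ``cutoff`` is
    None every cell passes.
    """
    S = similarity_matrix(query, kernel)
    idx = np.argmax(S, axis=1)  # first maximum = earliest stage on ties
    best = S[np.arange(S.shape[0]), idx]
    n_tied = int(np.sum(np.sum(S == best[:, None], axis=1) > 1))
    if n_tied:
        logger.info("%d cells had tied maximal similarity; earliest stage kept", n_tied)
    passed = np.ones(len(idx), dtype=bool) if cutoff is None else best >= cutoff
    return pd.DataFrame(
        {
            "cell_id": query.cell_ids,
            "stage_index": idx + 1,
            "pseudotime": kernel.stage_grid[idx],
            "similarity": best,
            "passed_cutoff": passed,
        }
    )
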