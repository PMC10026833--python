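"""Batch-harmonized representation via time-series partitions.

Once reference and query cells share a pseudotime axis (the reference's own
normalized pseudotime, and the transferred stage pseudotime for the query),
cells are binned into P equal-width pseudotime partitions. Two artifacts are
produced: a partition-level trend matrix (gene-wise z-scored pooled partition
means) and a per-cell corrected matrix in which each gene is batch-centered
within its partition — cells of different batches at the same stage end up on
a common scale without any mutual-nearest-neighbor pairing, which is what
makes the approach safe for mosaic batches with no shared populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix


@dataclass
class PartitionedDataset:
    """Joint representation of several batches binned by pseudotime."""

    cell_ids: np.ndarray
    batch: np.ndarray
    pseudotime: np.ndarray
    partition_index: np.ndarray  # 1-based, in [1, P]
    genes: np.ndarray
    partition_trend: np.ndarray  # genes x P, NaN columns for empty partitions
    corrected: np.ndarray  # genes x cells
    empty_partitions: np.ndarray  # 1-based indices of partitions with no cells

    @property
    def n_partitions(self) -> int:
        return self.partition_trend.shape[1]

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "batch": self.batch,
                "pseudotime": self.pseudotime,
                "partition": self.partition_index,
            }
        )


def assign_partitions(pseudotime, P: int = 100) -> np.ndarray:
    """Map pseudotimes in [0, 1] to 1-based partition indices.

    Partitions are equal-width half-open bins [(p-1)/P, p/P) with the last
    bin closed at 1, i.e. index = min(P, floor(t * P) + 1).
    """
    t = np.asarray(pseudotime, dtype=float)
    if P < 1:
        raise ValidationError(f"P must be >= 1, got {P}")
    if t.size and (t.min() < 0 or t.max() > 1):
        raise ValidationError("pseudotime outside [0, 1]")
    return np.minimum(P, np.floor(t * P).astype(int) + 1)


def integrate_by_partition(
    datasets: Sequence[tuple[ExpressionMatrix, str, np.ndarray]],
    genes,
    P: int = 100,
) -> PartitionedDataset:
    """Pool batches on the shared pseudotime axis and batch-center per partition.

    ``datasets`` is a list of (log-normalized ExpressionMatrix, batch label,
    per-cell pseudotime in [0, 1]). All matrices must contain every gene in
    ``genes`` (typically the kernel panel). Per gene and partition, the
    corrected value is x - batch-partition mean + pooled partition mean, so a
    single batch passes through unchanged and additive-in-log batch shifts
    cancel exactly. The trend matrix holds pooled per-partition means,
    z-scored per gene across non-empty partitions (empty partitions are NaN
    and excluded from the scaling statistics).
    """
    genes = np.asarray(genes, dtype=object)
    if len(datasets) == 0:
        raise ValidationError("no datasets to integrate")
    blocks, batches, times, cells = [], [], [], []
    for expr, label, t in datasets:
        t = np.asarray(t, dtype=float)
        if t.shape[0] != expr.n_cells:
            raise ValidationError(f"batch {label!r}: pseudotime length != cell count")
        if t.size and (t.min() < 0 or t.max() > 1):
            raise ValidationError(f"batch {label!r}: pseudotime outside [0, 1]")
        index = {g: i for i, g in enumerate(expr.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise ValidationError(f"batch {label!r} lacks genes: {missing[:10]}")
        rows = np.array([index[g] for g in genes], dtype=int)
        blocks.append(expr.values[rows])
        batches.append(np.full(expr.n_cells, label, dtype=object))
        times.append(t)
        cells.append(expr.cell_ids)
    X = np.hstack(blocks)  # genes x all cells
    batch = np.concatenate(batches)
    t_all = np.concatenate(times)
    cell_ids = np.concatenate(cells)
    part = assign_partitions(t_all, P=P)

    pooled = np.full((len(genes), P), np.nan)
    corrected = X.copy()
    batch_labels = pd.unique(batch)
    occupied = np.zeros(P, dtype=bool)
    for p in range(1, P + 1):
        in_p = part == p
        if not np.any(in_p):
            continue
        occupied[p - 1] = True
        mu_pool = X[:, in_p].mean(axis=1)
        pooled[:, p - 1] = mu_pool
        for b in batch_labels:
            sel = in_p & (batch == b)
            if not np.any(sel):
                continue
            mu_b = X[:, sel].mean(axis=1)
            corrected[:, sel] += (mu_pool - mu_b)[:, None]
    if not occupied.any():
        raise ValidationError("no non-empty partitions")

    trend = np.full_like(pooled, np.nan)
    occ = pooled[:, occupied]
    mu = occ.mean(axis=1, keepdims=True)
    sd = occ.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # flat genes: z-score is 0, not NaN
    trend[:, occupied] = (occ - mu) / sd
    return PartitionedDataset(
        cell_ids=cell_ids,
        batch=batch,
        pseudotime=t_all,
        partition_index=part,
        genes=genes,
        partition_trend=trend,
        corrected=corrected,
        empty_partitions=np.flatnonzero(~occupied) + 1,
    )
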