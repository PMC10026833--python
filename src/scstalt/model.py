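"""Model/Results facade over kernel building and label transfer.

``StageKernelModel`` holds the reference data (log-normalized expression and
normalized pseudotime); ``fit()`` runs the per-gene spline regressions and the
FDR-controlled dynamic-gene selection and returns a ``StageKernelResults``
carrying the kernel profile, the full gene-trend test table and a ``summary()``.
Query datasets are mapped with ``results.transfer(query)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .integrate import PartitionedDataset, integrate_by_partition
from .io import ExpressionMatrix
from .kernel import KernelProfile, build_kernel, log_normalize, normalize_pseudotime
from .transfer import align_genes, transfer_labels


class StageKernelModel:
    """Reference-trajectory kernel model.

    Parameters
    ----------
    expr
        Reference expression; a ``counts`` layer is log-normalized on entry,
        a ``lognorm`` layer is used as-is.
    pseudotime
        Raw per-cell pseudotime in the same cell order as ``expr`` (or a
        Series indexed by cell id); normalized to [0, 1] internally.
    m, fdr, df
        Number of kernel stages, selection FDR, spline degrees of freedom.
    """

    def __init__(self, expr: ExpressionMatrix, pseudotime, m: int = 100,
                 fdr: float = 0.05, df: int = 6):
        if isinstance(pseudotime, pd.Series):
            missing = [c for c in expr.cell_ids if c not in pseudotime.index]
            if missing:
                raise ValidationError(f"pseudotime missing for cells: {missing[:10]}")
            pseudotime = pseudotime.loc[expr.cell_ids].to_numpy()
        self.expr = log_normalize(expr) if expr.layer == "counts" else expr
        self.pseudotime = normalize_pseudotime(np.asarray(pseudotime, dtype=float))
        self.m = m
        self.fdr = fdr
        self.df = df

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, pseudotime, layer: str = "lognorm", **kw):
        """Build from a gene-by-cell DataFrame (index = genes, columns = cells)."""
        expr = ExpressionMatrix(
            frame.to_numpy(dtype=float),
            frame.index.to_numpy(dtype=object),
            frame.columns.to_numpy(dtype=object),
            layer=layer,
        )
        return cls(expr, pseudotime, **kw)

    def fit(self) -> "StageKernelResults":
        kernel, table = build_kernel(
            self.expr, self.pseudotime, m=self.m, fdr=self.fdr, df=self.df
        )
        return StageKernelResults(self, kernel, table)


@dataclass
class StageKernelResults:
    """Fitted kernel profile with the per-gene association-test table."""

    model: StageKernelModel
    kernel: KernelProfile
    gene_trends: pd.DataFrame

    @property
    def n_dynamic(self) -> int:
        return self.kernel.k

    def summary(self) -> str:
        t = self.gene_trends
        top = (
            t[t["selected"]]
            .sort_values("fit_statistic", ascending=False)
            .head(10)[["gene_id", "fit_statistic", "p_value", "q_value"]]
        )
        lines = [
            "Stage kernel profile",
            "====================",
            f"reference cells:      {self.model.expr.n_cells}",
            f"genes tested:         {len(t)}",
            f"dynamic genes (k):    {self.n_dynamic}  (q < {self.model.fdr})",
            f"stages (m):           {self.kernel.m}",
            f"spline df:            {self.model.df}",
            "",
            "Top dynamic genes by F statistic:",
            top.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def transfer(self, query: ExpressionMatrix, cutoff: float | None = None,
                 min_overlap: float = 0.8) -> "TransferResults":
        """Assign every query cell to its maximal-cosine-similarity stage."""
        if query.layer == "counts":
            query = log_normalize(query)
        profile = align_genes(query, self.kernel, min_overlap=min_overlap)
        frame = transfer_labels(profile, self.kernel, cutoff=cutoff)
        return TransferResults(self, frame, cutoff, profile.overlap_fraction, query)

    def integrate(self, query_results: "TransferResults",
                  P: int = 100, ref_label: str = "reference",
                  query_label: str = "query") -> PartitionedDataset:
        """Joint batch-corrected representation of reference + transferred query."""
        return integrate_by_partition(
            [
                (self.model.expr, ref_label, self.model.pseudotime),
                (query_results.query_expr, query_label,
                 query_results.frame["pseudotime"].to_numpy()),
            ],
            self.kernel.genes,
            P=P,
        )


@dataclass
class TransferResults:
    """Per-cell stage assignments for one query dataset."""

    results: StageKernelResults
    frame: pd.DataFrame
    cutoff: float | None
    overlap_fraction: float
    query_expr: ExpressionMatrix | None = None

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def summary(self) -> str:
        f = self.frame
        lines = [
            "Stage label transfer",
            "====================",
            f"query cells:          {len(f)}",
            f"kernel gene overlap:  {self.overlap_fraction:.1%}",
            f"similarity (S):       median {f['similarity'].median():.4f}, "
            f"min {f['similarity'].min():.4f}, max {f['similarity'].max():.4f}",
            f"stages hit:           {f['stage_index'].nunique()} of {self.results.kernel.m}",
        ]
        if self.cutoff is not None:
            lines.append(
                f"passed cutoff {self.cutoff}: {int(f['passed_cutoff'].sum())}/{len(f)}"
            )
        return "\n".join(lines)
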