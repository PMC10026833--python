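"""Build the kernel gene-expression profile R_{k,m}.

The reference trajectory is smoothed into a fixed model of m stages: for every
gene, expression is regressed on normalized pseudotime with a cubic
B-spline basis; genes whose smooth varies significantly along the trajectory
(F-test against the intercept-only model, Benjamini-Hochberg at fdr < 0.05)
are the *dynamic genes*, and their fitted curves evaluated on an m-point stage
grid form the k x m kernel matrix used as in-silico anchors for label
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from patsy import build_design_matrices, dmatrix
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateTrajectoryError,
    EmptyKernelError,
    FitError,
    ValidationError,
)
from .io import ExpressionMatrix


@dataclass
class GeneTrend:
    """Smoothed trend of one gene along pseudotime with its association test."""

    gene_id: str
    grid_values: np.ndarray
    fit_statistic: float
    p_value: float
    q_value: float = np.nan


@dataclass
class KernelProfile:
    """The k x m kernel: dynamic genes evaluated on the stage grid.

    ``R[i, j]`` is the smoothed log-normalized expression of gene ``genes[i]``
    at pseudotime ``stage_grid[j]``. Stages are 1-based in reports; columns
    are ordered by increasing stage pseudotime.
    """

    genes: np.ndarray
    stage_grid: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.stage_grid = np.asarray(self.stage_grid, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("kernel contains duplicate genes")
        if self.R.shape != (len(self.genes), len(self.stage_grid)):
            raise ValidationError("kernel matrix shape does not match genes x stages")
        if np.any(np.diff(self.stage_grid) <= 0):
            raise ValidationError("stage grid must be strictly increasing")
        if not np.all(np.isfinite(self.R)):
            raise ValidationError("kernel matrix contains non-finite entries")

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.stage_grid)


def normalize_pseudotime(t_raw) -> np.ndarray:
    """Affine-map raw pseudotime onto [0, 1]: t -> (t - min) / (max - min).

    Order-preserving and idempotent; raises if the trajectory is degenerate
    (all values identical).
    """
    t = np.asarray(t_raw, dtype=float)
    if t.size < 2:
        raise DegenerateTrajectoryError("need at least two cells to normalize pseudotime")
    if not np.all(np.isfinite(t)):
        raise ValidationError("pseudotime contains non-finite values")
    lo, hi = t.min(), t.max()
    if hi == lo:
        raise DegenerateTrajectoryError("all pseudotime values identical; no trajectory")
    return (t - lo) / (hi - lo)


def log_normalize(counts: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalize and log-transform: x = ln(1 + scale * c / total).

    The per-cell total is the column sum; cells with zero total counts are
    rejected since their proportions are undefined.
    """
    if counts.layer != "counts":
        raise ValidationError("log_normalize expects a counts layer")
    totals = counts.values.sum(axis=0)
    zero = totals == 0
    if np.any(zero):
        bad = list(counts.cell_ids[zero][:10])
        raise ValidationError(f"cells with zero total counts: {bad}")
    values = np.log1p(scale * counts.values / totals)
    return ExpressionMatrix(values, counts.gene_ids, counts.cell_ids, layer="lognorm")


def _spline_design(t: np.ndarray, df: int):
    """Cubic B-spline design matrix (df columns whose span includes constants)."""
    if len(np.unique(t)) <= df:
        raise FitError(
            f"only {len(np.unique(t))} distinct pseudotime values for df={df}; "
            "basis would be rank-deficient"
        )
    try:
        X = dmatrix(
            "bs(t, df=df, include_intercept=True) - 1",
            {"t": t, "df": df},
            return_type="dataframe",
        )
    except Exception as exc:
        raise FitError(f"could not build spline basis: {exc}") from exc
    return np.asarray(X), X.design_info


def _spline_eval_design(design_info, t_obs: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # evaluation outside the observed range is clamped to the boundary fit
    clamped = np.clip(grid, t_obs.min(), t_obs.max())
    (Xg,) = build_design_matrices([design_info], {"t": clamped})
    return np.asarray(Xg)


def fit_gene_trends(
    Y: np.ndarray,
    t: np.ndarray,
    stage_grid: np.ndarray,
    df: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit all genes at once; returns (grid_values, F, p).

    ``Y`` is cells x genes. Each gene is regressed on a cubic B-spline
    basis in ``t`` by least squares; ``F`` tests the spline model against the
    intercept-only model. Degenerate genes (zero variance) get F = 0, p = 1;
    exact fits with non-zero variance get F = inf, p = 0.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = np.asarray(t, dtype=float)
    if Y.shape[0] != t.shape[0]:
        raise ValidationError("expression rows must match pseudotime length")
    n = t.shape[0]
    if n < df + 2:
        raise FitError(f"need at least df+2={df + 2} cells, got {n}")
    X, design_info = _spline_design(t, df)
    p_params = X.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p_params:
        raise FitError(f"spline basis is rank-deficient (rank {rank} < {p_params})")
    resid = Y - X @ beta
    rss1 = np.einsum("ij,ij->j", resid, resid)
    centered = Y - Y.mean(axis=0)
    rss0 = np.einsum("ij,ij->j", centered, centered)
    df_num = p_params - 1
    df_den = n - p_params
    if df_den <= 0:
        raise FitError(f"not enough residual degrees of freedom (n={n}, params={p_params})")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df_num) / (rss1 / df_den)
    # constant gene: no variance to explain
    F = np.where(rss0 <= 1e-12 * np.maximum(1.0, np.abs(Y).max(axis=0)) ** 2, 0.0, F)
    F = np.where(np.isnan(F), 0.0, np.maximum(F, 0.0))
    pvals = scipy.stats.f.sf(F, df_num, df_den)
    pvals = np.where(np.isinf(F), 0.0, pvals)
    Xg = _spline_eval_design(design_info, t, np.asarray(stage_grid, dtype=float))
    grid_values = (Xg @ beta).T  # genes x m
    return grid_values, F, pvals


def fit_gene_trend(
    expr_g,
    t,
    stage_grid,
    df: int = 6,
    gene_id: str = "gene",
) -> GeneTrend:
    """Fit a single gene's smooth trend; see :func:`fit_gene_trends`."""
    grid_values, F, p = fit_gene_trends(
        np.asarray(expr_g, dtype=float).reshape(-1, 1), np.asarray(t), stage_grid, df=df
    )
    return GeneTrend(gene_id, grid_values[0], float(F[0]), float(p[0]))


def select_dynamic_genes(
    expr: ExpressionMatrix,
    t,
    fdr: float = 0.05,
    df: int = 6,
    stage_grid=None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Identify trajectory-dynamic genes at the given FDR.

    Every gene is tested (spline F-test), p-values are Benjamini-Hochberg
    corrected across all genes, and genes with q < fdr are returned sorted by
    F statistic, descending. The full trend table (gene_id, F, p, q, selected,
    grid values) is returned alongside.
    """
    if not (0.0 < fdr < 1.0):
        raise ValidationError(f"fdr must lie in (0, 1), got {fdr}")
    if expr.layer != "lognorm":
        raise ValidationError("dynamic-gene selection expects log-normalized expression")
    t = np.asarray(t, dtype=float)
    if stage_grid is None:
        stage_grid = np.linspace(0.0, 1.0, 100)
    grid_values, F, p = fit_gene_trends(expr.values.T, t, stage_grid, df=df)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    selected = q < fdr
    table = pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "fit_statistic": F,
            "p_value": p,
            "q_value": q,
            "selected": selected,
        }
    )
    table["grid_values"] = list(grid_values)
    order = np.argsort(-F[selected], kind="stable")
    genes = expr.gene_ids[selected][order]
    return genes, table


def build_kernel(
    expr: ExpressionMatrix,
    t,
    m: int = 100,
    fdr: float = 0.05,
    df: int = 6,
) -> tuple[KernelProfile, pd.DataFrame]:
    """Build the k x m kernel profile from a log-normalized reference.

    The stage grid is m equally spaced pseudotimes spanning [0, 1] inclusive.
    Raises :class:`EmptyKernelError` when no gene passes selection.
    """
    if m < 2:
        raise ValidationError(f"kernel needs at least 2 stages, got m={m}")
    t = np.asarray(t, dtype=float)
    if t.min() < 0 or t.max() > 1:
        raise ValidationError("pseudotime must be normalized to [0, 1] before kernel building")
    stage_grid = np.linspace(0.0, 1.0, m)
    genes, table = select_dynamic_genes(expr, t, fdr=fdr, df=df, stage_grid=stage_grid)
    if len(genes) == 0:
        raise EmptyKernelError(
            f"no gene passed dynamic-gene selection at fdr={fdr}; consider a laxer threshold"
        )
    by_gene = {g: gv for g, gv in zip(table["gene_id"], table["grid_values"])}
    R = np.vstack([by_gene[g] for g in genes])
    return KernelProfile(genes=genes, stage_grid=stage_grid, R=R), table
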