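"""Step-path single-cell count simulator with two mosaic batches.

The generative model emulates a continuous differentiation of ``m_stages``
discrete stages sampled mosaically by two batches: batch 1 covers stage
windows A (1-20), C (40-60) and E (80-100); batch 2 covers B (30-35) and
D (70-75), so the batches share no stages at all. Counts are negative
binomial around a per-cell rate

    lambda_gc = L_c * softmax_g( mu_g(s_c) + beta_g,b(c) + eta_gc )

where ``mu_g(s)`` is the gene's log-scale stage trend, ``beta_gb`` a per-gene
per-batch additive-in-log batch effect, ``eta_gc`` non-stage biological noise
and ``L_c`` a log-normal library size. A fraction ``p_dynamic`` of genes
carries a stage trend; of those, ``nonlinear_prop`` get a nonlinear shape
(random-midpoint sigmoid or Gaussian bump) instead of a line. The
signal-to-noise ratio ``snr`` scales the trend amplitude relative to the
fixed biological noise scale: |Delta_g| = snr * trend_scale * u_g with
u_g ~ U(0.5, 1.5), so mean trend amplitude grows linearly in snr and snr=0
yields flat genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, write_expression, write_manifest

#: default mosaic stage windows; batch1 = A, C, E and batch2 = B, D
DEFAULT_WINDOWS: dict[str, tuple[tuple[int, int], ...]] = {
    "batch1": ((1, 20), (40, 60), (80, 100)),
    "batch2": ((30, 35), (70, 75)),
}

#: window letters for reporting, keyed by (batch, window interval)
WINDOW_LABELS: dict[tuple[int, int], str] = {
    (1, 20): "A",
    (30, 35): "B",
    (40, 60): "C",
    (70, 75): "D",
    (80, 100): "E",
}


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the step-path simulator; every run is seed-reproducible."""

    m_stages: int = 100
    n_genes: int = 2000
    n_cells: int = 3000  # total across both batches; odd remainder to batch1
    batch_windows: Mapping[str, tuple[tuple[int, int], ...]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    p_dynamic: float = 0.3
    snr: float = 0.2
    nonlinear_prop: float = 0.1
    batch_effect_sd: float = 0.15
    nb_dispersion: float = 0.2
    lib_size_logmean: float = 9.2  # ~10k counts per cell
    lib_size_logsd: float = 0.25
    sigma_bio: float = 0.5  # non-stage biological noise sd, log units
    trend_scale: float = 6.0  # log-unit trend amplitude per unit snr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_stages < 2:
            raise ValidationError("m_stages must be >= 2")
        if not (0.0 <= self.p_dynamic <= 1.0) or not (0.0 <= self.nonlinear_prop <= 1.0):
            raise ValidationError("p_dynamic and nonlinear_prop must lie in [0, 1]")
        if self.snr < 0:
            raise ValidationError("snr must be >= 0")
        if self.batch_effect_sd < 0 or self.nb_dispersion <= 0:
            raise ValidationError("invalid noise/dispersion parameters")
        for b, windows in self.batch_windows.items():
            if len(windows) == 0:
                raise ValidationError(f"batch {b!r} has an empty window union")
            for lo, hi in windows:
                if not (1 <= lo <= hi <= self.m_stages):
                    raise ValidationError(
                        f"window ({lo}, {hi}) of batch {b!r} outside [1, {self.m_stages}]"
                    )

    def window_label(self, batch: str, stage: int) -> str | None:
        """A-E letter of the window containing ``stage`` (default design only)."""
        for lo, hi in self.batch_windows[batch]:
            if lo <= stage <= hi:
                return WINDOW_LABELS.get((lo, hi))
        return None


@dataclass
class SimulationDataset:
    """Simulated counts plus the ground truth needed for benchmarking."""

    counts: ExpressionMatrix
    true_stage: np.ndarray  # integer in [1, m] per cell
    batch: np.ndarray  # batch label per cell
    gene_meta: pd.DataFrame  # gene_id, is_dynamic, is_nonlinear, shape, delta
    config: SimulationConfig

    @property
    def true_pseudotime(self) -> np.ndarray:
        """Normalized stage (s - 1) / (m - 1) in [0, 1]."""
        return (self.true_stage - 1) / (self.config.m_stages - 1)

    def batch_mask(self, label: str) -> np.ndarray:
        return self.batch == label


def _window_union(windows: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.arange(lo, hi + 1) for lo, hi in windows])


def sample_stages(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (stage, batch) per cell: equal batch split, uniform over windows."""
    batches = list(config.batch_windows)
    sizes = [config.n_cells // len(batches)] * len(batches)
    sizes[0] += config.n_cells - sum(sizes)  # odd remainder to the first batch
    stage_parts, batch_parts = [], []
    for label, size in zip(batches, sizes):
        pool = _window_union(config.batch_windows[label])
        stage_parts.append(rng.choice(pool, size=size, replace=True))
        batch_parts.append(np.full(size, label, dtype=object))
    return np.concatenate(stage_parts), np.concatenate(batch_parts)


def _shape_on_grid(kind: str, params: tuple, grid: np.ndarray) -> np.ndarray:
    """Unit-amplitude trend shape evaluated on the normalized stage grid."""
    if kind == "linear":
        return grid
    if kind == "sigmoid":
        t0, w = params
        s = 1.0 / (1.0 + np.exp(-(grid - t0) / w))
        s0 = 1.0 / (1.0 + np.exp(t0 / w))
        s1 = 1.0 / (1.0 + np.exp(-(1.0 - t0) / w))
        return (s - s0) / (s1 - s0)
    if kind == "bump":
        c, w = params
        g = np.exp(-((grid - c) ** 2) / (2.0 * w**2))
        return (g - g.min()) / (g.max() - g.min())
    raise ValueError(f"unknown shape kind {kind!r}")


def gene_trends(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-gene log-mean trend matrix mu_g(s) over all m stages, plus metadata.

    Returns ``M`` of shape (n_genes, m_stages) and a gene_meta table. Baselines
    are log-normal; dynamic genes add delta_g * h((s-1)/(m-1)) with h linear,
    sigmoid or bump (unit amplitude), |delta_g| = snr * trend_scale * u_g,
    sign equiprobable.
    """
    m, G = config.m_stages, config.n_genes
    grid = np.arange(m) / (m - 1)
    base = rng.normal(0.0, 1.0, size=G)  # log-scale baselines, lognormal means
    n_dyn = int(round(config.p_dynamic * G))
    dyn_idx = rng.choice(G, size=n_dyn, replace=False)
    n_nl = int(round(config.nonlinear_prop * n_dyn))
    nl_idx = set(rng.choice(dyn_idx, size=n_nl, replace=False).tolist()) if n_dyn else set()
    sign = rng.choice([-1.0, 1.0], size=G)
    u = rng.uniform(0.5, 1.5, size=G)
    # shape parameters drawn for every gene to keep the stream layout fixed
    kind_draw = rng.random(G)
    p1 = rng.uniform(0.2, 0.8, size=G)
    p2_sig = rng.uniform(0.05, 0.15, size=G)
    p2_bump = rng.uniform(0.05, 0.2, size=G)

    M = np.tile(base[:, None], (1, m))
    meta = {
        "gene_id": np.array([f"gene_{i:05d}" for i in range(G)], dtype=object),
        "is_dynamic": np.zeros(G, dtype=bool),
        "is_nonlinear": np.zeros(G, dtype=bool),
        "shape": np.full(G, "flat", dtype=object),
        "delta": np.zeros(G),
        "baseline_log": base,
    }
    for g in dyn_idx:
        delta = sign[g] * config.snr * config.trend_scale * u[g]
        if g in nl_idx:
            kind = "sigmoid" if kind_draw[g] < 0.5 else "bump"
            params = (p1[g], p2_sig[g] if kind == "sigmoid" else p2_bump[g])
        else:
            kind, params = "linear", ()
        M[g] = base[g] + delta * _shape_on_grid(kind, params, grid)
        meta["is_dynamic"][g] = True
        meta["is_nonlinear"][g] = g in nl_idx
        meta["shape"][g] = kind
        meta["delta"][g] = delta
    return M, pd.DataFrame(meta)


def simulate_counts(config: SimulationConfig) -> SimulationDataset:
    """Run the full generative model; identical config + seed => identical counts."""
    rng = np.random.default_rng(config.seed)
    stages, batch = sample_stages(config, rng)
    M, gene_meta = gene_trends(config, rng)
    batches = list(config.batch_windows)
    beta = rng.normal(0.0, config.batch_effect_sd, size=(config.n_genes, len(batches)))
    lib = rng.lognormal(config.lib_size_logmean, config.lib_size_logsd, size=config.n_cells)
    eta = rng.normal(0.0, config.sigma_bio, size=(config.n_genes, config.n_cells))

    batch_col = np.array([batches.index(b) for b in batch])
    logmu = M[:, stages - 1] + beta[:, batch_col] + eta
    logmu -= logmu.max(axis=0, keepdims=True)  # softmax stabilization
    w = np.exp(logmu)
    mean = lib * (w / w.sum(axis=0, keepdims=True))
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(float)

    cell_ids = np.array([f"cell_{i:05d}" for i in range(config.n_cells)], dtype=object)
    expr = ExpressionMatrix(counts, gene_meta["gene_id"].to_numpy(), cell_ids, layer="counts")
    return SimulationDataset(expr, stages.astype(int), batch, gene_meta, config)


def write_simulation(dataset: SimulationDataset, out_dir) -> None:
    """Write matrix.mtx + features/barcodes, truth.tsv, gene_meta.tsv, manifest."""
    out_dir = Path(out_dir)
    write_expression(dataset.counts, out_dir, format="mtx_triplet")
    truth = pd.DataFrame(
        {
            "cell_id": dataset.counts.cell_ids,
            "batch": dataset.batch,
            "stage": dataset.true_stage,
        }
    )
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    dataset.gene_meta.to_csv(out_dir / "gene_meta.tsv", sep="\t", index=False)
    cfg = {k: getattr(dataset.config, k) for k in dataset.config.__dataclass_fields__}
    cfg["batch_windows"] = {b: [list(w) for w in ws] for b, ws in cfg["batch_windows"].items()}
    write_manifest(out_dir, "simulate", cfg)


def read_simulation(out_dir) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read back counts + truth table written by :func:`write_simulation`."""
    from .io import read_expression

    out_dir = Path(out_dir)
    expr = read_expression(out_dir, format="mtx_triplet")
    truth = pd.read_csv(out_dir / "truth.tsv", sep="\t")
    return expr, truth
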