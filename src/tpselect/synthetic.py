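"""Seeded generators of pilot-style time-series datasets with ground truth.

The generated data emulate the regime of a dense developmental pilot
experiment: a panel of ~100-200 genes profiled over ~40 time points (a
prenatal point followed by dense early postnatal sampling that relaxes
later), a few repeats per point, cluster-structured smooth trajectories
with localized sigmoidal transitions at unknown times, and i.i.d. Gaussian
repeat noise.  A paired generator shares the latent cluster dynamics
between two datasets (with transformed identities and extra noise) to
emulate a second data type -- miRNA- or methylation-like -- measured on the
same grid.

Everything is reproducible from the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import TimeGrid, TimeSeriesDataset, repeat_noise

__all__ = [
    "default_grid",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_paired_dataset",
    "generate_changepoint_dataset",
    "corrupt_with_random_genes",
]


def default_grid() -> TimeGrid:
    """Developmental-style sampling grid (days; birth = 0).

    One prenatal point at -3.0 d (E16.5 in mouse), then 0.5 d steps from
    P0.5 through P14, then daily from P15 through P28 (43 points).
    """
    times = np.concatenate(
        [[-3.0], np.arange(0.5, 14.0 + 1e-9, 0.5), np.arange(15.0, 28.0 + 1e-9, 1.0)]
    )
    return TimeGrid(times)


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    Defaults mirror the pilot regime the package targets: 126 genes in 8
    co-expression clusters, 3 repeats per point, repeat noise sd 0.33 (so
    the per-measurement noise variance is about 0.109 on the log-expression
    scale), and two sigmoidal transitions per cluster with widths spanning
    slow to rapid regimes.
    """

    n_genes: int = 126
    grid: TimeGrid = field(default_factory=default_grid)
    n_clusters: int = 8
    n_repeats: int = 3
    noise_sd: float = 0.33
    transitions_per_cluster: int = 2
    transition_width: tuple[float, float] = (0.3, 2.0)
    amplitude: tuple[float, float] = (0.5, 1.5)
    trend_scale: float = 0.3
    gene_deviation_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 1 <= self.n_clusters <= self.n_genes:
            raise ValueError("need 1 <= n_clusters <= n_genes")
        if self.n_repeats < 1:
            raise ValueError("need >= 1 repeat")


@dataclass
class GroundTruth:
    """What the generator knows: noiseless curves and latent structure."""

    true_curves: np.ndarray  # genes x times, noiseless values on the grid
    cluster_labels: np.ndarray  # genes
    transition_times: list[list[float]]  # per cluster


def _logistic(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - center) / width))


def _cluster_curves(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[list[float]]]:
    t = cfg.grid.times
    t0, t1 = cfg.grid.span
    u = (t - t0) / (t1 - t0)
    curves = np.zeros((cfg.n_clusters, t.size))
    transitions: list[list[float]] = []
    for c in range(cfg.n_clusters):
        # slow polynomial trend
        a = rng.normal(0.0, cfg.trend_scale, size=3)
        curve = a[0] + a[1] * u + a[2] * u**2
        centers = []
        for _ in range(cfg.transitions_per_cluster):
            center = rng.uniform(t0 + 0.05 * (t1 - t0), t1 - 0.05 * (t1 - t0))
            width = rng.uniform(*cfg.transition_width)
            amp = rng.uniform(*cfg.amplitude) * rng.choice([-1.0, 1.0])
            curve = curve + amp * _logistic(t, center, width)
            centers.append(float(center))
        curves[c] = curve
        transitions.append(sorted(centers))
    return curves, transitions


def _gene_deviation(
    cfg: SyntheticConfig, rng: np.random.Generator, n_genes: int
) -> np.ndarray:
    """Small smooth per-gene departures from the cluster mean."""
    t = cfg.grid.times
    t0, t1 = cfg.grid.span
    u = (t - t0) / (t1 - t0)
    basis = np.stack([np.ones_like(u), u, u**2, np.sin(np.pi * u)])
    coef = rng.normal(0.0, cfg.gene_deviation_sd, size=(n_genes, basis.shape[0]))
    return coef @ basis


def generate_dataset(
    cfg: SyntheticConfig | None = None,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Draw one pilot-style dataset and its ground truth."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    cluster_curves, transitions = _cluster_curves(cfg, rng)
    labels = np.sort(rng.integers(0, cfg.n_clusters, size=cfg.n_genes))
    # guarantee every cluster is populated
    labels[: cfg.n_clusters] = np.arange(cfg.n_clusters)
    true_curves = cluster_curves[labels] + _gene_deviation(cfg, rng, cfg.n_genes)
    noise = rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, cfg.grid.n, cfg.n_repeats)
    )
    values = true_curves[:, :, None] + noise
    width = len(str(cfg.n_genes))
    gene_ids = [f"gene_{i:0{width}d}" for i in range(cfg.n_genes)]
    ds = TimeSeriesDataset(cfg.grid, gene_ids, values)
    return ds, GroundTruth(true_curves, labels, transitions)


def generate_paired_dataset(
    cfg: SyntheticConfig | None = None,
    target_noise_multiplier: float = 1.5,
    target_transform: str = "sign_flip",
) -> tuple[TimeSeriesDataset, TimeSeriesDataset, GroundTruth]:
    """Source dataset plus a paired target sharing its latent dynamics.

    Target gene curves are monotone transforms of the *source* cluster
    dynamics -- same transition timing, different identities -- with
    independent, typically larger, repeat noise:

    * ``identity``: the cluster curve itself,
    * ``sign_flip``: each target gene follows its cluster curve with a
      random sign (emulating coordinate up- and down-regulation, e.g.
      miRNA repressing its targets),
    * ``negate``: all target genes anti-correlated with the source
      (methylation-style negative coupling).
    """
    cfg = cfg or SyntheticConfig()
    src_ds, truth = generate_dataset(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    cluster_curves = np.stack(
        [
            truth.true_curves[truth.cluster_labels == c].mean(axis=0)
            for c in range(cfg.n_clusters)
        ]
    )
    labels = np.sort(rng.integers(0, cfg.n_clusters, size=cfg.n_genes))
    labels[: cfg.n_clusters] = np.arange(cfg.n_clusters)
    if target_transform == "identity":
        signs = np.ones(cfg.n_genes)
    elif target_transform == "sign_flip":
        signs = rng.choice([-1.0, 1.0], size=cfg.n_genes)
    elif target_transform == "negate":
        signs = -np.ones(cfg.n_genes)
    else:
        raise ValueError("transform must be identity, sign_flip or negate")
    target_curves = signs[:, None] * cluster_curves[labels] + _gene_deviation(
        cfg, rng, cfg.n_genes
    )
    sd = cfg.noise_sd * target_noise_multiplier
    noise = rng.normal(0.0, sd, size=(cfg.n_genes, cfg.grid.n, cfg.n_repeats))
    values = target_curves[:, :, None] + noise
    width = len(str(cfg.n_genes))
    ids = [f"mir_{i:0{width}d}" for i in range(cfg.n_genes)]
    tgt_ds = TimeSeriesDataset(cfg.grid, ids, values)
    return src_ds, tgt_ds, truth


def generate_changepoint_dataset(
    tau: float | None = None,
    n_points: int = 25,
    n_genes: int = 40,
    n_repeats: int = 3,
    noise_sd: float = 0.2,
    width: float = 1.0,
    seed: int = 0,
) -> tuple[TimeSeriesDataset, float]:
    """Profiles with one shared sharp transient event at an unknown time.

    The grid is uniform with unit spacing; ``tau`` defaults to a uniformly
    drawn interior grid point.  Every gene expresses a sharp Gaussian pulse
    at ``tau`` (random amplitude and sign; ``width`` in grid steps) on top
    of a mild linear trend -- the transient-program regime in which a
    design that does not sample near the event cannot reconstruct it.
    Returns the dataset and the true event time.

    A shared *monotone* shift (a sigmoidal step) is deliberately not used
    here: for a symmetric step the reconstruction-optimal design brackets
    the transition from both shoulders rather than sampling its midpoint,
    so "selected a point at the transition" is only the right notion of
    recovery for a localized event.
    """
    rng = np.random.default_rng(seed)
    grid = TimeGrid(np.arange(float(n_points)))
    if tau is None:
        tau = float(rng.integers(2, n_points - 2))
    u = grid.times / (n_points - 1)
    amps = rng.uniform(0.8, 1.5, size=n_genes) * rng.choice([-1, 1], size=n_genes)
    slopes = rng.normal(0.0, 0.2, size=n_genes)
    pulse = np.exp(-((grid.times - tau) ** 2) / (2.0 * width**2))
    curves = slopes[:, None] * u[None, :] + amps[:, None] * pulse[None, :]
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_points, n_repeats))
    ds = TimeSeriesDataset(
        grid,
        [f"gene_{i:02d}" for i in range(n_genes)],
        curves[:, :, None] + noise,
    )
    return ds, tau


def corrupt_with_random_genes(
    ds: TimeSeriesDataset, fraction: float, seed: int = 0
) -> TimeSeriesDataset:
    """Replace a fraction of genes with pure-noise time series.

    The replaced genes' series become i.i.d. Gaussian draws with mean 0 and
    standard deviation equal to the dataset's repeat-noise sd, emulating a
    pilot panel in which only the remaining fraction of genes is actually
    informative about the process.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = ds.copy()
    n_replace = int(np.floor(fraction * ds.n_genes))
    if n_replace == 0:
        return out
    chosen = rng.choice(ds.n_genes, size=n_replace, replace=False)
    try:
        sd = float(np.sqrt(repeat_noise(ds).variance))
    except ValueError:  # single-repeat data: fall back to overall scatter
        sd = float(np.nanstd(ds.values))
    observed = np.isfinite(out.values[chosen])
    replacement = rng.normal(0.0, sd, size=out.values[chosen].shape)
    new_block = np.where(observed, replacement, np.nan)
    out.values[chosen] = new_block
    return out


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(cfg, seed=seed)
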