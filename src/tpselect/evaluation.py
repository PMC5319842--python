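"""Baselines, significance, cross-data-type transfer, and correlations.

The selection method is judged the way a study designer would judge it:
against the conventional uniform design, against random designs of the same
size (with a randomization p-value), against the repeat-noise floor that no
reconstruction can beat, and by *transfer* -- scoring points chosen on a
cheap pilot data type (mRNA) by how well they reconstruct a different data
type (miRNA, protein, methylation) sampled on the same grid.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import TimeGrid, TimeSeriesDataset, repeat_noise
from .selection import (
    PointSet,
    SelectionResult,
    SplineScorer,
    greedy_search,
    init_equal_partition,
    search_all_inits,
    simulated_annealing_search,
)

__all__ = [
    "ComparisonReport",
    "TransferResult",
    "CorrelationResult",
    "uniform_points",
    "random_points",
    "compare_methods",
    "transfer_evaluation",
    "correlate_profiles",
    "evaluate_designs",
]


def uniform_points(grid: TimeGrid, k: int) -> PointSet:
    """The conventional baseline: k points spread evenly over the span."""
    return init_equal_partition(grid, k)


def random_points(grid: TimeGrid, k: int, seed: int | np.random.Generator) -> PointSet:
    """Endpoints plus a uniform draw of k-2 interior points (seeded)."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if not 3 <= k < grid.n:
        raise ValueError(f"need 3 <= k < n, got k={k}, n={grid.n}")
    interior = rng.choice(np.arange(1, grid.n - 1), size=k - 2, replace=False)
    return PointSet(grid, (0, *sorted(int(i) for i in interior), grid.n - 1))


@dataclass
class ComparisonReport:
    """One row of the design comparison, for a single budget k."""

    k: int
    tps_avg_mse: float
    tps_points: list[float]
    uniform_avg_mse: float
    random_avg_mse: list[float]
    p_value: float
    noise_floor: float
    variant_avg_mse: dict[str, float] = field(default_factory=dict)

    @property
    def random_mean(self) -> float:
        return float(np.mean(self.random_avg_mse))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "tps_avg_mse": self.tps_avg_mse,
            "tps_points": self.tps_points,
            "uniform_avg_mse": self.uniform_avg_mse,
            "random_mean_avg_mse": self.random_mean,
            "random_avg_mse": list(self.random_avg_mse),
            "p_value": self.p_value,
            "noise_floor": self.noise_floor,
            "variant_avg_mse": self.variant_avg_mse,
        }


def reports_to_tsv(reports: list[ComparisonReport]) -> str:
    """Plot-ready table: budget k vs average MSE per method, noise floor."""
    header = ["k", "tps", "uniform", "random_mean", "noise_floor", "p_value"]
    lines = ["\t".join(header)]
    for r in reports:
        lines.append(
            "\t".join(
                f"{v:.6g}"
                for v in (
                    r.k,
                    r.tps_avg_mse,
                    r.uniform_avg_mse,
                    r.random_mean,
                    r.noise_floor,
                    r.p_value,
                )
            )
        )
    return "\n".join(lines) + "\n"


def reports_to_json(reports: list[ComparisonReport]) -> str:
    return json.dumps([r.to_dict() for r in reports], indent=2)


def compare_methods(
    ds: TimeSeriesDataset,
    k_range,
    n_random_trials: int = 50,
    seed: int = 0,
    variants: tuple[str, ...] = ("greedy",),
    init="abs",
    weights_by_variant: dict | None = None,
) -> list[ComparisonReport]:
    """Compare selection variants with uniform and random baselines.

    For each budget k, runs the requested variants ("greedy", "greedy_all",
    "sa", "weighted" via ``weights_by_variant``), the uniform design, and
    ``n_random_trials`` seeded random designs, all scored by spline
    reconstruction error on the left-out points.  The randomization p-value
    for the first variant uses the add-one convention
    ``(1 + #{random <= tps}) / (1 + #trials)`` so it is never zero.
    """
    if n_random_trials < 19:
        raise ValueError("need >= 19 random trials for p-value resolution")
    noise = repeat_noise(ds).variance
    scorer = SplineScorer(ds)
    rng = np.random.default_rng(seed)
    reports = []
    for k in k_range:
        variant_mse: dict[str, float] = {}
        tps_points: list[float] | None = None
        for variant in variants:
            if variant == "greedy":
                res = greedy_search(ds, k, init=init, scorer=scorer)
            elif variant == "greedy_all":
                res, _ = search_all_inits(ds, k, scorer=scorer)
            elif variant == "sa":
                res = simulated_annealing_search(
                    ds, k, init=init, seed=int(rng.integers(2**31)), scorer=scorer
                )
            elif variant == "weighted":
                w = weights_by_variant["weighted"]
                res = greedy_search(ds, k, init=init, weights=w)
            else:
                raise ValueError(f"unknown variant {variant!r}")
            variant_mse[variant] = res.avg_mse
            if tps_points is None:
                tps_points = [float(t) for t in res.point_set.times]
                tps_mse = res.avg_mse
        uniform_mse = scorer.score(uniform_points(ds.grid, k).indices).avg_mse
        random_mse = [
            scorer.score(random_points(ds.grid, k, rng).indices).avg_mse
            for _ in range(n_random_trials)
        ]
        n_better = sum(1 for e in random_mse if e <= tps_mse)
        p = (1 + n_better) / (1 + n_random_trials)
        reports.append(
            ComparisonReport(
                k=int(k),
                tps_avg_mse=tps_mse,
                tps_points=tps_points,
                uniform_avg_mse=uniform_mse,
                random_avg_mse=random_mse,
                p_value=p,
                noise_floor=noise,
                variant_avg_mse=variant_mse,
            )
        )
    return reports


@dataclass
class TransferResult:
    """Cross-data-type evaluation of a point set."""

    source_points: PointSet
    transfer_avg_mse: float  # source-selected points scored on the target
    native_points: PointSet
    native_avg_mse: float  # points selected on the target itself
    random_mean_avg_mse: float

    def to_dict(self) -> dict:
        return {
            "source_points": [float(t) for t in self.source_points.times],
            "transfer_avg_mse": self.transfer_avg_mse,
            "native_points": [float(t) for t in self.native_points.times],
            "native_avg_mse": self.native_avg_mse,
            "random_mean_avg_mse": self.random_mean_avg_mse,
        }


def transfer_evaluation(
    source_ds: TimeSeriesDataset,
    target_ds: TimeSeriesDataset,
    k: int,
    init="abs",
    n_random_trials: int = 30,
    seed: int = 0,
) -> TransferResult:
    """Score points chosen on one data type against another.

    Selects C on the source (e.g. the mRNA pilot), computes the spline
    reconstruction error of C on the target (e.g. miRNA), and separately
    runs the selection directly on the target for the had-we-trained-here
    comparison, plus a random-design reference on the target.
    """
    if source_ds.grid != target_ds.grid:
        raise ValueError("source and target must share the same time grid")
    src_res = greedy_search(source_ds, k, init=init)
    tgt_scorer = SplineScorer(target_ds)
    transfer_mse = tgt_scorer.score(src_res.point_set.indices).avg_mse
    native = greedy_search(target_ds, k, init=init, scorer=tgt_scorer)
    rng = np.random.default_rng(seed)
    rand = [
        tgt_scorer.score(random_points(target_ds.grid, k, rng).indices).avg_mse
        for _ in range(n_random_trials)
    ]
    return TransferResult(
        source_points=src_res.point_set,
        transfer_avg_mse=transfer_mse,
        native_points=native.point_set,
        native_avg_mse=native.avg_mse,
        random_mean_avg_mse=float(np.mean(rand)),
    )


def evaluate_designs(
    ds: TimeSeriesDataset,
    designs: dict[str, list[float]],
    reconstruction: str = "spline",
) -> dict[str, float]:
    """Score named historical sampling designs on the pilot data.

    Each design is a list of times (snapped to the nearest grid point);
    reconstruction is either a per-gene LOOCV-smoothed spline or the
    piecewise-linear connect-the-dots implicit in conventional sparse
    designs.  Grid times strictly inside the design's span and not in the
    design are predicted and scored against every repeat; the average MSE
    per design is returned.  Designs need not include the grid endpoints
    (prior studies often start later than the pilot), so only the covered
    span is evaluated.
    """
    from .splines import (
        default_s_grid,
        fit_spline,
        piecewise_linear_reconstruct,
        select_smoothing_loocv,
    )

    if reconstruction not in ("spline", "linear"):
        raise ValueError("reconstruction must be 'spline' or 'linear'")
    times = ds.grid.times
    means = ds.repeat_means()
    out: dict[str, float] = {}
    for name, design in designs.items():
        idx = sorted({int(np.argmin(np.abs(times - t))) for t in design})
        if len(idx) < 2:
            raise ValueError(f"design {name!r} needs >= 2 distinct grid points")
        span = set(range(idx[0], idx[-1] + 1))
        left_out = sorted(span - set(idx))
        if not left_out:
            raise ValueError(f"design {name!r} leaves no grid point to score")
        x = times[idx]
        q = times[left_out]
        sq_err = 0.0
        n_meas = 0
        for g in range(ds.n_genes):
            y = means[g, idx]
            if reconstruction == "linear":
                pred = piecewise_linear_reconstruct(x, y, q)
            else:
                if x.size >= 5:
                    s = select_smoothing_loocv(x, y).s
                else:
                    s = float(np.median(default_s_grid(x, y)))
                pred = fit_spline(x, y, s=s).predict(q)
            for p, t_idx in zip(pred, left_out):
                reps = ds.values[g, t_idx]
                reps = reps[np.isfinite(reps)]
                sq_err += float(np.sum((p - reps) ** 2))
                n_meas += reps.size
        out[name] = sq_err / n_meas
    return out


@dataclass
class CorrelationResult:
    r: float
    jackknife_r: np.ndarray
    subset_size: int


def correlate_profiles(
    profile_a, profile_b, subset_size: int | None = None
) -> CorrelationResult:
    """Pearson r between two profiles, plus r over all subsets of m-1 points.

    Used for concordance analyses between data types measured on the same
    few time points (e.g. expression vs promoter methylation), where the
    leave-one-out (jackknife) r values show whether the correlation hinges
    on a single time point.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be equal-length 1-D arrays")
    m = a.size
    if m < 3:
        raise ValueError("need at least 3 points")
    if subset_size is None:
        subset_size = m - 1
    if not 3 <= subset_size <= m:
        raise ValueError("subset size must be in [3, m]")
    if np.std(a) <= 1e-15 or np.std(b) <= 1e-15:
        raise ValueError("correlation undefined: a profile has zero variance")
    r_full = float(stats.pearsonr(a, b).statistic)
    subset_r = []
    for keep in itertools.combinations(range(m), subset_size):
        idx = list(keep)
        subset_r.append(float(stats.pearsonr(a[idx], b[idx]).statistic))
    return CorrelationResult(
        r=r_full, jackknife_r=np.array(subset_r), subset_size=subset_size
    )
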