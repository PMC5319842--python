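"""Data model for dense pilot time-series expression experiments.

A pilot experiment profiles a small panel of genes (typically 100-200) at a
high sampling rate -- tens of time points, a few repeats each -- so that a
much sparser design can be chosen for the expensive genome-wide follow-up.
This module holds the in-memory containers for such data, elementary
summaries (per-cell repeat means, the repeat-noise floor), the
variance/mean normalization used for count-style panels, the methylation
site filter, and delimited-text I/O.

Times are arbitrary strictly increasing reals measured in days; prenatal
ages are encoded as negative offsets relative to birth (e.g. E16.5 in mouse
-> -3.0 d).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimeGrid",
    "TimeSeriesDataset",
    "NoiseEstimate",
    "MethylationFilterReport",
    "mean_profile",
    "repeat_noise",
    "normalize_variance_mean",
    "filter_methylation_sites",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class TimeGrid:
    """The full set of sampled time points (days, strictly increasing)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1 or times.size < 3:
            raise ValueError("a time grid needs at least 3 points")
        if not np.all(np.isfinite(times)):
            raise ValueError("time grid contains non-finite values")
        if np.any(np.diff(times) <= 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def index_of(self, time: float) -> int:
        idx = int(np.argmin(np.abs(self.times - time)))
        if not np.isclose(self.times[idx], time):
            raise KeyError(f"time {time!r} is not on the grid")
        return idx

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeGrid):
            return NotImplemented
        return self.times.shape == other.times.shape and bool(
            np.allclose(self.times, other.times)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.times.tobytes())


class TimeSeriesDataset:
    """Genes x time points x repeats expression cube.

    ``values`` has shape (G, n, R_max); missing repeats are NaN (repeat
    counts may vary per time point).  Every (gene, time) cell must retain at
    least one observed repeat -- the method assumes a dense pilot grid.
    """

    def __init__(
        self,
        grid: TimeGrid,
        gene_ids: list[str],
        values: np.ndarray,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim == 2:
            values = values[:, :, None]
        if values.ndim != 3:
            raise ValueError("values must be a (genes, times, repeats) array")
        if len(gene_ids) != values.shape[0]:
            raise ValueError("gene_ids length does not match values")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene identifiers must be unique")
        if values.shape[1] != grid.n:
            raise ValueError("values second axis does not match the grid")
        observed = np.isfinite(values)
        if not observed.any(axis=2).all():
            raise ValueError("every (gene, time) cell needs >= 1 observed repeat")
        with np.errstate(invalid="ignore"):
            if not np.all(np.isfinite(values[observed])):
                raise ValueError("observed values must be finite")
        self.grid = grid
        self.gene_ids = list(gene_ids)
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- elementary summaries -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def max_repeats(self) -> int:
        return self.values.shape[2]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene identifier {gene!r}") from None

    def repeat_means(self) -> np.ndarray:
        """(G, n) per-(gene, time) mean over observed repeats."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=2)

    def repeat_counts(self) -> np.ndarray:
        """(G, n) number of observed repeats per cell."""
        return np.isfinite(self.values).sum(axis=2)

    def within_cell_ss(self) -> np.ndarray:
        """(G, n) sum of squared deviations of repeats from their cell mean."""
        means = self.repeat_means()
        dev = self.values - means[:, :, None]
        return np.nansum(dev**2, axis=2)

    def subset_genes(self, genes: list[str]) -> "TimeSeriesDataset":
        idx = [self.gene_index(g) for g in genes]
        return TimeSeriesDataset(self.grid, genes, self.values[idx])

    def copy(self) -> "TimeSeriesDataset":
        return TimeSeriesDataset(self.grid, list(self.gene_ids), self.values.copy())


@dataclass(frozen=True)
class NoiseEstimate:
    """Repeat-to-repeat variability: the floor for reconstruction error.

    ``overall`` is the mean squared deviation of repeats from their
    per-(gene, time) mean, weighted by measurement (the default convention);
    ``per_gene_mean`` averages the per-gene statistics instead.
    ``variance`` is the bias-corrected per-measurement noise variance
    sigma^2 (the within-cell SS divided by measurements minus cells), which
    is the irreducible expected MSE when predicting an unseen repeat.
    """

    overall: float
    per_time: np.ndarray
    per_gene_mean: float
    variance: float


def mean_profile(ds: TimeSeriesDataset, gene: str) -> np.ndarray:
    """Per-time repeat means for one gene (length = grid size)."""
    return ds.repeat_means()[ds.gene_index(gene)]


def repeat_noise(ds: TimeSeriesDataset) -> NoiseEstimate:
    """Estimate the repeat-noise floor from replicate scatter.

    Pools, over every (gene, time) cell, the squared deviations of repeats
    from the cell mean.  Cells with a single repeat contribute zero scatter
    but are counted, so the statistic estimates sigma^2 * (R-1)/R for R
    equal repeats; ``variance`` removes that bias.
    """
    counts = ds.repeat_counts()
    if not np.any(counts >= 2):
        raise ValueError("noise floor undefined: all cells have a single repeat")
    ss = ds.within_cell_ss()
    n_meas = counts.sum()
    overall = float(ss.sum() / n_meas)
    per_time = ss.sum(axis=0) / counts.sum(axis=0)
    per_gene = ss.sum(axis=1) / counts.sum(axis=1)
    variance = float(ss.sum() / (n_meas - counts.size))
    return NoiseEstimate(
        overall=overall,
        per_time=np.asarray(per_time, dtype=float),
        per_gene_mean=float(per_gene.mean()),
        variance=variance,
    )


def normalize_variance_mean(
    ds: TimeSeriesDataset,
) -> tuple[TimeSeriesDataset, list[str]]:
    """Center each gene by its grand mean and scale by its sd across time.

    Statistics are computed on per-time repeat means (population sd) and
    applied to all repeats, so normalized time-means have mean 0 and sd 1.
    Constant genes cannot be scaled; they are excluded with a warning and
    returned as the second element.
    """
    means = ds.repeat_means()
    center = means.mean(axis=1)
    scale = means.std(axis=1)  # population sd across time-means
    constant = scale <= 1e-12
    excluded = [g for g, c in zip(ds.gene_ids, constant) if c]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} constant gene(s) from normalization: "
            + ", ".join(excluded[:5]),
            stacklevel=2,
        )
    keep = ~constant
    if not keep.any():
        raise ValueError("no gene with nonzero temporal variance")
    values = (ds.values[keep] - center[keep, None, None]) / scale[keep, None, None]
    kept_ids = [g for g, c in zip(ds.gene_ids, constant) if not c]
    return TimeSeriesDataset(ds.grid, kept_ids, values), excluded


@dataclass
class MethylationFilterReport:
    """Which sites the methylation filter removed, and why."""

    removed: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            [{"site": s, "rule": r} for s, r in self.removed], indent=2
        )


def filter_methylation_sites(
    ds: TimeSeriesDataset,
    min_range: float = 5.0,
    jump: float = 20.0,
    min_nonzero: int = 3,
) -> tuple[TimeSeriesDataset, MethylationFilterReport]:
    """Drop uninformative or artifactual methylation sites.

    Values are methylation percentages in [0, 100], sites play the role of
    genes.  A site is removed when (first triggering rule is reported):

    * its range of time-means over the whole period is below ``min_range``;
    * a single interior time-mean exceeds both temporal neighbors by more
      than ``jump`` percentage points in the same direction (spike artifact);
    * it has fewer than ``min_nonzero`` non-zero time-means.
    """
    if np.nanmin(ds.values) < 0 or np.nanmax(ds.values) > 100:
        raise ValueError("methylation values must lie in [0, 100]")
    means = ds.repeat_means()
    report = MethylationFilterReport()
    keep: list[str] = []
    for g, gene in enumerate(ds.gene_ids):
        m = means[g]
        if m.max() - m.min() < min_range:
            report.removed.append((gene, "range_below_min"))
            continue
        interior = m[1:-1]
        spike = np.maximum(interior - m[:-2], 0) > jump
        dip = np.maximum(m[:-2] - interior, 0) > jump
        spike &= (interior - m[2:]) > jump
        dip &= (m[2:] - interior) > jump
        if np.any(spike | dip):
            report.removed.append((gene, "single_point_jump"))
            continue
        if np.count_nonzero(m) < min_nonzero:
            report.removed.append((gene, "too_few_nonzero"))
            continue
        keep.append(gene)
    filtered = ds.subset_genes(keep) if keep else None
    if filtered is None:
        raise ValueError("all sites removed by the methylation filter")
    return filtered, report


# -- delimited-text I/O -------------------------------------------------------

_WIDE_COL = re.compile(r"^t(-?\d+(?:\.\d+)?)_r(\d+)$")


def read_dataset(path: str) -> TimeSeriesDataset:
    """Read a dataset from delimited text (TSV or CSV, auto-detected).

    Two layouts are accepted: a wide table whose first column is the gene id
    and whose remaining columns are named ``t<time>_r<repeat>`` (e.g.
    ``t0.5_r1``), or a long table with columns (gene, time, repeat, value).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"gene", "time", "repeat", "value"}.issubset(cols):
        return _from_long(df)
    wide = [c for c in cols[1:] if _WIDE_COL.match(c)]
    if len(wide) != len(cols) - 1:
        bad = [c for c in cols[1:] if not _WIDE_COL.match(c)]
        raise ValueError(
            f"unrecognized column(s) {bad[:3]}: expected 't<time>_r<rep>' "
            "headers or a long (gene, time, repeat, value) table"
        )
    return _from_wide(df)


def _from_wide(df: pd.DataFrame) -> TimeSeriesDataset:
    gene_ids = df.iloc[:, 0].astype(str).tolist()
    parsed = [(_WIDE_COL.match(c).groups(), c) for c in df.columns[1:]]
    times = sorted({float(t) for (t, _r), _c in parsed})
    reps = sorted({int(r) for (_t, r), _c in parsed})
    t_idx = {t: i for i, t in enumerate(times)}
    r_idx = {r: i for i, r in enumerate(reps)}
    values = np.full((len(gene_ids), len(times), len(reps)), np.nan)
    for (t, r), col in parsed:
        values[:, t_idx[float(t)], r_idx[int(r)]] = df[col].to_numpy(float)
    return TimeSeriesDataset(TimeGrid(np.array(times)), gene_ids, values)


def _from_long(df: pd.DataFrame) -> TimeSeriesDataset:
    genes = df["gene"].astype(str)
    gene_ids = list(dict.fromkeys(genes))
    times = np.array(sorted(df["time"].astype(float).unique()))
    reps = sorted(df["repeat"].astype(int).unique())
    g_idx = {g: i for i, g in enumerate(gene_ids)}
    t_idx = {t: i for i, t in enumerate(times)}
    r_idx = {r: i for i, r in enumerate(reps)}
    values = np.full((len(gene_ids), len(times), len(reps)), np.nan)
    for g, t, r, v in zip(
        genes, df["time"].astype(float), df["repeat"].astype(int), df["value"]
    ):
        values[g_idx[g], t_idx[t], r_idx[r]] = float(v)
    return TimeSeriesDataset(TimeGrid(times), gene_ids, values)


def write_dataset(ds: TimeSeriesDataset, path: str) -> None:
    """Write a dataset as a wide delimited table (lossless round-trip)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    data = {"gene": ds.gene_ids}
    for t_i, t in enumerate(ds.grid.times):
        for r in range(ds.max_repeats):
            col = ds.values[:, t_i, r]
            if np.all(np.isnan(col)):
                continue
            data[f"t{t:g}_r{r + 1}"] = col
    pd.DataFrame(data).to_csv(path, sep=sep, index=False, na_rep="NA")
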