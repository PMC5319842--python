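import numpy as np
import pytest

from tpselect.data import TimeGrid, TimeSeriesDataset


def make_dataset(values, times=None, gene_ids=None):
    """Build a dataset from a (genes, times[, repeats]) array."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    n = values.shape[1]
    grid = TimeGrid(np.arange(float(n)) if times is None else np.asarray(times, float))
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    return TimeSeriesDataset(grid, gene_ids, values)


@pytest.fixture
def linear_gene_ds():
    """One noiseless linear gene, two identical repeats, 8 time points."""
    t = np.arange(8.0)
    vals = np.stack([2.0 * t + 1.0, 2.0 * t + 1.0], axis=-1)[None, :, :]
    return make_dataset(vals, times=t)


@pytest.fixture
def small_noisy_ds():
    """Deterministic small dataset with visible temporal structure."""
    rng = np.random.default_rng(42)
    t = np.arange(12.0)
    curves = np.stack(
        [np.tanh(t - 4.0), np.sin(t / 3.0), 0.3 * t / 11.0, 1.0 / (1 + np.exp(6 - t))]
    )
    vals = curves[:, :, None] + rng.normal(0, 0.1, size=(4, 12, 2))
    return make_dataset(vals, times=t)
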