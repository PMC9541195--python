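import numpy as np
import pytest
from hypothesis import settings

from kelpsync.data_io import LocationInfo, QuarterlySeriesMatrix, quarter_range
from kelpsync.wavelets import WaveletSet, coi_mask_for, make_timescale_grid

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_matrix(values, start=(1990, 1), name="biomass", units="kg"):
    """Quarterly matrix with synthetic location metadata."""
    values = np.asarray(values, dtype=float)
    n, T = values.shape
    axis = quarter_range(start, _advance(start, T - 1))
    locs = [LocationInfo(f"L{i}", 36.0 - 0.1 * i, -121.0) for i in range(n)]
    return QuarterlySeriesMatrix(values, axis, name, units, locs)


def _advance(tq, k):
    y, q = tq
    for _ in range(k):
        y, q = (y, q + 1) if q < 4 else (y + 1, 1)
    return (y, q)


def white_noise_set(n, T, seed, normalised=True):
    """Power-normalised wavelet set of iid Gaussian series."""
    from kelpsync.preprocess import CleaningOptions, clean_series
    from kelpsync.wavelets import normalize_power, transform_set

    rng = np.random.default_rng(seed)
    m = make_matrix(rng.standard_normal((n, T)))
    cleaned = clean_series(m, CleaningOptions(marginal_transform="none", detrend_degree=0))
    w = transform_set(cleaned, make_timescale_grid(T))
    return normalize_power(w) if normalised else w


def synthetic_waveset(coeffs, T=None, normalised=True):
    """Wrap a raw complex coefficient array [n x S x T] as a WaveletSet on a
    matching grid/mask (for small constructed regression instances)."""
    coeffs = np.asarray(coeffs, dtype=complex)
    n, S, T_ = coeffs.shape
    grid = make_timescale_grid(max(T_, 8))
    # regrid to exactly S timescales by truncating
    from kelpsync.wavelets import TimescaleGrid

    ts = grid.timescales[:S]
    grid = TimescaleGrid(ts, grid.spacing_factor, grid.min_ts, float(ts[-1]))
    mask = coi_mask_for(grid, T_)
    return WaveletSet(coeffs, grid, mask, normalised=normalised)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
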