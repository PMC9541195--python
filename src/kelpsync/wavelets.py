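"""Continuous Morlet wavelet transform on a common geometric timescale
grid, with cone-of-influence masking and power normalisation.

Conventions
-----------
The transform of a length-T series x is

    W(s, t) = s^{-1/2} * sum_u x(u) * k((u - t) / s),
    k(eta)  = pi^{-1/4} * exp(+i * 2*pi*f0 * eta) * exp(-eta^2 / 2),

with central frequency f0 = 1 so a timescale s corresponds to a Fourier
period of ~0.99 s (timescales are quoted directly as periods in timestep
units).  The kernel's sign convention is chosen so that a response lagging
its driver by L timesteps carries a regression-coefficient phase of
+2*pi*L/s: positive phases mean "response lags driver", matching how phase
shifts are reported downstream.

Coefficients within ``coi_factor * s`` (default sqrt(2), the e-folding
distance of the Gaussian envelope) of either series end are masked out and
excluded from every downstream average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CleanedMatrix

__all__ = [
    "TimescaleGrid",
    "WaveletSet",
    "make_timescale_grid",
    "morlet_kernel",
    "morlet_transform",
    "transform_set",
    "normalize_power",
]

COI_FACTOR = float(np.sqrt(2.0))


@dataclass(frozen=True)
class TimescaleGrid:
    """Geometric sequence of timescales (periods) in timestep units."""

    timescales: np.ndarray
    spacing_factor: float
    min_ts: float
    max_ts: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timescales, dtype=float)
        object.__setattr__(self, "timescales", ts)
        if len(ts) == 0:
            raise ValueError("empty timescale grid")
        ratios = ts[1:] / ts[:-1]
        if len(ratios) and np.any(np.abs(ratios - self.spacing_factor) > 1e-12 * self.spacing_factor):
            raise ValueError("timescales are not geometric with the stated spacing_factor")

    def __len__(self) -> int:
        return len(self.timescales)

    def in_years(self, quarters_per_year: int = 4) -> np.ndarray:
        return self.timescales / quarters_per_year


@dataclass
class WaveletSet:
    """Complex wavelet coefficients for a set of locations sharing one
    grid and cone-of-influence mask.

    coefficients : complex array [n locations x S timescales x T times]
    coi_mask     : boolean [S x T]; True = usable (outside edge influence)
    """

    coefficients: np.ndarray
    grid: TimescaleGrid
    coi_mask: np.ndarray
    normalised: bool = False
    locations: list | None = None

    @property
    def n_locations(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[2]

    def subset_locations(self, keep) -> "WaveletSet":
        keep = list(keep)
        return WaveletSet(
            coefficients=self.coefficients[keep],
            grid=self.grid,
            coi_mask=self.coi_mask,
            normalised=self.normalised,
            locations=[self.locations[i] for i in keep] if self.locations is not None else None,
        )


def make_timescale_grid(
    T: int,
    min_ts: float = 2.0,
    max_ts: float | None = None,
    spacing_factor: float = 1.05,
) -> TimescaleGrid:
    """Geometric timescale grid from ``min_ts`` (default the Nyquist period,
    2 timesteps) up to the largest multiple of ``spacing_factor`` not
    exceeding ``max_ts`` (default T/2)."""
    if T < 8:
        raise ValueError("need T >= 8")
    if max_ts is None:
        max_ts = T / 2.0
    if not spacing_factor > 1:
        raise ValueError("spacing_factor must exceed 1")
    if min_ts >= max_ts:
        raise ValueError(f"min_ts ({min_ts}) must be below max_ts ({max_ts})")
    n = int(np.floor(np.log(max_ts / min_ts) / np.log(spacing_factor))) + 1
    ts = min_ts * spacing_factor ** np.arange(n)
    # guard against floating-point overshoot of max_ts
    ts = ts[ts <= max_ts * (1 + 1e-12)]
    return TimescaleGrid(ts, spacing_factor, float(min_ts), float(max_ts))


def morlet_kernel(eta: np.ndarray, f0: float = 1.0) -> np.ndarray:
    """Morlet kernel k(eta); see module docstring for the sign convention."""
    eta = np.asarray(eta, dtype=float)
    return np.pi ** -0.25 * np.exp(1j * 2.0 * np.pi * f0 * eta) * np.exp(-0.5 * eta**2)


def coi_mask_for(grid: TimescaleGrid, T: int, coi_factor: float = COI_FACTOR) -> np.ndarray:
    """True where the distance to the nearer series end is at least
    ``coi_factor * s``."""
    t = np.arange(T)
    dist = np.minimum(t, T - 1 - t)
    return dist[None, :] >= coi_factor * grid.timescales[:, None]


def morlet_transform(
    x: np.ndarray,
    grid: TimescaleGrid,
    f0: float = 1.0,
    coi_factor: float = COI_FACTOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet transform of one complete series.

    Returns (coefficients [S x T], coi_mask [S x T]).  The transform is the
    exact direct sum over all samples (vectorised as one kernel-matrix
    product per timescale); no truncation or zero-padding is applied.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("input series contains non-finite values")
    coeffs, mask = _transform_rows(x[None, :], grid, f0, coi_factor)
    return coeffs[0], mask


def _kernel_stack(grid: TimescaleGrid, T: int, f0: float) -> np.ndarray:
    """K[s] is the T x T matrix with K[s][u, t] = s^{-1/2} k((u-t)/s)."""
    u = np.arange(T, dtype=float)
    lag = u[:, None] - u[None, :]  # (u - t)
    K = np.empty((len(grid), T, T), dtype=complex)
    for si, s in enumerate(grid.timescales):
        K[si] = s**-0.5 * morlet_kernel(lag / s, f0)
    return K


def _transform_rows(
    rows: np.ndarray, grid: TimescaleGrid, f0: float, coi_factor: float
) -> tuple[np.ndarray, np.ndarray]:
    n, T = rows.shape
    K = _kernel_stack(grid, T, f0)
    # coeffs[i, si, t] = sum_u rows[i, u] K[si, u, t]
    coeffs = np.einsum("iu,sut->ist", rows, K, optimize=True)
    return coeffs, coi_mask_for(grid, T, coi_factor)


def transform_set(
    m: CleanedMatrix,
    grid: TimescaleGrid,
    f0: float = 1.0,
    coi_factor: float = COI_FACTOR,
) -> WaveletSet:
    """Transform every location of a cleaned matrix onto the shared grid."""
    if not np.all(np.isfinite(m.values)):
        raise ValueError("cleaned matrix contains non-finite values")
    coeffs, mask = _transform_rows(m.values, grid, f0, coi_factor)
    if not mask.any():
        raise ValueError("cone of influence masks out every coefficient; series too short for this grid")
    return WaveletSet(coeffs, grid, mask, normalised=False, locations=list(m.locations))


def normalize_power(w: WaveletSet) -> WaveletSet:
    """Divide each location's coefficients by the square root of its mean
    squared modulus over all masked-in (timescale, time) cells, so every
    location contributes unit average power.  Relative power between
    timescales within a location is preserved."""
    if w.normalised:
        raise ValueError("WaveletSet is already normalised")
    mask = w.coi_mask
    power = np.abs(w.coefficients) ** 2
    mean_power = power[:, mask].mean(axis=1)
    if np.any(mean_power <= 0):
        bad = int(np.argmin(mean_power))
        raise ValueError(f"location index {bad} has zero total wavelet power")
    scaled = w.coefficients / np.sqrt(mean_power)[:, None, None]
    return WaveletSet(scaled, w.grid, w.coi_mask, normalised=True, locations=w.locations)
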