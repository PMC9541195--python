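"""Per-location series cleaning: gap interpolation, optional Box-Cox
marginal normalisation, polynomial detrending, and z-scoring.

The wavelet statistics downstream assume complete, roughly stationary,
zero-mean unit-variance series per location; this module produces them and
records the per-location transform parameters (provenance) so a run can be
audited or reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import QuarterlySeriesMatrix

__all__ = ["CleaningOptions", "CleanedMatrix", "impute_missing", "clean_series", "clean_index"]

# Box-Cox lambda is selected on a fixed grid so results are exactly
# reproducible across SciPy versions.
_BOXCOX_LAMBDA_GRID = np.round(np.arange(-1.0, 2.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class CleaningOptions:
    """Switches for :func:`clean_series`.

    detrend_degree : polynomial degree removed by least squares (>= 0).
    standardise    : scale each residual series to mean 0, variance 1.
    marginal_transform : "none" or "box_cox_optimal" (grid-searched lambda).
    zero_offset    : constant added before the power transform when zeros
        are present; None = half the smallest positive value per location.
    """

    detrend_degree: int = 1
    standardise: bool = True
    marginal_transform: str = "box_cox_optimal"
    zero_offset: float | None = None

    def __post_init__(self) -> None:
        if self.detrend_degree < 0:
            raise ValueError("detrend_degree must be >= 0")
        if self.marginal_transform not in ("none", "box_cox_optimal"):
            raise ValueError(f"unknown marginal_transform {self.marginal_transform!r}")


@dataclass
class CleanedMatrix:
    """Complete, cleaned locations x quarters matrix plus provenance."""

    values: np.ndarray
    time_axis: list[tuple[int, int]]
    variable_name: str
    locations: list
    options: CleaningOptions
    boxcox_lambda: list[float | None] = field(default_factory=list)
    trend_coefficients: list[np.ndarray] = field(default_factory=list)

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_quarters(self) -> int:
        return self.values.shape[1]


def _interpolate_one(x: np.ndarray, max_run: int, label: str) -> np.ndarray:
    miss = np.isnan(x)
    if not miss.any():
        return x.copy()
    if miss[0] or miss[-1]:
        raise ValueError(f"location {label!r}: missing value at series endpoint")
    # locate runs of consecutive missing values
    idx = np.flatnonzero(miss)
    run_start = idx[np.r_[True, np.diff(idx) > 1]]
    run_end = idx[np.r_[np.diff(idx) > 1, True]]
    for a, b in zip(run_start, run_end):
        if b - a + 1 > max_run:
            raise ValueError(
                f"location {label!r}: missing run of length {b - a + 1} exceeds max_run={max_run}"
            )
    out = x.copy()
    obs = np.flatnonzero(~miss)
    out[miss] = np.interp(np.flatnonzero(miss), obs, x[obs])
    return out


def impute_missing(m: QuarterlySeriesMatrix, max_run: int = 4) -> QuarterlySeriesMatrix:
    """Fill missing cells by linear interpolation between the nearest
    observed neighbours.  Runs longer than ``max_run`` or missing endpoints
    raise, naming the location."""
    filled = np.empty_like(m.values)
    for i, loc in enumerate(m.locations):
        filled[i] = _interpolate_one(m.values[i], max_run, loc.location_id)
    return QuarterlySeriesMatrix(filled, list(m.time_axis), m.variable_name, m.units, list(m.locations))


def _boxcox_grid(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda maximising the normal log-likelihood
    over a fixed grid [-1, 2] step 0.01.  Requires x > 0."""
    lls = np.array([stats.boxcox_llf(l, x) for l in _BOXCOX_LAMBDA_GRID])
    lam = float(_BOXCOX_LAMBDA_GRID[int(np.argmax(lls))])
    return stats.boxcox(x, lmbda=lam), lam


def _clean_one(
    x: np.ndarray, opts: CleaningOptions, label: str
) -> tuple[np.ndarray, float | None, np.ndarray]:
    if np.isnan(x).any():
        raise ValueError(f"location {label!r}: series has missing values; impute first")
    lam: float | None = None
    if opts.marginal_transform == "box_cox_optimal":
        offset = 0.0
        if np.any(x <= 0):
            if opts.zero_offset is not None:
                offset = opts.zero_offset
            else:
                pos = x[x > 0]
                if len(pos) == 0:
                    raise ValueError(f"location {label!r}: no positive values for Box-Cox")
                offset = 0.5 * float(pos.min())
            offset += max(0.0, -float(x.min()))  # guard against negatives
        x, lam = _boxcox_grid(x + offset)
    t = np.arange(len(x), dtype=float)
    # orthonormal polynomial basis for a numerically stable detrend
    basis = np.polynomial.polynomial.polyvander(
        2.0 * t / (len(x) - 1) - 1.0, opts.detrend_degree
    )
    coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
    resid = x - basis @ coef
    if opts.standardise:
        sd = resid.std()
        scale = max(1.0, float(np.abs(x).max()))
        if not np.isfinite(sd) or sd <= 1e-10 * scale:
            raise ValueError(f"location {label!r}: zero variance after detrending")
        resid = (resid - resid.mean()) / sd
    return resid, lam, coef


def clean_series(m: QuarterlySeriesMatrix, opts: CleaningOptions | None = None) -> CleanedMatrix:
    """Clean every location's series: optional Box-Cox (grid-optimal
    lambda), polynomial detrend, then centre/scale to unit variance."""
    opts = opts or CleaningOptions()
    out = np.empty_like(m.values)
    lams: list[float | None] = []
    coefs: list[np.ndarray] = []
    for i, loc in enumerate(m.locations):
        out[i], lam, coef = _clean_one(m.values[i].astype(float), opts, loc.location_id)
        lams.append(lam)
        coefs.append(coef)
    return CleanedMatrix(
        values=out,
        time_axis=list(m.time_axis),
        variable_name=m.variable_name,
        locations=list(m.locations),
        options=opts,
        boxcox_lambda=lams,
        trend_coefficients=coefs,
    )


def clean_index(values: np.ndarray, opts: CleaningOptions | None = None) -> np.ndarray:
    """Clean a single non-spatial series with the same recipe (climate
    indices are already roughly symmetric, so the default skips Box-Cox)."""
    opts = opts or CleaningOptions(marginal_transform="none")
    cleaned, _, _ = _clean_one(np.asarray(values, dtype=float), opts, "index")
    return cleaned
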