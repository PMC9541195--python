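"""Mean-field synchrony statistics and the phase-synchrony significance
test.

Two mean fields are used.  The wavelet mean field (WMF) averages the
(power-normalised) complex transforms across locations; its squared modulus
is near 1 when locations fluctuate in phase with comparable amplitude and
near 0 when they do not.  The wavelet phasor mean field (WPMF) averages
unit-modulus phasors instead, measuring pure phase agreement regardless of
amplitude.  Time-averaging the squared modulus gives the mean squared
synchrony profile per timescale, which is summarised over timescale bands
(annual < 2 y, short interannual 2-4 y, long interannual 4-10 y).

Phase synchrony is tested against the null hypothesis of unsynchronised
phases: every location-phasor replaced by exp(i*U), U ~ Uniform(0, 2*pi)
iid.  Under this null the mean-field modulus has the same distribution at
every (timescale, time) cell, so one Monte-Carlo pool of surrogate moduli
is drawn per call and each observed cell is ranked against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelets import TimescaleGrid, WaveletSet

__all__ = [
    "MeanField",
    "SynchronyProfile",
    "BandDef",
    "STANDARD_BANDS",
    "SignificanceField",
    "wavelet_mean_field",
    "wavelet_phasor_mean_field",
    "wpmf_significance",
    "mean_squared_synchrony",
    "band_average",
    "band_indices",
]


@dataclass
class MeanField:
    """Timescales x times complex field; kind is "wmf" or "wpmf"."""

    values: np.ndarray
    kind: str
    n_locations: int
    coi_mask: np.ndarray
    grid: TimescaleGrid


@dataclass
class SynchronyProfile:
    """Per-timescale time-averaged squared mean-field modulus.  NaN where a
    timescale has no masked-in times."""

    values: np.ndarray
    grid: TimescaleGrid
    kind: str


@dataclass(frozen=True)
class BandDef:
    """A timescale band in years.  Membership is half-open [min, max),
    except that ``closed_max=True`` makes the upper edge inclusive (used for
    the top band so the bands partition the grid)."""

    name: str
    min_period_years: float
    max_period_years: float
    quarters_per_year: int = 4
    closed_max: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_period_years < self.max_period_years:
            raise ValueError(f"band {self.name!r}: need 0 < min < max period")

    def contains(self, timescale: np.ndarray) -> np.ndarray:
        years = np.asarray(timescale, dtype=float) / self.quarters_per_year
        hi = years <= self.max_period_years if self.closed_max else years < self.max_period_years
        return (years >= self.min_period_years) & hi


#: Annual, short-interannual and long-interannual bands; together they
#: partition periods of 0.5-10 years (2-40 quarters).
STANDARD_BANDS = [
    BandDef("annual", 0.5, 2.0),
    BandDef("short_interannual", 2.0, 4.0),
    BandDef("long_interannual", 4.0, 10.0, closed_max=True),
]


@dataclass
class SignificanceField:
    """Per-cell p-values for the phase-synchrony test (NaN off-mask)."""

    p_values: np.ndarray
    n_surrogates: int
    seed: int


def wavelet_mean_field(w: WaveletSet) -> MeanField:
    """Across-location mean of normalised transforms at every cell."""
    if not w.normalised:
        raise ValueError("wavelet_mean_field requires a power-normalised WaveletSet")
    return MeanField(
        values=w.coefficients.mean(axis=0),
        kind="wmf",
        n_locations=w.n_locations,
        coi_mask=w.coi_mask,
        grid=w.grid,
    )


def _phasors(coefficients: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit phasors with zero-modulus cells dropped (returned count per
    cell).  Zero coefficients only occur on degenerate inputs."""
    mod = np.abs(coefficients)
    ok = mod > 0
    phasors = np.where(ok, coefficients / np.where(ok, mod, 1.0), 0.0)
    counts = ok.sum(axis=0)
    return phasors, counts


def wavelet_phasor_mean_field(w: WaveletSet) -> MeanField:
    """Across-location mean of unit-modulus phasors; amplitude-blind."""
    if w.n_locations < 2:
        raise ValueError("wavelet_phasor_mean_field requires at least 2 locations")
    phasors, counts = _phasors(w.coefficients)
    with np.errstate(invalid="ignore"):
        values = phasors.sum(axis=0) / np.where(counts > 0, counts, np.nan)
    return MeanField(values, "wpmf", w.n_locations, w.coi_mask, w.grid)


def wpmf_significance(
    w: WaveletSet, n_surrogates: int = 10_000, seed: int | None = None
) -> SignificanceField:
    """Rank the observed phasor-mean-field modulus at every masked-in cell
    against ``n_surrogates`` draws of the unsynchronised-phases null.

    p(s, t) = (1 + #{surrogate modulus >= observed}) / (n_surrogates + 1),
    so the smallest attainable p is 1/(n_surrogates + 1).  The seed fully
    determines the output.
    """
    if n_surrogates < 99:
        raise ValueError("n_surrogates must be at least 99 for usable resolution")
    if seed is None:
        raise ValueError("a seed is required: the test is Monte-Carlo")
    field = wavelet_phasor_mean_field(w)
    observed = np.abs(field.values)

    rng = np.random.default_rng(seed)
    n = w.n_locations
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, n))
    null_moduli = np.abs(np.exp(1j * phases).mean(axis=1))
    null_sorted = np.sort(null_moduli)

    # #{null >= obs} via binary search on the sorted pool
    n_ge = n_surrogates - np.searchsorted(null_sorted, observed, side="left")
    p = (1.0 + n_ge) / (n_surrogates + 1.0)
    p = np.where(w.coi_mask & np.isfinite(observed), p, np.nan)
    return SignificanceField(p, n_surrogates, seed)


def mean_squared_synchrony(f: MeanField) -> SynchronyProfile:
    """Time average of the squared mean-field modulus at each timescale,
    over masked-in times only; NaN where a timescale row is fully masked."""
    sq = np.abs(f.values) ** 2
    mask = f.coi_mask & np.isfinite(sq)
    counts = mask.sum(axis=1)
    sums = np.where(mask, sq, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SynchronyProfile(prof, f.grid, f.kind)


def band_indices(grid: TimescaleGrid, band: BandDef) -> np.ndarray:
    idx = np.flatnonzero(band.contains(grid.timescales))
    if len(idx) == 0:
        raise ValueError(f"no grid timescales fall in band {band.name!r}")
    return idx


def band_average(profile: SynchronyProfile, band: BandDef) -> float:
    """Unweighted mean of the profile over grid timescales in the band."""
    idx = band_indices(profile.grid, band)
    vals = profile.values[idx]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError(f"band {band.name!r} has no usable (unmasked) timescales")
    return float(vals.mean())
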