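"""Multivariate wavelet linear models and synchrony attribution.

For each timescale s independently, the complex coefficient vector beta(s)
solves the pooled least-squares problem

    min_beta  sum over masked-in (i, t) of
              | Y_i(s,t) - sum_k beta_k(s) X_{k,i}(s,t) |^2,

where Y and X_k are power-normalised wavelet transforms of the response and
predictor fields over a common set of locations.  Coefficients are shared
across locations and times within a timescale, so each predictor gets one
magnitude (strength of association) and one phase (temporal lag of
association) per timescale.

The synchrony explained by the model decomposes exactly.  Writing MF_k for
predictor k's mean field and P_k(s) = mean_t |MF_k(s,t)|^2:

    S_k(s)   = |beta_k(s)|^2 * P_k(s)                    (main effects, >= 0)
    S_int(s) = sum_{k<l} 2 Re( beta_k conj(beta_l) * mean_t MF_k conj(MF_l) )
    S_mod(s) = sum_k S_k(s) + S_int(s) = mean_t |model mean field|^2.

Band-level fractions q are ratios of band-averaged numerators to the
band-averaged observed mean squared synchrony, so q_all = sum_k q_k + q_int
holds to machine precision by construction.  Positive interaction terms are
synergistic (drivers' spatially shared effects reinforce), negative terms
antagonistic.  A predictor's phase phi_k (in fractions of pi) is the
attribution-power-weighted circular mean of arg beta_k over the band's
timescales; phi > 0 means the attributed response lags the driver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import IndexSeries
from .preprocess import CleaningOptions, clean_index
from .synchrony import (
    BandDef,
    MeanField,
    SynchronyProfile,
    band_indices,
    mean_squared_synchrony,
    wavelet_mean_field,
)
from .wavelets import WaveletSet, _transform_rows

__all__ = [
    "WLMFit",
    "AttributionTable",
    "CollinearPredictorsError",
    "fit_wlm",
    "predicted_synchrony",
    "attribute_synchrony",
    "coefficient_phase",
    "coherence",
    "index_coherence_model",
]


class CollinearPredictorsError(np.linalg.LinAlgError):
    pass


@dataclass
class WLMFit:
    """Fitted wavelet linear model for one region."""

    coefficients: np.ndarray  # [K predictors x S timescales], complex
    response_meanfield: MeanField
    predictor_meanfields: list[MeanField]
    model_meanfield: MeanField
    residual_power: np.ndarray  # per timescale, mean |residual|^2
    predictor_names: list[str]
    region: str | None = None

    @property
    def n_predictors(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class AttributionTable:
    """Per (region, band) synchrony-attribution results.

    Each row holds q values as fractions of observed synchrony (1.0 = 100%)
    and per-predictor phases in fractions of pi.
    """

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @staticmethod
    def concat(tables: Sequence["AttributionTable"]) -> "AttributionTable":
        out = AttributionTable()
        for t in tables:
            out.rows.extend(t.rows)
        return out


def _resolve_subset(w: WaveletSet, region_subset) -> list[int]:
    if region_subset is None:
        return list(range(w.n_locations))
    if isinstance(region_subset, str):
        if w.locations is None:
            raise ValueError("region subset by name requires location metadata on the WaveletSet")
        idx = [i for i, loc in enumerate(w.locations) if loc.region == region_subset]
        if not idx:
            raise ValueError(f"no locations in region {region_subset!r}")
        return idx
    return list(region_subset)


def _check_aligned(y: WaveletSet, X: Sequence[WaveletSet]) -> None:
    for k, x in enumerate(X):
        if x.coefficients.shape != y.coefficients.shape:
            raise ValueError(f"predictor {k} shape differs from response")
        if not np.array_equal(x.coi_mask, y.coi_mask):
            raise ValueError(f"predictor {k} mask differs from response")
        if len(x.grid) != len(y.grid) or np.any(np.abs(x.grid.timescales - y.grid.timescales) > 1e-9):
            raise ValueError(f"predictor {k} grid differs from response")


def fit_wlm(
    y: WaveletSet,
    X: Sequence[WaveletSet],
    region_subset=None,
    predictor_names: Sequence[str] | None = None,
    rcond: float = 1e-10,
) -> WLMFit:
    """Fit the per-timescale pooled complex least-squares model.

    All sets must be power-normalised, share grid, mask and locations;
    ``region_subset`` restricts to a region label or explicit location
    indices before fitting.  Raises :class:`CollinearPredictorsError` when
    the predictor cross-product is rank-deficient at any timescale.
    """
    if not y.normalised or any(not x.normalised for x in X):
        raise ValueError("fit_wlm requires power-normalised wavelet sets")
    if len(X) < 1:
        raise ValueError("need at least one predictor")
    _check_aligned(y, X)

    subset = _resolve_subset(y, region_subset)
    y = y.subset_locations(subset)
    X = [x.subset_locations(subset) for x in X]
    region = region_subset if isinstance(region_subset, str) else None
    names = list(predictor_names) if predictor_names else [f"x{k + 1}" for k in range(len(X))]

    K = len(X)
    S, T = y.coefficients.shape[1:]
    mask = y.coi_mask
    beta = np.zeros((K, S), dtype=complex)
    resid_power = np.full(S, np.nan)

    for si in range(S):
        cols = np.flatnonzero(mask[si])
        if len(cols) == 0:
            continue
        # design matrix: rows are (location, time) cells
        D = np.stack([x.coefficients[:, si, cols].ravel() for x in X], axis=1)
        yv = y.coefficients[:, si, cols].ravel()
        A = D.conj().T @ D
        b = D.conj().T @ yv
        sv = np.linalg.svd(A, compute_uv=False)
        if sv[-1] <= rcond * sv[0]:
            raise CollinearPredictorsError(
                f"predictors are collinear at timescale {y.grid.timescales[si]:.3f} timesteps"
            )
        beta[:, si] = np.linalg.solve(A, b)
        resid = yv - D @ beta[:, si]
        resid_power[si] = float(np.mean(np.abs(resid) ** 2))

    mf_y = wavelet_mean_field(y)
    mf_X = [wavelet_mean_field(x) for x in X]
    model_vals = np.zeros_like(mf_y.values)
    for k in range(K):
        model_vals += beta[k][:, None] * mf_X[k].values
    mf_model = MeanField(model_vals, "wmf", y.n_locations, y.coi_mask, y.grid)

    return WLMFit(
        coefficients=beta,
        response_meanfield=mf_y,
        predictor_meanfields=mf_X,
        model_meanfield=mf_model,
        residual_power=resid_power,
        predictor_names=names,
        region=region,
    )


def predicted_synchrony(fit: WLMFit) -> SynchronyProfile:
    """Mean squared synchrony of the model mean field."""
    return mean_squared_synchrony(fit.model_meanfield)


def _masked_time_mean(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-timescale mean over masked-in times; NaN for empty rows."""
    counts = mask.sum(axis=1)
    sums = np.where(mask, values, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def attribution_terms(fit: WLMFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-timescale main-effect terms S_k [K x S] and interaction term
    S_int [S] of the model's mean squared synchrony."""
    K, S = fit.coefficients.shape
    mask = fit.model_meanfield.coi_mask
    MF = [mf.values for mf in fit.predictor_meanfields]
    S_k = np.empty((K, S))
    for k in range(K):
        P_k = _masked_time_mean(np.abs(MF[k]) ** 2, mask)
        S_k[k] = np.abs(fit.coefficients[k]) ** 2 * P_k
    S_int = np.zeros(S)
    for k in range(K):
        for l in range(k + 1, K):
            cross = _masked_time_mean((MF[k] * np.conj(MF[l])).real, mask) + 1j * _masked_time_mean(
                (MF[k] * np.conj(MF[l])).imag, mask
            )
            S_int += 2.0 * (fit.coefficients[k] * np.conj(fit.coefficients[l]) * cross).real
    return S_k, S_int


def coefficient_phase(fit: WLMFit, band: BandDef) -> np.ndarray:
    """Per-predictor band phase phi_k in fractions of pi, in (-1, 1].

    The circular mean of the unit coefficient phasors over the band's
    timescales, weighted by the attribution power S_k(s) so timescales that
    contribute nothing to explained synchrony do not move the phase.
    Returns NaN for a predictor whose coefficients vanish across the band.
    """
    S_k, _ = attribution_terms(fit)
    idx = band_indices(fit.model_meanfield.grid, band)
    phis = np.full(fit.n_predictors, np.nan)
    for k in range(fit.n_predictors):
        b = fit.coefficients[k, idx]
        w = S_k[k, idx]
        ok = (np.abs(b) > 0) & np.isfinite(w)
        if not ok.any() or np.nansum(w[ok]) == 0:
            continue
        mean_phasor = np.sum(w[ok] * b[ok] / np.abs(b[ok]))
        if np.abs(mean_phasor) > 0:
            phis[k] = float(np.angle(mean_phasor) / np.pi)
    return phis


def attribute_synchrony(
    fit: WLMFit,
    observed: SynchronyProfile,
    bands: Sequence[BandDef],
    region: str | None = None,
) -> AttributionTable:
    """Band-level attribution of observed synchrony to the fitted model.

    q values are ratios of band-averaged attribution terms to the
    band-averaged observed profile (ratio of means, which preserves
    q_all = sum_k q_k + q_int exactly).  Raises when a band's observed mean
    synchrony is zero (fraction undefined).
    """
    if len(observed.values) != len(fit.model_meanfield.grid):
        raise ValueError("observed profile and fit are on different grids")
    S_k, S_int = attribution_terms(fit)
    region = region if region is not None else fit.region
    table = AttributionTable()
    for band in bands:
        idx = band_indices(observed.grid, band)
        ok = np.isfinite(observed.values[idx])
        if not ok.any():
            raise ValueError(f"band {band.name!r}: no usable timescales in observed profile")
        idx = idx[ok]
        denom = float(observed.values[idx].mean())
        if denom == 0:
            raise ValueError(f"band {band.name!r}: observed synchrony is zero; q undefined")
        q_k = S_k[:, idx].mean(axis=1) / denom
        q_int = float(S_int[idx].mean()) / denom
        phis = coefficient_phase(fit, band)
        row: dict = {
            "region": region,
            "band": band.name,
            "q_all": float(q_k.sum() + q_int),
        }
        for k, name in enumerate(fit.predictor_names):
            row[f"q_{name}"] = float(q_k[k])
            row[f"phi_{name}"] = float(phis[k]) if np.isfinite(phis[k]) else np.nan
        row["q_int"] = q_int
        table.rows.append(row)
    return table


def coherence(y: WaveletSet, x: WaveletSet) -> np.ndarray:
    """Per-timescale complex coherence between two wavelet sets:
    mean(Y conj X) / sqrt(mean |Y|^2 * mean |X|^2) over masked (i, t).
    Modulus lies in [0, 1]; the phase carries the lag of y behind x."""
    _check_aligned(y, [x])
    mask = y.coi_mask
    S = len(y.grid)
    out = np.full(S, np.nan, dtype=complex)
    for si in range(S):
        cols = np.flatnonzero(mask[si])
        if len(cols) == 0:
            continue
        Y = y.coefficients[:, si, cols].ravel()
        Xv = x.coefficients[:, si, cols].ravel()
        py = np.mean(np.abs(Y) ** 2)
        px = np.mean(np.abs(Xv) ** 2)
        if py == 0 or px == 0:
            raise ValueError(f"zero power at timescale {y.grid.timescales[si]:.3f}")
        out[si] = np.mean(Y * np.conj(Xv)) / np.sqrt(py * px)
    return out


def index_coherence_model(
    y: WaveletSet,
    idx: IndexSeries,
    bands: Sequence[BandDef],
    cleaning: CleaningOptions | None = None,
    region: str | None = None,
) -> tuple[WLMFit, AttributionTable]:
    """Single-predictor wavelet model of a spatial response against one
    non-spatial index series (e.g. a climate index).

    The index is cleaned once, transformed on the response's grid,
    replicated across the response's locations, power-normalised, and fed
    through :func:`fit_wlm` and :func:`attribute_synchrony` (K=1, so
    q_int = 0 identically).
    """
    if not y.normalised:
        raise ValueError("response set must be power-normalised")
    if len(idx.values) != y.n_times:
        raise ValueError("index length does not match response time axis")
    cleaned = clean_index(idx.values, cleaning)
    coeffs, _ = _transform_rows(cleaned[None, :], y.grid, f0=1.0, coi_factor=np.inf)
    # replicate across locations on the response's own mask
    rep = np.repeat(coeffs, y.n_locations, axis=0)
    xset = WaveletSet(rep, y.grid, y.coi_mask, normalised=False, locations=y.locations)
    from .wavelets import normalize_power

    xset = normalize_power(xset)
    fit = fit_wlm(y, [xset], predictor_names=[idx.name], region_subset=None)
    fit.region = region
    observed = mean_squared_synchrony(wavelet_mean_field(y))
    return fit, attribute_synchrony(fit, observed, bands, region=region)
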