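"""Wavelet linear models, synchrony attribution, coefficient phases,
coherence and the single-index model."""

import numpy as np
import pytest

from kelpsync.data_io import IndexSeries
from kelpsync.preprocess import CleaningOptions, clean_series
from kelpsync.synchrony import (
    STANDARD_BANDS,
    BandDef,
    mean_squared_synchrony,
    wavelet_mean_field,
)
from kelpsync.wavelets import make_timescale_grid, normalize_power, transform_set
from kelpsync.wlm import (
    CollinearPredictorsError,
    attribute_synchrony,
    coefficient_phase,
    coherence,
    fit_wlm,
    index_coherence_model,
    predicted_synchrony,
)

from conftest import make_matrix, synthetic_waveset, white_noise_set


def _noise_sets(n, T, K, seed):
    y = white_noise_set(n, T, seed)
    X = [white_noise_set(n, T, seed + 10 * (k + 1)) for k in range(K)]
    return y, X


class TestFitWlm:
    def test_exact_recovery(self):
        x = white_noise_set(4, 48, seed=1)
        beta = 0.5 + 0.5j
        y = synthetic_waveset(beta * x.coefficients)
        y.grid, y.coi_mask = x.grid, x.coi_mask  # share exactly
        fit = fit_wlm(y, [x])
        ok = np.isfinite(fit.residual_power)
        np.testing.assert_allclose(fit.coefficients[0, ok], beta, atol=1e-10)
        assert np.nanmax(fit.residual_power) < 1e-20

    def test_zero_response(self):
        x = white_noise_set(3, 48, seed=2)
        y = synthetic_waveset(np.zeros_like(x.coefficients))
        y.grid, y.coi_mask = x.grid, x.coi_mask
        fit = fit_wlm(y, [x])
        assert np.all(fit.coefficients == 0)

    def test_orthogonal_predictors_match_univariate(self, rng):
        # construct predictors orthogonal per timescale, response a mix
        n, T = 3, 48
        base = white_noise_set(n, T, seed=3)
        S = len(base.grid)
        c1 = rng.standard_normal((n, S, T)) + 1j * rng.standard_normal((n, S, T))
        c2 = np.empty_like(c1)
        mask = base.coi_mask
        for si in range(S):
            cols = np.flatnonzero(mask[si])
            if len(cols) == 0:
                c2[:, si, :] = rng.standard_normal((n, T))
                continue
            v1 = c1[:, si, cols].ravel()
            raw = rng.standard_normal(len(v1)) + 1j * rng.standard_normal(len(v1))
            raw -= (np.vdot(v1, raw) / np.vdot(v1, v1)) * v1
            c2[:, si, :] = 0.0
            c2[:, si, cols] = raw.reshape(n, len(cols))
        x1, x2 = synthetic_waveset(c1), synthetic_waveset(c2)
        x2.grid, x2.coi_mask = x1.grid, x1.coi_mask
        yc = (1.0 - 2.0j) * c1 + (0.3 + 0.1j) * c2
        y = synthetic_waveset(yc)
        y.grid, y.coi_mask = x1.grid, x1.coi_mask

        multi = fit_wlm(y, [x1, x2])
        uni1 = fit_wlm(y, [x1])
        uni2 = fit_wlm(y, [x2])
        rows = np.flatnonzero(mask.any(axis=1))
        np.testing.assert_allclose(
            multi.coefficients[0, rows], uni1.coefficients[0, rows], atol=1e-8
        )
        np.testing.assert_allclose(
            multi.coefficients[1, rows], uni2.coefficients[0, rows], atol=1e-8
        )

    def test_collinear_predictors_rejected(self):
        x = white_noise_set(3, 48, seed=4)
        with pytest.raises(CollinearPredictorsError, match="timescale"):
            fit_wlm(white_noise_set(3, 48, seed=5), [x, x])

    def test_model_meanfield_identity(self):
        y, X = _noise_sets(5, 64, 2, seed=6)
        fit = fit_wlm(y, X)
        recon = sum(
            fit.coefficients[k][:, None] * fit.predictor_meanfields[k].values for k in range(2)
        )
        np.testing.assert_allclose(fit.model_meanfield.values, recon, atol=1e-12)


class TestPredictedSynchrony:
    def test_zero_fit(self):
        x = white_noise_set(3, 48, seed=7)
        y = synthetic_waveset(np.zeros_like(x.coefficients))
        y.grid, y.coi_mask = x.grid, x.coi_mask
        prof = predicted_synchrony(fit_wlm(y, [x]))
        assert np.nanmax(prof.values) == 0

    def test_exact_model_matches_observed(self):
        x = white_noise_set(4, 64, seed=8)
        y = synthetic_waveset((0.8 - 0.2j) * x.coefficients)
        y.grid, y.coi_mask = x.grid, x.coi_mask
        fit = fit_wlm(y, [x])
        obs = mean_squared_synchrony(wavelet_mean_field(y))
        pred = predicted_synchrony(fit)
        ok = np.isfinite(obs.values)
        np.testing.assert_allclose(pred.values[ok], obs.values[ok], atol=1e-10)

    def test_predicted_at_most_observed_on_noisy_fits(self):
        y, X = _noise_sets(10, 96, 2, seed=9)
        fit = fit_wlm(y, X)
        obs = mean_squared_synchrony(wavelet_mean_field(y))
        pred = predicted_synchrony(fit)
        for band in STANDARD_BANDS:
            from kelpsync.synchrony import band_average

            # predicted band synchrony may not exceed observed except by
            # projection noise; allow a small margin
            assert band_average(pred, band) <= band_average(obs, band) + 0.15


class TestAttribution:
    def test_single_predictor_zero_interaction(self):
        y, X = _noise_sets(5, 64, 1, seed=10)
        fit = fit_wlm(y, X)
        obs = mean_squared_synchrony(wavelet_mean_field(y))
        table = attribute_synchrony(fit, obs, STANDARD_BANDS).to_frame()
        assert np.all(table["q_int"] == 0.0)

    def test_identity_on_random_fits(self):
        for seed, (n, K) in enumerate([(5, 1), (5, 2), (12, 2)]):
            y, X = _noise_sets(n, 64, K, seed=20 + seed)
            fit = fit_wlm(y, X)
            obs = mean_squared_synchrony(wavelet_mean_field(y))
            table = attribute_synchrony(fit, obs, STANDARD_BANDS).to_frame()
            q_k = sum(table[f"q_x{k + 1}"] for k in range(K))
            resid = (table["q_all"] - q_k - table["q_int"]).abs().max()
            assert resid < 1e-10

    def test_main_effects_nonnegative(self):
        y, X = _noise_sets(8, 64, 2, seed=30)
        fit = fit_wlm(y, X)
        obs = mean_squared_synchrony(wavelet_mean_field(y))
        table = attribute_synchrony(fit, obs, STANDARD_BANDS).to_frame()
        assert np.all(table["q_x1"] >= 0) and np.all(table["q_x2"] >= 0)

    def test_unsynchronised_predictor_explains_nothing(self):
        # a spatially unsynchronised predictor's main-effect q shrinks as 1/n
        vals = []
        for seed in range(20):
            y, X = _noise_sets(100, 64, 1, seed=40 + seed)
            fit = fit_wlm(y, X)
            obs = mean_squared_synchrony(wavelet_mean_field(y))
            table = attribute_synchrony(fit, obs, STANDARD_BANDS).to_frame()
            vals.append(table["q_x1"].mean())
        assert np.mean(vals) <= 2.0 / 100


class TestCoefficientPhase:
    def _fit_with_lag(self, lag, gamma=1.0, T=96):
        rng = np.random.default_rng(50 + lag)
        from kelpsync.synthetic import narrowband_series

        n = 6
        full = np.stack([narrowband_series(rng, T + lag, 4.0, 1.0) for _ in range(n)])
        x = make_matrix(full[:, lag:])  # driver
        y = make_matrix(gamma * full[:, :T])  # response = gamma * driver(t - lag)
        opts = CleaningOptions(marginal_transform="none", detrend_degree=0)
        grid = make_timescale_grid(T)
        xs = normalize_power(transform_set(clean_series(x, opts), grid))
        ys = normalize_power(transform_set(clean_series(y, opts), grid))
        return fit_wlm(ys, [xs])

    def test_in_phase(self):
        fit = self._fit_with_lag(0, gamma=1.0)
        phi = coefficient_phase(fit, STANDARD_BANDS[0])[0]
        assert abs(phi) < 0.05

    def test_anti_phase(self):
        fit = self._fit_with_lag(0, gamma=-1.0)
        phi = coefficient_phase(fit, STANDARD_BANDS[0])[0]
        assert abs(abs(phi) - 1.0) < 0.05

    def test_quarter_cycle_lag(self):
        # response delayed one timestep; at the 4-quarter timescale the
        # coefficient phase is +0.5 (quarter cycle), response lagging driver
        fit = self._fit_with_lag(1, gamma=1.0)
        si = int(np.argmin(np.abs(fit.model_meanfield.grid.timescales - 4.0)))
        phi = np.angle(fit.coefficients[0, si]) / np.pi
        assert phi == pytest.approx(0.5, abs=0.05)

    def test_zero_coefficients_flagged(self):
        x = white_noise_set(3, 48, seed=60)
        y = synthetic_waveset(np.zeros_like(x.coefficients))
        y.grid, y.coi_mask = x.grid, x.coi_mask
        fit = fit_wlm(y, [x])
        phi = coefficient_phase(fit, STANDARD_BANDS[0])
        assert np.isnan(phi[0])


class TestCoherence:
    def test_self_coherence(self):
        x = white_noise_set(4, 64, seed=70)
        coh = coherence(x, x)
        ok = np.isfinite(coh)
        np.testing.assert_allclose(np.abs(coh[ok]), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.angle(coh[ok]), 0.0, atol=1e-10)

    def test_independent_fields_low_coherence(self):
        mods = []
        for seed in range(10):
            y = white_noise_set(30, 132, seed=80 + seed)
            x = white_noise_set(30, 132, seed=980 + seed)
            coh = coherence(y, x)
            mods.append(np.nanmean(np.abs(coh)))
        assert np.mean(mods) < 0.1

    def test_lagged_phase(self, rng):
        T, lag = 128, 1
        n = 5
        xs = rng.standard_normal((n, T + lag))
        y = make_matrix(xs[:, :T])  # y(t) = x(t - lag)
        x = make_matrix(xs[:, lag:])
        opts = CleaningOptions(marginal_transform="none", detrend_degree=0)
        grid = make_timescale_grid(T, max_ts=24)
        ys = normalize_power(transform_set(clean_series(y, opts), grid))
        xw = normalize_power(transform_set(clean_series(x, opts), grid))
        coh = coherence(ys, xw)
        ts = grid.timescales
        for si in np.flatnonzero(np.isfinite(coh)):
            if ts[si] < 4:
                continue  # phase wraps too fast near Nyquist for a clean check
            assert np.angle(coh[si]) == pytest.approx(2 * np.pi * lag / ts[si], abs=0.05)


class TestIndexModel:
    def _field(self, n, T, seed):
        return white_noise_set(n, T, seed)

    def test_index_equal_to_field(self):
        T = 96
        rng = np.random.default_rng(90)
        x = rng.standard_normal(T)
        m = make_matrix(np.tile(x, (5, 1)))
        opts = CleaningOptions(marginal_transform="none", detrend_degree=0)
        w = normalize_power(transform_set(clean_series(m, opts), make_timescale_grid(T)))
        idx = IndexSeries(x.copy(), m.time_axis, "idx")
        _, table = index_coherence_model(w, idx, STANDARD_BANDS, cleaning=opts)
        df = table.to_frame()
        np.testing.assert_allclose(df["q_all"], 1.0, atol=1e-8)
        assert np.all(df["q_int"] == 0)

    def test_independent_index_explains_little(self):
        # At annual timescales there are many independent cycles, so an
        # unrelated index explains almost nothing.  At long interannual
        # timescales (~3 cycles in 33 years) even an unrelated index can
        # absorb a large apparent fraction: one free complex coefficient
        # per timescale against few effective degrees of freedom.
        from kelpsync.data_io import quarter_range

        axis = quarter_range((1987, 1), (2019, 4))
        annual, long_band = [], []
        for seed in range(10):
            w = self._field(30, 132, seed=100 + seed)
            rng = np.random.default_rng(9000 + seed)
            idx = IndexSeries(rng.standard_normal(132), axis, "idx")
            _, table = index_coherence_model(w, idx, STANDARD_BANDS)
            df = table.to_frame().set_index("band")
            annual.append(df.loc["annual", "q_all"])
            long_band.append(df.loc["long_interannual", "q_all"])
        assert np.mean(annual) < 0.15
        assert np.mean(long_band) < 1.0  # bounded, but overfits few cycles
        assert np.mean(annual) < np.mean(long_band)

    def test_long_band_index_dominates_long_band(self):
        from kelpsync.synthetic import SyntheticConfig, gen_dataset

        cfg = SyntheticConfig(n_locations=20, seed=77, index_noise_sd=0.05)
        d = gen_dataset(cfg)
        opts = CleaningOptions(marginal_transform="none", detrend_degree=0)
        w = normalize_power(
            transform_set(clean_series(d["kelp"], opts), make_timescale_grid(132))
        )
        _, table = index_coherence_model(w, d["index"], STANDARD_BANDS)
        df = table.to_frame().set_index("band")
        assert df.loc["long_interannual", "q_all"] > 3 * df.loc["annual", "q_all"]
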