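# Methods

This note documents the models and procedures implemented in `kelpsync`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the package's known limitations.

## Data model and cleaning

Inputs are locations × quarters real matrices (`QuarterlySeriesMatrix`)
with an explicit gap-free (year, quarter) axis; missing values live
in-matrix as NaN, never as absent columns. Quarters follow the calendar
convention winter = Jan–Mar, spring = Apr–Jun, summer = Jul–Sep, autumn =
Oct–Dec. Sub-quarterly records are aggregated with a per-variable
statistic: mean for biomass-like and concentration-like variables, max for
episodic disturbance variables such as significant wave height.

Persistence filtering retains locations whose cumulative count of
fully-absent calendar years (every quarter zero *or* missing) is at most
`max_absent_years` (default 3). The count is cumulative rather than
consecutive because the rule counts years, not runs; the threshold is
configurable so the consecutive reading can be emulated by sensitivity
analysis. Zero is treated as a valid observation (population absent) and
differs from missingness only in that both count toward absence.
Regionalisation splits locations at a boundary latitude (default 34.45°N,
the Point Conception area); latitudes strictly above are "central", the
rest "southern", so the regions partition the retained set.

Cleaning per location, in order: optional Box–Cox with λ maximising the
normal log-likelihood on the fixed grid [−1, 2] step 0.01 (a grid, not a
numeric optimiser, so results are bit-reproducible across SciPy versions);
if zeros are present, a zero offset of half the smallest positive value is
added first (scale-aware, avoids log-zero failures). Then a least-squares
polynomial detrend (default degree 1) on an orthogonal basis, then
centring and scaling to unit (population) variance. Missing runs up to 4
quarters are linearly interpolated beforehand; longer runs or missing
endpoints are errors — such locations should have been removed by the
persistence filter. All switches sit in `CleaningOptions` and the chosen
parameters (λ per location, trend coefficients) are recorded as
provenance. Because the upstream study's exact cleaning recipe is not
published in its main text, sensitivity of q values to these options is
the intended workflow, not an afterthought.

## Wavelet transform

Continuous Morlet transform, energy-normalised:

    W(s, t) = s^(-1/2) Σ_u x(u) k((u − t)/s),
    k(η) = π^(-1/4) exp(+i 2π f0 η) exp(−η²/2),  f0 = 1,

computed as an exact direct sum (one kernel-matrix product per timescale;
no truncation, no padding — series here are a few hundred points at most,
so the O(S·T²) cost is negligible and an explicit-loop oracle verifies the
vectorised path to 1e-15). With f0 = 1 the timescale axis reads directly
as period in quarters; the continuous power maximum for a pure sinusoid
sits at ≈ 1.013× its Fourier period, a bias smaller than one step of the
default grid.

The kernel's sign convention is deliberate: it makes the phase of a
regression coefficient equal +2πL/s when the response lags its driver by L
timesteps, so reported phases read naturally (ϕ > 0: response lags driver;
ϕ = +0.5: quarter-cycle delay; |ϕ| = 1: anti-phase). The conjugate
convention would flip every reported phase sign while leaving all moduli,
mean fields and q values untouched.

Timescales form a geometric grid from 2 timesteps (Nyquist period) to T/2,
spacing factor 1.05. The cone of influence masks coefficients within
√2·s of either series end (the e-folding distance of the Gaussian
envelope; the multiplier is configurable), and every downstream average
uses masked-in cells only. Power normalisation divides each location's
coefficients by the root-mean-square modulus over all masked-in (s, t)
cells — an across-timescale normalisation that preserves each location's
relative power profile, so a location's synchrony contribution is weighted
by where its variance actually lives. The per-timescale alternative
(flattening every location's spectrum) is deliberately not the default;
switching normalisation is possible by normalising per timescale slice
before the mean-field step.

One consequence worth remembering: energy-normalised wavelet power scales
as (variance × timescale), so a slow band contributes more normalised
power per unit variance than a fast one. Band synchrony values are
comparable *within* a timescale, and between datasets, but raw band power
is not variance.

## Synchrony measures and the phase test

The wavelet mean field averages normalised transforms across locations;
its squared modulus, time-averaged per timescale, is the mean squared
synchrony profile, summarised over bands — annual [0.5, 2) y, short
interannual [2, 4) y, long interannual [4, 10] y; membership is half-open
except the top band's inclusive upper edge, so the bands partition 2–40
quarters with no orphan grid point (8 quarters = 2 y belongs to short
interannual). Band values are unweighted means over the band's grid
timescales.

The phasor mean field replaces each coefficient with its unit phasor
first, making the statistic amplitude-blind; cells with an exactly zero
coefficient (degenerate inputs only) are dropped from that cell's mean
with n reduced accordingly.

Significance uses the literal unsynchronised-phases null: every
location-phasor replaced by exp(iU), U iid uniform on (0, 2π). Under this
null the mean-field modulus has one and the same distribution at every
(s, t) cell, so the implementation draws a single Monte-Carlo pool of
`n_surrogates` (default 10 000) null moduli per call and ranks every
observed cell against it: p = (1 + #{null ≥ observed})/(n_surrogates + 1),
with floor 1/(n_surrogates + 1). The pool is shared across cells — the
marginal null is exact, and p-values at different cells were never
independent anyway (wavelet smoothing correlates neighbouring cells).
Autocorrelation-preserving surrogates are out of scope but the null is a
single pluggable function. Calibration: on independent-noise fields the
mask-averaged squared phasor-mean-field modulus times n is 1.00 (50
seeds), pooled null p-values are uniform to KS distance < 0.04, and the
p < 0.05 rejection rate is 5% ± 2%.

## Wavelet linear model and attribution

Per timescale s, β(s) solves the pooled complex least-squares problem over
all masked (location, time) cells, via the normal equations with
conjugate-transpose cross-products; an SVD condition check raises on
collinear predictors, naming the timescale. Coefficients are constant
across locations and times within a timescale — the form consistent with
reporting one magnitude and one phase per predictor per band. Fits are run
separately per region; regions share only the timescale grid.

With MF_k the k-th predictor's mean field and P_k(s) its time-averaged
squared modulus:

    S_k(s)   = |β_k(s)|² P_k(s)
    S_int(s) = Σ_{k<l} 2 Re(β_k conj(β_l) · mean_t MF_k conj(MF_l))
    S_mod(s) = Σ_k S_k + S_int = mean_t |Σ_k β_k MF_k|²

Band fractions q are ratios of band-averaged numerators to the
band-averaged observed profile (ratio of means, not mean of ratios), so
q_all = Σ q_k + q_int holds to machine precision after band averaging —
the package's central invariant, asserted on every fit. Main effects are
non-negative by construction and vanish when a predictor is spatially
unsynchronised (its mean field → 0 as n grows). Band phases ϕ_k are
circular means of the coefficient phasors weighted by S_k(s), so
timescales contributing nothing to explained synchrony do not move the
phase; an all-zero coefficient band yields NaN, flagged rather than
guessed.

The single-index model cleans a non-spatial series once, transforms it,
replicates it across the region's locations as a one-predictor design
(q_int ≡ 0) and runs the same machinery. Caveat, quantified in the tests:
with one free complex coefficient per timescale and only ~3 cycles of a
10-year period in a 33-year record, even an *unrelated* index "explains"
~30% of long-band synchrony in expectation (and ~9% at annual timescales
at n = 30). Long-band index results should be read against that baseline;
this is the overfitting-at-few-cycles regime, not evidence of association.

No model selection and no coefficient significance testing is performed:
the inference surface is the q decomposition and the phase estimates.

## Synthetic generator

`SyntheticConfig` defaults encode the study conditions the package is
tested under: 40 locations × 132 quarters (33 years), three spectral bands
centred at 4, 12 and 24 quarters, response transfer γ_waves = −1 at lag 0
(immediate negative disturbance effect) and γ_nutrients = +1 at lag 1
quarter (delayed positive resource effect), AR(1) observation noise
(coefficient 0.2) scaled to signal-to-noise ratio 2.

Each band's driver variability is a narrowband Gaussian process — white
noise filtered by a Gaussian spectral window at the centre frequency,
window width period/4 — rather than a sinusoid, so phases drift
realistically and the estimators face honest inputs. A location's series
mixes a shared component (fraction ρ of band variance, default 0.5, the
driver's own spatial synchrony) with iid idiosyncratic narrowband noise.
Cross-driver dependence is injected only through the shared components:
the nutrient shared component is r × the wave component delayed by
`cross_lag` quarters plus an independent remainder. Defaults r = 0.8 and
cross_lag = 1: the two drivers are strongly tied to the same underlying
climate variability, with nutrient maxima trailing wave maxima by one
season (winter storms, spring upwelling). The r value is pinned by the
magnitude of the interaction terms such a system produces: attribution
tables with |q_int| approaching or exceeding the main effects require an
effective driver correlation of roughly 0.7–0.9; at r ≈ 0.5 interaction
signs at slow timescales drown in the few usable cycles of a 33-year
record.

These timing defaults make the interaction's sign analytic. The two
drivers' attributed effects are offset by (L_n + cross_lag − L_w) = 2
quarters, so the cross term at period p carries
sign(2 γ_w γ_n r cos(2π·2/p)): positive (synergy) at the 4-quarter band
(half an annual cycle offset × negative wave gain), negative (antagonism)
at 12 and 24 quarters where two quarters is a small phase. The pipeline's
fitted interaction reproduces this sign, checked over each band's spectral
support where the analytic sign is uniform; at band edges (e.g. 8 quarters,
where a 2-quarter offset is exactly a quarter cycle) the true cross term
passes through zero and its sign is undefined.

What the generator does **not** emulate: spatial distance-decay of
correlation (locations are exchangeable within shared/unshared),
demography (no recruitment/mortality state, no lower bound at zero
biomass), non-Gaussian marginals, observation gaps, and trends.
Consequently, passing tests demonstrate the statistical machinery is
correct and calibrated — not that real canopy-biomass data meet the
stationarity and Gaussianity assumptions; the cleaning options exist to
bring real data closer to them.

Determinism: all randomness flows through numpy Generators seeded from the
config; identical config + seed gives byte-identical fixture files, and
the fixture manifest echoes the config with the analytic cross-term signs
and realised shared-component correlations.

## Pipeline and numerics

The pipeline (YAML-configured, CLI `kelpsync run|simulate|validate-config`)
runs ingest → persistence filter → regionalise → impute → clean →
transform → normalise → per-region mean fields, phase-significance,
two-predictor fit, attribution, and optionally the index model; outputs
are CSV tables (rounded tables always ship with a full-precision
companion) written atomically via temp-file-and-rename, so failed runs
leave nothing behind. The run manifest records package version, config
hash and every seed, and suffices to reproduce a run bit-for-bit.

Numerical choices collected in one place: Box–Cox λ on a fixed grid;
zero-variance series rejected at 1e-10 relative tolerance; rank deficiency
in the regression at 1e-10 relative SVD tolerance; COI multiplier √2;
grid spacing 1.05; masked-empty timescales propagate NaN and are excluded
from band means; region tie at the boundary latitude goes south; the
smallest attainable p-value is 1/(n_surrogates + 1), and n_surrogates
below 99 is rejected as too coarse.

Problem sizes used by the test suite and the acceptance script — up to 40
locations × 132 quarters, 20–50 Monte-Carlo seeds, 1999 surrogates for
calibration checks — are the study-scale conditions the generator encodes;
the full suite runs in well under a minute on one core.

## Known limitations

- Per-timescale coefficients are global over a region; spatially varying
  responses are averaged, not modelled.
- The significance null ignores temporal autocorrelation of phases by
  construction (it is the stated unsynchronised-phases null); against
  strongly autocorrelated but unsynchronised fields it is conservative in
  modulus but can misstate cell-level dependence.
- Long-interannual statistics from 33-year records rest on ~3 cycles;
  both the index-model overfitting baseline above and wide q_int
  variability at slow timescales follow from that, and no amount of
  machinery removes it.
- The optional reproduction against the publicly deposited coastal dataset
  requires a network download and a cleaning recipe not published in the
  source's main text; it is deliberately outside the test suite.
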