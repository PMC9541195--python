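# kelpsync

Timescale-specific spatial synchrony analysis for quarterly spatiotemporal
population data, with multivariate wavelet regression and synchrony
attribution.

## The problem

Spatial synchrony — correlated fluctuations of populations at different
locations — controls regional population stability, and it is rarely the
work of a single environmental driver. Storm waves can crash a kelp forest
the same winter everywhere along a coast; nutrient pulses can lift growth a
season later across the same region. Whether two such Moran drivers
reinforce (synergy) or cancel (antagonism) depends on the *timescale* of
the fluctuation and the *timing* of each driver's effect. `kelpsync` is a
toolkit for asking exactly that question of locations × quarters data: a
population response field (e.g. satellite-derived kelp canopy biomass), two
or more spatial driver fields (e.g. maximum wave height, mean surface
nitrate), and optionally a non-spatial climate index.

## The statistics

For each location *i*, the cleaned series is transformed with a continuous
Morlet wavelet, W\_i(s, t), on a common geometric grid of timescales *s*
(periods, in quarters), with cone-of-influence masking at the series ends.
After per-location power normalisation:

- **Wavelet mean field**: WMF(s, t) = (1/n) Σ\_i W\_i(s, t). Its
  time-averaged squared modulus per timescale is the *mean squared
  synchrony* — near 1 for in-phase fields, near 0 for incoherent ones.
- **Wavelet phasor mean field**: the same average over unit phasors
  W\_i/|W\_i|, measuring pure phase agreement. Its modulus is ranked
  against Monte-Carlo draws from the null of unsynchronised (iid uniform)
  phases to give per-cell p-values.
- **Wavelet linear model**: per timescale, complex least squares pooled
  over locations and times, Y\_i(s,t) ≈ Σ\_k β\_k(s) X\_{k,i}(s,t). Each
  β\_k(s) has a magnitude (strength of association) and a phase (lag of the
  response behind driver k; ϕ in fractions of π, so ϕ = 0.5 is a
  quarter-cycle lag and |ϕ| = 1 anti-phase).
- **Synchrony attribution**: the model's explained synchrony decomposes
  exactly into per-driver main terms q\_k ≥ 0 and a signed interaction term
  q\_int, with q\_all = Σ q\_k + q\_int. Positive q\_int is synergy, negative
  is antagonism; main effects can exceed 100% when offset by a negative
  interaction.

Statistics are summarised over three timescale bands: annual (< 2 y),
short interannual (2–4 y) and long interannual (4–10 y), separately per
geographic region.

A synthetic generator (`kelpsync.synthetic`) builds driver/response fields
with known band structure, spatially shared fractions, cross-driver
correlation and lags — an immediate negative "wave" effect and a
one-quarter-delayed positive "nutrient" effect by default — so the whole
chain is testable without downloading anything.

## Worked example

Generate a synthetic coastal dataset (40 locations × 132 quarters, two
regions) and run the full pipeline on it:

```sh
kelpsync simulate --out demo --seed 11
kelpsync run demo/pipeline.yaml
cat demo/results/attribution.csv
```

```text
region,band,q_all,q_waves,phi_waves,q_nutrients,phi_nutrients,q_int
central,annual,91.9,26.3,-0.99,32.0,0.46,33.6
central,short_interannual,100.7,85.4,0.97,68.9,0.17,-53.5
central,long_interannual,111.3,373.2,0.99,136.1,0.09,-398.0
southern,annual,94.2,26.5,-0.98,31.8,0.47,35.8
southern,short_interannual,92.6,99.0,-0.99,140.2,0.18,-146.6
southern,long_interannual,87.2,173.1,1.00,80.0,0.12,-165.9
```

Reading the annual rows: the model explains ~92% of observed annual
synchrony; waves act in anti-phase (ϕ ≈ ±1, an immediate negative effect),
nutrients act with ϕ ≈ +0.5 (a quarter-cycle delayed positive effect), and
the interaction is strongly positive (+34%) — the two drivers' effects
align in time and *synergistically* amplify annual synchrony. At
interannual timescales the same lags become a negligible fraction of a
cycle, the correlated drivers push in opposite directions, and the
interaction turns negative (antagonism), with main effects exceeding 100%
exactly because they are offset by it. Within each row,
`q_all = q_waves + q_nutrients + q_int` holds to machine precision before
rounding (a full-precision companion file `attribution.full.csv` is
written alongside).

The library surface mirrors the pipeline stages: `data_io` (long-format
CSV in, persistence filtering, regionalisation), `preprocess` (gap
interpolation, Box–Cox, detrend, z-score), `wavelets`, `synchrony`,
`wlm`, `synthetic`, `pipeline`/`cli`. See `docs/methods.md` for the model
details, parameter defaults and limitations.

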