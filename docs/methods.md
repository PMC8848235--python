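# Methods

## Problem setting

A hospital transfusion service produces apheresis platelet concentrates in
house. The production chain (donor activation, preparation, quality
control) takes 2 days, donors are activated Monday–Friday only, and a unit
entering stock has a remaining shelf life of 4 days. Daily demand is an
overdispersed count series with a pronounced weekday profile, week-scale
autocorrelation, and a slow secular rise. The package quantifies, in
retrospective simulation, how much outdating and shortage a demand
forecast can remove when it drives the nightly production order.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any particular hospital's records. Demand on day *i* is drawn
negative-binomially (gamma-mixed Poisson, shape *k*) around

    rate_i = base_rate · m[d_w(i)] · g^{t_i(years)} · exp(e_i − σ²/2)

with weekday multipliers *m* (Sunday = 0 … Saturday = 6, normalized to
mean 1, weekends below weekdays), annual growth factor *g*, and a
stationary latent AR(1) process *e* on the log rate (coefficient φ,
stationary SD σ) that carries the autocorrelation.

Defaults (chosen once by moment-matching to the emulation targets — mean
≈ 11.5 units/day, SD ≈ 6, annual totals rising ≈ 2.3× across 11 years,
weekday > weekend — and then frozen):

| parameter | default | meaning |
|---|---|---|
| `base_rate` | 11.2 units/day | baseline demand level |
| `weekday_multipliers` | (0.60, 1.08, 1.14, 1.16, 1.13, 1.16, 0.73) | Sun…Sat relative levels |
| `annual_trend` | (5891/2566)^(1/10) ≈ 1.087 | growth per year |
| `ar_coefficient` φ | 0.9 | persistence of the latent log-rate |
| `latent_sigma` σ | 0.18 | stationary SD of the latent log-rate |
| `dispersion` k | 25 | NB shape; Var = μ + μ²/k |

Signal covariates are noisy monotone transforms of demand hitting a
configured same-day Pearson correlation; CBC-style columns are built from
the sum of same-day and next-day demand (low platelet counts *lead*
transfusion) with a self-calibrated mixing weight so their same-day
correlation still meets the target — this plants causal-in-time predictive
structure that a forecaster can exploit. Decoy columns are independent
negative-binomial counts. A strength-1 signal is an exact integer linear
transform of same-day demand so the limiting case is noise-free.

What the generator does **not** emulate: patient-level structure, blood
types, mislabeled traffic, departmental reorganizations, calendar
holidays, or month-of-year effects. Passing tests on this data show the
pipeline's mechanics and qualitative behavior, not site-specific accuracy.

## Feature pipeline

Missing count cells mean "nothing recorded", so they are imputed as zeros;
calendar gaps are contract violations instead. Covariates with fewer than
400 nonzero values, or with a ≥ 365-day all-zero run (a source that did
not continually exist), are excluded. The correlation screen keeps
covariates with squared Pearson correlation to platelet use ≥ 0.2. PL7 is
the mean demand over the strictly previous 7 days (the current day is
excluded to avoid outcome leakage); six weekday dummies use Sunday as the
reference. Targets: y2 and y4, the summed demand of the next 2 and 4 days.

The screen is recomputed on each training span inside the rolling-origin
loop rather than once globally — the leakage-free reading for a reusable
tool; `build_design_matrix(..., r2_threshold=0.2)` or the CLI flag
`--global-screen` restores the one-shot global variant.

## Forecasting protocol

Rolling-origin recalibration: train on the first 500 design-matrix rows,
predict the next 28, extend the training span, repeat; every refit
recalibrates hyperparameters with 5-fold *blocked* cross-validation
(contiguous unshuffled folds) minimizing MSE. Predictions are clamped at
zero. Separate models are fit per horizon (y2, y4) rather than one
multi-output model, since the ordering policy needs both horizons
independently. An augmented Dickey–Fuller test with constant + linear
trend (`statsmodels`, `regression="ct"`) verifies trend-stationarity
before the expanding-window protocol is applied.

**LASSO.** Features are standardized on the training span (a shared L1
penalty is meaningless across raw count scales); coefficients are mapped
back to the original scale for reporting. The penalty grid is 100
log-spaced values from λ_max = max|Xᵀ(y−ȳ)|/n down four decades, standard
practice when no grid is prescribed. The OLS limit uses a vanishing
penalty (1e−12) for numerical stability.

**LSTM.** One LSTM layer over a lookback window of daily feature vectors,
flatten over all timestep outputs with a ReLU or linear activation,
dropout, and a single linear dense neuron. Implemented directly in NumPy
with analytic backpropagation through time (gradient-checked against
central finite differences in the tests), Adam (lr 1e−3), MSE loss, L1–L2
penalties on the LSTM kernel and dense weights, and early stopping on a
validation MSE (patience 20, max 200 epochs by default). Hyperparameters
are drawn by randomized search from the discrete space {batch 50, 100} ×
{units 10, 50} × {dropout 0…0.5 step 0.05} × {L1, L2 ∈ 1e−9, 1e−7, 1e−5,
1e−3} × {ReLU, linear}; each draw is scored by blocked CV, the best refit
on the full span. Design choices the architecture leaves open and how they
were resolved:

- lookback = 7 days (one weekly seasonal cycle), configurable;
- optimizer/epochs/stopping are unspecified by the architecture, so the
  standard bounded-compute choice above is used;
- the network consumes the same screened tabular features as the LASSO,
  arranged as lookback sequences;
- batches preserve temporal order and are not reshuffled across epochs,
  which keeps training bit-reproducible under a seed.

## Metrics

RMSE, squared Pearson correlation of predictions and truth (r²), and MAPE
(days with zero truth excluded, count logged; an epsilon-substitution
variant is not provided because zero 2-day demand sums are rare at these
demand levels). 95% CIs are percentile bootstrap over days (default 2000
replicates, seeded). Model differences are tested by converting each CI to
a standard error, SE = (hi − lo)/(2·1.96), and forming a two-sided Normal
z test on the difference — valid to the extent the metric's sampling
distribution is Normal. Whether to bootstrap per-day errors or
per-iteration errors is an open choice; per-day is used.

## Inventory simulator

Stock is stratified by remaining shelf life r0…r3 (r0 expires at the end
of the current day). The daily step: (1) age stock and receive the order
placed two days ago into r3; (2) consume demand oldest-first, tracking
cumulative balances t1…t4 so t4 = stock − u, possibly negative; (3) if
t4 ≤ β, purchase b = max(0, γ − t4) units — purchases first cover the
deficit, any surplus enters stock at r3 (freshest age; this only matters
when γ > 0); (4) unconsumed r0 units are wasted; (5) end-of-day stock
s = r1 + r2 + r3. All arithmetic is integer. A per-unit FIFO reference
implementation in the test suite reproduces these ledgers exactly.

The ordering rule o_i = round(max(0, p + α − s_i − o_{i−1})) nets out both
current stock and the pipeline order arriving tomorrow, so inventory is
never double-ordered; p is the 2-day forecast for Sunday–Wednesday orders
and the 4-day forecast on Thursday (whose order must also cover the
orderless Friday–Saturday gap); Friday and Saturday place no orders, which
is also why nothing arrives on Sundays and Mondays. Real-valued forecasts
are rounded half-up: platelet units are discrete and rounding up biases
against shortage, consistent with the asymmetric cost.

The simulation starts from empty stock; the first 14 days are excluded
from all totals to remove the initialization transient (the rates are
insensitive to this choice on horizons ≥ 200 days).

## Cost and policy search

c = 350·Σwaste + 700·Σpurchases (US$/unit — local production price, and
an emergency price of "almost double" rounded up to penalize the
transfusion delay a purchase implies). (α, β, γ) are chosen by exhaustive
search over {0..30}³ with lexicographic smallest-first tie-breaking.
Policy parameters are optimized on the same retrospective span that is
reported, mirroring the study design this package operationalizes; for
leakage-free deployment the search can be run on a separate span by
passing a restricted demand/forecast window. The desk-scale default
searches α with β = γ = 0 fixed (their optimum on every configuration
examined, and the values that make purchases exactly cover daily
deficits); the full 31³ search is available through the library and CLI.

## Problem sizes and numerical choices

The default study uses 780 synthetic days → 269 evaluation days after the
500-day initial span and the 11 rows consumed by PL7 and the 4-day target,
with the LSTM search reduced to 2 random draws and 40 epochs; these sizes
were chosen as the package's desk-scale defaults and every one scales up
through configuration. Zero-variance features standardize to zero and are
effectively dropped by the L1 penalty; a constant target returns an
intercept-only model with a logged warning; a diverging LSTM draw (non-
finite loss) is discarded with a warning rather than aborting the search.
Grid-search ties are broken toward the smallest (α, β, γ).

## Known limitations

- The simulator models one product pool: no ABO/Rh compartments, no
  platelet sales to other clinics, no intra-day timing of the ~2-hour
  emergency purchase lead.
- The ordering rule ignores the expiry profile of current stock (only its
  total); an expiry-aware rule is a natural extension.
- MSE-trained forecasts are not tailored to the asymmetric inventory
  cost; a model slightly worse in MAPE can still yield lower inventory
  cost, and the simulation stage is the arbiter of practical value.
- The shelf life of emergency-purchased units entering stock is assumed
  maximal (r3); this is only observable when γ > 0.
- Bootstrap CIs treat days as exchangeable, understating uncertainty
  under strong serial correlation of errors.
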