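# bloodstock

Forecasting daily platelet demand and simulating a hospital blood-bank
inventory to quantify how much outdating (waste) and shortage a
forecast-driven ordering policy can avoid.

Platelet concentrates are among the most perishable blood products: after
preparation and quality control they keep a remaining shelf life of about 4
days, daily demand is highly variable with a strong weekday pattern, and
production (apheresis donation, preparation, quality control) takes 2 days
with no donor activation on Fridays and Saturdays. A transfusion service
must therefore decide every evening how many units to start producing,
two days before they become available — order too many and units expire,
too few and units must be bought externally at roughly double cost.

## What the package does

1. **Synthetic data** (`bloodstock.synthetic`) — generates daily platelet
   use *u_i* as an overdispersed (negative-binomial) count series with
   multiplicative weekday profile, exponential secular trend and a latent
   AR(1) log-rate, plus census / planned-surgery / CBC-style covariates with
   planted correlations and independent decoys. Calibrated so an 11-year
   series has mean ≈ 11.5 units/day (SD ≈ 6) and annual totals rising
   ≈ 2.3-fold.
2. **Features** (`bloodstock.features`) — zero imputation, removal of
   sparse (< 400 nonzero values) and discontinuous covariates, an
   *r*² ≥ 0.2 correlation screen against platelet use, the PL7 predictor
   (mean transfusions over the strictly previous 7 days), six weekday
   dummies (Sunday reference), and the targets
   y2(i) = u(i+1)+u(i+2), y4(i) = u(i+1)+…+u(i+4).
3. **Forecasting** (`bloodstock.forecasting`, `bloodstock.nn`) — a LASSO
   and an LSTM network predicting y2 and y4 under
   rolling-origin-recalibration: train on the first 500 days, predict the
   next 28, retrain, repeat; all hyperparameters recalibrated each
   iteration by 5-fold blocked cross-validation on MSE. The LSTM
   (LSTM layer → flatten with ReLU/linear activation → dense(1)) is a
   self-contained NumPy implementation trained with Adam and
   backpropagation through time, with its hyperparameters drawn by
   randomized search from a fixed discrete space.
4. **Metrics** (`bloodstock.metrics`) — RMSE, squared Pearson correlation
   r², MAPE, percentile-bootstrap 95% CIs over days, and two-sided p
   values for model differences reconstructed from the CIs (Altman–Bland).
5. **Inventory** (`bloodstock.inventory`) — a daily stepwise simulator with
   age-stratified stock r0…r3, FIFO issuance, 2-day order lead time, no
   arrivals on Sundays/Mondays, and emergency purchases: when the
   post-consumption balance t4 = stock − u falls to or below β, buy
   b = γ − t4 units. The ordering strategy restores an end-of-day stock
   target α over the order's coverage window:
   o_i = round(max(0, p + α − s_i − o_{i−1})), with p the 2-day forecast
   Sunday–Wednesday and the 4-day forecast on Thursdays.
6. **Policy** (`bloodstock.policy`) — total cost
   c = 350·Σw + 700·Σb (US$/unit: local production vs emergency purchase)
   minimized by exhaustive grid search over (α, β, γ) ∈ {0..30}³.

## Worked example

```python
from bloodstock.inventory import InventoryState, step_day

# stock of 2 units, an unexpected need for 4, purchase parameters β=γ=0
state = InventoryState(r1=1, r2=1)
_, day = step_day(state, u=4, beta=0, gamma=0)
print(day.t4, day.purchase, day.stock)   # -> -2 2 0
```

The balance after consumption is t4 = 2 − 4 = −2, so 2 units are bought
(b = γ − t4 = 0 + 2) and the day ends with empty stock.

A full desk-scale study from the shell:

```sh
bloodstock simulate-data --n-days 780 --seed 1 --out data.csv
bloodstock run-study --seed 1 --out study_out
```

On this fixture (780 synthetic days; 269 evaluation days after the 500-day
initial training span) the run prints, among others:

| quantity | constant-order baseline | LASSO-driven | LSTM-driven |
|---|---|---|---|
| MAPE, 2-day forecast | — | 26.2 % | 28.4 % |
| MAPE, 4-day forecast | — | 20.4 % | 21.0 % |
| optimized stock target α | — | 14 | 15 |
| waste rate | 9.2 % | 5.0 % | 5.4 % |
| shortage rate | 6.1 % | 0.7 % | 1.2 % |

Reading: aggregating to the 4-day horizon smooths relative error, so the
4-day MAPE is lower than the 2-day MAPE for both models; and driving the
ordering policy with either forecast roughly halves waste and cuts
shortage several-fold relative to ordering a constant quantity matched to
mean demand.

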