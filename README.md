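# cryoextender

Multivariate optimization of bull-semen cryopreservation extender media.

Freezing bull semen for artificial insemination requires an *extender*: a
protective medium of buffer, sugars, egg yolk, cryoprotectants,
antioxidants and membrane stabilizers. Post-thaw motility depends on the
concentrations of many components at once, and on the bull. This package
implements the full multivariate workflow used to screen and optimize
12-component extender formulations:

* **I-optimal experimental design** — coordinate-exchange construction of
  designs minimizing the average prediction variance
  `I(X) = tr[(XᵀX)⁻¹ M]` over the coded cube, with the moments matrix `M`
  in closed form;
* **Response-surface ANOVA** — least-squares fits, sequential
  linear/quadratic/cubic fit summaries, Type III (partial) sums of
  squares;
* **Preprocessing** — removal of the k largest-|residual| observations,
  seeded shuffling and a 75/25 calibration/validation split;
* **NIPALS PLS2 regression** — joint modelling of total (TM) and
  progressive (PM) motility on the 12 concentrations, with original-unit
  prediction equations `ŷ = b₀ + Σ bⱼ xⱼ`, the w\*/c loading map,
  leave-one-bull-out jackknife cross-validation, and validation metrics
  R², RMSE, MAPE and RPD = SD/RMSE;
* **Bull clustering** — UPGMA on Euclidean distances between per-bull
  mean PLS scores (t₁, t₂, t₃), with Newick export;
* **Monte Carlo formulation screening** — 10,000 truncated-normal draws
  per component, predicted motility via the PLS equations, a
  correlation/contribution sensitivity table
  (contributionⱼ = 100·rⱼ²/Σr²), top-k formulations and distribution
  summaries;
* **Multiple factor analysis (MFA)** — group-weighted global PCA
  (weights 1/λ₁ per group) with a supplementary categorical "bulls"
  projection;
* **PLS path modeling (PLS-PM)** — reflective five-block measurement
  model, centroid/factorial/path inner schemes, Dillon-Goldstein's rho,
  structural path coefficients, per-block R² and the goodness of fit
  GoF = √(mean communality × mean R²).

A synthetic-data generator reproduces the statistical structure of the
motivating study — 122 runs × 4 replicates = 488 media over the published
component ranges, a ground-truth response surface anchored on the
published PLS coefficients, per-bull intercept shifts for 43 bulls in
4 cohorts, and Gaussian residual noise — so the entire pipeline is
testable end to end without the original measurements.

## Worked example

```python
import pandas as pd
from cryoextender import reference
from cryoextender.pls import predict_from_equation

best = pd.DataFrame([reference.BEST_TM_FORMULATION])
tm = predict_from_equation(
    reference.INTERCEPT["tm"], reference.COEFFICIENTS["tm"], best
)[0]
print(f"predicted total motility: {tm:.2f}%")
```

```
predicted total motility: 73.66%
```

The reference prediction equation for total motility, evaluated at the
best formulation found by Monte Carlo screening (glycerol 0.66 mL,
trehalose 161.8 mg, ethylene glycol 0.06 mL, ...), predicts 73.66%
post-thaw total motility — the published value for this formulation is
73.75%, the difference coming from coefficient rounding.

Running the whole pipeline on synthetic data:

```bash
cryoextender run-all --seed 42 --out-dir out/
```

writes the design, experiment table, ANOVA, calibration/validation
split (300/100 records after removing 88 outliers from 488), PLS
coefficients, bull dendrogram (Newick), Monte Carlo sensitivity and
top-10 formulation tables, MFA contributions and PLS-PM paths, plus a
manifest that makes the run bit-reproducible.

## Layout

```
src/cryoextender/
  components.py   component definitions and published ranges
  simulate.py     synthetic experiment-table generator
  design.py       I-optimality criterion, coordinate exchange, decoding
  rsm.py          OLS response surfaces, fit summary, Type III ANOVA
  preprocess.py   outlier removal, shuffle/split, quantile summaries
  pls.py          NIPALS PLS2, metrics, jackknife CV, loading map
  cluster.py      per-bull scores, UPGMA, tree cutting, Newick export
  montecarlo.py   truncated-normal screening, sensitivity, top-k tables
  mfa.py          multiple factor analysis with supplementary groups
  plspm.py        PLS path modeling, Dillon-Goldstein rho, GoF
  reference.py    published coefficient sets and formulations (inputs)
  io.py, pipeline.py, cli.py
```

See `docs/methods.md` for the statistical methods, default parameters and
known limitations.
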