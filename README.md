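# acsidm

Estimation of the transition rates of the extended illness-death model
for chronic diseases from **aggregated current-status (ACS) data** —
counts of people per health state at a handful of monitoring ages, with
no individual follow-up.

The package is aimed at epidemiologists and biostatisticians studying
chronic-disease incidence and differential mortality when cohort
follow-up is unavailable (claims data, privacy-restricted registries,
repeated cross-sectional surveys). It provides both the forward problem
(micro-simulating ACS tables from known rates) and the inverse problem
(recovering the rates from a table).

## Model

Four states: **1** non-diseased, **2** diseased, **3** dead without
disease, **4** dead with disease. Three age-dependent hazards connect
them — incidence *i*(*t*) and the mortalities *m*₀(*t*) (non-diseased)
and *m*₁(*t*) (diseased):

```
i(t)  = θ₂ · max(0, t − θ₁)        (hinge-linear incidence)
m₀(t) = exp(θ₃ + θ₄ t)             (Gompertz)
m₁(t) = exp(θ₅ + θ₆ t)             (Gompertz)
```

The state-occupation probabilities *p*(*t*) = (*p*₁, *p*₂, *p*₃, *p*₄)
solve the linear system *p*′ = *A*(*t*) *p*:

```
p₁′ = −(i + m₀) p₁        p₂′ = i p₁ − m₁ p₂
p₃′ = m₀ p₁               p₄′ = m₁ p₂
```

A cross-section of *N*ₖ subjects observed at age *t*ₖ yields a count
vector *X*(*t*ₖ) = (*S*, *C*, *D*₀, *D*₁) ~ Multinomial(*N*ₖ, *p*(*t*ₖ)).
Two estimators of θ = (θ₁,…,θ₆) are implemented:

* **least squares** — minimize Σₖ Σⱼ ( *p*ⱼ(*t*ₖ; θ) − *x*ₖⱼ/*N*ₖ )²;
* **maximum likelihood** — maximize the exact multinomial
  log-likelihood ℓ(θ) = Σₖ [ log *N*ₖ! + Σⱼ ( *x*ₖⱼ log *p*ⱼ(*t*ₖ; θ) − log *x*ₖⱼ! ) ].

Both are optimized by Nelder–Mead over (θ₁, log θ₂, θ₃,…,θ₆), with
*p*(*t*; θ) from a fixed-step classical RK4 solve (default step 0.1
years). The micro-simulator draws event times by exact
inverse-transform sampling of the closed-form cumulative hazards.

## Worked example

A reference ACS table is packaged: a simulated birth cohort of 10,000
subjects (diabetes-motivated rates, onset age 30, incidence slope
1/2000, Gompertz mortalities exp(−10.7 + t/10) and exp(−10 + t/10))
observed at eleven cross-sections at ages 0, 10, …, 100. Fitting it by
maximum likelihood:

```bash
acsidm fit --method ml --true-theta "30,0.0005,-10.7,0.1,-10,0.1"
```

prints

```
            method parameter    estimate  converged  true_value  rel_error_pct  estimate_per_10000
maximum_likelihood    theta1     30.3062       True          30        1.02058                 NaN
maximum_likelihood    theta2 0.000516566       True      0.0005         3.3132             5.16566
maximum_likelihood    theta3    -10.8193       True       -10.7        1.11537                 NaN
maximum_likelihood    theta4    0.101134       True         0.1        1.13421                 NaN
maximum_likelihood    theta5    -9.76997       True         -10        2.30026                 NaN
maximum_likelihood    theta6   0.0980183       True         0.1         1.9817                 NaN
max relative error (maximum_likelihood): 3.31%
```

Every parameter is recovered within 3.4% of the value that generated
the data — onset age 30.3 vs 30, incidence slope 5.17 vs 5 per 10,000
per year, and both Gompertz mortalities within ~2% — even though the
estimator only ever saw 44 aggregated counts. The `estimate_per_10000`
column rescales the incidence slope to its conventional reporting unit.

The same experiment end-to-end with a fresh simulation:

```bash
acsidm recover --n 10000 --seed 7 --times 0:100:10 --out-prefix run7
```

writes `run7_acs.csv` (the simulated count table) and
`run7_report.csv` (estimates and relative errors for both methods).

Library use mirrors the CLI:

```python
import numpy as np
from acsidm import THETA_TRUE, run_recovery_experiment

report = run_recovery_experiment(THETA_TRUE, 10000, np.arange(0, 101, 10), seed=7)
print(report.max_relative_error("maximum_likelihood"))
```

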