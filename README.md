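# growthdesign

Tools for designing cross-sectional growth-reference centile studies:
how many children to measure, and at what ages, to estimate centile
curves (weight, height, BMI, head circumference, ...) with a required
precision.

## The problem and the approach

Growth reference charts are built by fitting smooth centile curves to a
cross-sectional sample with the LMS method: at each age the measurement
distribution is summarised by its median μ, generalised coefficient of
variation σ (so the generalised SD is μσ) and Box-Cox skewness power ν —
the BCCG distribution.  A measurement *y* maps to a z-score

    z = ((y/μ)^ν − 1) / (νσ)        (ν ≠ 0;  log(y/μ)/σ for ν = 0)

and the centile for normal deviate z_α is C₁₀₀α = μ(1 + νσz_α)^(1/ν).

Two design questions arise: the **sample size** n, and the **sample
composition** — how measurement ages are distributed.  Both are handled
on the z-score scale, where the standard error of an estimated centile
(SE_z) is the same for every measurement.  For a single age group of
size n, normal theory gives SE_z = √((1 + z²/2)/n).  For smoothed curves
the package quantifies SE_z by simulation: datasets are drawn from a
base model with ages sampled *uniformly on the age^λ scale* (λ < 1
over-samples infancy), BCCG moment curves are refitted with penalized
P-splines, and bootstrap SE_z curves are summarised as linear trends of
log SE_z on age (2–18 y).  A meta-regression

    log SE_z ~ age * (log(1 + z²/2) + λ)      (age centred at 10 y)

then yields, for any centile, the composition λ\* that makes the SE_z
curve flat (the optimal-design criterion), the SE_z achieved at the
reference size n = 6878, and — through the empirical scaling law
n ∝ SE_z^(−1.85) — the sample size required for any target precision.

## Worked example

Design a study around the 2nd/98th centiles (z = ±2) with a target
precision of 0.06 z-score units:

```
$ growthdesign design --z 2 --target-se 0.06
centile z = 2  ->  optimal lambda = 0.76
required n for SE_z = 0.06: 8301
at n = 8301: SE_z = 0.060, 95% CI for the centile: (97.0, 98.3)%
```

Reading: ages should be sampled uniformly on the age^0.76 scale
(moderate infant over-sampling); about 8300 subjects per sex achieve
SE_z = 0.06, and the 98th centile is then estimated within (97.0, 98.3)%
— equivalently the 2nd centile within (1.7, 3.0)%.  Allocate 10,000
subjects to one-year age groups under that composition:

```
$ growthdesign allocate --n 10000 --groups 20 --range 0 20 --z 2
lambda from flatness condition at z=2: 0.7553
wrote allocation.csv (total 10000)
```

The allocation falls from 1041 children at age 0–1 to 380 at 19–20.
Other subcommands: `fixture` writes synthetic LMS reference tables,
`simulate` draws datasets from them, `fit` estimates BCCG moment curves
from a CSV of (age, y), `se-curve` bootstraps SE_z curves, and `flatten`
runs the full simulate → fit → bootstrap → trend loop to find the
flat-SE_z composition λ\* directly.

The same operations are available as a library:

```python
import numpy as np
from growthdesign import (DEFAULT_DESIGN_MODEL, FitConfig, SamplingScheme,
                          fit_bccg, make_fixture, optimal_lambda,
                          simulate_dataset)

lam = optimal_lambda(DEFAULT_DESIGN_MODEL, z=0.0)       # 0.382 for the median
model = make_fixture("weight")
scheme = SamplingScheme(lambda_age=lam, age_min=0, age_max=20, n=6878)
data = simulate_dataset(model, scheme, np.random.default_rng(1))
fit = fit_bccg(data, FitConfig(xi="search"))
print(fit.summary())
```

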