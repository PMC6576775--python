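# multiscale-occupancy

Multi-scale occupancy analysis for camera-trap arrays: does adding a second
or third camera to a survey site — and does spacing them 100 m or 150 m
apart — actually raise the chance of detecting a species that is present?

The package is for wildlife ecologists designing or evaluating multi-camera
survey protocols. It takes per-camera daily detection histories
(0 / 1 / missing), pools them into *methods* — named camera subsets such as
"one camera", "two cameras 100 m apart", "three cameras 150 m apart" —
by logical OR, and fits a three-scale hierarchical Bernoulli model to the
pooled histories:

- **Ψ** (occupancy): the species uses the landscape around the site during
  the survey season;
- **θ** (availability): conditional on occupancy, the species is in the
  immediate vicinity of the array on a given day;
- **p** (detection): conditional on availability, pooling method *s*
  records the species that day.

For a site with daily records *y<sub>ts</sub>* over methods *s* and days *t*,

```
L = Ψ · ∏_t [ θ_t ∏_s p_ts^y (1−p_ts)^(1−y)  +  (1−θ_t)·1{no detection on day t} ]
    + (1−Ψ)·1{no detection on any day}
```

with missing visits contributing no factor. All three scales take logit-link
covariates (study area, access type, distance to access, tree-loss
proportion at several buffer radii; detection additionally takes the method
factor and method-level distance summaries). Because every method at a site
shares the same Ψ and θ, differences in detection success are attributed to
the method structure itself — that is what makes pooled, physically
overlapping camera subsets comparable. Models are ranked by AICc
(n = sites), competitive models (ΔAICc ≤ 2) feed a staged selection
workflow, and per-method detection estimates are model-averaged with
unconditional standard errors.

A seeded synthetic-data generator produces surveys with exactly this
hierarchical structure, either at the method level (matching the fitted
model) or at the physical camera level (inducing the real dependence
between methods that share cameras), plus internally consistent covariates
and missing visits — so every stage of the pipeline can be exercised and
calibrated without field data.

## Worked example

```python
import pandas as pd
from multiscale_occupancy import (CovariateTable, ModelSpec, SimDesign,
                                  fit_model, predict_probabilities,
                                  simulate_method_level)

design = SimDesign(n_sites=500, occasions=(16, 23), psi_true=0.76,
                   theta_true=0.24, p_true=(0.29, 0.47, 0.79, 0.55, 0.58),
                   seed=42)
pooled, truth = simulate_method_level(design)
cov = CovariateTable(pd.DataFrame(index=pd.Index(pooled.site_ids, name="site")))
fit = fit_model(ModelSpec.from_formula("psi(.) theta(.) p(Method)"),
                cov, pooled, n_starts=5, seed=1)
pred = predict_probabilities(fit)
```

This prints (`python examples/02_fit_multiscale_model.py`):

```
model: psi(.) theta(.) p(Method)   loglik = -9598.41   K = 7
occupancy    psi   = 0.741 (se 0.020)   truth 0.76
availability theta = 0.241 (se 0.005)   truth 0.24
detection given availability, and derived daily detection theta*p:
  m1: p = 0.280 (se 0.011)   theta*p = 0.068
  m2: p = 0.475 (se 0.012)   theta*p = 0.115
  m3: p = 0.793 (se 0.010)   theta*p = 0.191
  m4: p = 0.552 (se 0.012)   theta*p = 0.133
  m5: p = 0.599 (se 0.012)   theta*p = 0.144
```

The 500-site fit recovers the generating values within sampling error: one
camera detects an available animal on 28% of days, three cameras at 100 m
spacing on 79%. The product θ·p is the daily detection probability an
ordinary single-scale occupancy model would see for that method's data
alone — the number a survey designer compares across configurations.

Other narrative scripts in `examples/`: pooling semantics and effort
summaries (`01`), the staged AICc selection workflow with covariates
(`03`), and camera-level simulation showing the closed-form pooled rate
1−(1−q)^k and the dependence between nested methods (`04`).

## Command line

A thin CLI wraps the library for file-based runs:

```bash
msocc simulate --config run.yaml        # synthetic survey + covariates + truth
msocc pool     --detections d.csv       # per-camera -> per-method histories
msocc fit      --config run.yaml --formula "psi(.) theta(.) p(Method)"
msocc select   --config run.yaml        # staged AICc workflow + reports
```

Every command logs the package version, a config hash and the seed; outputs
are CSV (ranking tables, estimate tables with the θ·p column, model-averaged
detection per method).

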