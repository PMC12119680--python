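# anaemia-access

Travel time to emergency care and the severity of paediatric anaemia at
hospital admission.

## The problem

Severe anaemia (haemoglobin < 5 g/dl) in young children is a medical
emergency whose treatment — blood transfusion — is typically available only
at referral hospitals. Where emergency care is scarce, children living far
from the hospital may present later and sicker. This package implements, as
a tested and reusable pipeline, the analysis of how modelled travel time to
a referral hospital relates to anaemia severity at admission in a rural,
malaria-endemic setting (a western-Kenya county referral hospital with 42
months of paediatric ward surveillance, 2020–2023):

1. **Accessibility** — a friction surface (seconds/metre) is built from
   road class, land cover and barrier layers with per-class travel speeds,
   and least-cost-path travel time to the hospital is computed on the
   8-connected pixel graph (edge cost `d(a,b) · (f(a)+f(b))/2`, rook moves
   `d = pixel`, diagonal `d = pixel·√2`). Enumeration-area (EA) mean travel
   times feed 30-minute exposure classes (`<30`, `30–59`, `60–89`, `≥90`).
2. **Cohort** — haemoglobin is altitude-adjusted (WHO step table), severity
   classified (mild `[7,10)`, moderate `[5,7)`, severe `<5` g/dl), and an
   auditable exclusion cascade applied (residents aged 1–59 months → drop
   cause-related admissions → drop missing Hb → drop non-anaemic).
3. **Descriptives** — admission rates per 1,000 under-fives by EA and
   15-minute travel band (distance decay), Wilson 95% CIs, Kruskal–Wallis
   and Fisher exact tests, and crude odds ratios.
4. **Geostatistical model** — a Bayesian Bernoulli-logit for severe vs
   mild/moderate anaemia with fixed effects (travel class + screened
   covariates) and a spatially structured random effect over EA centroids:

   ```
   Y_ik ~ Bernoulli(π_ik),   logit(π_ik) = β₀ + Σ_j β_j x_ij + ω(s_k)
   ω ~ GP(0, C),   C(h) = σ² · 2^(1−ν)/Γ(ν) · (κh)^ν · K_ν(κh)
   ```

   With only a few hundred EAs the Gaussian process is represented exactly
   over the centroids (no mesh/SPDE approximation). Inference is a Laplace
   approximation over (β, ω) at fixed (σ², κ), with the conditional
   posteriors averaged over a log-spaced hyperparameter grid using Laplace
   marginal-likelihood weights. Adjusted odds ratios (AORs) are the
   exponentiated posterior quantiles of the travel-class coefficients.
5. **Synthetic region** — because the hospital data are not publicly
   deposited, a generator produces landscapes, EAs and admission registers
   with known ground truth, with severity generated from the same logit
   model the pipeline fits. Every stage is exercised and tested against
   this truth.

It is aimed at epidemiologists and health-geography researchers who want a
transparent, scriptable alternative to GIS-GUI accessibility tools plus a
self-contained model-based-geostatistics fit for binary outcomes at
village-scale units.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic
data (shared `results/` directory):

```bash
python analysis/01_simulate_region.py --seed 1
python analysis/02_travel_time.py
python analysis/03_build_cohort.py --seed 1
python analysis/04_descriptives.py --seed 1
python analysis/05_fit_geostat.py
python analysis/06_parameter_recovery.py --seed 1
```

Representative output (seed 1):

```
Travel time computed for 60/60 EAs (median 73.6 min, max 241.8 min).
Extracted 4,361 admissions; excluded 645 for cause, 255 without Hb,
1266 not anaemic; analysed 2,195.
Univariate screen (P < 0.2) kept 8 covariates: age_cat, nutrition,
vaccinated, malaria_dx, scd, weekday, pfpr, urban
Posterior spatial variance sigma2 = 0.50 (nu = 1)
Travel-time association (crude and adjusted):
tt_class    n       pct         crude_or              aor
     <30 1123 51.161731              Ref              Ref
   30-59  786 35.808656 2.81 (2.28-3.47) 2.69 (1.67-4.30)
   60-89  240 10.933941 3.59 (2.66-4.82) 3.09 (1.50-5.80)
    >=90   46  2.095672 2.42 (1.29-4.52) 2.50 (0.88-6.92)
```

Reading this: the cascade keeps 2,195 of 4,361 simulated admissions; the
screen retains the eight covariates the generator actually uses; the fit
recovers the generative spatial variance (σ² = 0.5) and travel-class
effects that rise with travel time, each with a 95% credible interval. The
`04` driver also reproduces, from the published aggregate counts, the
study's printed descriptive quantities — crude ORs 3.56 (30–59 min), 5.66
(60–89) and 4.22 (≥90) versus `<30`, and the severity/travel proportions
(34.9% of severe admissions within 30 min, 82.5% within 1 h, …).

The same stages are exposed as a CLI (`anaemia-access simulate|traveltime|
cohort|describe|fit|report|all`) and as library functions
(`anaemia_access.pipeline.run_pipeline` for one-call runs).

## Layout

```
src/anaemia_access/   raster, region, accessibility, cohort, descriptive,
                      geostat, synthetic, reference_tables, pipeline, cli
analysis/             numbered narrative drivers (01 … 06)
scripts/acceptance.py headline-number reproduction
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       model, assumptions, defaults and limitations
```
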