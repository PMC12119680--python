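# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Accessibility model

Travel time from every raster cell to the hospital is computed by
cost-distance analysis. Each surface class carries a travel speed and mode
(walking, motorcycle, vehicle); friction is the reciprocal speed in
seconds per metre (`3.6 / v[km/h]`). The default speed table is a hybrid
scenario typical of rural East-African accessibility studies: tarmac
80 km/h (vehicle), gravel 40 (motorcycle), earth 20 (motorcycle), built-up
5 km/h and open land cover 2–4 km/h on foot; water bodies and protected
areas are impassable. A road pixel overrides the underlying land cover;
there is no explicit mode-switch penalty — the mode is a property of the
surface being crossed, which reproduces walk-to-road-then-ride behaviour
implicitly.

Least-cost travel time is single-source Dijkstra on the 8-connected pixel
graph with the symmetric mean-friction edge cost
`d(a,b) · (f(a)+f(b))/2` (`d` = pixel size for rook moves, `pixel·√2`
diagonal). The model is isotropic: no slope or anisotropy correction —
altitude is used only for haemoglobin adjustment. Unreachable cells are
flagged, not errors; an impassable origin is an error. The implementation
is checked exactly against an independent brute-force shortest-path oracle
on random instances, and satisfies monotonicity (raising any friction never
shortens any travel time) and the potential inequality
`|t(a) − t(b)| ≤ edge cost(a,b)`.

EA-level exposure is the arithmetic mean of travel time over reachable
pixels whose centre lies inside the EA polygon, assigned to every admission
from that EA, then binned into half-open 30-minute classes
(`[0,30) [30,60) [60,90) [90,∞)`; 15-minute bands analogously) — so 30.0
minutes falls in `30–59`.

## Cohort construction

Raw haemoglobin is adjusted for altitude with the WHO (2011) step table
(subtract 0.0 below 1000 m; 0.2 for 1000–1499; 0.5 for 1500–1999; 0.8 for
2000–2499; 1.3 for 2500–2999; 1.9 for 3000–3499; continuing 2.7/3.5/4.5
above). The step form (no interpolation) is the guideline's native form;
the table is configurable. The altitude used is the EA-mean altitude
(configurable to a scalar) — the per-child residence altitude is not
observable at village-scale geolocation.

Severity on adjusted Hb: severe `< 5`, moderate `[5, 7)`, mild `[7, 10)`,
not anaemic `≥ 10` g/dl. Nutrition from MUAC z-score: well `> −1`, mild
`(−2, −1]`, moderate `(−3, −2]`, severe `≤ −3`, with missing MUAC retained
as its own category.

The exclusion cascade is sequential and order-fixed: (1) restrict to
resident children aged 1–59 months (defining "extracted"); (2) remove
admissions whose cause is unrelated to residence (bites, burns,
malignancy/congenital, poisoning, surgery, trauma); (3) remove records
without an Hb result; (4) remove the non-anaemic. A record matching several
criteria is counted once, at the first matching step. The flow ledger
enforces exact conservation (`analysed = extracted − Σ removed`) on every
run.

## Descriptive layer

Admission rates are `1000 · admissions / under-five population` over the
whole surveillance window (not annualised), by EA and by 15-minute travel
band; band denominators pool the under-five population of the EAs whose
mean travel time falls in the band. Binomial proportions carry Wilson 95%
score intervals. Continuous comparisons across severity classes use the
tie-corrected Kruskal–Wallis test (the all-tied degenerate case returns
H = 0, p = 1 by convention). Categorical comparisons use Fisher's exact
test: the exact point-probability rule for 2×2; full enumeration of the
conditional table space for r×c tables with total n ≤ 200; otherwise a
Monte-Carlo p from ≥10⁵ Patefield-sampled tables with fixed margins and
fixed seed, reported with its Monte-Carlo standard error.

Crude odds ratios for severe-vs-other by travel class use
`OR = (a/b)/(c/d)` against the `<30` reference with the Woolf (log-method)
interval `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`; zero cells get the
Haldane–Anscombe +0.5 correction to all cells, flagged in the output. On
the published aggregate counts this reproduces the printed crude ORs to
±0.005; interval endpoints match to last-digit rounding except one upper
bound (7.98 vs the printed 8.00), consistent with the published intervals
having come from a likelihood-based fit rather than the Woolf formula.

## Geostatistical model

Outcome: severe vs mild/moderate anaemia per admission. Model:

```
Y_ik ~ Bernoulli(π_ik)
logit(π_ik) = β₀ + Σ_j β_j x_ij + ω(s_k)
ω ~ N(0, Σ),   Σ_kl = σ² 2^(1−ν)/Γ(ν) (κ h_kl)^ν K_ν(κ h_kl)
```

with `h` the Euclidean distance between EA centroids (planar metres).
Covariates enter as categoricals (reference levels: travel `<30`, nutrition
`well`, age `<1`) except the community parasite rate PfPR₂₋₁₀, which is
continuous. Candidate covariates are screened one at a time by logistic
regression, kept when any non-reference level has Wald p < 0.2; travel
class is always retained as the exposure of interest; separated or
non-converged screens are flagged and kept. Residual spatial
autocorrelation is diagnosed with an empirical semivariogram of EA-mean
deviance residuals from the non-spatial fit (equal-width lag bins to half
the maximum pairwise distance; with only two locations the single pair's
lag is used).

**Inference.** The EA count (hundreds) makes the exact GP tractable, so no
mesh or SPDE approximation is used. At fixed (σ², κ) the joint posterior
of (β, ω) is approximated by Newton-maximising the penalised Bernoulli
log-posterior (step-halving keeps it monotone; non-convergence raises with
the gradient norm) and taking the Gaussian (Laplace) approximation at the
mode. The Laplace marginal likelihood
`ℓ(ẑ) − ½ẑ'Q₀ẑ + ½log|Q₀| − ½log|Q₀ + M'WM|` is evaluated on a log-spaced
grid over σ² ∈ [10⁻², 4] and κ ∈ [2/diameter, 2/min-distance] (7×7 by
default, plus the σ² = 0 non-spatial candidate), and the conditional
fixed-effect posteriors are averaged with marginal-likelihood weights —
so hyperparameter uncertainty propagates into the credible intervals, the
same device the nested-Laplace family of methods uses. Quantiles come from
the weighted normal mixture by bisection on its CDF. ν is fixed at 1 (the
customary two-dimensional smoothness); β priors are normal(0, 10²) —
proper but weak. The admission-level noise term is off by default: under a
Bernoulli likelihood it is weakly identified and its variance trades off
against the intercept scale; a config flag restores it. With σ² forced to
0 the fixed effects agree with the ordinary logistic MLE to well within
0.01 at study scale (tested).

AORs are `exp` of the travel-class posterior quantiles, reported in a
four-row table (reference row `Ref`) alongside the descriptive module's
crude ORs.

## Synthetic generator

The generator defines the study conditions for every test:

- **Region**: 300×300 pixels at 100 m (30×30 km) with the hospital at the
  centre; two tarmac trunk roads to the region edge and eight secondary
  gravel/earth roads branching off the network (connected by
  construction); land cover, altitude (1130–1350 m) and water barriers
  (4% of pixels) from thresholded smoothed noise; 60 EAs as the Voronoi
  tiling of random seed points, so every pixel belongs to exactly one EA.
  The coarse pixel keeps the graph small while walking-scale off-road
  speeds spread EA travel times across all four 30-minute classes; the
  12.5 m convention of real road data remains available via `pixel_size`.
- **EA attributes**: under-five population log-normal (median 150), NTL
  positive only within 2.5 km of the hospital (NTL > 0 ⇒ urban), PfPR from
  a smooth spatial surface in [0.20, 0.55].
- **Admissions**: EA membership drawn with probability ∝ population ×
  `exp(−0.04/min × travel time)`; the decay constant was set once so band
  rates fall ≈5–6× between the 15-minute and 60-minute bands, matching the
  published mild-anaemia decay shape. Covariates are drawn independently
  from marginals matching the published cohort (age shares, 41.2% female,
  94% vaccinated, 40% malaria, 16% SCD, 78.5% weekday, 51.6% wet season,
  nutrition mix with 8.5% missing MUAC); dates are drawn consistently with
  the weekday/season flags within the 42-month window.
- **Severity**: generated from the model above with default truth
  β₀ = −4.8, travel-class log-ORs log(2.44)/log(3.55)/log(3.41) (mirroring
  the published adjusted estimates), moderate covariate effects, and a
  Matérn field with σ² = 0.5, ν = 1, κ = 10⁻³ m⁻¹ (practical range
  ≈ 2.8 km) — yielding ≈29% severe among analysed admissions. Mild vs
  moderate among the non-severe is a single Bernoulli split (default
  1151/1553), cosmetic to the severe-vs-other model. Raw Hb is
  back-derived from the generated class and the EA altitude so the cohort
  stage recovers the class exactly. Exclusion-path fractions default to
  the published cascade proportions.
- **Light-weight EA sampler** (`make_random_eas`) for model-recovery
  experiments without a landscape: travel classes drawn at the published
  N-column shares. Geometry `"uniform"` places centroids independently of
  travel class — the clean condition for recovery experiments;
  `"correlated"` places distal classes farther from the centre
  (distance-decay realism).

What the generator does **not** emulate: real road topology and
WorldPop-fidelity population surfaces; dependence between covariates
(e.g. malaria × PfPR — available via config, off by default since no joint
distribution is published); seasonality of transmission; readmissions
(every admission independent); hospital competition. Passing tests
therefore demonstrate correctness of the pipeline's computations and the
fitting machinery under the stated generative structure, not agreement
with any real cohort's individual-level data. Absolute synthetic admission
rates per 1,000 exceed the published ones (the synthetic county has 60
large EAs rather than thousands of small ones), while the decay shape is
preserved.

## Numerical choices

- Matérn evaluation in log-space with the `K_ν` Bessel function; `σ²` at
  h = 0; the covariance matrix gets diagonal jitter ≤ 10⁻⁸σ² before
  Cholesky, and failure after jitter is an error.
- Newton tolerance 10⁻⁸ (relative gradient norm), ≤50 iterations, 40
  step-halvings; warm starts across the hyperparameter grid.
- Priority-queue tie-breaks in Dijkstra cannot affect travel-time values
  (costs are deterministic); traversal order is fixed by construction.
- Fisher Monte-Carlo p uses the `(hits+1)/(B+1)` estimator.
- All generators are pure functions of (config, seed); pipeline reruns
  with the same config are bit-identical for deterministic stages.

## Known limitations

- **Spatial confounding**: when the exposure itself is spatially smooth
  (travel time is a function of location), the spatial random effect
  absorbs part of the exposure effect and attenuates the travel-class
  coefficients; under the correlated EA geometry, credible-interval
  coverage for those coefficients drops from the nominal 95% to roughly
  90%. This is a property of the model class (shared by any GP/SPDE-based
  spatial logit), not of the implementation; the recovery experiment is
  therefore defined under exposure-independent geometry, and results under
  correlated geometry should be read with this attenuation in mind.
- The Laplace/grid posterior is an approximation; no MCMC verification is
  run by default.
- The univariate screen at α = 0.2 has, by design, ≈20% false retention on
  null covariates, and its power depends on covariate prevalence: effects
  on high-prevalence binaries (e.g. 94% vaccinated) need to be strong to
  clear the threshold reliably at n ≈ 2,200.
- Speeds are season- and traffic-invariant; travel time is modelled, not
  observed.
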