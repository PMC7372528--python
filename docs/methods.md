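# Methods

This note documents the models and procedures `trialcea` implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Costing model

A patient's 12-month cost from the health-system perspective has four
components, summed exactly (rounding to cents happens only in reports):

- **Workshop share.** GP training was delivered as group workshops per region
  and arm. The cost of one workshop is divided by the mean number of GPs it
  trained and then by the number of patients that GP treated during the
  trial: `share = workshop_cost(region, arm) / (gps_per_workshop ×
  patients_per_gp)`. Patients-per-GP comes from the GP registry; when a GP is
  unknown the arm-level average is used. TAU has no workshop, so the share
  is 0.
- **Initial visit.** The per-protocol cessation interview, charged at the
  region's initial-visit tariff (€62 / €40 / €56.39 for Balearic / Catalunya
  / Valencia) for intervention-arm patients only.
- **Contact visits.** The recorded count of follow-up GP contacts times the
  region's follow-up tariff (€32 / €40 / €28.76). TAU contacts are costed at
  the same follow-up tariffs.
- **Drugs.** Consumption is observed only at the three assessment waves, so
  the cost between waves must be attributed by rule. Three rules are
  selectable (`--attribution`), and the choice is recorded in the manifest:
  - `trapezoid` (default): months between waves × the average of the two
    endpoint monthly costs — the natural analogue of the QALY AUC rule;
  - `carry_forward`: each wave's monthly cost applies until the next
    assessment;
  - `snapshot_sum`: one month charged per assessment.

  All three agree under constant consumption. A per-wave formulation-specific
  monthly cost override takes precedence over the product-level table.

Unit costs are euro at 2013 prices. The GBP/EUR and GBP/USD multipliers are
carried verbatim in the cost table for reporting-time conversion only; they
are never applied inside the analysis.

One known tension in the published tariffs: the Valencia arm-level mean
contact costs are consistent with a ≈€40 follow-up tariff rather than the
€28.76 unit cost. `UnitCostTable.with_followup_override` lets either reading
be configured explicitly; the package does not silently pick one.

## Utilities and QALYs

Generic health-state utilities come from a regression crosswalk of the two
HADS subscales: `u = intercept + c_A·HADS-A + c_D·HADS-D` (optional squared
and interaction terms are supported), clamped to `[floor, cap]` with the
conventional UK EQ-5D tariff floor −0.594 and cap 1.0. Clamping at 1.0 is on
by default, consistent with observed utility maxima of exactly 1. The
bundled coefficients are an illustrative linear set with explicit provenance
text; the published crosswalk should be substituted via YAML for substantive
work.

QALYs are the trapezoid-rule area under each patient's utility trajectory at
the *actual* assessment times when available (nominal 0 / 0.5 / 1 years
otherwise), with no extrapolation beyond the observed span and no
discounting (one-year horizon). QALY analysis is complete-case: a patient
missing any wave contributes to that wave's utility summaries but not to the
QALY; every stage reports its Ns.

## Estimation

Incremental effects are the arm coefficients of OLS
`QALY ~ baseline utility + I(SIW) + I(SIF)` on complete cases — the adjusted
coefficients, not raw arm mean differences, feed the headline ICER. Costs
enter as unadjusted arm means (a switch enables regression-adjusted costs as
a sensitivity analysis). Standard errors are plain OLS by default;
GP-cluster-robust errors are available. The ICER is ΔC/ΔE with a
cost-effectiveness-plane quadrant label; ΔE = 0 yields an "undefined" signal
rather than an error. Crude relative risks of 12-month discontinuation use
the ratio of proportions with a log-normal CI from event counts; the original
trial's cluster-adjusted estimates may differ slightly.

## Bootstrap, ellipses, CEAC

The bootstrap resamples units with replacement within arm, preserving arm
sizes, and refits the adjustment regression in every replicate (per-patient
costs and QALYs are fixed quantities carried with each unit). The default
unit is the patient; `gp_cluster` resamples whole GP clusters, the
appropriate unit when variance sits on the cluster level of the
cluster-randomised design (see below). Replicates that leave an arm without
complete cases, or a rank-deficient design, are redrawn and counted. B
defaults to 5,000 and a seed is mandatory whenever bootstrapping, so the
whole pipeline is reproducible end-to-end from one seed.

Confidence ellipses are the normal approximation on the bootstrap cloud:
center = mean, covariance = sample covariance, level-p contour
`(x−μ)ᵀΣ⁻¹(x−μ) = χ²₂(p)` at p ∈ {0.50, 0.75, 0.95}; semi-axes scale with
`sqrt(χ²₂(p))`. A singular covariance is flagged degenerate with collapsed
axes rather than raised. Marginal intervals of the ellipse use the 1-df
quantile (`μ ± z·σ`, z ≈ 1.96 at 95 %). An empirical alternative to the
normal contour is the Mahalanobis-quantile check exposed by
`EllipseSpec.mahalanobis_sq`.

`CEAC(λ) = (1/B) Σ 1{λ·ΔE_b − ΔC_b > 0}` on a grid (default 0–100,000 step
500) with exact recomputation at any off-grid λ — indicators are never
interpolated. The inequality is strict: a replicate with ΔE = 0 (or exactly
zero NMB) counts as not cost-effective at every λ.

## Synthetic data generator

The generator's defaults emulate the source cohort: arm sizes 168/191/173
(SIW/SIF/TAU), 25 GP clusters per arm, region weights 0.351/0.361/0.288,
6- and 12-month discontinuation probabilities (0.459, 0.382, 0.146) and
(0.452, 0.450, 0.150), baseline product mixes and per-arm-per-region contact
rates as published, baseline utility means/SDs (0.749/0.165, 0.731/0.154,
0.758/0.158), and target adjusted incremental QALYs 0.0144 (SIW) and 0.0340
(SIF).

Structure:

- **Clusters.** Each GP gets a region (categorical draw with the region
  weights), an additive Gaussian utility effect (SD `cluster_sd` = 0.03) and
  a unit-mean log-normal contact-rate multiplier (σ = `cluster_sd`). Patients
  are assigned to GPs uniformly within arm. Because *regions sit on GPs*,
  arm-level mean costs inherit cluster-level variance — the feature that
  makes the cluster-bootstrap option meaningful.
- **Contacts.** Poisson with mean `rate(arm, region) × cluster multiplier`.
- **Products.** Everyone consumes at baseline (long-term users); a two-state
  continue/discontinue process with product retention for continuers hits the
  configured 6- and 12-month marginal discontinuation probabilities exactly
  (when the 12-month probability is below the 6-month one, the appropriate
  fraction of quitters relapses to their retained product). Product switching
  beyond retention is not modelled.
- **Utilities.** Latent trajectories
  `u_b = m_a + c_g + z`, `u_t = m_a + d_t + e_a + c_g + ρz + ε_t` with
  baseline SD per arm from the configuration, common secular drift
  `d = (0.026, 0.046)` at 6/12 months (the TAU trajectory), within-patient
  autocorrelation ρ = 0.6 (a free choice with no empirical anchor — surfaced
  in the config as `utility_autocorrelation`), and residual SD 0.12. Each
  wave's latent utility is inverted to an integer (HADS-A, HADS-D) pair by
  splitting the utility deficit evenly between the subscales and rounding,
  so the mapping stage is exercised end-to-end.
- **Missingness** is completely at random per wave (default 5 %, giving
  roughly the observed per-wave Ns and a complete-trajectory fraction near
  the published regression n). Informative missingness is out of scope.

### Effect calibration

HADS quantisation and the utility cap at 1.0 make the observed utility mean
a nonlinear function of the latent mean, so adding `ΔE/0.75` on the latent
scale would *not* make the adjusted regression recover ΔE. Instead the
latent additive effect `e_a` is calibrated: the population value of the
adjusted arm coefficient is expressed through deterministic quadrature
moments of the quantised mapping (means, variances and baseline/follow-up
cross-moments of `q(N(m, s))` over a 2001-point Gauss grid, with the pooled
within-arm regression slope), and `e_a` is solved by Brent root finding so
that this population coefficient equals the configured target exactly. The
calibration is cached per configuration; `true_parameters` therefore returns
the configured targets as ground truth, and a large-n test (36,000 patients)
confirms the fitted coefficient matches the target within its standard
error. Expected per-arm costs follow in closed form from the configured
rates, mixes, discontinuation probabilities and unit costs (workshop share
uses clusters-per-arm over patients-per-arm; the probability of an empty
cluster, ≈e⁻⁷, is neglected).

### What passing tests do and do not show

The generator reproduces the cohort's first- and second-moment structure and
known ground truth, which validates the *pipeline arithmetic* — costing
rules, mapping, AUC, adjustment, bootstrap mechanics. It does not reproduce
real-data features such as informative missingness, assessment-date jitter
(nominal times are used, so drug-attribution and QALY weights are exact),
utility floor effects, product switching, or region-by-arm imbalance, so
recovery on synthetic data does not certify behaviour under those
violations.

Interval-coverage evaluation uses the GP-cluster bootstrap: with regions and
random effects on clusters, patient-level resampling understates the
variance of arm mean costs (measured ≈85 % coverage of nominal 95 %
intervals, versus ≈93–97 % for the cluster bootstrap at 25 clusters/arm —
itself mildly conservative-to-liberal as is typical for few clusters).

## Numerical choices

- Monetary arithmetic unrounded internally; 2-decimal rounding at reporting.
- Quadrature: ±8 SD grids, 2001 points (outer×inner for cross-moments);
  Brent tolerance 1e-7 on the latent effect; three outer iterations of the
  pooled-slope fixed point (the coupling through the slope is weak).
- OLS via statsmodels; the per-replicate bootstrap refit uses a numpy
  `lstsq` fast path, tested to 1e-10 against the statsmodels fit.
- Rank-deficient designs raise a `SingularDesignError` naming the collinear
  column(s) (e.g. constant baseline utility).
- Degenerate inputs: empty CSV → empty dataset with a warning; ΔE = 0 →
  undefined-ICER signal; singular bootstrap covariance → degenerate ellipse
  flag; zero workshop cost → zero share regardless of denominators.
- Problem sizes in the test suite are chosen to keep the default run within
  a few minutes: 200 replicate trials with B = 300 for recovery/coverage,
  B ≤ 1000 elsewhere; the package default for real analyses remains
  B = 5000.

## Known limitations

- The headline reproduction of the published arm-level cost means and CEAC
  probabilities (0.7983 / 0.9777 at €45,000/QALY) requires the deposited
  patient-level data; without them those values are documented fixtures in
  `reference_values.PUBLISHED`, not recomputed quantities.
- Adverse events, hospitalisations and societal costs are outside the
  costing perspective; no extrapolation beyond the trial year.
- The crosswalk's known weaknesses apply: concordance with the generic
  index is poorer at the severe end, utilities rest on the UK tariff, and
  generic health is proxied through anxiety/depression alone.
- Relative risks are crude ratios; the trial's design-adjusted estimates may
  differ in the second decimal.
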