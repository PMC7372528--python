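# trialcea

Within-trial cost-effectiveness analysis of brief structured interventions to
discontinue long-term benzodiazepine use in primary care.

## The problem

Long-term benzodiazepine use is common in Spain, has little clinical benefit,
and costs the health system both directly (prescriptions) and through adverse
outcomes. A three-arm cluster-randomised trial in three Spanish regions
(Balearic Islands, Catalunya, Valencia) randomised 75 general practitioners
(GPs) — and through them 532 long-term users — to treatment as usual (**TAU**),
a structured tapering interview with written instructions (**SIW**), or the
same interview with scheduled follow-up visits (**SIF**). `trialcea`
implements the economic evaluation run alongside that trial, from the
perspective of the Spanish health system over the 12-month follow-up, as a
reusable, tested pipeline:

1. **Costing** — per-patient 12-month cost: a share of the GP training
   workshop (spread over the patients each GP treated), the per-protocol
   initial cessation visit, follow-up GP contacts at region-specific tariffs,
   and benzodiazepine consumption at per-product monthly reference prices.
2. **Outcomes** — the trial measured anxiety/depression with the HADS
   subscales (each 0–21); a regression crosswalk maps (HADS-A, HADS-D) to an
   EQ-5D utility index at each of the three assessment waves (baseline, 6 and
   12 months), and per-patient QALYs are the area under the utility curve:
   `QALY = Σ_k (t_{k+1} − t_k) · (u_k + u_{k+1}) / 2`.
3. **Estimation** — incremental QALYs adjusted for baseline utility by OLS
   (`QALY ~ baseline utility + SIW + SIF`, TAU reference); incremental costs
   as arm mean differences; `ICER = ΔC / ΔE` per intervention arm; net
   monetary benefit `NMB(λ) = λ·ΔE − ΔC` against a willingness-to-pay
   threshold (€45,000/QALY is the commonly cited Spanish value).
4. **Uncertainty** — non-parametric bootstrap (patients within arm, or GP
   clusters for the cluster-randomised design), 50/75/95 % confidence
   ellipses on the cost-effectiveness plane, and the cost-effectiveness
   acceptability curve `CEAC(λ) = P(λ·ΔE − ΔC > 0)`.
5. **Synthetic data** — a generator producing cluster trials with the same
   statistical structure (arm sizes, discontinuation proportions, contact
   intensities, utility distributions) and *known* incremental costs and
   QALYs, so every stage is testable without the deposited patient data.

The study's patient-level data live in a public research-data archive and are
not redistributed here; `trialcea.reference_values.load_study_deposit` feeds
them into the same pipeline if you obtain them.

## Worked example

The headline arithmetic, computed from the bundled published summary values:

```bash
$ trialcea demo
Worked example: headline within-trial cost-effectiveness arithmetic
--------------------------------------------------------------------
Data available at 12 months: 523/532 (98.3%)
SIW: delta cost =   117.94 EUR, adjusted delta QALY = 0.0144, ICER =  8190.28 EUR/QALY (NE), RR(discontinuation) = 3.01 (95% CI 2.04 to 4.45)
SIF: delta cost =   218.40 EUR, adjusted delta QALY = 0.0340, ICER =  6423.53 EUR/QALY (NE), RR(discontinuation) = 3.00 (95% CI 2.03 to 4.41)
SIW: NMB at 45,000 EUR/QALY =   530.06 EUR
SIF: NMB at 45,000 EUR/QALY =  1311.60 EUR
```

Reading: SIW costs an extra €117.94 per participant versus usual care and
yields 0.0144 extra QALYs, i.e. €8,190.28 per QALY gained; SIF costs €218.40
more for 0.0340 extra QALYs (€6,423.53/QALY). Both fall in the north-east
quadrant (costlier, more effective) well below the €45,000/QALY threshold,
so both have positive net monetary benefit. The relative risks say patients
of trained GPs were three times as likely to be off benzodiazepines at 12
months.

A full synthetic run (simulate → cost → map → adjust → bootstrap → figures):

```bash
trialcea simulate --seed 1 --out trial.csv --truth-out truth.json
trialcea analyze --data trial.csv --seed 1 --bootstrap-B 5000 --outdir results/
```

`results/` then contains the per-patient analysis table, arm cost and QALY
summaries, the adjustment regression, bootstrap replicates, ellipse and CEAC
CSVs, the two figures, and `manifest.json` with the point estimates and the
CEAC value at the threshold. Every figure has a CSV twin of its plotted
values.

### Mapping coefficients

The published HADS→EQ-5D crosswalk coefficients are *not* hard-coded: the
bundled default (`MappingCoefficients.illustrative_default()`: intercept 1.0,
−0.025 per HADS-A point, −0.035 per HADS-D point, clamped to [−0.594, 1]) is
clearly labelled illustrative. For substantive analyses write the published
coefficients to YAML (with the `provenance` field filled in) and pass
`--coeffs mapping.yaml`.

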