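# glaucoma-claims

Pharmacy-claims analysis of first-line glaucoma therapy: who starts on a
single eye drop versus a fixed-combination bottle, how well patients adhere
to and persist on that first-line therapy over 12 months, and which
baseline factors relate to a guideline-discordant (fixed-combination-first)
start.

Japanese glaucoma guidelines recommend starting treatment with one topical
IOP-lowering agent and stepping up one drug at a time; a fixed combination
(two drug classes in one bottle, e.g. latanoprost/timolol) is the canonical
second-line step. In administrative claims data this sequencing is
observable, and so are the two outcomes that matter for eye drops:

* **Adherence** — proportion of days covered (PDC) over the 12-month
  post-index window:

  `PDC = 100 × (days covered by dispensed supply in [t0, t0+364]) / 365`,

  where the index date `t0` is the first topical IOP-lowering dispensing
  after a 365-day treatment-free washout. Dispensed volume is converted to
  bottles (2.5 mL once-daily / 5 mL multi-daily), one bottle covers one eye
  for 30 days, a single prescription of ≥7 bottles marks bilateral
  treatment (supply consumed twice as fast), and early refills carry
  forward. The a-priori adherence cutoff is PDC ≥ 80%.

* **Persistence** — time from index to discontinuation of the first-line
  regimen *category*, where discontinuation is a refill gap exceeding a
  30-day grace period after supply exhaustion, or a switch out of the
  category (mono → any combination; fixed → mono or unfixed). The
  discontinuation curve is estimated by the Kaplan–Meier product-limit
  estimator with Greenwood variance, plain-scale Wald 95% CIs,
  Hall–Wellner simultaneous bands, and a two-group log-rank test;
  persistence% = 100 − cumulative discontinuation%.

Comparisons between the guideline-compliant cohort (mono first, fixed
second) and the noncompliant cohort (fixed first) use a pooled t test on
mean PDC and an uncorrected Pearson χ² on the 80% split, Bonferroni-adjusted
at m = 6 (significance iff p < 0.05/6 ≈ 0.00833). A univariate logistic
screen at p < 0.1 followed by stepwise selection (entry/stay 0.10) looks
for factors associated with the noncompliant start.

The proprietary claims source such a study runs on is not distributable,
so the package includes a **synthetic claims generator**: per-patient
refill streams driven by a latent adherence propensity θ (refill gaps
inflate by 1/θ), a latent discontinuation day from a constant daily
hazard, configurable cohort mixing, exams, rare surgeries and health-checkup
covariates — with every latent quantity recorded as ground truth so each
pipeline stage is testable.

## Worked example

```python
from glaucoma_claims import StudyConfig, SimulationConfig, run_study

cfg = StudyConfig(simulation=SimulationConfig(n_patients=2000, seed=1))
report = run_study(cfg)
print(report.attrition.to_string(index=False))
```

```
                  stage    n  pct_of_analyzed
              extracted 2000              NaN
         excluded_no_rx    0              NaN
excluded_no_glaucoma_dx    0              NaN
 excluded_short_washout  126              NaN
 excluded_prior_surgery  141              NaN
excluded_short_followup  133              NaN
               analyzed 1600          100.000
 first_line_monotherapy 1518           94.875
           gl_compliant  164           10.250
        gl_noncompliant   82            5.125
                  other 1354           84.625
```

Of 2,000 extracted patients, 400 fail the new-user screen (short washout,
prior surgery including laser, or under 12 months of follow-up). Among the
1,600 analyzed, 10.3% follow the guideline sequence mono → fixed, 5.1%
start on a fixed combination, and the rest stay on monotherapy or move to
unfixed combinations. Adherence and persistence for the two cohorts:

```
         cohort   n  mean_pdc  sd_pdc  n_adherent
   GL_COMPLIANT 164      69.6    22.6          67
GL_NONCOMPLIANT  82      45.7    27.8          12
         pooled 246      61.6    26.9          79

GL_COMPLIANT:    6m 12.2% (7.2-17.2),   12m  0.0%
GL_NONCOMPLIANT: 6m 34.1% (23.9-44.4),  12m 18.3% (9.9-26.7)
log-rank chi2 22.06, p < 0.0001, Bonferroni-significant: True
```

Under the default synthetic conditions every compliant-cohort patient
switches within the year, so first-line persistence falls to 0% by month
12 (the switch itself is the discontinuation event), while a fraction of
fixed-combination starters persists — the mechanics of the definitions,
visible because the generator's ground truth is known.

The same pipeline runs from the shell:

```bash
glaucoma-claims simulate --n 2000 --seed 1 --out claims/
glaucoma-claims build-cohort --claims claims/ --out assignments.csv
glaucoma-claims pdc --claims claims/ --assignments assignments.csv --out pdc.csv
glaucoma-claims run-all --n 2000 --seed 1 --out report.json
glaucoma-claims fixture-report
```

`fixture-report` prints the packaged conversion example — a claim of
7.5 mL of a once-daily 2.5 mL product is 3 bottles and 90 days of supply,
whatever the claim's period field says; 7 bottles at once flags bilateral
use (105 days) — together with the two published 2×2 adherence tables run
through the χ² comparison (p = 0.3225 cohort-level, p = 0.0061 for the
latanoprost vs latanoprost/timolol subset).

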