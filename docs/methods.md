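# Methods

## Cohort construction

A patient's **index date** is the first dispensing of any topical
IOP-lowering product in the formulary. Eligibility requires, in flowchart
order: a glaucoma diagnosis (ICD-10 H401 or H409) anywhere in the record;
at least `washout_days` (default 365) of observable, glaucoma-treatment-free
history before index; no glaucoma surgery — laser included — on or before
index; and at least `followup_days` (default 365) of observable post-index
time. The first failing rule is the reported exclusion reason. Because
claims absence is indistinguishable from disenrollment, observability comes
from an explicit per-patient coverage table (emitted by the generator, or
supplied alongside real tables).

Eligible patients are labelled by first-line regimen at index:
**GL_NONCOMPLIANT** for a fixed-combination start; for a monotherapy start
the post-index fill days are scanned within `compliance_window_days`
(default 365) — mono→mono changes continue the scan (class switches are
adherent to first-line monotherapy), the first change to a fixed
combination yields **GL_COMPLIANT** with that date as second-line start,
and an unfixed-combination day (two or more distinct products dispensed
the same day) or no step-up at all yields **OTHER**. Unfixed starters are
OTHER. The window length is a genuine open point — the source design does
not bound how late a step-up may define compliance — and 365 days was
chosen to match the 12-month outcome horizon; it is configurable.

## Dispensed volume to covered days

The claim's period field is recorded but never used: payer period codes
are unreliable (a period of "1" can stand for a three-month supply). Days
of supply are derived from volume alone: bottles = quantity_ml /
bottle_volume_ml (2.5 mL once-daily, 5 mL multi-daily; non-integral ratios
beyond 1e-6 are flagged and rounded, minimum one bottle); one bottle covers
one eye for 30 dispensed days; a single prescription of ≥7 bottles marks
bilateral treatment, and days supplied = floor(bottles × 30 / eyes).
Non-integral ratios are kept rather than rejected because real claims
contain occasional partial volumes.

Coverage intervals carry forward: a fill's interval starts at the later of
its dispense date and the day after the previous interval ends, so early
refills stockpile rather than vanish. This is conventional PDC practice
and consistent with the grace-period philosophy. PDC uses a fixed 365-day
denominator with the index date as covered day 0; the published formula
for the source analysis is not legible, and covered-days/365 is the
standard reading consistent with its text. The PDC numerator defaults to
coverage by *any* topical glaucoma product ("regardless of switching");
a scope restricted to a product subset is available via
`build_supply_intervals(..., scope=...)`.

## Persistence and the product-limit estimator

Persistence is tracked for the index regimen *category*: monotherapies as
a class for mono starters, fixed combinations as a class for fixed
starters, so within-category switches (timolol→latanoprost, or one fixed
combination to another) are continuation. Discontinuation is the earlier
of (a) a supply-exhaustion gap longer than `grace_days` (default 30)
before the next in-category fill — the event time is the exhaustion day,
i.e. last fill date plus its days supplied, not exhaustion plus grace —
and (b) the first out-of-category dispensing day. A same-day tie resolves
to the switch, the more specific reason. Patients with neither event by
day 365 are censored at 365; a gap can only be *observed* if more than
`grace_days` remain in the window after exhaustion, so exhaustion after
day 334 censors.

The Kaplan–Meier estimator, Greenwood variance, Wald CIs, log-rank test
and Hall–Wellner bands are implemented in the package (the external
survival libraries serve as independent cross-checks in the test suite,
not as the implementation):

* Wald CIs are plain-scale, S ± 1.96·sqrt(Greenwood), clipped to [0, 1].
  A log(−log) transform is deliberately not the default because the
  analysis this mirrors reports plain Wald intervals.
* When the at-risk set is exhausted (S = 0) the Greenwood formula is
  undefined; the variance is reported as 0 with a `degenerate_variance`
  flag rather than NaN.
* The Hall–Wellner band half-width at an event time is
  h·n^(−1/2)·(1 + n·σ²)·S with σ² the Greenwood variance over S². The
  critical value h uses the full Brownian-bridge sup quantile (Kolmogorov
  distribution; 1.3581 at 95%) rather than the restricted-interval table,
  a conservative choice that also guarantees the band is everywhere at
  least as wide as the pointwise Wald interval. With no events the band
  collapses to the point estimate and is flagged.
* The log-rank statistic uses the hypergeometric variance with the usual
  (n−d)/(n−1) tie correction; times where the combined risk set is below
  2 contribute nothing.

## Statistical layer

The t test on mean PDC is pooled-variance Student's t by default (Welch
available); only "t test" is specified upstream, and the pooled variant is
the one whose p-value lands nearest the published 0.5131 from the printed
summaries. Pearson's χ² on 2×2 tables uses **no continuity correction**:
this is validated, not assumed — the uncorrected statistic reproduces both
published p-values (0.3225 and 0.0061) to four decimals, while the Yates
correction does not. Multiplicity uses Bonferroni with m = 6 prespecified
tests; significance is strict, p < 0.05/6 ≈ 0.00833 (the source sentence
printing ">" alongside "=0.00833" is an evident typo for "<").

The factor screen fits one univariate logistic model per covariate on its
complete cases (checkup covariates are ~45–55% missing by design, so
per-factor n varies), with a likelihood-ratio p-value against the
intercept-only model; Wald p-values are obtainable from the returned fits
but LR is the default because it is better calibrated at these event
rates. Factors with p < 0.1 enter forward/backward stepwise selection
(entry 0.10, stay 0.10 — unspecified upstream, chosen to match the screen
threshold; configurable). Separation is detected (non-overlapping covariate
ranges between outcome classes) and flagged, never silently dropped. An
empty final model is a valid outcome. Final odds ratios are per unit with
Wald 95% CIs.

## Utilization

Exam claims are counted per category (ophthalmoscopy/tonometry, perimetry,
OCT) over post-index days 0–364 and bucketed (0, 1–3, 4–6, 7–9, 10–12,
>12). Surgery incidence counts patients with a first glaucoma surgery in
the window; person-time runs from index to first surgery, capped at one
year for surgery-free patients (the published rates' person-time basis is
unstated, so the capped convention is documented here and those rates are
not treated as reproducible).

## Synthetic claims generator

The generator emulates the *structure* the analysis assumes, not the
source population:

* **Adherence propensity** θ ~ Beta(α, β) per patient (defaults α = 2,
  β = 1, mean 2/3 ≈ the published ~60% mean PDC), floored at 0.05;
  `adherence_fixed_theta` pins θ for calibration runs. Refills fall due at
  supply exhaustion and the realized cycle is max(supply,
  round(supply/θ)), so long-run coverage fraction ≈ θ — which makes mean
  PDC analytically checkable.
* **Discontinuation** is a latent exponential day D at
  `discontinuation_hazard_per_day` (default 0.003). A due refill is
  dispensed only if its supply would be consumed by D, so the final
  claim's coverage ends at or shortly before D and the claims-derived
  event time does not overshoot the latent day.
* **Paths**: guideline-compliant (mono at index, fixed-combination switch
  on a uniform day in [30, 330]), noncompliant (fixed at index), other
  (mono only, or mono→unfixed for ~9%), ineligible (exactly one violated
  rule: short washout, pre-index surgery, or short follow-up). The default
  mix gives the published 10.1 / 4.6 / 85.3 split within eligibles and a
  20% ineligible arm. First-line product frequencies follow the published
  first-line landscape (latanoprost 32.9%, tafluprost 20.6%, travoprost
  13.9%, ... ; dorzolamide/timolol 42.3% of fixed starts). The
  second-line stream after a compliant switch is not subject to the
  first-line discontinuation clock (it represents a new therapy episode).
* **Bilateral** patients (10%) always fill 7 bottles; unilateral fills
  draw 1–3 bottles (0.5/0.3/0.2). Diagnoses are H401 with probability 0.8
  else H409, dated at index. Exams are Poisson with the published annual
  means (5.0 / 0.04 / 1.2); surgery occurs with probability 0.015 on a
  uniform day strictly after index. Checkup covariates are independent
  draws around published means (age 52 ± 12, BMI 23.2 ± 3.7, log-normal
  γ-GTP, ...) with 45% missingness on checkup fields.

Ground truth records each patient's path, θ, latent discontinuation day,
eye count, switch day and violated rule, enabling exact label-recovery
tests. What the generator does **not** emulate: enrollment churn and
death, seasonality, dose strengths, billing code realism, correlated
covariates, or any dependence of adherence on covariates — so passing
tests demonstrate the *pipeline's* correctness under known conditions,
not fidelity of any particular estimate to a real population.

## Calibration checks and problem sizes

The suite validates each estimator against an independent oracle: PDC
against a per-day inventory recount (1,000 random timelines), the
product-limit fit against a naive risk-set recount (n ≤ 20) and against
lifelines, the log-rank test against a hand tally and lifelines, the
Hall–Wellner band against a from-scratch formula evaluation. Statistical
calibration uses: log-rank type-I error over 1,000 equal-hazard replicates
(0.05 ± 0.02); screen pass-rate over 600 null factors at n = 5,000
(0.1 ± 0.04); odds-ratio CI coverage ≥ 90% over 100 replicates each at
true OR 1.5 and 2.0, n = 5,000.

End-to-end recovery runs the full pipeline: with hazard 0 and θ ≡ 1,
PDC and 12-month persistence are exactly 100%; with hazard h = 0.002 at
n = 2,000 the KM 12-month persistence is compared to the closed form
100·(1−h)^365 within three Monte-Carlo standard errors. The hazard
calibration uses single-bottle fills (30-day cycles) and no bilateral
fills: coarser supplies (60/90/105-day cycles) quantize the claims-based
event time up to a full cycle below the latent day, a real feature of
claims-measured persistence that the continuous closed form deliberately
ignores; the finest granularity the model supports aligns the experiment
with the formula's assumption.

## Known limitations

* Index-day regimen classification treats any multi-product day as
  unfixed combination; simultaneous dispensing of drops for the fellow eye
  is not distinguishable in claims.
* The observability (coverage) table is trusted as given; there is no
  enrollment-gap inference.
* The stepwise screen is complete-case per model; no imputation, no
  interactions, no penalization.
* Persistence within the compliant cohort is structurally short whenever
  every member's defining switch occurs inside the outcome window — with
  the default 365-day compliance window the cohort's 12-month first-line
  persistence is 0 by construction. Interpreting cohort persistence
  therefore requires attention to the window configuration.
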