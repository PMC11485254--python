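# Methods

This note documents the models, rules and numerical choices behind the
package: the 0–6 GDMT score, the synthetic trial generator, and the
pre-specified statistical analysis. It records the design decisions made
where the underlying protocol leaves the choice open.

## The GDMT score

The score summarizes adherence to the non-conditional (class I)
pharmacotherapy recommendations for heart failure with reduced ejection
fraction (HFrEF). Six components each contribute up to one point:

| component | value | basis |
|---|---|---|
| ACE/ARB/ARNI dose | used dose / target dose, capped at 1 | dose ratio |
| switch to ARNI | 1 if an ARNI is prescribed | binary |
| β-blocker dose | used dose / target dose, capped at 1 | dose ratio |
| MRA dose | used dose / target dose, capped at 1 | dose ratio |
| SGLT2i | 1 if prescribed | binary |
| iron | 1 if screened ≤ 365 days ago and replete (or IV iron given) | binary |

The total is the plain sum, 0–6; ΔGDMT is the follow-up total minus the
baseline total, so positive values mean therapy improved. (The protocol's
verbal description of the subtraction order is ambiguous; the
follow-up-minus-baseline convention is the one under which an improving
patient has a positive change, matching how the trial reports medians.)

Dose ratios are capped at 1 because the score bounds demand it: a dose
above target is "at target" for adherence purposes. SGLT2i is scored
prescribed/not-prescribed regardless of dose, since both approved agents
have a single target dose. The ARNI switch point is granted whenever an
ARNI is prescribed, including de novo starts that never passed through an
ACE inhibitor.

Target doses come from a shipped reference table
(`gdmttrial/data/target_doses.json`, ESC-style targets such as
sacubitril/valsartan 400 mg/day, bisoprolol 10 mg/day, spironolactone
50 mg/day, dapagliflozin 10 mg/day). The table is a configuration file,
not a constant: users can replace it with any JSON/TSV covering the six
drug classes.

### Valid reasons (contraindications)

A documented reason for not prescribing a medication scores its component
as 1 — the score measures what is achievable for the patient. The engine
implements the protocol's reason list with thresholds applied exactly as
written (strict where strict):

- persistent systolic BP ≤ 90 mmHg — two or more readings ≤ 90 within a
  14-day lookback, in a patient *without* symptoms (the protocol gives
  the two-reading rule but no window; 14 days is this package's choice);
  excuses all four medication groups, including the ARNI switch;
- symptomatic hypotension — excuses all four groups;
- eGFR < 30 mL/min/1.73 m² — excuses ACE/ARB/ARNI and MRA;
- eGFR < 20 — excuses SGLT2i;
- potassium > 5.0 mmol/L — excuses ACE/ARB/ARNI and MRA;
- heart rate ≤ 60 bpm (latest reading) — excuses the β-blocker;
- allergy — excuses its own class.

A reason lifts a component to 1 only if it is below 1; a component already
at target keeps its dose-ratio basis. A threshold reason never fires on
missing data (a missing lab is not a contraindication), and the iron
component has no pharmacological contraindication, so reasons never apply
to it. Iron deficiency is ferritin < 100 µg/L, or ferritin < 300 µg/L with
transferrin saturation < 20%; when the labs needed to decide are absent
the state is "unscreened", which is deliberately distinct from
"not deficient" (`UnscreenedError`).

### OMT and time to OMT

Optimal medical therapy is a score of 1 for every component, equivalent to
a total of exactly 6. Whether the iron and ARNI-switch components belong
in the OMT definition is arguable; `is_omt` therefore takes a
`components` argument (default: all six) so either convention can be
used. `time_to_omt` scans a time-ordered snapshot trajectory and returns
the first qualifying day, or censoring at the horizon (84 days by
default).

## The synthetic trial generator

No patient-level data are distributed with the trial this package
emulates, so every analysis runs on synthetic cohorts. The generator
reproduces the *design*: 150 patients, 1:1 stratified variable-block
randomization (blocks of 2, 4 and 6 drawn uniformly per block; strata =
new-onset status × hospital), 12-week follow-up, ~5% dropout.

Baseline distributions are calibrated to the published baseline table of
the trial: prescription rates per medication group (RASi 0.91, of which
47% ARNI; β-blocker 0.79; MRA 0.64; SGLT2i 0.57), potassium ~
N(4.26, 0.45²) mmol/L, eGFR log-normal with median ≈ 67 mL/min/1.73 m²,
systolic BP ~ N(125, 15²) mmHg, iron screened at baseline in ~31% with
~64% of screened patients deficient. Dose fractions sit on the discrete
grid {¼, ½, 1} with per-class weights matching the published class-level
mean ratios, because real titration proceeds in discrete steps.
Contraindications are *induced by the drawn labs and vitals* — a patient
whose potassium comes out at 5.3 genuinely triggers the hyperkalemia rule
in the scoring engine — never assigned as independent labels.

Follow-up dynamics are artifact choices (the trial reports outcomes, not
a generative model): consults arrive as Poisson counts per arm (defaults:
remote 2.4/1.3 and physical 1.2/1.4 per 84 days for DC/usual care); at
each consult every sub-target component independently moves one step up
the dose grid with an arm-specific probability unless a valid reason
excuses it; patients on ACE/ARB may switch to ARNI with the same
probability; iron screening occurs per consult with an arm-specific
probability. The per-consult uptitration probabilities are unreported in
the source trial; the defaults (DC 0.20, usual care 0.08) were chosen so
that the simulated usual-care arm yields a small median ΔGDMT (~0–0.1)
and the DC arm ~1–1.3, the stated calibration targets. Reaching OMT is
absorbing for medication changes. All calibration constants live in
`gdmttrial/data/default_sim_config.json`, not in code.

Baseline iron screenings are drawn at most `365 − horizon` days old, so a
screen valid at randomization cannot silently expire mid-trial.

Randomness: one seed per dataset, split into per-patient streams via
`SeedSequence([seed, patient_index, stage])`, so enlarging a cohort never
perturbs already-generated patients; the randomization sequence has its
own reserved stream.

What the generator does **not** emulate: mortality, NT-proBNP dynamics,
hospitalization causes (a plain Poisson count stands in), clinician
behavior beyond the per-consult probabilities, item-level KCCQ-12 scoring
(a 0–100 summary score is drawn directly), and any correlation between
questionnaire scores and treatment. Passing tests therefore demonstrate
that the *pipeline* is correct and calibrated (type-I error at the
nominal level, effects monotone in the injected parameter), not that the
simulator predicts real titration behavior.

## Statistical analysis

- **Mann–Whitney U** (primary test): exact null distribution by a
  Gaussian-binomial recursion when `n·m ≤ 400` and the data are tie-free;
  otherwise the normal approximation with tie correction and continuity
  correction. An all-equal pooled sample returns p = 1.
- **Hodges–Lehmann shift**: median of all pairwise treatment-minus-control
  differences, with the CI from inverting the rank-sum test (exact null
  CDF on the same small-sample domain, continuity-corrected normal
  otherwise). This is the estimate consistent with a Mann–Whitney
  analysis; it is *not* the difference of group medians, which the
  `EffectEstimate` exposes separately (`median_difference`). In tiny
  samples the midrank point estimate can sit a grid step outside the
  inversion interval; the interval is widened to bracket it.
- **Consult rates**: Poisson log-linear regression with an arm indicator;
  if the Pearson dispersion statistic per degree of freedom exceeds 1.5
  (the protocol says "in case of over-dispersion" without a rule), a
  negative-binomial model with ML dispersion is fitted instead, and the
  model used is reported.
- **Time to OMT**: Cox proportional hazards with a single binary
  covariate, Breslow tie handling, Newton–Raphson on the partial
  likelihood, Wald CI/p. Patients at OMT on day 0 were never at risk and
  are excluded. No events, or events confined to one arm (monotone
  likelihood), raise instead of returning a sham estimate. Cumulative
  incidence is 1 − Kaplan–Meier with Greenwood-based pointwise CIs
  (via lifelines).
- **Safety counts**: Pearson 2×2 chi-square without continuity correction
  (a Yates toggle is provided).
- **Subgroups**: the Hodges–Lehmann shift within and outside each binary
  split; its SE by seeded nonparametric bootstrap (B = 1000 by default,
  the protocol names no estimator); heterogeneity tested as
  t = (Δ_in − Δ_out)/√(SE_in² + SE_out²) against the large-sample normal
  reference (the protocol specifies no degrees of freedom). No
  multiplicity adjustment across subgroups, mirroring the exploratory
  framing.
- **NPS**: promoters 9–10, passives 7–8, detractors ≤ 6;
  NPS = 100·(promoters − detractors)/n. The mean rating is reported
  alongside, since a "moderately positive" single-digit NPS quoted for a
  7/11/6 panel is arithmetically the mean rating (≈7.4), not the
  classical NPS (≈+4.2); the package reports both and asserts neither
  interpretation.
- **Design**: sample size by exact noncentral-t power of the two-sided
  two-group t-test — the smallest equal n per arm attaining the target
  power (71 per arm for Δ = 0.36, SD = 0.76, α = 0.05, power 0.80) —
  and enrolment inflated by the dropout fraction and rounded up to an
  even total (150 at 5%).

## Problem sizes and tolerances

The test suite calibrates the full simulate–score–test pipeline on 500
replicate null trials of 150 patients (type-I error required in
[0.03, 0.07]) and checks Cox log-hazard recovery at HR 4.5 on 200
replicates of 500 patients per arm (mean log-HR within 10%). Monte-Carlo
power verification uses 5000 replicate t-tests. These sizes keep the
whole suite around two to three minutes while leaving Monte-Carlo error
well inside the asserted bands. Newton iterations stop at a step below
1e-10; a |log HR| above 50 is treated as divergence.

## Known limitations

- The valid-reason engine implements the protocol's "common valid
  reasons" only; in the real trial the treating clinician could document
  other reasons.
- Dose ratios assume the prescription's total daily dose is comparable to
  the target as a scalar; combination-pill equivalence (e.g. ARNI
  components) is handled by expressing targets as total mg/day of the
  combination.
- The generator's arm effect enters only through consult frequency,
  uptitration probability and iron-screening probability; real
  intervention effects are plausibly heterogeneous across patients.
- The subgroup bootstrap resamples within arms independently, ignoring
  stratification; at trial scale the effect on SEs is small.
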