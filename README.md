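# gdmttrial

Tools for studying **guideline-directed medical therapy (GDMT) optimization
in heart failure with reduced ejection fraction (HFrEF)**: a rule-based
0–6 GDMT adherence score, a seed-reproducible synthetic two-arm trial
generator, and the pre-specified statistical analysis of a 12-week
remote-titration trial. It is written for biostatisticians and
trialists who want to test, calibrate or power this kind of
titration-score endpoint without access to patient-level data.

## The score

Each patient snapshot (prescriptions, labs, home vitals, iron screening
history) is scored on six components with equal weight:

- ACE/ARB/ARNI dose — used dose / guideline target dose, capped at 1
- switch to ARNI — 0 or 1
- β-blocker dose — 0–1
- MRA dose — 0–1
- SGLT2i prescribed — 0 or 1
- iron screening (≤ 1 year) and, if deficient, IV supplementation — 0 or 1

A documented contraindication ("valid reason": persistent systolic BP
≤ 90 mmHg, symptomatic hypotension, eGFR < 30 (< 20 for SGLT2i),
potassium > 5.0 mmol/L, heart rate ≤ 60 for β-blockers, allergy) counts
as 1 for the affected component, so the total (0–6) measures achievable
adherence. **Optimal medical therapy (OMT)** is a score of 1 on every
component; the primary endpoint is **ΔGDMT = score(12 wk) −
score(baseline)**. See `docs/methods.md` for every rule and the design
decisions behind them.

## Worked example

```python
from gdmttrial import (SimConfig, simulate_trial, analyze_dataset,
                       sample_size_two_group_t, enrollment_with_dropout)

# design: n per arm for delta 0.36 score units, SD 0.76, 80% power
n = sample_size_two_group_t(0.36, 0.76, 0.80, 0.05)   # -> 71
total = enrollment_with_dropout(n, 0.05)              # -> 150

# a full synthetic trial and its pre-specified analysis
dataset = simulate_trial(SimConfig.default(seed=20260929))
report = analyze_dataset(dataset, seed=20260929)
pr = report.primary
print(f"DC median {pr.median_b:.2f} vs usual care {pr.median_a:.2f}; "
      f"shift {pr.shift:.2f} (95% CI {pr.ci_low:.2f}, {pr.ci_high:.2f}), "
      f"p = {pr.p_value:.2g}")
```

which prints

```
DC median 1.50 vs usual care 0.00; shift 1.00 (95% CI 1.00, 1.25), p = 8.2e-12
```

i.e. in this simulated trial the digital-consult arm improved its median
GDMT score by 1.5 points over 12 weeks while usual care was flat; the
Hodges–Lehmann estimate of the between-arm shift is 1.00 score units and
the Mann–Whitney test rejects decisively. `report` also carries the
component table (per-medication baseline/follow-up/increase by arm), OMT
counts, the Breslow–Cox time-to-OMT hazard ratio with cumulative
incidence curves, Poisson/negative-binomial consult-rate ratios,
chi-square safety counts, patient-reported outcomes and the subgroup /
interaction analysis.

The same steps are available as numbered analysis drivers —
`analysis/01_design_power.py` … `04_null_calibration.py` — which write
their tables under `results/`, and as a CLI:

```sh
gdmt-trial simulate --seed 1 --out data/
gdmt-trial score    --data data/ --out scores.csv
gdmt-trial analyze  --data data/ --seed 1 --out report/
gdmt-trial power    --delta 0.36 --sd 0.76 --dropout 0.05
```

The target-dose table (`src/gdmttrial/data/target_doses.json`) and every
simulator calibration constant
(`src/gdmttrial/data/default_sim_config.json`) are plain JSON files that
can be overridden per run.

## Layout

- `src/gdmttrial/` — scoring engine, simulator, statistics, IO, pipeline, CLI
- `analysis/` — numbered narrative drivers over the library
- `tests/` — unit, property (hypothesis) and acceptance tests
- `docs/methods.md` — models, assumptions, calibration and limitations
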