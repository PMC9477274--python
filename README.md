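# nodulegrowth

Growth adjudication and VDT-based diagnostic referral for
screening-detected **indeterminate pulmonary nodules**.

In low-dose CT lung cancer screening, nodules of intermediate size (solid
nodules of 50–500 mm³; part-solid nodules whose solid component is
50–500 mm³ or whose ground-glass component averages ≥ 8 mm in diameter) are
managed by follow-up imaging, and the decision to refer a participant for
invasive workup hinges on whether — and how fast — the nodule grew. This
package implements, as a tested reusable pipeline, the competing growth
definitions and referral rules used in screening practice, and the full
paired diagnostic-performance evaluation for comparing them on a cohort
with pathology-proven outcomes. It is aimed at screening-program analysts
and radiology researchers working with semi-automated volumetry exports.

## What it computes

Per nodule, from baseline/follow-up volumes V₁, V₂ (mm³), average diameters
D₁, D₂ (mm) and interval Δt (days):

- **percentage volume growth** PVG = (V₂ − V₁)/V₁ × 100,
- **absolute diameter growth** ADG = D₂ − D₁,
- **volume doubling time** VDT = ln2 · Δt / ln(V₂/V₁) (growing volumes only),

each evaluated for the whole nodule and, for part-solid nodules, the solid
component (growth of *either* component counts). Decision rules: volumetric
growth (PVG ≥ 25%, NELSON), diametric growth (ADG > 1.5 mm, Lung-RADS),
the radiologist's subjective call, VDT-threshold referral (a ≥ 25%-growing
component with VDT < t, for t in 100–600 days), and VDT OR radiologist
referral. Rules are scored by paired sensitivity/specificity with hybrid
Wald/Clopper–Pearson 95% CIs, exact McNemar comparisons, DeLong-corrected
ROC/AUC analysis, and inter-rater agreement statistics (Cohen's κ, percent
agreement, ICC(2,1), Bland–Altman limits). A calibrated synthetic-cohort
simulator makes every stage testable without patient data. See
`docs/methods.md` for the model, defaults and limitations.

## Worked example

```python
from nodulegrowth import (NoduleObservation, ScreeningCase, Consistency,
                          compute_growth_metrics, vdt_referral, proportion_ci)

base = NoduleObservation("n1", Consistency.SOLID, whole_volume=52.0, whole_avg_diameter=4.6)
fu   = NoduleObservation("n1", Consistency.SOLID, whole_volume=76.1, whole_avg_diameter=5.3)
case = ScreeningCase("case-001", base, fu, interval_days=331, cancer=True)

m = compute_growth_metrics(case)
print(f"PVG = {m.pvg_whole:.1f}%   ADG = {m.adg_whole:.1f} mm   VDT = {m.vdt_whole:.0f} d")
print("refer at VDT<600 d:", vdt_referral(m, 600), " at VDT<400 d:", vdt_referral(m, 400))

est = proportion_ci(16, 26)
print(f"sensitivity {est.value:.1f}% (95% CI {est.ci_low:.1f}-{est.ci_high:.1f}%) "
      f"[{est.numerator} of {est.denominator}]")
```

prints

```
PVG = 46.3%   ADG = 0.7 mm   VDT = 602 d
refer at VDT<600 d: False  at VDT<400 d: False
sensitivity 61.5% (95% CI 42.8-80.2%) [16 of 26]
```

The nodule grew 46.3% in volume but only 0.7 mm in diameter, so the
volumetric rule flags it while the diametric rule does not; its doubling
time of 602 days is too slow for referral at any standard VDT threshold.
The last line is the operating-point estimate for a rule that detected 16
of 26 cancers.

## Command line

```sh
nodulegrowth simulate --n 115 --seed 7 --out-cohort cohort.csv --out-truth truth.csv
nodulegrowth assess   --cohort cohort.csv --out metrics.csv
nodulegrowth evaluate --cohort cohort.csv --out report.json
nodulegrowth report   --report report.json
```

`simulate` draws a synthetic screening cohort (defaults: 115 cases, 22.6%
cancer prevalence, study-calibrated noise); `assess` writes per-case growth
metrics and rule decisions; `evaluate` produces the full JSON study report
(operating points with raw counts and CIs, VDT-threshold table with paired
comparisons, combined-referral curves, AUCs, agreement block, solid-only
subgroup); `report` renders it as plain-text tables. Real cohorts enter as
a CSV in the schema documented in `nodulegrowth/cohort_io.py`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole pipeline from scratch: it simulates a default-configured
cohort with the given seed, executes the complete diagnostic-performance
study, and writes the cohort, truth table, JSON report and rendered tables
next to the manifest at `--out`.
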