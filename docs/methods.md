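# Methods

## Problem and scope

`nodulegrowth` analyzes two-timepoint CT volumetry of *indeterminate*
screening-detected pulmonary nodules — solid nodules of 50–500 mm³, or
part-solid nodules whose solid component is 50–500 mm³ or whose ground-glass
component has an average diameter ≥ 8 mm (the NELSON management window).
Measurements enter as numbers (volumes in mm³, average transverse diameters
in mm); image acquisition and segmentation are out of scope. The package
answers two questions about such a cohort with pathology-proven outcomes:

1. Which binary *growth* definition best discriminates lung cancer —
   percentage volume growth ≥ 25% (volumetric, NELSON), absolute average
   diameter growth > 1.5 mm (diametric, Lung-RADS), or the radiologist's
   subjective call?
2. How do *diagnostic referral* rules based on volume doubling time (VDT)
   thresholds of 100–600 days perform, alone and OR-combined with the
   radiologist's subjective referral?

## Growth model and decision rules

For baseline volume V₁, follow-up volume V₂ and interval Δt (days):

- PVG = (V₂ − V₁)/V₁ × 100 (%),
- ADG = D₂ − D₁ (mm),
- VDT = ln2 · Δt / ln(V₂/V₁) (days), defined only when V₂ > V₁.

Part-solid nodules are measured twice (whole nodule and solid component) and
the **either-component rule** applies to every rule: growth of either
component counts. VDT referral at threshold t fires when some component both
grew ≥ 25% in volume *and* has VDT < t (strict, per the NELSON description
of "VDT < 400 days positive"); VDT is never evaluated in components below
the 25% growth gate, so a referral cannot arise from a barely-drifting
volume with a short nominal doubling time. Thresholds (25%, 1.5 mm, the VDT
grid) are parameters with these defaults, never hidden constants.
Consistency (solid vs part-solid) is fixed at baseline for rule dispatch.
Dominant-nodule selection orders by comparable volume (whole volume for
solid, solid-component volume for part-solid) and breaks ties by solid
priority, then identifier. The 50–500 mm³ window is inclusive at both ends.
No rounding occurs before thresholding; reported percentages are rounded to
one decimal only in the text renderer.

One measured inconsistency in the source material is resolved in favor of
the stated formula: the worked example's percentage (31.7% for
52.0→76.1 mm³) matches a follow-up-volume denominator; the definition above
yields 46.3%, and that is what the package computes.

## Statistics

**Operating-point CIs.** Sensitivity/specificity CIs use a hybrid rule
reverse-engineered from the printed intervals: Wald p̂ ± 1.96·√(p̂(1−p̂)/n)
clipped to [0, 100] for 0 < k < n, exact Clopper–Pearson when k = 0 or
k = n (where Wald is degenerate). This reproduces all fourteen distinct
printed intervals to one decimal. Both pure methods are selectable.

**Paired comparisons.** Sensitivities (on cancers) and specificities (on
benigns) of two rules are compared with McNemar's test; the default is the
exact two-sided binomial on the discordant pairs, p = min(1, 2·P(X ≤
min(b,c)) ), appropriate for the small discordant counts typical here; the
continuity-corrected χ² variant is available. The source's own p-values
came from unstated software defaults and are treated as qualitative, not
reproduction targets.

**ROC/AUC.** The empirical AUC is the tie-corrected Mann–Whitney statistic
(half credit for ties); the curve comes from `sklearn.metrics.roc_curve`.
Variance and the paired test use DeLong's placement-value (structural
component) machinery, implemented with midranks in O(n log n); CIs are
auc ± 1.96·se clipped to [0, 1]. Case-level scores: max-over-components PVG
and ADG, and −(shortest VDT among ≥25%-growing components) with
non-qualifying cases ranked at the bottom.

**Agreement.** Cohen's κ with the Fleiss–Cohen–Everitt asymptotic CI
(clipped to [−1, 1]; identical constant raters yield a perfect-agreement
sentinel), raw percent agreement, ICC(2,1) (two-way random effects,
absolute agreement, single measurement) from ANOVA mean squares with the
McGraw–Wong F-based CI, and Bland–Altman limits d̄ ± 1.96·SD (ddof = 1).
The shipped report applies κ/percent agreement to pairs of binary rules;
the measurement-agreement functions (ICC, Bland–Altman) are library
functions for duplicate-reading data, which the cohort schema itself does
not carry.

## Synthetic cohort generator

The generator emulates the *structure* of the motivating 115-nodule cohort;
defaults are that study's marginals:

| parameter | default | basis |
|---|---|---|
| n_cases / prevalence | 115 / 0.226 | cohort size, 26/115 cancers |
| part-solid fraction | 7/89 benign, 15/26 cancer | consistency mix |
| baseline volumes | lognormal per stratum | moment-matched to the reported stratum means/SDs; solid strata truncated to 50–500 mm³ |
| interval | lognormal, median 201 d, log-SD 0.795 (IQR ≈ 127–371 d), min 30 d | follow-up interval distribution |
| cancer VDT | lognormal, median 260 d, log-SD 0.45 | growing-nodule mean VDT 260.3 d, range ≈ 71–391 d |
| indolent fraction | 8/26 | cancers with VDT > 600 d; drawn from a lognormal (median 900 d) truncated above 600 d |
| benign true growth | 0.05 solid, 0.30 part-solid, VDT 800 d | reproduces truly growing benign (especially part-solid) nodules |
| volume noise CV | 0.17 per scan | calibrated: 1 − Φ(ln1.25/(σ√2)) = 0.157 with σ = ln(1 + CV), matching the 14/89 benign false-growth rate |
| diameter noise | 0.5 mm per scan, additive | chosen so benign diametric false positives are rare (~2%), consistent with the reported 3/89; the inter-reader LoA (±2.75 mm) includes between-reader segmentation disagreement and would overstate scan–rescan noise |
| reader calls | growth 14/26 & 88/89, referral 20/26 & 86/89 | reported reader operating points |

Mechanics: cancers grow exponentially, V(t) = V₀·2^(Δt/VDT), both part-solid
components sharing the drawn VDT (the study reports near-identical component
VDTs); benign nodules are static unless drawn as true growers. Measured
volumes are truth × exp(ε) with ε ~ N(0, σ²) *per scan* (baseline and
follow-up errors independent, matching a two-scanner reality; σ adds in
quadrature across the pair). Diameters are sphere-equivalent, (6V/π)^(1/3),
plus additive noise — the study provides no measured volume–diameter
relation. The part-solid solid fraction is Beta(2, 20) (mean ≈ 0.09, the
reported component/whole volume ratio), which keeps solid ≤ whole by
construction. Reader calls are Bernoulli draws conditional on cancer status.
Every draw flows through one `numpy` generator keyed by `seed`.

Baseline eligibility is guaranteed by rejection: the per-case draw is
repeated until the *measured* baseline observation passes the indeterminate
filter. This conditions baseline noise slightly near the window edges; the
empirically measured benign flag rate stays within ~1.5 binomial SE of the
closed form at n = 10⁴.

**What a green test does not establish.** The generator draws each case
independently; it has no scanner- or reader-identity effects, no
correlation between nodule size and noise, no volume–diameter measurement
discrepancy beyond additive noise, only two timepoints, and realistic but
convenient parametric shapes. Recovery of its own parameters validates the
pipeline's arithmetic and calibration logic, not the clinical
generalizability of any operating point.

## Numerical and degenerate-input choices

- VDT for non-growing volumes is *absent* (None), not infinite or negative.
- Wald z = 1.959964 (Φ⁻¹(0.975)); Bland–Altman uses the conventional 1.96.
- McNemar with no discordant pairs: statistic 0, p = 1.
- DeLong with zero variance of the difference: p = 1 for equal AUCs, 0
  otherwise; perfect separation gives CI (1, 1).
- ICC with zero between-subject variance returns a degenerate sentinel;
  MSE = 0 (perfect within-subject reproducibility) collapses the CI to the
  point estimate.
- Cohorts lacking either outcome class are rejected
  (`DegenerateCohortError`); the solid-only subgroup is emitted only when it
  retains ≥ 2 cases per class, otherwise marked unavailable. Missing reader
  columns drop the reader-dependent blocks rather than erroring.
- Every percentage in a report is stored beside its numerator/denominator;
  `audit_report` re-derives each one (built into the test suite).

## Known limitations

- The combined referral's union default cannot reproduce the source
  Discussion's "same sensitivity at higher specificity" claim from printed
  marginals; the intersection mode is provided, but the exact intended
  semantics are unknowable from the text.
- The hybrid CI rule is a reconstruction: it matches every printed interval,
  but the original software's method is unstated.
- p-values are reproduced qualitatively (significant vs not), not bit-exactly,
  since the original software defaults are unknown.
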