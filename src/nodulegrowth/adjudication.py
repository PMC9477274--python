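"""Binary growth adjudication and diagnostic-referral rules.

Three growth definitions are supported: volumetric (percentage volume growth
>= 25%, the NELSON criterion), diametric (absolute average-diameter growth
> 1.5 mm, the Lung-RADS criterion) and the radiologist's subjective call,
which enters as a recorded label.  Diagnostic referral is driven by the
volume doubling time: a case is referred at threshold ``t`` when some
component grew >= 25% in volume and that component's VDT is shorter than
``t`` days.  For part-solid nodules the either-component rule applies
throughout: growth of either the whole nodule or the solid component counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .errors import EmptyInputError, InsufficientDataError
from .growth import compute_growth_metrics
from .performance import ConfusionCounts
from .types import GrowthMetrics, ScreeningCase

#: Default thresholds; all of them are parameters, never hidden constants.
VOLUMETRIC_THRESHOLD_PERCENT = 25.0
DIAMETRIC_THRESHOLD_MM = 1.5
VDT_THRESHOLDS_DAYS = (600, 500, 400, 300, 200, 100)

RuleName = Literal["volumetric", "diametric", "radiologist", "vdt", "combined"]
CombineMode = Literal["union", "intersection"]


@dataclass(frozen=True)
class GrowthCall:
    """Per-case growth adjudication under the three definitions."""

    volumetric: bool
    diametric: bool
    radiologist: bool | None = None


@dataclass(frozen=True)
class ReferralCall:
    """Per-case VDT referral decision, optionally combined with the reader."""

    vdt_threshold_days: int
    vdt_positive: bool
    combined_positive: bool | None = None


@dataclass(frozen=True)
class RuleSpec:
    """Parameterization of one binary decision rule."""

    rule: RuleName
    vdt_threshold_days: int = 400
    combine_mode: CombineMode = "union"
    volumetric_threshold_percent: float = VOLUMETRIC_THRESHOLD_PERCENT
    diametric_threshold_mm: float = DIAMETRIC_THRESHOLD_MM


def volumetric_growth(
    m: GrowthMetrics, threshold_percent: float = VOLUMETRIC_THRESHOLD_PERCENT
) -> bool:
    """Percentage volume growth >= threshold in any component (inclusive)."""
    if m.pvg_whole >= threshold_percent:
        return True
    return m.is_part_solid and m.pvg_solid is not None and m.pvg_solid >= threshold_percent


def diametric_growth(m: GrowthMetrics, threshold_mm: float = DIAMETRIC_THRESHOLD_MM) -> bool:
    """Absolute diameter growth strictly > threshold in any component."""
    if m.adg_whole > threshold_mm:
        return True
    return m.is_part_solid and m.adg_solid is not None and m.adg_solid > threshold_mm


def vdt_referral(
    m: GrowthMetrics,
    vdt_threshold_days: float,
    growth_threshold_percent: float = VOLUMETRIC_THRESHOLD_PERCENT,
) -> bool:
    """VDT-based referral: a component must first qualify as growing.

    VDT is only evaluated in components with percentage volume growth >= 25%
    (so a component whose volume did not grow can never trigger referral);
    the referral fires when such a component's VDT is strictly below the
    threshold.
    """
    if vdt_threshold_days <= 0:
        raise ValueError(f"vdt_threshold_days must be > 0, got {vdt_threshold_days}")
    components = [(m.pvg_whole, m.vdt_whole)]
    if m.is_part_solid:
        components.append((m.pvg_solid, m.vdt_solid))
    for pvg, vdt in components:
        if pvg is None or vdt is None:
            continue
        if pvg >= growth_threshold_percent and vdt < vdt_threshold_days:
            return True
    return False


def combined_referral(
    vdt_positive: bool,
    radiologist_referral: bool | None,
    mode: CombineMode = "union",
) -> bool:
    """Combine the VDT referral with the radiologist's subjective referral."""
    if radiologist_referral is None:
        raise InsufficientDataError("combined referral requires a radiologist referral call")
    if mode == "union":
        return vdt_positive or radiologist_referral
    if mode == "intersection":
        return vdt_positive and radiologist_referral
    raise ValueError(f"unknown combine mode: {mode!r}")


def decide_case(case: ScreeningCase, m: GrowthMetrics, rule: RuleSpec) -> bool:
    """Apply one rule to one case's growth metrics."""
    if rule.rule == "volumetric":
        return volumetric_growth(m, rule.volumetric_threshold_percent)
    if rule.rule == "diametric":
        return diametric_growth(m, rule.diametric_threshold_mm)
    if rule.rule == "radiologist":
        if case.radiologist_growth is None:
            raise InsufficientDataError(
                f"case {case.case_id}: radiologist growth call missing"
            )
        return case.radiologist_growth
    if rule.rule == "vdt":
        return vdt_referral(m, rule.vdt_threshold_days, rule.volumetric_threshold_percent)
    if rule.rule == "combined":
        vdt_pos = vdt_referral(m, rule.vdt_threshold_days, rule.volumetric_threshold_percent)
        return combined_referral(vdt_pos, case.radiologist_referral, rule.combine_mode)
    raise ValueError(f"unknown rule: {rule.rule!r}")


@dataclass(frozen=True)
class ClassificationResult:
    """Per-case decisions (input order) and their 2x2 tabulation."""

    rule: RuleSpec
    decisions: list[bool] = field(default_factory=list)
    counts: ConfusionCounts = None  # type: ignore[assignment]


def classify_cohort(cases: list[ScreeningCase], rule: RuleSpec) -> ClassificationResult:
    """Vectorized rule application plus tabulation against cancer status."""
    if not cases:
        raise EmptyInputError("classify_cohort: empty cohort")
    decisions = [decide_case(c, compute_growth_metrics(c), rule) for c in cases]
    tp = sum(1 for c, d in zip(cases, decisions) if c.cancer and d)
    fn = sum(1 for c, d in zip(cases, decisions) if c.cancer and not d)
    fp = sum(1 for c, d in zip(cases, decisions) if not c.cancer and d)
    tn = sum(1 for c, d in zip(cases, decisions) if not c.cancer and not d)
    return ClassificationResult(
        rule=rule, decisions=decisions, counts=ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    )
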