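"""End-to-end study evaluation: cohort summary, operating points, VDT
threshold analysis, ROC/AUC comparison and rule-agreement statistics.

``run_study`` composes the growth, adjudication and performance modules
into a single JSON-serializable report mirroring a diagnostic-accuracy
paper's result tables: a baseline measurement summary, the three growth
definitions' operating points with paired McNemar comparisons, the VDT
referral thresholds compared against the 600-day reference and against the
radiologist's subjective referral, combined (VDT OR reader) referral
curves, AUCs with DeLong CIs, and agreement between the binary rules.

Every percentage stored in the report sits beside the raw counts it was
computed from, so reports are self-auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .adjudication import (
    DIAMETRIC_THRESHOLD_MM,
    VDT_THRESHOLDS_DAYS,
    VOLUMETRIC_THRESHOLD_PERCENT,
    RuleSpec,
    classify_cohort,
    combined_referral,
)
from .errors import DegenerateCohortError, EmptyInputError
from .growth import compute_growth_metrics
from .performance import (
    ConfusionCounts,
    cohens_kappa,
    delong_auc_ci,
    delong_paired_test,
    mcnemar_test,
    percent_agreement,
    sensitivity_specificity,
)
from .types import Consistency, GrowthMetrics, ScreeningCase

REPORT_SCHEMA_VERSION = 1

#: score given to cases with no VDT-eligible growing component (ranks last)
_NO_VDT_SCORE = -1.0e12


@dataclass(frozen=True)
class StudyReport:
    """Thin wrapper around the JSON-serializable report dictionary."""

    data: dict[str, Any]

    def __getitem__(self, key: str) -> Any:
        return self.data[key]


# ---------------------------------------------------------------------------
# summary (baseline-characteristics table analog)


def _stat_block(values: list[float]) -> dict[str, float | int]:
    if not values:
        return {"n": 0}
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def summarize_cohort(cases: list[ScreeningCase]) -> dict[str, Any]:
    """Per-stratum mean +- SD and range of volumes/diameters, growth counts.

    Strata: {total, solid, part_solid, solid_component} x {all, cancer,
    benign} x {baseline, followup}.  Growth counts use the whole-nodule
    volumetric (>= 25%) and diametric (> 1.5 mm) criteria.
    """
    if not cases:
        raise EmptyInputError("summarize_cohort: empty cohort")
    metrics = [compute_growth_metrics(c) for c in cases]

    def subset(group: str) -> list[tuple[ScreeningCase, GrowthMetrics]]:
        pairs = list(zip(cases, metrics))
        if group == "cancer":
            return [(c, m) for c, m in pairs if c.cancer]
        if group == "benign":
            return [(c, m) for c, m in pairs if not c.cancer]
        return pairs

    out: dict[str, Any] = {"n_cases": len(cases), "strata": {}}
    for group in ("all", "cancer", "benign"):
        pairs = subset(group)
        gdict: dict[str, Any] = {}
        for stratum in ("total", "solid", "part_solid", "solid_component"):
            if stratum == "total":
                sel = pairs
            elif stratum == "solid":
                sel = [(c, m) for c, m in pairs if c.consistency is Consistency.SOLID]
            else:
                sel = [(c, m) for c, m in pairs if c.consistency is Consistency.PART_SOLID]
            if stratum == "solid_component":
                vol_b = [c.baseline.solid_volume for c, _ in sel]
                vol_f = [c.followup.solid_volume for c, _ in sel]
                dia_b = [c.baseline.solid_avg_diameter for c, _ in sel]
                dia_f = [c.followup.solid_avg_diameter for c, _ in sel]
                growth: dict[str, Any] = {"volumetric": None, "diametric": None}
            else:
                vol_b = [c.baseline.whole_volume for c, _ in sel]
                vol_f = [c.followup.whole_volume for c, _ in sel]
                dia_b = [c.baseline.whole_avg_diameter for c, _ in sel]
                dia_f = [c.followup.whole_avg_diameter for c, _ in sel]
                growth = {
                    "volumetric": sum(
                        1 for _, m in sel if m.pvg_whole >= VOLUMETRIC_THRESHOLD_PERCENT
                    ),
                    "diametric": sum(
                        1 for _, m in sel if m.adg_whole > DIAMETRIC_THRESHOLD_MM
                    ),
                }
            gdict[stratum] = {
                "volume_baseline": _stat_block([v for v in vol_b if v is not None]),
                "volume_followup": _stat_block([v for v in vol_f if v is not None]),
                "diameter_baseline": _stat_block([v for v in dia_b if v is not None]),
                "diameter_followup": _stat_block([v for v in dia_f if v is not None]),
                "growing": growth,
            }
        out["strata"][group] = gdict
    return out


# ---------------------------------------------------------------------------
# per-case metrics table (used by the `assess` CLI step)


def metrics_frame(
    cases: list[ScreeningCase],
    vdt_thresholds: tuple[int, ...] = VDT_THRESHOLDS_DAYS,
) -> pd.DataFrame:
    """Per-case growth metrics and rule decisions, aligned with input order."""
    if not cases:
        raise EmptyInputError("metrics_frame: empty cohort")
    rows = []
    for c in cases:
        m = compute_growth_metrics(c)
        vol = classify_cohort([c], RuleSpec("volumetric")).decisions[0]
        dia = classify_cohort([c], RuleSpec("diametric")).decisions[0]
        row: dict[str, Any] = {
            "case_id": c.case_id,
            "cancer": int(c.cancer),
            "consistency": c.consistency.value,
            "pvg_whole": m.pvg_whole,
            "adg_whole": m.adg_whole,
            "vdt_whole": m.vdt_whole,
            "pvg_solid": m.pvg_solid,
            "adg_solid": m.adg_solid,
            "vdt_solid": m.vdt_solid,
            "volumetric_growth": int(vol),
            "diametric_growth": int(dia),
        }
        for t in vdt_thresholds:
            row[f"vdt_referral_{t}d"] = int(
                classify_cohort([c], RuleSpec("vdt", vdt_threshold_days=t)).decisions[0]
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full study


def _prop_dict(p) -> dict[str, Any]:
    return {
        "value": p.value,
        "ci_low": p.ci_low,
        "ci_high": p.ci_high,
        "numerator": p.numerator,
        "denominator": p.denominator,
        "method": p.method,
    }


def _operating_point(cases, decisions) -> dict[str, Any]:
    tp = sum(1 for c, d in zip(cases, decisions) if c.cancer and d)
    fn = sum(1 for c, d in zip(cases, decisions) if c.cancer and not d)
    fp = sum(1 for c, d in zip(cases, decisions) if not c.cancer and d)
    tn = sum(1 for c, d in zip(cases, decisions) if not c.cancer and not d)
    counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    sens, spec = sensitivity_specificity(counts)
    return {
        "counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        "sensitivity": _prop_dict(sens),
        "specificity": _prop_dict(spec),
    }


def _paired_p(cases, dec_a, dec_b, on: str) -> float:
    keep = [c.cancer for c in cases] if on == "cancer" else [not c.cancer for c in cases]
    a = [d for d, k in zip(dec_a, keep) if k]
    b = [d for d, k in zip(dec_b, keep) if k]
    return mcnemar_test(a, b).p_value


def _case_scores(cases: list[ScreeningCase]) -> dict[str, list[float]]:
    """Case-level continuous scores for ROC analysis (either-component rule).

    ``pvg``/``adg``: the larger of the whole-nodule and solid-component
    values.  ``neg_vdt``: minus the shortest VDT among components that grew
    >= 25% in volume; cases with no such component rank at the bottom.
    """
    pvg, adg, neg_vdt = [], [], []
    for c in cases:
        m = compute_growth_metrics(c)
        pvals = [m.pvg_whole] + ([m.pvg_solid] if m.pvg_solid is not None else [])
        avals = [m.adg_whole] + ([m.adg_solid] if m.adg_solid is not None else [])
        pvg.append(max(pvals))
        adg.append(max(avals))
        vdts = [
            v
            for p, v in [(m.pvg_whole, m.vdt_whole), (m.pvg_solid, m.vdt_solid)]
            if p is not None and v is not None and p >= VOLUMETRIC_THRESHOLD_PERCENT
        ]
        neg_vdt.append(-min(vdts) if vdts else _NO_VDT_SCORE)
    return {"pvg": pvg, "adg": adg, "neg_vdt": neg_vdt}


def _auc_block(cases: list[ScreeningCase]) -> dict[str, Any]:
    labels = [c.cancer for c in cases]
    scores = _case_scores(cases)
    block: dict[str, Any] = {}
    for name in ("pvg", "adg", "neg_vdt"):
        auc, lo, hi = delong_auc_ci(scores[name], labels)
        block[name] = {"auc": auc, "ci_low": lo, "ci_high": hi}
    cmp_res = delong_paired_test(scores["pvg"], scores["adg"], labels)
    block["pvg_vs_adg"] = {"z": cmp_res.statistic, "p_value": cmp_res.p_value}
    return block


def _analysis_block(
    cases: list[ScreeningCase],
    vdt_thresholds: tuple[int, ...],
    combine_mode: str,
) -> dict[str, Any]:
    growth_available = all(c.radiologist_growth is not None for c in cases)
    referral_available = all(c.radiologist_referral is not None for c in cases)

    dec_vol = classify_cohort(cases, RuleSpec("volumetric")).decisions
    dec_dia = classify_cohort(cases, RuleSpec("diametric")).decisions

    growth_rules: dict[str, Any] = {
        "volumetric": _operating_point(cases, dec_vol),
        "diametric": _operating_point(cases, dec_dia),
    }
    comparisons = {
        "volumetric_vs_diametric": {
            "sensitivity_p": _paired_p(cases, dec_vol, dec_dia, "cancer"),
            "specificity_p": _paired_p(cases, dec_vol, dec_dia, "benign"),
        }
    }
    dec_rad = None
    if growth_available:
        dec_rad = classify_cohort(cases, RuleSpec("radiologist")).decisions
        growth_rules["radiologist"] = _operating_point(cases, dec_rad)
        comparisons["volumetric_vs_radiologist"] = {
            "sensitivity_p": _paired_p(cases, dec_vol, dec_rad, "cancer"),
            "specificity_p": _paired_p(cases, dec_vol, dec_rad, "benign"),
        }
        comparisons["diametric_vs_radiologist"] = {
            "sensitivity_p": _paired_p(cases, dec_dia, dec_rad, "cancer"),
            "specificity_p": _paired_p(cases, dec_dia, dec_rad, "benign"),
        }

    # VDT threshold table, reference = longest threshold (paper: 600 days)
    thresholds = tuple(sorted(vdt_thresholds, reverse=True))
    vdt_decisions = {
        t: classify_cohort(cases, RuleSpec("vdt", vdt_threshold_days=t)).decisions
        for t in thresholds
    }
    ref_t = thresholds[0]
    dec_ref_reader = None
    if referral_available:
        dec_ref_reader = [bool(c.radiologist_referral) for c in cases]
    vdt_table = []
    for t in thresholds:
        row: dict[str, Any] = {"vdt_threshold_days": t}
        row.update(_operating_point(cases, vdt_decisions[t]))
        if t != ref_t:
            row["vs_reference"] = {
                "sensitivity_p": _paired_p(cases, vdt_decisions[t], vdt_decisions[ref_t], "cancer"),
                "specificity_p": _paired_p(cases, vdt_decisions[t], vdt_decisions[ref_t], "benign"),
            }
        if dec_ref_reader is not None:
            row["vs_radiologist_referral"] = {
                "sensitivity_p": _paired_p(cases, vdt_decisions[t], dec_ref_reader, "cancer"),
                "specificity_p": _paired_p(cases, vdt_decisions[t], dec_ref_reader, "benign"),
            }
        vdt_table.append(row)

    block: dict[str, Any] = {
        "n_cases": len(cases),
        "n_cancer": sum(c.cancer for c in cases),
        "n_benign": sum(not c.cancer for c in cases),
        "growth_rules": growth_rules,
        "growth_rule_comparisons": comparisons,
        "vdt_referral": {"reference_threshold_days": ref_t, "table": vdt_table},
        "auc": _auc_block(cases),
    }

    if referral_available:
        block["radiologist_referral"] = _operating_point(cases, dec_ref_reader)
        combined_table = []
        for t in thresholds:
            dec_comb = [
                combined_referral(v, r, combine_mode)  # type: ignore[arg-type]
                for v, r in zip(vdt_decisions[t], dec_ref_reader)
            ]
            row = {"vdt_threshold_days": t, "combine_mode": combine_mode}
            row.update(_operating_point(cases, dec_comb))
            combined_table.append(row)
        block["combined_referral"] = combined_table
    else:
        block["radiologist_referral"] = None
        block["combined_referral"] = None

    # agreement between the available binary growth calls
    agreement: dict[str, Any] = {}
    named = {"volumetric": dec_vol, "diametric": dec_dia}
    if dec_rad is not None:
        named["radiologist"] = dec_rad
    names = list(named)
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            kap = cohens_kappa(named[na], named[nb])
            agreement[f"{na}_vs_{nb}"] = {
                "kappa": kap.kappa,
                "kappa_ci_low": kap.ci_low,
                "kappa_ci_high": kap.ci_high,
                "percent_agreement": percent_agreement(named[na], named[nb]),
            }
    block["rule_agreement"] = agreement
    return block


def run_study(
    cases: list[ScreeningCase],
    vdt_thresholds: tuple[int, ...] = VDT_THRESHOLDS_DAYS,
    combine_mode: str = "union",
) -> StudyReport:
    """Full diagnostic-performance report for a cohort.

    The primary analysis covers all cases; a subgroup analysis repeats it
    for baseline-solid nodules when that subgroup still contains both
    outcome classes.
    """
    if not cases:
        raise EmptyInputError("run_study: empty cohort")
    n_cancer = sum(c.cancer for c in cases)
    if n_cancer == 0 or n_cancer == len(cases):
        raise DegenerateCohortError(
            "run_study: cohort must contain both cancer and benign cases"
        )
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "summary": summarize_cohort(cases),
        "primary": _analysis_block(cases, vdt_thresholds, combine_mode),
    }
    solid = [c for c in cases if c.consistency is Consistency.SOLID]
    n_solid_cancer = sum(c.cancer for c in solid)
    if solid and 2 <= n_solid_cancer <= len(solid) - 2:
        report["solid_subgroup"] = _analysis_block(solid, vdt_thresholds, combine_mode)
    else:
        report["solid_subgroup"] = None
    return StudyReport(data=report)


# ---------------------------------------------------------------------------
# plain-text rendering


def _fmt_prop(p: dict[str, Any]) -> str:
    return (
        f"{p['value']:.1f}% ({p['ci_low']:.1f}-{p['ci_high']:.1f}%) "
        f"[{p['numerator']} of {p['denominator']}]"
    )


def _render_block(block: dict[str, Any], title: str) -> list[str]:
    lines = [f"== {title} (n={block['n_cases']}; cancer {block['n_cancer']}, "
             f"benign {block['n_benign']}) =="]
    lines.append("-- growth definitions --")
    for name, op in block["growth_rules"].items():
        lines.append(
            f"{name:>12}: sens {_fmt_prop(op['sensitivity'])}, "
            f"spec {_fmt_prop(op['specificity'])}"
        )
    for name, cmp_d in block["growth_rule_comparisons"].items():
        lines.append(
            f"{name}: sens p={cmp_d['sensitivity_p']:.3f}, "
            f"spec p={cmp_d['specificity_p']:.3f}"
        )
    lines.append("-- VDT referral thresholds --")
    for row in block["vdt_referral"]["table"]:
        extra = ""
        if "vs_reference" in row:
            extra = (
                f"  (vs {block['vdt_referral']['reference_threshold_days']} d: "
                f"sens p={row['vs_reference']['sensitivity_p']:.3f}, "
                f"spec p={row['vs_reference']['specificity_p']:.3f})"
            )
        lines.append(
            f"{row['vdt_threshold_days']:>5} d: sens {_fmt_prop(row['sensitivity'])}, "
            f"spec {_fmt_prop(row['specificity'])}{extra}"
        )
    if block.get("radiologist_referral"):
        op = block["radiologist_referral"]
        lines.append(
            f"radiologist referral: sens {_fmt_prop(op['sensitivity'])}, "
            f"spec {_fmt_prop(op['specificity'])}"
        )
    if block.get("combined_referral"):
        lines.append("-- combined referral (VDT + radiologist) --")
        for row in block["combined_referral"]:
            lines.append(
                f"{row['vdt_threshold_days']:>5} d [{row['combine_mode']}]: "
                f"sens {_fmt_prop(row['sensitivity'])}, spec {_fmt_prop(row['specificity'])}"
            )
    lines.append("-- AUC (DeLong 95% CI) --")
    for name in ("pvg", "adg", "neg_vdt"):
        a = block["auc"][name]
        lines.append(f"{name:>8}: {a['auc']:.3f} ({a['ci_low']:.3f}-{a['ci_high']:.3f})")
    pa = block["auc"]["pvg_vs_adg"]
    lines.append(f"pvg vs adg: z={pa['z']:.3f}, p={pa['p_value']:.3f}")
    if block.get("rule_agreement"):
        lines.append("-- agreement between rules --")
        for name, ag in block["rule_agreement"].items():
            lines.append(
                f"{name}: kappa {ag['kappa']:.3f} "
                f"({ag['kappa_ci_low']:.3f}-{ag['kappa_ci_high']:.3f}), "
                f"agreement {ag['percent_agreement']:.1f}%"
            )
    return lines


def render_report(report: StudyReport | dict[str, Any]) -> str:
    """Plain-text tables; a pure function of the JSON report."""
    data = report.data if isinstance(report, StudyReport) else report
    lines: list[str] = ["nodulegrowth study report", ""]
    summary = data["summary"]
    lines.append(f"cohort: {summary['n_cases']} cases")
    for group in ("all", "cancer", "benign"):
        tot = summary["strata"][group]["total"]
        vb = tot["volume_baseline"]
        if vb["n"]:
            lines.append(
                f"  {group:>6} (n={vb['n']}): baseline volume "
                f"{vb['mean']:.1f} +- {vb['sd']:.1f} mm3 ({vb['min']:.1f}-{vb['max']:.1f}); "
                f"growing (volumetric) {tot['growing']['volumetric']}, "
                f"(diametric) {tot['growing']['diametric']}"
            )
    lines.append("")
    lines.extend(_render_block(data["primary"], "all nodules"))
    if data.get("solid_subgroup"):
        lines.append("")
        lines.extend(_render_block(data["solid_subgroup"], "solid-nodule subgroup"))
    return "\n".join(lines) + "\n"


def audit_report(report: StudyReport | dict[str, Any]) -> bool:
    """Self-consistency audit: every stored percentage must equal 100*k/n."""
    data = report.data if isinstance(report, StudyReport) else report

    def walk(node: Any) -> bool:
        if isinstance(node, dict):
            if {"value", "numerator", "denominator"} <= set(node):
                expected = 100.0 * node["numerator"] / node["denominator"]
                if not math.isclose(node["value"], expected, abs_tol=1e-9):
                    return False
            return all(walk(v) for v in node.values())
        if isinstance(node, list):
            return all(walk(v) for v in node)
        return True

    return walk(data)
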