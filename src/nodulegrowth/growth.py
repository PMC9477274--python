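"""Growth metrics, eligibility filtering and dominant-nodule selection.

The three growth quantities for a nodule measured at baseline and follow-up:

* percentage volume growth, ``PVG = (V2 - V1) / V1 * 100``;
* absolute diameter growth, ``ADG = D2 - D1`` (average transverse diameter);
* volume doubling time, ``VDT = ln 2 * dt / ln(V2 / V1)``, defined only for
  nodules whose volume increased (no finite doubling time otherwise).

For part-solid nodules each quantity is computed twice: for the whole nodule
(ground-glass included) and for the solid component.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

from .errors import EmptyInputError, InsufficientDataError, InvalidMeasurementError
from .types import Consistency, GrowthMetrics, NoduleObservation, ScreeningCase

#: NELSON-style indeterminate window for solid volumes (mm^3), inclusive.
ELIGIBLE_VOLUME_MIN = 50.0
ELIGIBLE_VOLUME_MAX = 500.0
#: Minimum ground-glass component diameter (mm) for part-solid eligibility.
NONSOLID_DIAMETER_MIN = 8.0


def percentage_volume_growth(v_base: float, v_follow: float) -> float:
    """Relative volume change in percent, baseline volume as denominator."""
    if not v_base > 0:
        raise InvalidMeasurementError(f"baseline volume must be > 0, got {v_base}")
    return (v_follow - v_base) / v_base * 100.0


def absolute_diameter_growth(d_base: float, d_follow: float) -> float:
    """Change in average diameter, mm (may be negative)."""
    if not d_base > 0:
        raise InvalidMeasurementError(f"baseline diameter must be > 0, got {d_base}")
    return d_follow - d_base


def volume_doubling_time(v_base: float, v_follow: float, interval_days: float) -> float | None:
    """Volume doubling time in days under exponential growth.

    Returns ``None`` when the volume did not increase: a static or shrinking
    nodule has no finite doubling time.
    """
    if not v_base > 0:
        raise InvalidMeasurementError(f"baseline volume must be > 0, got {v_base}")
    if not v_follow > 0:
        raise InvalidMeasurementError(f"follow-up volume must be > 0, got {v_follow}")
    if interval_days < 1:
        raise InvalidMeasurementError(f"interval must be >= 1 day, got {interval_days}")
    if v_follow <= v_base:
        return None
    return math.log(2.0) * interval_days / math.log(v_follow / v_base)


def compute_growth_metrics(case: ScreeningCase) -> GrowthMetrics:
    """Apply the three growth formulas to one screening case.

    Solid-component metrics are computed only for part-solid nodules
    (consistency taken from the baseline observation); they require solid
    volume and diameter at both timepoints.
    """
    b, f = case.baseline, case.followup
    try:
        pvg_w = percentage_volume_growth(b.whole_volume, f.whole_volume)
        adg_w = absolute_diameter_growth(b.whole_avg_diameter, f.whole_avg_diameter)
        vdt_w = volume_doubling_time(b.whole_volume, f.whole_volume, case.interval_days)
    except InvalidMeasurementError as err:
        raise InvalidMeasurementError(f"case {case.case_id}: {err}") from err

    pvg_s = adg_s = vdt_s = None
    if case.consistency is Consistency.PART_SOLID:
        missing = [
            name
            for obs, tag in ((b, "baseline"), (f, "followup"))
            for name, val in (
                (f"{tag}.solid_volume", obs.solid_volume),
                (f"{tag}.solid_avg_diameter", obs.solid_avg_diameter),
            )
            if val is None
        ]
        if missing:
            raise InsufficientDataError(
                f"case {case.case_id}: part-solid nodule lacks solid-component "
                f"measurements: {', '.join(missing)}"
            )
        try:
            pvg_s = percentage_volume_growth(b.solid_volume, f.solid_volume)
            adg_s = absolute_diameter_growth(b.solid_avg_diameter, f.solid_avg_diameter)
            vdt_s = volume_doubling_time(b.solid_volume, f.solid_volume, case.interval_days)
        except InvalidMeasurementError as err:
            raise InvalidMeasurementError(
                f"case {case.case_id} (solid component): {err}"
            ) from err

    return GrowthMetrics(
        consistency=case.consistency,
        pvg_whole=pvg_w,
        adg_whole=adg_w,
        vdt_whole=vdt_w,
        pvg_solid=pvg_s,
        adg_solid=adg_s,
        vdt_solid=vdt_s,
    )


def nelson_indeterminate(obs: NoduleObservation) -> bool:
    """NELSON indeterminate-size eligibility of a baseline observation.

    Solid nodules qualify with a whole volume of 50-500 mm^3 (inclusive at
    both ends); part-solid nodules with a solid-component volume of
    50-500 mm^3 or a ground-glass component of average diameter >= 8 mm.
    """
    if obs.consistency is Consistency.SOLID:
        return ELIGIBLE_VOLUME_MIN <= obs.whole_volume <= ELIGIBLE_VOLUME_MAX
    if obs.solid_volume is None and obs.nonsolid_avg_diameter is None:
        raise InsufficientDataError(
            f"nodule {obs.nodule_id}: part-solid eligibility needs solid_volume "
            "or nonsolid_avg_diameter"
        )
    by_solid = (
        obs.solid_volume is not None
        and ELIGIBLE_VOLUME_MIN <= obs.solid_volume <= ELIGIBLE_VOLUME_MAX
    )
    by_nonsolid = (
        obs.nonsolid_avg_diameter is not None
        and obs.nonsolid_avg_diameter >= NONSOLID_DIAMETER_MIN
    )
    return by_solid or by_nonsolid


def _comparable_volume(obs: NoduleObservation) -> float:
    if obs.consistency is Consistency.SOLID:
        return obs.whole_volume
    if obs.solid_volume is None:
        raise InsufficientDataError(
            f"nodule {obs.nodule_id}: part-solid comparable volume needs solid_volume"
        )
    return obs.solid_volume


def select_dominant_nodule(observations: Iterable[NoduleObservation]) -> NoduleObservation:
    """Pick the single dominant nodule when a scan shows several.

    Ordering: largest comparable volume first (whole volume for solid
    nodules, solid-component volume for part-solid), ties broken in favor of
    solid consistency, then by nodule identifier for determinism.
    """
    candidates = list(observations)
    if not candidates:
        raise EmptyInputError("select_dominant_nodule: empty observation list")
    return min(
        candidates,
        key=lambda o: (
            -_comparable_volume(o),
            0 if o.consistency is Consistency.SOLID else 1,
            o.nodule_id,
        ),
    )
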