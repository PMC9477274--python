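"""Core domain types.

A screening case pairs two low-dose CT observations of the same pulmonary
nodule — baseline and follow-up — together with the scan interval, the
pathology-proven cancer status, and (optionally) a radiologist's subjective
growth and diagnostic-referral calls.

Part-solid nodules carry two measured components: the whole nodule
(including the ground-glass part) and the solid component.  Solid nodules
carry whole-nodule measurements only.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import InvalidMeasurementError


class Consistency(str, Enum):
    """Nodule consistency on baseline CT. Non-solid nodules are out of scope."""

    SOLID = "solid"
    PART_SOLID = "part_solid"


@dataclass(frozen=True)
class NoduleObservation:
    """One timepoint's semi-automated measurements of one nodule.

    Volumes in mm^3, diameters (average transverse diameter) in mm.
    ``solid_*`` fields describe the solid component of a part-solid nodule;
    ``nonsolid_avg_diameter`` describes its ground-glass component.
    """

    nodule_id: str
    consistency: Consistency
    whole_volume: float
    whole_avg_diameter: float
    solid_volume: float | None = None
    solid_avg_diameter: float | None = None
    nonsolid_avg_diameter: float | None = None

    def __post_init__(self) -> None:
        if not self.whole_volume > 0:
            raise InvalidMeasurementError(
                f"nodule {self.nodule_id}: whole_volume must be > 0, got {self.whole_volume}"
            )
        if not self.whole_avg_diameter > 0:
            raise InvalidMeasurementError(
                f"nodule {self.nodule_id}: whole_avg_diameter must be > 0, "
                f"got {self.whole_avg_diameter}"
            )
        for name in ("solid_volume", "solid_avg_diameter", "nonsolid_avg_diameter"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InvalidMeasurementError(
                    f"nodule {self.nodule_id}: {name} must be >= 0, got {value}"
                )
        if (
            self.consistency is Consistency.PART_SOLID
            and self.solid_volume is not None
            and self.solid_volume > self.whole_volume
        ):
            raise InvalidMeasurementError(
                f"nodule {self.nodule_id}: solid_volume ({self.solid_volume}) exceeds "
                f"whole_volume ({self.whole_volume})"
            )

    @property
    def is_part_solid(self) -> bool:
        return self.consistency is Consistency.PART_SOLID


@dataclass(frozen=True)
class ScreeningCase:
    """Baseline/follow-up observation pair with outcome and reader calls."""

    case_id: str
    baseline: NoduleObservation
    followup: NoduleObservation
    interval_days: int
    cancer: bool
    radiologist_growth: bool | None = None
    radiologist_referral: bool | None = None

    def __post_init__(self) -> None:
        if self.interval_days < 1:
            raise InvalidMeasurementError(
                f"case {self.case_id}: interval_days must be >= 1, got {self.interval_days}"
            )
        if self.baseline.nodule_id != self.followup.nodule_id:
            raise InvalidMeasurementError(
                f"case {self.case_id}: baseline and follow-up observations refer to "
                f"different nodules ({self.baseline.nodule_id!r} vs "
                f"{self.followup.nodule_id!r})"
            )

    @property
    def consistency(self) -> Consistency:
        """Consistency used for rule dispatch: taken from the baseline scan."""
        return self.baseline.consistency


@dataclass(frozen=True)
class GrowthMetrics:
    """The three growth quantities, per measured component.

    ``pvg``: percentage volume growth (%); ``adg``: absolute growth of the
    average diameter (mm); ``vdt``: volume doubling time (days), defined only
    when the volume actually increased.  ``*_solid`` fields are present only
    for part-solid nodules.
    """

    consistency: Consistency
    pvg_whole: float
    adg_whole: float
    vdt_whole: float | None
    pvg_solid: float | None = None
    adg_solid: float | None = None
    vdt_solid: float | None = None

    @property
    def is_part_solid(self) -> bool:
        return self.consistency is Consistency.PART_SOLID
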