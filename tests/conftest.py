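"""Shared fixtures.

``published_cohort`` is a synthetic stand-in for the study's per-nodule
dataset (which is not redistributed here): 115 solid-nodule cases whose
growth metrics are constructed so that every published 2x2 count — the
three growth definitions and each VDT referral threshold — is reproduced
exactly.  It exercises the pipeline end to end against the printed
operating points without the original measurements.
"""

from __future__ import annotations

import dataclasses

import pytest

from nodulegrowth import ScreeningCase, default_config, simulate_cohort
from nodulegrowth.types import Consistency, NoduleObservation

INTERVAL_DAYS = 300


def _case(
    case_id: str,
    cancer: bool,
    vdt: float | None,
    volume_ratio_if_static: float,
    diam_growth: bool,
    rad_growth: bool,
    rad_referral: bool,
) -> ScreeningCase:
    """One all-solid case with exactly the requested growth metrics.

    A target VDT of ``v`` days is realized exactly by a follow-up/baseline
    volume ratio of ``2**(INTERVAL_DAYS / v)``; a static (or sub-threshold)
    case uses ``volume_ratio_if_static`` instead.
    """
    ratio = 2.0 ** (INTERVAL_DAYS / vdt) if vdt is not None else volume_ratio_if_static
    base = NoduleObservation(
        nodule_id=case_id,
        consistency=Consistency.SOLID,
        whole_volume=100.0,
        whole_avg_diameter=6.0,
    )
    follow = NoduleObservation(
        nodule_id=case_id,
        consistency=Consistency.SOLID,
        whole_volume=100.0 * ratio,
        whole_avg_diameter=6.0 + (2.0 if diam_growth else 0.3),
    )
    return ScreeningCase(
        case_id=case_id,
        baseline=base,
        followup=follow,
        interval_days=INTERVAL_DAYS,
        cancer=cancer,
        radiologist_growth=rad_growth,
        radiologist_referral=rad_referral,
    )


def build_published_counts_cohort() -> list[ScreeningCase]:
    """115 cases reproducing the published counts.

    Cancers (26): 18 volumetric growers with VDTs placed across the
    referral bins to give 1/8/11/15/15/16 positives at 100/200/300/400/
    500/600 days; 11 diametric growers; 14 radiologist growth calls;
    20 radiologist referrals.  Benign (89): 16 volumetric growers with
    VDTs giving 0/0/5/7/7/11 false positives at the same thresholds;
    3 diametric growers; 1 radiologist growth call; 3 referrals.
    """
    cancer_vdts: list[float | None] = (
        [80.0]
        + [150.0] * 7
        + [250.0] * 3
        + [350.0] * 4
        + [550.0]
        + [700.0] * 2
        + [None] * 8  # no volume growth >= 25%
    )
    benign_vdts: list[float | None] = (
        [250.0] * 5 + [350.0] * 2 + [550.0] * 4 + [700.0] * 5 + [None] * 73
    )
    cases = []
    for i, vdt in enumerate(cancer_vdts):
        cases.append(
            _case(
                f"ca-{i:03d}",
                cancer=True,
                vdt=vdt,
                volume_ratio_if_static=1.10,  # grows 10%, below threshold
                diam_growth=i < 11,
                rad_growth=i < 14,
                rad_referral=i < 20,
            )
        )
    for i, vdt in enumerate(benign_vdts):
        cases.append(
            _case(
                f"be-{i:03d}",
                cancer=False,
                vdt=vdt,
                volume_ratio_if_static=1.0,  # truly static
                diam_growth=i < 3,
                rad_growth=i < 1,
                rad_referral=i < 3,
            )
        )
    assert len(cases) == 115
    return cases


@pytest.fixture(scope="session")
def published_cohort() -> list[ScreeningCase]:
    return build_published_counts_cohort()


@pytest.fixture(scope="session")
def cohort_10k():
    """Large default-noise cohort with truly-static benign nodules.

    Used for the calibration and monotonicity checks; benign true growth is
    switched off so the closed-form false-growth rate applies exactly.
    """
    cfg = dataclasses.replace(
        default_config(),
        n_cases=10_000,
        seed=1234,
        benign_growth_fraction_solid=0.0,
        benign_growth_fraction_part_solid=0.0,
    )
    cases, truths = simulate_cohort(cfg)
    return cfg, cases, truths
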