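"""Synthetic screening-cohort generator.

The generator emulates the measurement structure of a two-timepoint
volumetry study of indeterminate screening-detected nodules:

* a case mix of solid and part-solid nodules with ~22.6% cancer prevalence;
* baseline volumes drawn lognormally per stratum and constrained to the
  indeterminate eligibility window;
* follow-up intervals lognormal around a 201-day median (IQR ~127-371 d);
* cancers growing exponentially with lognormal volume doubling times
  centered near 260 days, plus an indolent (> 600 d) component; benign
  nodules static apart from a small truly-growing fraction;
* multiplicative per-scan volumetry noise, calibrated so that ~15.7% of
  static benign nodules exceed the +25% volume-growth threshold;
* sphere-equivalent diameters with additive per-scan noise;
* reader growth/referral calls as Bernoulli draws conditional on cancer
  status.

Every stochastic draw flows through a single ``numpy`` generator keyed by
``config.seed``, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigValidationError
from .growth import nelson_indeterminate
from .types import Consistency, NoduleObservation, ScreeningCase

_LN2 = math.log(2.0)


def sphere_equivalent_diameter(volume_mm3: float) -> float:
    """Diameter (mm) of the sphere with the given volume: (6V/pi)^(1/3)."""
    return (6.0 * volume_mm3 / math.pi) ** (1.0 / 3.0)


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    Lognormal strata are moment-matched to the benign/cancer volume means
    and SDs of a 115-nodule screening cohort (benign solid 151.5 +- 109.1,
    cancer solid 287.0 +- 152.6, benign part-solid whole 670.9 +- 311.0,
    cancer part-solid whole 1262.9 +- 844.5 mm^3).
    """

    n_cases: int = 115
    cancer_prevalence: float = 26 / 115
    part_solid_fraction_benign: float = 7 / 89
    part_solid_fraction_cancer: float = 15 / 26

    # baseline whole-nodule volume, lognormal (log-mean, log-sd) per stratum
    solid_benign_vol_logmean: float = 4.8117
    solid_benign_vol_logsd: float = 0.6463
    solid_cancer_vol_logmean: float = 5.5350
    solid_cancer_vol_logsd: float = 0.4989
    ps_benign_vol_logmean: float = 6.4114
    ps_benign_vol_logsd: float = 0.4412
    ps_cancer_vol_logmean: float = 6.9564
    ps_cancer_vol_logsd: float = 0.6079
    # solid-component fraction of part-solid whole volume, Beta(a, b)
    solid_fraction_beta_a: float = 2.0
    solid_fraction_beta_b: float = 20.0

    eligible_volume_min: float = 50.0
    eligible_volume_max: float = 500.0
    nonsolid_diameter_min_mm: float = 8.0

    interval_logmean: float = 5.3033  # median ~201 days
    interval_logsd: float = 0.7947  # IQR ~127-371 days
    interval_min_days: int = 30

    cancer_vdt_logmean: float = 5.5607  # median ~260 days
    cancer_vdt_logsd: float = 0.45
    indolent_fraction: float = 8 / 26  # slow-growing (> 600 d) cancers
    indolent_vdt_logmean: float = 6.8024  # median ~900 days
    indolent_vdt_logsd: float = 0.25
    indolent_vdt_min_days: float = 600.0

    benign_growth_fraction_solid: float = 0.05
    benign_growth_fraction_part_solid: float = 0.30
    benign_growth_vdt_days: float = 800.0

    volume_noise_cv: float = 0.17  # per-scan multiplicative lognormal CV
    diameter_noise_sd_mm: float = 0.5  # per-scan additive

    reader_growth_sens: float = 14 / 26
    reader_growth_spec: float = 88 / 89
    reader_referral_sens: float = 20 / 26
    reader_referral_spec: float = 86 / 89

    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_cases < 1:
            bad.append("n_cases")
        for name in (
            "cancer_prevalence",
            "part_solid_fraction_benign",
            "part_solid_fraction_cancer",
            "indolent_fraction",
            "benign_growth_fraction_solid",
            "benign_growth_fraction_part_solid",
            "reader_growth_sens",
            "reader_growth_spec",
            "reader_referral_sens",
            "reader_referral_spec",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                bad.append(name)
        for name in ("volume_noise_cv", "diameter_noise_sd_mm"):
            if getattr(self, name) < 0.0:
                bad.append(name)
        for name in (
            "solid_benign_vol_logsd",
            "solid_cancer_vol_logsd",
            "ps_benign_vol_logsd",
            "ps_cancer_vol_logsd",
            "interval_logsd",
            "cancer_vdt_logsd",
            "indolent_vdt_logsd",
        ):
            if getattr(self, name) <= 0.0:
                bad.append(name)
        if not 0 < self.eligible_volume_min < self.eligible_volume_max:
            bad.append("eligible_volume_min/eligible_volume_max")
        if self.benign_growth_vdt_days <= 0:
            bad.append("benign_growth_vdt_days")
        if self.interval_min_days < 1:
            bad.append("interval_min_days")
        if self.solid_fraction_beta_a <= 0 or self.solid_fraction_beta_b <= 0:
            bad.append("solid_fraction_beta_a/solid_fraction_beta_b")
        if bad:
            raise ConfigValidationError(bad)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated case, for parameter-recovery tests."""

    case_id: str
    cancer: bool
    consistency: Consistency
    true_base_volume: float
    true_followup_volume: float
    true_vdt: float | None  # None for static nodules
    true_solid_base_volume: float | None
    true_solid_followup_volume: float | None
    reader_growth_correct: bool | None
    reader_referral_correct: bool | None


def default_config() -> SimulationConfig:
    """The study-calibrated default configuration (n=115, prevalence 22.6%)."""
    return SimulationConfig()


def benign_flag_rate(config: SimulationConfig) -> float:
    """Probability that a truly static nodule's measured PVG reaches +25%.

    With independent per-scan lognormal errors of log-SD
    ``sigma = ln(1 + CV)``, the measured log volume ratio is
    ``N(0, 2 sigma^2)``, so the rate is ``1 - Phi(ln 1.25 / (sigma sqrt 2))``.
    Used to calibrate ``volume_noise_cv`` against the observed benign
    false-growth fraction.
    """
    sigma = math.log(1.0 + config.volume_noise_cv)
    if sigma == 0.0:
        return 0.0
    return float(1.0 - norm.cdf(math.log(1.25) / (sigma * math.sqrt(2.0))))


def _truncated_lognormal(rng: np.random.Generator, mu: float, sd: float,
                         lo: float, hi: float) -> float:
    for _ in range(100_000):
        v = float(rng.lognormal(mu, sd))
        if lo <= v <= hi:
            return v
    raise RuntimeError("truncated lognormal rejection failed; check parameters")


def _draw_interval(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    days = int(round(rng.lognormal(cfg.interval_logmean, cfg.interval_logsd)))
    return max(cfg.interval_min_days, days)


def _draw_cancer_vdt(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    if rng.random() < cfg.indolent_fraction:
        for _ in range(100_000):
            v = float(rng.lognormal(cfg.indolent_vdt_logmean, cfg.indolent_vdt_logsd))
            if v > cfg.indolent_vdt_min_days:
                return v
        raise RuntimeError("indolent VDT rejection failed")
    return float(rng.lognormal(cfg.cancer_vdt_logmean, cfg.cancer_vdt_logsd))


def _noisy_volume(rng: np.random.Generator, true_volume: float, sigma: float) -> float:
    return true_volume * math.exp(rng.normal(0.0, sigma)) if sigma > 0 else true_volume


def _noisy_diameter(rng: np.random.Generator, volume: float, sd: float) -> float:
    d = sphere_equivalent_diameter(volume)
    if sd > 0:
        d += rng.normal(0.0, sd)
    return max(d, 0.1)


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[list[ScreeningCase], list[TruthRecord]]:
    """Draw a synthetic cohort; deterministic under a fixed ``config.seed``.

    Baseline observations are guaranteed to satisfy the indeterminate
    eligibility rule: the per-case draw (true volume plus baseline
    measurement noise) is rejected and repeated until the *measured*
    baseline observation qualifies.
    """
    cfg = config or default_config()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sigma = math.log(1.0 + cfg.volume_noise_cv)

    cases: list[ScreeningCase] = []
    truths: list[TruthRecord] = []
    for i in range(cfg.n_cases):
        case_id = f"sim-{i:05d}"
        cancer = bool(rng.random() < cfg.cancer_prevalence)
        ps_frac = cfg.part_solid_fraction_cancer if cancer else cfg.part_solid_fraction_benign
        part_solid = bool(rng.random() < ps_frac)
        consistency = Consistency.PART_SOLID if part_solid else Consistency.SOLID
        interval = _draw_interval(rng, cfg)

        # true growth
        if cancer:
            vdt: float | None = _draw_cancer_vdt(rng, cfg)
        else:
            frac = (
                cfg.benign_growth_fraction_part_solid
                if part_solid
                else cfg.benign_growth_fraction_solid
            )
            vdt = cfg.benign_growth_vdt_days if rng.random() < frac else None
        gfactor = 2.0 ** (interval / vdt) if vdt is not None else 1.0

        # baseline truth + measured baseline, rejected until eligible
        for _ in range(100_000):
            if part_solid:
                mu, sd = (
                    (cfg.ps_cancer_vol_logmean, cfg.ps_cancer_vol_logsd)
                    if cancer
                    else (cfg.ps_benign_vol_logmean, cfg.ps_benign_vol_logsd)
                )
                true_base = float(rng.lognormal(mu, sd))
                solid_frac = float(
                    rng.beta(cfg.solid_fraction_beta_a, cfg.solid_fraction_beta_b)
                )
                true_solid_base = solid_frac * true_base
                meas_base = _noisy_volume(rng, true_base, sigma)
                meas_solid_base = min(
                    _noisy_volume(rng, true_solid_base, sigma), meas_base
                )
                baseline = NoduleObservation(
                    nodule_id=case_id,
                    consistency=consistency,
                    whole_volume=meas_base,
                    whole_avg_diameter=_noisy_diameter(
                        rng, meas_base, cfg.diameter_noise_sd_mm
                    ),
                    solid_volume=meas_solid_base,
                    solid_avg_diameter=_noisy_diameter(
                        rng, meas_solid_base, cfg.diameter_noise_sd_mm
                    ),
                    nonsolid_avg_diameter=_noisy_diameter(
                        rng, max(meas_base - meas_solid_base, 1e-6),
                        cfg.diameter_noise_sd_mm,
                    ),
                )
            else:
                mu, sd = (
                    (cfg.solid_cancer_vol_logmean, cfg.solid_cancer_vol_logsd)
                    if cancer
                    else (cfg.solid_benign_vol_logmean, cfg.solid_benign_vol_logsd)
                )
                true_base = _truncated_lognormal(
                    rng, mu, sd, cfg.eligible_volume_min, cfg.eligible_volume_max
                )
                true_solid_base = None
                meas_base = _noisy_volume(rng, true_base, sigma)
                meas_solid_base = None
                baseline = NoduleObservation(
                    nodule_id=case_id,
                    consistency=consistency,
                    whole_volume=meas_base,
                    whole_avg_diameter=_noisy_diameter(
                        rng, meas_base, cfg.diameter_noise_sd_mm
                    ),
                )
            if nelson_indeterminate(baseline):
                break
        else:  # pragma: no cover
            raise RuntimeError("eligibility rejection failed; check configuration")

        # follow-up: both components grow with the same true VDT
        true_fu = true_base * gfactor
        meas_fu = _noisy_volume(rng, true_fu, sigma)
        if part_solid:
            true_solid_fu = true_solid_base * gfactor
            meas_solid_fu = min(_noisy_volume(rng, true_solid_fu, sigma), meas_fu)
            followup = NoduleObservation(
                nodule_id=case_id,
                consistency=consistency,
                whole_volume=meas_fu,
                whole_avg_diameter=_noisy_diameter(rng, meas_fu, cfg.diameter_noise_sd_mm),
                solid_volume=meas_solid_fu,
                solid_avg_diameter=_noisy_diameter(
                    rng, meas_solid_fu, cfg.diameter_noise_sd_mm
                ),
                nonsolid_avg_diameter=_noisy_diameter(
                    rng, max(meas_fu - meas_solid_fu, 1e-6), cfg.diameter_noise_sd_mm
                ),
            )
        else:
            true_solid_fu = None
            followup = NoduleObservation(
                nodule_id=case_id,
                consistency=consistency,
                whole_volume=meas_fu,
                whole_avg_diameter=_noisy_diameter(rng, meas_fu, cfg.diameter_noise_sd_mm),
            )

        # reader calls: Bernoulli conditional on cancer status
        u_growth, u_ref = rng.random(), rng.random()
        if cancer:
            reader_growth = bool(u_growth < cfg.reader_growth_sens)
            reader_referral = bool(u_ref < cfg.reader_referral_sens)
            growth_correct, referral_correct = reader_growth, reader_referral
        else:
            reader_growth = bool(u_growth >= cfg.reader_growth_spec)
            reader_referral = bool(u_ref >= cfg.reader_referral_spec)
            growth_correct, referral_correct = not reader_growth, not reader_referral

        cases.append(
            ScreeningCase(
                case_id=case_id,
                baseline=baseline,
                followup=followup,
                interval_days=interval,
                cancer=cancer,
                radiologist_growth=reader_growth,
                radiologist_referral=reader_referral,
            )
        )
        truths.append(
            TruthRecord(
                case_id=case_id,
                cancer=cancer,
                consistency=consistency,
                true_base_volume=true_base,
                true_followup_volume=true_fu,
                true_vdt=vdt,
                true_solid_base_volume=true_solid_base,
                true_solid_followup_volume=true_solid_fu,
                reader_growth_correct=growth_correct,
                reader_referral_correct=referral_correct,
            )
        )
    return cases, truths


# ---------------------------------------------------------------------------
# truth table and config file round trip


def truths_to_frame(truths: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "case_id": t.case_id,
                "cancer": int(t.cancer),
                "consistency": t.consistency.value,
                "true_base_volume": t.true_base_volume,
                "true_followup_volume": t.true_followup_volume,
                "true_vdt": t.true_vdt,
                "true_solid_base_volume": t.true_solid_base_volume,
                "true_solid_followup_volume": t.true_solid_followup_volume,
                "reader_growth_correct": int(t.reader_growth_correct)
                if t.reader_growth_correct is not None
                else None,
                "reader_referral_correct": int(t.reader_referral_correct)
                if t.reader_referral_correct is not None
                else None,
            }
            for t in truths
        ]
    )


def write_truth_csv(truths: list[TruthRecord], path: str | Path) -> None:
    truths_to_frame(truths).to_csv(path, index=False)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write the configuration as ``key = value`` lines."""
    lines = ["# nodulegrowth simulation configuration"]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> SimulationConfig:
    """Parse a ``key = value`` configuration file (round trip of save_config)."""
    field_types = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    kwargs: dict[str, float | int] = {}
    unknown: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            unknown.append(f"line {lineno}: not a key = value pair")
            continue
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in field_types:
            unknown.append(f"line {lineno}: unknown key {key!r}")
            continue
        kwargs[key] = int(value) if field_types[key] == "int" else float(value)
    if unknown:
        raise ConfigValidationError(unknown)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg
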