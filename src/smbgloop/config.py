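"""Configuration objects for the titration engine and the trial simulator.

Both configs are plain dataclasses with YAML round-trips so that a run is
fully described by one small text file plus a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

PREBREAKFAST = "prebreakfast"
PREDINNER = "predinner"
SLOTS = (PREBREAKFAST, PREDINNER)

#: Which premix injection governs the glucose observed in each SMBG slot.
#: The evening premix acts overnight and sets the next fasting (prebreakfast)
#: value; the morning premix carries through the day to the predinner value.
GOVERNING_DOSE = {PREBREAKFAST: "evening", PREDINNER: "morning"}


@dataclass(frozen=True)
class TitrationConfig:
    """Rule constants for the weekly dose-adjustment algorithm.

    The published description fixes the glycemic band (4-8 mmol/L), the
    weekly cadence, and the 15-20% step ceiling; the remaining constants
    (what "consistently" means, the tier boundary, the urgent threshold)
    are declared here and are all configurable.
    """

    band_low: float = 4.0                 # mmol/L, lower edge of target band
    band_high: float = 8.0                # mmol/L, upper edge of target band
    consistency_threshold: float = 4.0 / 7.0   # fraction of slot readings outside band
    min_readings_per_slot: int = 4        # fewer -> "insufficient", no change
    step_moderate: float = 0.15           # fractional dose step, moderate deviation
    step_severe: float = 0.20             # fractional dose step, severe deviation
    severity_margin: float = 2.0          # mmol/L beyond band edge that makes a deviation severe
    urgent_threshold: float = 3.0         # mmol/L; below this an out-of-cycle decrement fires
    level1_weekly_trigger: int = 2        # this many level-1 readings force a weekly decrement
    tdd_cap_per_kg: float = 1.5           # units/kg/day safety ceiling on total daily dose
    accept_probability: float = 1.0       # physician gate: P(accept) in simulation
    review_days: int = 7

    def __post_init__(self) -> None:
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be < band_high")
        if not 0.0 < self.step_moderate <= self.step_severe <= 0.20:
            raise ValueError("step tiers must satisfy 0 < moderate <= severe <= 0.20")
        if not 0.0 <= self.accept_probability <= 1.0:
            raise ValueError("accept_probability must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Generator moments and loop settings for the in-silico trial.

    The cohort moments default to the baseline characteristics of the
    25-participant study population (HbA1c 8.6 (0.7) %, TDD 0.73 (0.31)
    units/kg/day, BMI 29.0 (3.6) kg/m^2); eligibility (HbA1c 7.5-9.9 %,
    TDD < 1 unit/kg, BMI <= 40) is enforced by rejection sampling.
    """

    n_patients: int = 25
    weeks: int = 24
    seed: int = 0

    hba1c_mean: float = 8.6
    hba1c_sd: float = 0.7
    tdd_per_kg_mean: float = 0.73
    tdd_per_kg_sd: float = 0.31
    bmi_mean: float = 29.0
    bmi_sd: float = 3.6
    height_m_mean: float = 1.62
    height_m_sd: float = 0.08

    # latent glucose model
    sensitivity_mean: float = 10.0        # mmol/L drop per (unit/kg) of governing dose
    sensitivity_sd: float = 2.5
    sensitivity_min: float = 2.0
    within_day_sd_mean: float = 1.4       # mmol/L reading-to-reading noise
    within_day_sd_sd: float = 0.3
    within_day_sd_min: float = 0.0
    adherence_low: float = 0.94           # adherence_prob ~ Uniform(low, high)
    adherence_high: float = 1.0
    tau_days: float = 35.0                # HbA1c EWMA time constant
    morning_fraction: float = 0.6         # share of TDD given as the morning premix
    fasting_offset_mmol: float = 2.4      # fasting latent sits this far below the
                                          # daily mean; predinner the same above
                                          # (mean-preserving diurnal asymmetry)

    lab_noise_hba1c: float = 0.1          # % HbA1c
    lab_noise_fpg: float = 0.3            # mmol/L
    glucose_floor: float = 0.5            # mmol/L physiological floor on readings

    titration_on: bool = True
    setpoint_drift_per_week: float = 0.0  # optional behavioural setpoint drift (mmol/L/week)

    titration: TitrationConfig = field(default_factory=TitrationConfig)

    # eligibility window (inclusion criteria)
    hba1c_min: float = 7.5
    hba1c_max: float = 9.9
    tdd_per_kg_max: float = 1.0
    bmi_max: float = 40.0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.weeks < 1:
            raise ValueError("n_patients and weeks must be >= 1")
        for name in ("hba1c_sd", "tdd_per_kg_sd", "bmi_sd", "height_m_sd",
                     "sensitivity_sd", "within_day_sd_sd",
                     "lab_noise_hba1c", "lab_noise_fpg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _as_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return d


def config_hash(cfg) -> str:
    """Stable SHA-256 over the config contents (for run manifests)."""
    payload = json.dumps(_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def save_config(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_as_dict(cfg), sort_keys=True))


def load_sim_config(path: str | Path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    tit = raw.pop("titration", None)
    kwargs = dict(raw)
    if tit is not None:
        kwargs["titration"] = TitrationConfig(**tit)
    return SimConfig(**kwargs)


def load_titration_config(path: str | Path) -> TitrationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.pop("seed", None)  # tolerated in shared config files
    return TitrationConfig(**{k: v for k, v in raw.items()
                              if k in {f.name for f in dataclasses.fields(TitrationConfig)}})
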