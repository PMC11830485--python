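"""Virtual-patient cohort generation and the closed-loop in-silico trial.

The patient model is deliberately minimal so that every closed-loop
behaviour has a closed-form oracle: each slot's observed glucose is

    reading = setpoint_slot - sensitivity * governing_dose/weight + noise

with additive Gaussian within-day noise, Bernoulli adherence lapses, and
HbA1c tracked as an exponentially weighted moving average of the daily mean
latent glucose (time constant ``tau_days``) mapped through the ADAG
HbA1c <-> mean-glucose relation. Hypoglycemia arises from the same Gaussian
tail; there is no separate event process.

Cohort moments default to the source study's baseline characteristics and
eligibility is enforced by rejection sampling (HbA1c 7.5-9.9 %, total daily
dose < 1 unit/kg, BMI <= 40).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .analytics import eag_mmol_from_hba1c, hba1c_from_eag_mmol, summarize_trial, TrialSummary
from .config import GOVERNING_DOSE, PREBREAKFAST, PREDINNER, SLOTS, SimConfig
from .hypoglycemia import extract_episodes
from .titration import (GlucoseReading, Recommendation, Regimen, apply_approval,
                        hypoglycemia_trigger, make_window, recommend)

SLOT_HOURS = {PREBREAKFAST: 8, PREDINNER: 18}
DEFAULT_START = datetime(2021, 1, 4)  # arbitrary Monday enrollment date


@dataclass
class VirtualPatient:
    """Latent parameters of one simulated participant."""

    id: str
    weight_kg: float
    bmi: float
    baseline_hba1c_pct: float
    slot_setpoints: dict[str, float]      # mmol/L, dose-free latent mean per slot
    insulin_sensitivity: float            # mmol/L per (unit/kg) of governing dose
    within_day_sd: float                  # mmol/L
    adherence_prob: float
    hba1c_state: float                    # EWMA of mean latent glucose, mmol/L

    def latent(self, slot: str, regimen: Regimen) -> float:
        gov = GOVERNING_DOSE[slot]
        return (self.slot_setpoints[slot]
                - self.insulin_sensitivity * regimen.dose(gov) / self.weight_kg)


@dataclass
class TrialResult:
    """Tidy outputs of one simulated trial (all plain DataFrames)."""

    smbg: pd.DataFrame
    episodes: pd.DataFrame
    regimen_history: pd.DataFrame
    labs: pd.DataFrame
    summary: TrialSummary
    cohort: list


def _initial_regimen(tdd_per_kg: float, weight: float, morning_fraction: float) -> Regimen:
    tdd = max(1, round(tdd_per_kg * weight))
    morning = int(round(morning_fraction * tdd))
    morning = min(max(morning, 0), tdd)
    return Regimen(morning_dose=morning, evening_dose=tdd - morning, weight_kg=weight)


def sample_cohort(config: SimConfig, rng: np.random.Generator | None = None,
                  ) -> tuple[list[VirtualPatient], list[Regimen]]:
    """Rejection-sample an eligible cohort from the configured moments.

    Returns patients plus their enrollment regimens. Raises if the moment
    configuration is incompatible with the eligibility window (acceptance
    rate below 1%).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    patients: list[VirtualPatient] = []
    regimens: list[Regimen] = []
    attempts = 0
    while len(patients) < config.n_patients:
        attempts += 1
        if attempts > max(10_000, 100 * config.n_patients):
            raise RuntimeError("eligibility rejection rate > 99%: "
                               "infeasible moment configuration")
        hba1c = rng.normal(config.hba1c_mean, config.hba1c_sd)
        tdd_kg = rng.normal(config.tdd_per_kg_mean, config.tdd_per_kg_sd)
        bmi = rng.normal(config.bmi_mean, config.bmi_sd)
        height = rng.normal(config.height_m_mean, config.height_m_sd)
        if not (config.hba1c_min <= hba1c <= config.hba1c_max):
            continue
        if not (0.05 < tdd_kg < config.tdd_per_kg_max):
            continue
        if not (15.0 < bmi <= config.bmi_max):
            continue
        if height <= 1.2:
            continue
        weight = bmi * height ** 2
        sens = rng.normal(config.sensitivity_mean, config.sensitivity_sd)
        sens = max(config.sensitivity_min, sens)
        sd = max(config.within_day_sd_min,
                 rng.normal(config.within_day_sd_mean, config.within_day_sd_sd))
        adh = rng.uniform(config.adherence_low, config.adherence_high)

        regimen = _initial_regimen(tdd_kg, weight, config.morning_fraction)
        if regimen.tdd_per_kg >= config.tdd_per_kg_max:
            continue  # whole-unit rounding may push the draw over the limit
        eag0 = eag_mmol_from_hba1c(hba1c)
        # setpoints chosen so the mean latent glucose under the enrollment
        # regimen equals the eAG implied by baseline HbA1c; the diurnal
        # offset puts fasting below that mean and predinner above it
        offsets = {PREBREAKFAST: -config.fasting_offset_mmol,
                   PREDINNER: +config.fasting_offset_mmol}
        setpoints = {
            slot: eag0 + offsets[slot]
            + sens * regimen.dose(GOVERNING_DOSE[slot]) / weight
            for slot in SLOTS
        }
        pid = f"P{len(patients) + 1:03d}"
        patients.append(VirtualPatient(
            id=pid, weight_kg=weight, bmi=bmi, baseline_hba1c_pct=hba1c,
            slot_setpoints=setpoints, insulin_sensitivity=sens,
            within_day_sd=sd, adherence_prob=adh, hba1c_state=eag0,
        ))
        regimens.append(regimen)
    return patients, regimens


def step_day(patient: VirtualPatient, regimen: Regimen, rng: np.random.Generator,
             day: datetime, glucose_floor: float = 0.5,
             tau_days: float = 35.0) -> tuple[list[GlucoseReading], float]:
    """Simulate one day: up to two readings (adherence lapses drop a slot)
    and the EWMA HbA1c-state update from the day's mean latent glucose."""
    readings: list[GlucoseReading] = []
    latents = []
    for slot in SLOTS:
        latent = patient.latent(slot, regimen)
        latents.append(latent)
        if rng.uniform() <= patient.adherence_prob:
            glucose = max(glucose_floor,
                          latent + rng.normal(0.0, patient.within_day_sd))
            readings.append(GlucoseReading(
                participant_id=patient.id,
                time=datetime.combine(day.date(), time(SLOT_HOURS[slot])),
                slot=slot, glucose=float(glucose)))
    mean_latent = float(np.mean(latents))
    patient.hba1c_state += (mean_latent - patient.hba1c_state) / tau_days
    return readings, mean_latent


def _lab_row(patient: VirtualPatient, regimen: Regimen, week: int,
             rng: np.random.Generator, config: SimConfig) -> dict:
    hba1c = hba1c_from_eag_mmol(patient.hba1c_state) \
        + rng.normal(0.0, config.lab_noise_hba1c)
    fpg = patient.latent(PREBREAKFAST, regimen) \
        + rng.normal(0.0, config.lab_noise_fpg)
    return {"participant_id": patient.id, "week": week,
            "hba1c_pct": float(hba1c), "fpg_mmol_l": float(max(1.0, fpg)),
            "bmi": float(patient.bmi + 0.5 * week / 24.0)}


def run_trial(config: SimConfig, start: datetime = DEFAULT_START) -> TrialResult:
    """Run the full closed-loop in-silico trial.

    Weekly cadence: seven simulated days of twice-daily SMBG, an urgent
    out-of-cycle decrement whenever a reading falls below the urgent
    threshold (at most once per slot per week), then the weekly review
    and the physician gate. Labs are drawn at weeks 0, 12 and the final
    week. Fully reproducible for a given config (seed included).
    """
    root = np.random.SeedSequence(config.seed)
    cohort_seed, *patient_seeds = root.spawn(1 + config.n_patients)
    patients, regimens = sample_cohort(config, np.random.default_rng(cohort_seed))

    lab_weeks = sorted({0, 12, config.weeks} & set(range(0, config.weeks + 1)))
    smbg_rows: list[dict] = []
    regimen_rows: list[dict] = []
    lab_rows: list[dict] = []
    all_readings: list[GlucoseReading] = []

    for patient, regimen, seed in zip(patients, regimens, patient_seeds):
        rng = np.random.default_rng(seed)
        cfg_t = config.titration
        regimen_rows.append(_regimen_row(patient.id, regimen, start, 0))
        lab_rows.append(_lab_row(patient, regimen, 0, rng, config))

        for week in range(config.weeks):
            week_start = start + timedelta(days=7 * week)
            triggered: set[str] = set()
            week_readings: list[GlucoseReading] = []
            for d in range(7):
                day = week_start + timedelta(days=d)
                readings, _ = step_day(patient, regimen, rng, day,
                                       config.glucose_floor, config.tau_days)
                week_readings.extend(readings)
                all_readings.extend(readings)
                for r in readings:
                    smbg_rows.append({
                        "participant_id": r.participant_id,
                        "datetime": r.time, "slot": r.slot,
                        "glucose_mmol_l": r.glucose,
                        "assisted": 0,
                        "study_day": (r.time.date() - start.date()).days,
                    })
                if config.titration_on:
                    urgent = hypoglycemia_trigger(readings, regimen, cfg_t, triggered)
                    if urgent is not None:
                        triggered.update(urgent.rationale.keys())
                        if urgent.is_change:
                            new_regimen = _gate(urgent, regimen, rng,
                                                cfg_t.accept_probability, day)
                            if new_regimen is not regimen:
                                regimen = new_regimen
                                regimen_rows.append(_regimen_row(
                                    patient.id, regimen, day,
                                    (day.date() - start.date()).days, urgent=True))
            if config.titration_on:
                window = make_window(week_readings, week_start)
                rec = recommend(window, regimen, cfg_t)
                if rec.is_change:
                    decision_day = week_start + timedelta(days=7)
                    new_regimen = _gate(rec, regimen, rng, cfg_t.accept_probability,
                                        decision_day)
                    if new_regimen is not regimen:
                        regimen = new_regimen
                        regimen_rows.append(_regimen_row(
                            patient.id, regimen, decision_day, 7 * (week + 1)))
            if config.setpoint_drift_per_week:
                for slot in SLOTS:
                    patient.slot_setpoints[slot] -= config.setpoint_drift_per_week
            if (week + 1) in lab_weeks:
                lab_rows.append(_lab_row(patient, regimen, week + 1, rng, config))

    smbg = pd.DataFrame(smbg_rows, columns=["participant_id", "datetime", "slot",
                                            "glucose_mmol_l", "assisted", "study_day"])
    regimen_history = pd.DataFrame(regimen_rows)
    labs = pd.DataFrame(lab_rows)

    episode_objs = extract_episodes(all_readings, study_start=start,
                                    study_weeks=config.weeks)
    episodes = pd.DataFrame(
        [{"participant_id": e.participant_id, "datetime": e.time,
          "level": int(e.level), "glucose_mmol_l": e.glucose, "period": e.period}
         for e in episode_objs],
        columns=["participant_id", "datetime", "level", "glucose_mmol_l", "period"])

    summary = summarize_trial(smbg, episodes, regimen_history, labs,
                              weeks=config.weeks)
    return TrialResult(smbg=smbg, episodes=episodes,
                       regimen_history=regimen_history, labs=labs,
                       summary=summary, cohort=patients)


def _regimen_row(pid: str, regimen: Regimen, when: datetime, study_day: int,
                 urgent: bool = False) -> dict:
    return {"participant_id": pid, "effective_date": when,
            "study_day": study_day,
            "morning_dose_units": regimen.morning_dose,
            "evening_dose_units": regimen.evening_dose,
            "weight_kg": round(regimen.weight_kg, 1),
            "urgent": int(urgent)}


def _gate(rec: Recommendation, regimen: Regimen, rng: np.random.Generator,
          accept_probability: float, when: datetime) -> Regimen:
    """Physician accept/decline gate with configurable accept probability."""
    decision = "accept" if rng.uniform() <= accept_probability else "decline"
    return apply_approval(rec, regimen, decision, when)
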