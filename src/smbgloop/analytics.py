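"""Outcome measures: SMBG adherence, hypoglycemia incidence, glycemic and
dose summaries, and the standard HbA1c unit conversions.

Reporting precision follows clinical convention: percentages to 1 decimal,
per-participant incidence to 2 decimals. Change scores and dispersions only;
no inferential statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hypoglycemia import PERIOD_1, PERIOD_2

# NGSP(%) <-> IFCC(mmol/mol) master equation: NGSP = 0.09148*IFCC + 2.152,
# conventionally quoted as IFCC = (NGSP - 2.15) * 10.929.
_IFCC_SLOPE = 10.929
_IFCC_INTERCEPT = 2.15

# ADAG linear relation between HbA1c and estimated average glucose (mmol/L).
_EAG_SLOPE = 1.59
_EAG_INTERCEPT = -2.59

TIMEPOINT_WEEKS = (0, 12, 24)
LAB_VARS = ("hba1c_pct", "hba1c_mmol_mol", "fpg_mmol_l",
            "tdd_units", "tdd_units_per_kg", "bmi")


def adherence(completed: int, prescribed: int) -> float:
    """Percentage of prescribed SMBG measurements completed, to 1 decimal."""
    if prescribed <= 0:
        raise ValueError("prescribed count must be positive")
    if not 0 <= completed <= prescribed:
        raise ValueError("completed must lie in [0, prescribed]")
    return round(100.0 * completed / prescribed, 1)


def prescribed_count(days: int, slots_per_day: int = 2) -> int:
    """Number of prescribed SMBG measurements over ``days`` days."""
    if days < 0:
        raise ValueError("days must be >= 0")
    return days * slots_per_day


def incidence_per_participant(episodes: int, n_participants: int) -> float:
    """Episodes per participant over a period, to 2 decimals."""
    if n_participants <= 0:
        raise ValueError("participant count must be positive")
    if episodes < 0:
        raise ValueError("episode count must be >= 0")
    return round(episodes / n_participants, 2)


def ngsp_to_ifcc(hba1c_pct: float) -> float:
    """NGSP % -> IFCC mmol/mol via the master equation, to 1 decimal."""
    if hba1c_pct <= _IFCC_INTERCEPT:
        raise ValueError(f"HbA1c must exceed {_IFCC_INTERCEPT}%")
    return round((hba1c_pct - _IFCC_INTERCEPT) * _IFCC_SLOPE, 1)


def eag_mmol_from_hba1c(hba1c_pct: float) -> float:
    """Estimated average glucose (mmol/L) from HbA1c % (ADAG relation)."""
    if not 3.0 < hba1c_pct < 20.0:
        raise ValueError("HbA1c % out of supported range (3, 20)")
    return _EAG_SLOPE * hba1c_pct + _EAG_INTERCEPT


def hba1c_from_eag_mmol(eag_mmol_l: float) -> float:
    """Inverse ADAG mapping; composes with :func:`eag_mmol_from_hba1c` to
    the identity."""
    hba1c = (eag_mmol_l - _EAG_INTERCEPT) / _EAG_SLOPE
    if not 3.0 < hba1c < 20.0:
        raise ValueError("eAG out of supported range")
    return hba1c


@dataclass
class TrialSummary:
    """Per-timepoint moments, change scores, and per-period safety/adherence
    aggregates (the shape of a pre-post trial's outcome tables)."""

    timepoints: pd.DataFrame   # index week; columns (var, mean/sd/n)
    changes: pd.DataFrame      # index interval label; columns var -> delta of means
    periods: pd.DataFrame      # index period; adherence & incidence columns
    n_participants: int
    flagged: dict[str, list] = field(default_factory=dict)


def _timepoint_table(labs: pd.DataFrame, regimens: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    flagged: dict[str, list] = {}
    weights = regimens.sort_values("effective_date").groupby("participant_id")["weight_kg"].first()

    rows = {}
    for week in TIMEPOINT_WEEKS:
        lab_w = labs[labs["week"] == week].set_index("participant_id")
        missing = sorted(set(labs["participant_id"].unique()) - set(lab_w.index))
        if missing:
            flagged[f"week{week}_missing_labs"] = missing

        # regimen active at the timepoint: last change effective on/before day week*7
        reg = regimens.sort_values("effective_date").copy()
        active = (reg[reg["study_day"] <= week * 7]
                  .groupby("participant_id").last())
        tdd = active["morning_dose_units"] + active["evening_dose_units"]
        tdd_kg = tdd / weights.reindex(tdd.index)

        cells = {}
        frames = {
            "hba1c_pct": lab_w.get("hba1c_pct"),
            "hba1c_mmol_mol": (lab_w["hba1c_pct"].map(ngsp_to_ifcc)
                               if "hba1c_pct" in lab_w else None),
            "fpg_mmol_l": lab_w.get("fpg_mmol_l"),
            "bmi": lab_w.get("bmi"),
            "tdd_units": tdd,
            "tdd_units_per_kg": tdd_kg,
        }
        for var, series in frames.items():
            if series is None or series.dropna().empty:
                cells[(var, "mean")] = np.nan
                cells[(var, "sd")] = np.nan
                cells[(var, "n")] = 0
                continue
            s = series.dropna()
            cells[(var, "mean")] = float(s.mean())
            cells[(var, "sd")] = float(s.std(ddof=1)) if len(s) > 1 else np.nan
            cells[(var, "n")] = int(len(s))
            if len(s) == 1:
                flagged.setdefault("single_participant_cells", []).append((week, var))
        rows[week] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["variable", "stat"])
    table.index.name = "week"
    return table.sort_index(axis=1), flagged


def _change_table(timepoints: pd.DataFrame) -> pd.DataFrame:
    means = timepoints.xs("mean", axis=1, level="stat")
    intervals = [("weeks_0_12", 0, 12), ("weeks_13_24", 12, 24), ("weeks_0_24", 0, 24)]
    rows = {label: means.loc[b] - means.loc[a] for label, a, b in intervals}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "interval"
    return out


def _period_table(readings: pd.DataFrame, episodes: pd.DataFrame,
                  n_participants: int, weeks: int) -> pd.DataFrame:
    half_days = weeks * 7 // 2
    rows = {}
    for period, lo, hi in ((PERIOD_1, 0, half_days), (PERIOD_2, half_days, weeks * 7)):
        prescribed = prescribed_count(hi - lo) * n_participants
        done = int(((readings["study_day"] >= lo) & (readings["study_day"] < hi)).sum())
        ep = episodes[episodes["period"] == period] if len(episodes) else episodes
        counts = {lvl: int((ep["level"] == lvl).sum()) if len(ep) else 0 for lvl in (1, 2, 3)}
        rows[period] = {
            "prescribed": prescribed,
            "completed": done,
            "adherence_pct": adherence(done, prescribed),
            "episodes_level1": counts[1],
            "episodes_level2": counts[2],
            "episodes_level3": counts[3],
            "episodes_total": sum(counts.values()),
            "incidence_level1": incidence_per_participant(counts[1], n_participants),
            "incidence_level2": incidence_per_participant(counts[2], n_participants),
            "incidence_level3": incidence_per_participant(counts[3], n_participants),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "period"
    return out


def summarize_trial(readings: pd.DataFrame, episodes: pd.DataFrame,
                    regimens: pd.DataFrame, labs: pd.DataFrame,
                    weeks: int = 24) -> TrialSummary:
    """Assemble the trial's outcome tables from the four tidy inputs.

    ``readings``/``regimens`` must carry a ``study_day`` column (days since
    enrollment); ``labs`` has one row per participant and week in {0,12,24};
    ``episodes`` has integer ``level`` and ``period`` labels. Participants
    missing a timepoint are excluded from that cell (complete-case per cell)
    and listed in ``flagged``.
    """
    ids = set(labs["participant_id"]) | set(regimens["participant_id"])
    n = len(ids)
    if n == 0:
        raise ValueError("no participants in input")
    timepoints, flagged = _timepoint_table(labs, regimens)
    changes = _change_table(timepoints)
    periods = _period_table(readings, episodes, n, weeks)
    return TrialSummary(timepoints=timepoints, changes=changes,
                        periods=periods, n_participants=n, flagged=flagged)
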