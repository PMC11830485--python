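"""CSV readers/writers, row-level validation, and run manifests.

All formats are plain UTF-8 comma-delimited CSV with strict headers and
ISO-8601 timestamps; every writer is deterministic given its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import pandas as pd

from .analytics import TrialSummary
from .config import SLOTS
from .titration import GlucoseReading

log = logging.getLogger("smbgloop")

SMBG_COLUMNS = ["participant_id", "datetime", "slot", "glucose_mmol_l", "assisted"]
REGIMEN_COLUMNS = ["participant_id", "effective_date",
                   "morning_dose_units", "evening_dose_units", "weight_kg"]
LABS_COLUMNS = ["participant_id", "week", "hba1c_pct", "fpg_mmol_l", "bmi"]


class ValidationError(ValueError):
    """Structural input problem that should abort the run (exit code 1)."""


@dataclass
class ValidationReport:
    """Row-level problems found while reading an input file."""

    bad_rows: list[dict] = field(default_factory=list)
    duplicates: list[dict] = field(default_factory=list)
    n_total: int = 0

    @property
    def ok(self) -> bool:
        return not self.bad_rows

    def fraction_bad(self) -> float:
        return len(self.bad_rows) / self.n_total if self.n_total else 0.0


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_smbg(path: str | Path, max_bad_fraction: float = 0.05,
              ) -> tuple[list[GlucoseReading], ValidationReport]:
    """Read and validate an SMBG log.

    Rows with unknown slot labels, unparseable timestamps, or out-of-range
    glucose are collected in the report; duplicate (participant, day, slot)
    rows keep the earliest reading. The run continues unless more than
    ``max_bad_fraction`` of rows are bad.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, SMBG_COLUMNS, path)

    report = ValidationReport(n_total=len(df))
    records: list[GlucoseReading] = []
    for idx, row in df.iterrows():
        problems = []
        ts = pd.to_datetime(row["datetime"], errors="coerce")
        if pd.isna(ts):
            problems.append(f"bad timestamp {row['datetime']!r}")
        if row["slot"] not in SLOTS:
            problems.append(f"unknown slot {row['slot']!r}")
        glucose = pd.to_numeric(row["glucose_mmol_l"], errors="coerce")
        assisted = bool(row.get("assisted", 0))
        if pd.isna(glucose) or not (0 < glucose < 50):
            problems.append(f"bad glucose {row['glucose_mmol_l']!r}")
        if problems:
            report.bad_rows.append({"row": int(idx), "problems": problems})
            continue
        records.append(GlucoseReading(
            participant_id=str(row["participant_id"]),
            time=ts.to_pydatetime(), slot=row["slot"],
            glucose=float(glucose), assisted_event=assisted))

    # dedup per (participant, day, slot): earliest kept
    records.sort(key=lambda r: (r.participant_id, r.time))
    seen: dict[tuple, GlucoseReading] = {}
    for r in records:
        key = (r.participant_id, r.time.date(), r.slot)
        if key in seen:
            report.duplicates.append({"participant_id": r.participant_id,
                                      "datetime": r.time.isoformat(),
                                      "slot": r.slot})
        else:
            seen[key] = r
    kept = sorted(seen.values(), key=lambda r: (r.participant_id, r.time))

    if report.fraction_bad() >= max_bad_fraction and report.bad_rows:
        raise ValidationError(
            f"{path}: {len(report.bad_rows)}/{report.n_total} rows invalid "
            f"(>= {max_bad_fraction:.0%}); first: {report.bad_rows[0]}")
    for item in report.bad_rows:
        log.warning("rejected row %s: %s", item["row"], "; ".join(item["problems"]))
    for item in report.duplicates:
        log.info("duplicate reading dropped: %s", item)
    return kept, report


def read_regimens(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, REGIMEN_COLUMNS, path)
    df["effective_date"] = pd.to_datetime(df["effective_date"])
    for col in ("morning_dose_units", "evening_dose_units"):
        if (df[col] < 0).any() or (df[col] % 1 != 0).any():
            raise ValidationError(f"{path}: {col} must be non-negative whole units")
    if (df["weight_kg"] <= 0).any():
        raise ValidationError(f"{path}: weight_kg must be positive")
    return df


def read_labs(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: no such file")
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, LABS_COLUMNS, path)
    return df


def write_summary(summary: TrialSummary, out_dir: str | Path) -> list[Path]:
    """Write the summary tables as CSV plus a plain-text report.

    Column order is fixed, so identical summaries produce identical bytes.
    """
    if summary.n_participants == 0:
        raise ValueError("refusing to write a summary for an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    tp = summary.timepoints.copy()
    tp.columns = [f"{var}_{stat}" for var, stat in tp.columns]
    paths = {
        "timepoints.csv": tp,
        "changes.csv": summary.changes,
        "periods.csv": summary.periods,
    }
    for name, frame in paths.items():
        p = out / name
        frame.to_csv(p, float_format="%.6g")
        written.append(p)

    report = out / "report.txt"
    report.write_text(render_report(summary))
    written.append(report)
    return written


def render_report(summary: TrialSummary) -> str:
    """Human-readable report mirroring the layout of a pre-post trial's
    glycemic-outcome and hypoglycemia tables."""
    lines = [f"In-silico trial summary (n={summary.n_participants})", ""]
    lines.append("Glycemic outcomes, insulin doses, and BMI by timepoint "
                 "(mean (SD)):")
    means = summary.timepoints.xs("mean", axis=1, level="stat")
    sds = summary.timepoints.xs("sd", axis=1, level="stat")
    header = f"{'variable':<22}" + "".join(f"week {w:<10}" for w in means.index)
    lines.append(header)
    for var in means.columns:
        cells = "".join(f"{means.loc[w, var]:6.2f} ({sds.loc[w, var]:4.2f})  "
                        for w in means.index)
        lines.append(f"{var:<22}{cells}")
    lines.append("")
    lines.append("Change in means between timepoints:")
    for interval, row in summary.changes.iterrows():
        cells = ", ".join(f"{var} {row[var]:+.2f}" for var in row.index)
        lines.append(f"  {interval}: {cells}")
    lines.append("")
    lines.append("Hypoglycemia and SMBG adherence by 12-week period:")
    for period, row in summary.periods.iterrows():
        lines.append(f"  {period}: adherence {row['adherence_pct']:.1f}% "
                     f"({int(row['completed'])}/{int(row['prescribed'])}); "
                     f"episodes L1/L2/L3 = {int(row['episodes_level1'])}/"
                     f"{int(row['episodes_level2'])}/{int(row['episodes_level3'])}; "
                     f"incidence per participant "
                     f"{row['incidence_level1']:.2f}/{row['incidence_level2']:.2f}/"
                     f"{row['incidence_level3']:.2f}")
    return "\n".join(lines) + "\n"


@dataclass
class RunManifest:
    """Enough metadata to reproduce a run exactly."""

    config_hash: str
    seed: int
    package_version: str
    input_checksums: dict[str, str] = field(default_factory=dict)
    created: str = ""

    @classmethod
    def create(cls, config_hash: str, seed: int, version: str,
               inputs: dict[str, Path] | None = None) -> "RunManifest":
        checksums = {}
        for name, p in (inputs or {}).items():
            checksums[name] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        return cls(config_hash=config_hash, seed=seed, package_version=version,
                   input_checksums=checksums,
                   created=datetime.now().isoformat(timespec="seconds"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")
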