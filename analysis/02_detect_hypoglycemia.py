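#!/usr/bin/env python
"""Classify hypoglycemia and extract episodes from the simulated SMBG log.

Reads results/simulated/smbg.csv back through the validating CSV reader,
detects level-1/2/3 episodes with the 60-minute debounce, assigns each to
its 12-week period, and writes results/episodes_from_log.csv. Also reports
how the episode count depends on the debounce setting (with a zero gap,
every qualifying strip is its own episode).
"""

import argparse
from datetime import datetime
from pathlib import Path

import pandas as pd

from smbgloop.hypoglycemia import extract_episodes
from smbgloop.io import read_smbg

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--smbg", type=Path,
                        default=ROOT / "results" / "simulated" / "smbg.csv")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "episodes_from_log.csv")
    args = parser.parse_args()

    readings, report = read_smbg(args.smbg)
    print(f"read {len(readings)} readings "
          f"({len(report.bad_rows)} rejected, {len(report.duplicates)} duplicates)")

    start = datetime.combine(min(r.time for r in readings).date(),
                             datetime.min.time())
    episodes = extract_episodes(readings, study_start=start)
    df = pd.DataFrame([{"participant_id": e.participant_id,
                        "datetime": e.time, "level": int(e.level),
                        "glucose_mmol_l": e.glucose, "period": e.period}
                       for e in episodes])
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False)

    raw = extract_episodes(readings, study_start=start, debounce_gap_minutes=0)
    print(f"episodes (60-min debounce): {len(episodes)}; "
          f"qualifying strips (no debounce): {len(raw)}")
    if len(df):
        tab = df.groupby(["period", "level"]).size().unstack(fill_value=0)
        print("episodes by period and level:")
        print(tab.to_string())
        affected = df.participant_id.nunique()
        print(f"participants with >= 1 episode: {affected}")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
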