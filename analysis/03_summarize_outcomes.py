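#!/usr/bin/env python
"""Compute the trial's outcome tables from the simulated raw data.

Rebuilds the glycemic/dose/BMI timepoint table, the change scores between
timepoints, and the per-period adherence and hypoglycemia incidence table
from the CSVs written by 01_simulate_trial.py, and writes them (plus a
plain-text report) under results/tables/.
"""

import argparse
from pathlib import Path

import pandas as pd

from smbgloop.analytics import summarize_trial
from smbgloop.io import render_report, write_summary

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path,
                        default=ROOT / "results" / "simulated")
    parser.add_argument("--out-dir", type=Path,
                        default=ROOT / "results" / "tables")
    args = parser.parse_args()

    smbg = pd.read_csv(args.in_dir / "smbg.csv", parse_dates=["datetime"])
    episodes = pd.read_csv(args.in_dir / "episodes.csv", parse_dates=["datetime"])
    regimens = pd.read_csv(args.in_dir / "regimens.csv",
                           parse_dates=["effective_date"])
    labs = pd.read_csv(args.in_dir / "labs.csv")

    summary = summarize_trial(smbg, episodes, regimens, labs)
    write_summary(summary, args.out_dir)
    print(render_report(summary))
    print(f"tables written under {args.out_dir}")


if __name__ == "__main__":
    main()
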