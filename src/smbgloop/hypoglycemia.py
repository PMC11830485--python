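"""Hypoglycemia level classification and episode detection.

Levels follow the consensus definitions the study adopted:
level 1 = glucose 3.0-3.9 mmol/L (mild), level 2 = glucose < 3.0 mmol/L
(moderate), level 3 = severe hypoglycemia requiring external assistance,
regardless of the concurrent glucose value.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Optional, Sequence


class HypoLevel(enum.IntEnum):
    NONE = 0
    LEVEL1 = 1
    LEVEL2 = 2
    LEVEL3 = 3


PERIOD_1 = "weeks_1_12"
PERIOD_2 = "weeks_13_24"


@dataclass(frozen=True)
class HypoEpisode:
    participant_id: str
    time: datetime
    level: HypoLevel
    glucose: Optional[float]    # mmol/L; may be absent for assisted events
    period: str


def classify(glucose: Optional[float], assisted: bool = False) -> HypoLevel:
    """Classify one reading. Assistance dominates: a severe event is level 3
    whatever the strip shows."""
    if assisted:
        return HypoLevel.LEVEL3
    if glucose is None or glucose <= 0:
        raise ValueError("non-positive glucose without an assisted-event flag")
    if glucose < 3.0:
        return HypoLevel.LEVEL2
    if glucose <= 3.9:
        return HypoLevel.LEVEL1
    return HypoLevel.NONE


def extract_episodes(readings: Sequence, study_start: datetime,
                     study_weeks: int = 24,
                     debounce_gap_minutes: float = 60.0) -> list[HypoEpisode]:
    """Turn a reading stream into hypoglycemia episodes.

    Qualifying readings (level >= 1) closer together than ``debounce_gap``
    are one clinical event: repeated confirmatory strips merge into a single
    episode recorded at the lowest glucose (assistance, if flagged anywhere
    in the cluster, keeps the episode at level 3). Episodes are assigned to
    the first or second half of the study; readings outside the study window
    are excluded with a warning.

    ``readings`` are objects with participant_id/time/glucose/assisted_event
    attributes (e.g. :class:`smbgloop.titration.GlucoseReading`).
    """
    gap = timedelta(minutes=debounce_gap_minutes)
    midpoint = study_start + timedelta(days=study_weeks * 7 // 2)
    study_end = study_start + timedelta(weeks=study_weeks)

    by_participant: dict[str, list] = {}
    n_outside = 0
    for r in readings:
        if not (study_start <= r.time < study_end):
            n_outside += 1
            continue
        by_participant.setdefault(r.participant_id, []).append(r)
    if n_outside:
        warnings.warn(f"excluded {n_outside} reading(s) outside the "
                      f"{study_weeks}-week study window", stacklevel=2)

    episodes: list[HypoEpisode] = []
    for pid in sorted(by_participant):
        stream = sorted(by_participant[pid], key=lambda r: r.time)
        qualifying = [r for r in stream
                      if classify(r.glucose, r.assisted_event) is not HypoLevel.NONE]
        cluster: list = []
        for r in qualifying:
            if cluster and (r.time - cluster[-1].time) < gap:
                cluster.append(r)
            else:
                if cluster:
                    episodes.append(_close_cluster(pid, cluster, midpoint))
                cluster = [r]
        if cluster:
            episodes.append(_close_cluster(pid, cluster, midpoint))
    return episodes


def _close_cluster(pid: str, cluster: list, midpoint: datetime) -> HypoEpisode:
    worst = min(cluster, key=lambda r: r.glucose if r.glucose is not None else float("inf"))
    assisted = any(r.assisted_event for r in cluster)
    level = HypoLevel.LEVEL3 if assisted else classify(worst.glucose, False)
    period = PERIOD_1 if worst.time < midpoint else PERIOD_2
    return HypoEpisode(participant_id=pid, time=worst.time, level=level,
                       glucose=worst.glucose, period=period)
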