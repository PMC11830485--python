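"""Independent brute-force evaluator of the weekly titration rule table.

Written as a flat, literal transcription of the clinical rules (explicit
counting, no shared code with the package) so tests can check the engine
against it on enumerated and randomized review windows. The total-daily-dose
cap is deliberately out of scope here; equivalence tests use regimens where
the cap cannot bind.
"""

import math

BAND_LO, BAND_HI = 4.0, 8.0
SEVERITY_MARGIN = 2.0
MODERATE, SEVERE = 0.15, 0.20
MIN_READINGS = 4
CONSISTENCY_NUM, CONSISTENCY_DEN = 4, 7  # >= 4/7 of readings outside band


def _median(vals):
    s = sorted(vals)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def _round_half_away(x):
    return math.floor(x + 0.5) if x >= 0 else -math.floor(-x + 0.5)


def _step(dose, frac):
    if dose <= 0:
        return 0
    return min(max(1, _round_half_away(frac * dose)), math.ceil(0.20 * dose))


def slot_decision(values, dose):
    """(delta, label) for one slot's weekly readings acting on its governing
    dose. Labels mirror the engine's rationale vocabulary."""
    n = len(values)
    n_level2 = sum(1 for v in values if v < 3.0)
    n_level1 = sum(1 for v in values if 3.0 <= v <= 3.9)

    # hypoglycemia precedence: level 2, or two level-1 events, veto any
    # increment and force a decrement
    if n_level2 >= 1 or n_level1 >= 2:
        frac = SEVERE if n_level2 >= 1 else MODERATE
        d = _step(dose, frac)
        if d == 0:
            return 0, "capped"
        return -min(d, dose), "hypo_decrement"

    if n < MIN_READINGS:
        return 0, "insufficient_data"

    n_above = sum(1 for v in values if v > BAND_HI)
    n_below = sum(1 for v in values if v < BAND_LO)
    med = _median(values)

    if n_above * CONSISTENCY_DEN >= CONSISTENCY_NUM * n and med > BAND_HI:
        frac = SEVERE if med > BAND_HI + SEVERITY_MARGIN else MODERATE
        d = _step(dose, frac)
        return (+d, "hyper_increment") if d else (0, "capped")
    if n_below * CONSISTENCY_DEN >= CONSISTENCY_NUM * n and med < BAND_LO:
        frac = SEVERE if med < BAND_LO - SEVERITY_MARGIN else MODERATE
        d = _step(dose, frac)
        if d == 0:
            return 0, "capped"
        return -min(d, dose), "hypo_decrement"
    return 0, "in_range"


def oracle_recommend(prebreakfast_values, predinner_values, morning_dose,
                     evening_dose):
    """Expected (morning_delta, evening_delta) and per-slot labels.

    Cross-over governance: prebreakfast readings act on the evening premix,
    predinner readings on the morning premix.
    """
    evening_delta, pre_label = slot_decision(prebreakfast_values, evening_dose)
    morning_delta, din_label = slot_decision(predinner_values, morning_dose)
    return {"morning": morning_delta, "evening": evening_delta,
            "prebreakfast": pre_label, "predinner": din_label}
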