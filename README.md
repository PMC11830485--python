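# smbgloop

Algorithm-guided insulin titration for type 2 diabetes, as a testable
closed-loop system: a rules engine that turns weekly self-monitored blood
glucose (SMBG) logs into premixed-insulin dose recommendations, the safety
and outcome analytics of a 24-week treat-to-target trial (hypoglycemia
levels and episodes, SMBG adherence, glycemic/dose summaries), and a
virtual-patient simulator that runs the whole intervention in silico.

It is written for biostatisticians and diabetes-technology researchers who
want to study treat-to-target titration rules — their convergence, safety
behaviour, and sensitivity to rule constants — without access to trial data.

## The titration rule set

Participants on twice-daily premixed insulin measure capillary glucose
before breakfast and before dinner. Every 7 days the week's readings are
reviewed per slot against a 4–8 mmol/L target band:

- a slot is **consistently above** band when ≥ 4/7 of its readings exceed
  8 mmol/L *and* its median does; the dose governing that slot is then
  incremented by 15% (median within 2 mmol/L of the band edge) or 20%
  (beyond), rounded half-away-from-zero to whole pen units, never more
  than ⌈20%⌉;
- **consistently below** is symmetric, with a decrement;
- hypoglycemia takes precedence: any level-2 reading (< 3.0 mmol/L), or two
  level-1 readings (3.0–3.9 mmol/L), in a slot vetoes any increment and
  forces a decrement of its governing dose; a reading below 3.0 mmol/L
  additionally triggers an immediate out-of-cycle decrement;
- governance is crossed over, following premix pharmacodynamics: the
  evening premix governs next-morning fasting glucose, the morning premix
  governs predinner glucose;
- total daily dose is capped at 1.5 units/kg, and every recommendation
  passes a physician accept/decline gate.

The virtual patient behind the simulator is deliberately linear —
`reading = setpoint_slot − sensitivity × dose_gov/weight + ε`, with
Bernoulli adherence lapses and HbA1c as an exponentially weighted average
of mean latent glucose mapped through the ADAG relation — so every
closed-loop behaviour has a closed-form oracle. See `docs/methods.md`.

## Worked example

```
$ python analysis/01_simulate_trial.py --seed 0
simulated 25 patients x 24 weeks (seed 0) -> results/simulated
  readings logged: 8114 (adherence 96.6%)
  mean HbA1c: 8.64% -> 6.47% at week 24
  mean TDD: 0.71 -> 1.39 units/kg/day
  hypoglycemia episodes: 61 (18 level 2, 0 level 3)
```

A 25-patient virtual cohort (baseline HbA1c 8.6 (0.7) %, total daily dose
0.73 (0.31) units/kg/day) is titrated weekly for 24 weeks. Mean HbA1c falls
as doses rise toward the band; episodes of hypoglycemia are predominantly
mild and increase in the second half of the study as control tightens —
the qualitative signature of treat-to-target titration. Because this
virtual cohort improves *only* through dose increases, it needs a much
larger dose change than insulin-treated patients typically do in practice,
where redistribution of doses and behaviour change contribute; the
simulator makes no claim to reproduce a clinical effect size.

The remaining drivers build on this output:

- `analysis/02_detect_hypoglycemia.py` — re-reads the SMBG log through the
  validating CSV reader and extracts debounced hypoglycemia episodes;
- `analysis/03_summarize_outcomes.py` — rebuilds the timepoint, change-score
  and per-period adherence/incidence tables under `results/tables/`;
- `analysis/04_reported_arithmetic.py` — recomputes a published trial's
  internally-computable outcome arithmetic (adherence fractions, incidence
  rates, unit conversions, change scores) and tabulates agreement.

The same functionality is available as a console tool:

```
smbgloop simulate --seed 0 --out-dir out/
smbgloop titrate --smbg smbg.csv --regimen regimens.csv --out recs.csv
smbgloop analyze --smbg smbg.csv --regimen regimens.csv --labs labs.csv --out-dir tables/
smbgloop report --summary-dir out/summary
```

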