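# pdbia — budget-impact model for wearable Parkinson's monitoring

`pdbia` is a small, fully tested decision-analytic model of what a national
health system saves (or spends) by introducing a wearable inertial sensor
that objectively detects motor fluctuations and advanced-disease symptoms
in Parkinson's patients. It is aimed at health-technology-assessment
analysts who want a transparent, parameter-driven reimplementation of a
published five-country (Spain, Sweden, Germany, Italy, UK) cost-benefit
estimate, plus the sensitivity machinery the published analysis lacks.

## The model

Patients are stratified into three groups by Hoehn & Yahr (H&Y) stage:
mild (H&Y I–II), moderate (III), advanced (IV–V), with fixed shares
45% / 35% / 20%. For each country a multiplicative detection cascade
sizes the cohort the device can actually reach:

```
N = T × share × u × s × p
```

where `T` is the diagnosed national total, `share` the stage share of the
pool (mild pool for the "moderate detected" scenario, moderate pool for
"advanced detected"), `u` the underdiagnosis rate (0.18 mild, 0.36
moderate), `s` the device sensitivity (0.9) and `p` market penetration
(0.2). The annual saving per correctly reclassified patient is

```
saving = f·(DC_high − DC_low) − (MC_high − MC_low) − c
```

with `DC`/`MC` the per-stage direct and medication costs, `f` an
effectiveness factor, and `c` the amortized device cost
(2500 € / 30 uses × 2 prescriptions ≈ 166 €/patient‑year). National
savings are `saving × N` with `N` kept unrounded. Break-even pricing,
one-way sweeps, tornado rankings and Monte-Carlo propagation close the
loop on parameter uncertainty.

Two effectiveness presets exist: `equation` (f = 0.8, as the savings
formulas are written) and `published` (f = 1.0, the only value consistent
with the published national totals). The default is `published`; see
`docs/methods.md` for the discrepancy.

## Worked example

```python
>>> from pdbia import load_portfolio, run_full_model
>>> portfolio = load_portfolio("bundled:paper")
>>> for r in run_full_model(portfolio):
...     if r.country in ("SE", "DE"):
...         print(r.country, r.scenario, round(r.n_patients_unrounded, 1),
...               r.per_patient_saving, r.total_saving_display)
SE moderate_detected 291.6 3278.0 955865
SE advanced_detected 453.6 41988.0 19045757
DE moderate_detected 2624.4 3439.0 9025312
DE advanced_detected 4082.4 33759.0 137817742
```

Reading the Swedish advanced row: 453.6 moderate-pool patients per year
are underdiagnosed, detectable and reached (20 000 × 0.35 × 0.36 × 0.9 ×
0.2); each saves 41 988 € (the 45 167 € direct-cost gap between advanced
and moderate care, minus the 3 013 € extra medication and the 166 €
device), for a national total of about 19.0 M€/year.

The same numbers from the shell:

```
pdbia table7 --components
pdbia table6
pdbia sensitivity --param cascade.market_penetration --grid 0.1,0.2,0.3 --country DE --scenario advanced_detected
pdbia breakeven
pdbia synth --n 5 --seed 7 --out my_portfolio   # synthetic, editable portfolio
```

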