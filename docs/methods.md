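# Methods

## Model

The model is a single-year, payer-perspective budget-impact calculation.
It assumes that objective ambulatory monitoring reclassifies a fraction
of Parkinson's patients into their true (more severe) stage, and that a
correctly staged patient's *direct* care costs fall to the lower-stage
level while their *medication* costs rise to the higher-stage level.
Everything is closed-form arithmetic: no discounting, no multi-year
horizon, no QALYs, no indirect costs.

Stages: mild = Hoehn & Yahr I–II, moderate = III, advanced = IV–V.
Stage-V patients cannot walk and cannot wear a gait sensor, so the
monitorable fraction of a population is one minus its stage-V share
(94.4% pooled over the seven bundled prevalence columns).

Two scenarios are modelled per country:

* **moderate_detected** — patients in the *mild* pool whose motor
  fluctuations were missed (underdiagnosis rate 0.18); cost gaps are
  moderate − mild.
* **advanced_detected** — patients in the *moderate* pool whose advanced
  disease was missed (rate 0.36); cost gaps are advanced − moderate.

Cascade: `N = T × share × u × s × p`, all scalars. Savings:
`f·ΔDC − ΔMC − c` per patient, times the **unrounded** `N`. Rounding to
whole patients or euros is presentation-only; carrying fractional
cohorts is what makes the published totals reproducible to the euro
(e.g. 453.6 patients × 41 988 € = 19 045 756.8 → 19 045 757).

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| underdiagnosis rate, mild pool | 0.18 | proportion | observational under-recognition studies |
| underdiagnosis rate, moderate pool | 0.36 | proportion | idem |
| detection sensitivity | 0.9 | proportion | device validation studies |
| market penetration | 0.2 | proportion | conservative adoption assumption |
| stage shares | 0.45 / 0.35 / 0.20 | proportions | fixed constants, see below |
| device unit price | 2500 | € | quoted as 2500 ± 500 |
| uses per device-year | 30 | recordings | one-week recordings |
| prescriptions per patient-year | 2 | recordings | |
| effectiveness factor `f` | 1.0 (`published`) / 0.8 (`equation`) | proportion | see discrepancy below |

The bundled cost tables store the printed whole-euro values as exact
numbers (thousands-dot notation such as "9.105" is 9105 €).

### The effectiveness-factor discrepancy

The savings equations as published carry a 0.8 factor on the direct-cost
gap, but every national total that can be recomputed exactly from the
printed inputs (both Swedish cells, both German cells) requires the
factor to be 1.0. We expose both as presets, default `published` so the
flagship table reproduces, and keep a regression test asserting the
`equation` preset lands *below* the published German advanced figure so
the two can never be silently conflated.

### Two national totals per country

The five-stage prevalence table and the narrative both quantify the
diagnosed population, and they disagree (Germany 383 001 vs 180 000;
Spain 106 475 vs 150 000). The published per-stage patient counts mix
the two sources: Spain, Germany and the UK derive from the prevalence
sums, Sweden and Italy from the narrative round numbers — while the
detection cascade reproduces only with the narrative totals for *all*
countries. Both totals are therefore stored per country and
`ModelConfig.cascade_total_source` selects which feeds the cascade,
defaulting to the narrative totals.

### Stage shares

The fixed 45/35/20 split is treated as an authoritative constant rather
than recomputed from the prevalence table: no pooling or per-country
averaging of that table yields exactly those shares (the Spanish
stage-III count is anomalously low), so recomputation would silently
change every downstream number.

## Numerical choices

* **Display rounding** is round-half-away-from-zero to the nearest
  integer; it matches every printed count (47 913.75 → 47 914,
  172 350.45 → 172 350) where banker's rounding would not.
* **Device-cost rounding**: `floor_integer` truncates 166.67 → 166, the
  constant consistent with the exactly-reproducible totals; `exact` mode
  is available for sensitivity work.
* **Stratification residual**: mild and moderate counts are
  `total × share`; the advanced count is the residual
  `total − (mild + moderate)`, so the three unrounded counts sum to the
  input total without floating-point leakage. The residual form still
  reproduces all fifteen published stage counts.
* **Break-even** inverts the savings equation algebraically
  (`f·ΔDC − ΔMC`) and ignores display rounding — the root of a rounded
  step function is ill-defined. Because both sides evaluate the same
  float expression, the round-trip saving is exactly 0.0, which the
  property tests assert without tolerance.
* **Negative savings are reported, not clamped**; break-even analysis
  needs the sign.
* **Residual cells**: with the printed inputs, the Spain/Italy/UK totals
  deviate from the published ones by 0.003–0.095%. The deviation is
  consistent with the authors using unrounded spreadsheet inputs; we do
  not guess those, and the tests assert a 0.15% band for these six cells
  instead of equality.
* Cross-field validation errors (`SchemaError`, `ConfigurationError`,
  `PortfolioError`) are plain `Exception` subclasses rather than
  `ValueError`, so pydantic propagates them with their type intact.

## Sensitivity analysis

Parameters are addressed by dotted paths (`cascade.market_penetration`,
`device.unit_price`, `config.effectiveness_factor`, ...); every
perturbed evaluation rebuilds a validated portfolio copy, so domain
constraints apply to swept and sampled values. Tornado default ranges
(penetration 0.1–0.3, sensitivity 0.8–1.0, price 2000–3000 €,
underdiagnosis rates ±25% relative) are illustrative, not estimated.
Monte-Carlo draws parameters independently from one seeded generator —
no joint uncertainty information exists to support correlated sampling.
Point-mass distributions reproduce the deterministic pipeline bit for
bit, a cheap end-to-end integrity check.

## Synthetic data

The generator emulates the *structure* of the bundled parameter sets:
direct costs drawn as a mild-stage base (2 000–6 500 €) times stage
multipliers ≥ 1 (moderate 1.2–4.6× mild, advanced 1.1–7.5× moderate),
which guarantees the stage-monotone cost profile the savings equations
exploit; medication costs as a per-country fraction (0.30–0.75) of the
same stage's direct cost; national totals 20 000–180 000; an H&Y
histogram integerised to sum exactly to the total. Ranges bracket the
five bundled countries. Per-country streams are keyed by
`(seed, index)`, so country `i` is independent of how many countries are
generated.

What synthetic data does **not** emulate: realistic joint distributions
of national health costs, correlation between cost levels and population
size, or country-specific care structures. Passing property tests on
synthetic portfolios therefore demonstrates algebraic correctness of the
pipeline (oracle equivalence, linearity, invertibility, round-trip I/O),
not external validity of the economic assumptions.

## Problem sizes

The model is closed-form, so the suite runs everything at full size: all
property suites use 1000 synthetic portfolios, Monte-Carlo checks use
up to 10 000 draws, and the whole test suite finishes in a few seconds.

## Limitations

Single-year horizon; savings assume reclassification is achievable by
medication optimisation alone; underdiagnosis rates, sensitivity and
penetration are single national scalars; indirect and caregiver costs
are out of scope; currency conversion and inflation adjustment are out
of scope (inputs are pre-converted euros from heterogeneous years).
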