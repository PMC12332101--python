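# thermodev

Thermal phenology modelling for insect development, built around the two egg
parasitoids *Telenomus remus* (Nixon) and *Trichogramma foersteri* (Takahashi)
used in biological control in southern Brazil.

Given mean egg-to-adult development times at a handful of constant rearing
temperatures, the package

1. fits twelve temperature-dependent development-rate models — linear,
   Beta-16, β-type, Brière-1/2, Kontodimas, Lactin-1/2, Logan-6,
   Performance-2, Shi and Taylor — to the observed rates *r(T) = 1/time* by
   OLS or seeded multi-start bounded least squares;
2. scores each fit (regression standard error *S*, ΔAIC, ΔBIC) and derives
   its biologically meaningful parameters — the lower and upper thermal
   thresholds *T_L* and *T_H*, the optimum *T_opt*, and the linear model's
   thermal constant *K = 1/b* degree-days with *T_L = −a/b*;
3. screens those thresholds against species-specific plausibility windows and
   selects the model with the most plausible thresholds (ties broken by ΔAIC,
   then parsimony);
4. projects **voltinism**: daily development rates
   *r̄ = [r(T_min) + r(T_max)]/2* accumulate day by day, each time the total
   reaches 1 a generation is complete and the overshoot carries over, giving
   annual generation counts per grid cell — under current daily climatologies
   and under delta-change warming scenarios — plus annual counts of days with
   *T_min < T_L* (development halted by cold) and *T_max ≥ T_H* (heat stress).

A synthetic-data module generates both rearing experiments (multiplicative
noise on development *times*) and daily min/max climate grids (seasonal
sinusoid, diurnal range, day-to-day noise), so the whole pipeline is testable
without external climate downloads.

## Worked example

```python
import thermodev as td

data = td.telenomus_remus_development()     # packaged rearing table
fits = td.fit_all(data, n_starts=200, seed=0)
comparison = td.compare_models(fits)
print(td.select_best(comparison))           # -> briere2
```

`python examples/fit_and_select.py` prints the full comparison; the key rows:

```
   model  k      s  delta_aic      t_l   t_opt     t_h  marks  n_plausible
  linear  2 0.0109    20.1877  11.1656     NaN     NaN  + • •            1
 briere2  4 0.0017     0.0000   8.7233 34.0164 35.0380  + - +            2
 briere1  3 0.0057    13.6498  11.7243 33.8506 40.5408  + + -            2
selected model: briere2
```

The Brière-2 curve *r(T) = a·T·(T−T_L)·(T_H−T)^(1/m)* fits best (ΔAIC = 0,
S = 1.7·10⁻³ d⁻¹) and brackets development between T_L ≈ 8.7 °C and
T_H ≈ 35.0 °C with an optimum near 34 °C; the linear fit gives the classic
x-intercept threshold T_L ≈ 11.17 °C and a thermal constant of ≈ 176.9
degree-days. `examples/derive_thresholds.py`, `examples/voltinism_scenarios.py`
and `examples/synthetic_recovery.py` walk through threshold derivation from
published parameter sets, warming projections on a synthetic grid (cold cells
gain up to ~90% more generations under +4.4 °C while the warmest cells
saturate as days ≥ T_H appear), and closed-loop parameter recovery.

A thin CLI wraps the same calls:

```sh
thermodev fit --data dev.csv --seed 0
thermodev thresholds --species telenomus_remus
thermodev simulate --kind climate --cells 10 --out grid.csv
thermodev voltinism --climate grid.csv --scenario deltas.csv
```

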