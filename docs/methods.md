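# Methods

## The model set

All twelve rate functions map temperature *T* (°C) to a development rate
*r* (d⁻¹, reciprocal of the mean egg-to-adult time). Parameters named
`t_l`/`t_opt`/`t_h` are thermal thresholds in °C; every other symbol is a
fitted coefficient.

| model | r(T) | free parameters |
|---|---|---|
| linear | a + bT | a, b |
| beta16 | c_m · (T_H−T)/(T_H−T_opt) · [(T−T_L)/(T_opt−T_L)]^((T_opt−T_L)/(T_H−T_opt)) | c_m, T_L, T_opt, T_H |
| beta_type | ρ (a − T/10)(T/10)^β | ρ, a, β |
| briere1 | aT(T−T_L)(T_H−T)^(1/2) | a, T_L, T_H |
| briere2 | aT(T−T_L)(T_H−T)^(1/m) | a, m, T_L, T_H |
| kontodimas | α(T−T_L)²(T_H−T) | α, T_L, T_H |
| lactin1 | e^{ρT} − e^{ρT_H−(T_H−T)/Δ} | ρ, Δ, T_H |
| lactin2 | lactin1 + λ | ρ, Δ, λ, T_H |
| logan6 | φ·[e^{ρT} − e^{ρT_H−(T_H−T)/Δ}] | φ, ρ, Δ, T_H |
| performance2 | c(T−T_L)(1 − e^{K(T−T_H)}) | c, K, T_L, T_H |
| shi | c(1 − e^{−K₁(T−T_L)})(1 − e^{K₂(T−T_H)}) | c, K₁, K₂, T_L, T_H |
| taylor | R_m e^{−½((T−T_opt)/T_σ)²} | R_m, T_opt, T_σ |

Two forms need a reading decision. The Beta-16 function is implemented in
its canonical four-parameter beta shape (peak rate c_m at T_opt, zeros at
T_L and T_H); this is the only self-consistent reading of the published
parameter tables for these species, and a multi-start refit of the packaged
data recovers the published Beta-16 parameters to within rounding. Taylor's
third parameter is the Gaussian spread T_σ: the curve has no finite zeros,
so its thresholds are *undefined-by-model* even though source tables
conventionally print T_σ in the T_L slot (the packaged
`reference_parameters.yaml` keeps that printed slot for screening purposes
and documents it).

**Clamping contract.** `evaluate_rate` returns exactly 0 wherever the raw
formula is negative, complex-valued, or outside an explicit `[T_L, T_H]`
window (the Brière and Kontodimas polynomials are spuriously positive below
T_L at sub-zero temperatures, hence the window clamp). This makes daily-rate
accumulation total over any temperature input.

**Threshold derivation.** Explicit parameters pass through. T_opt is the
argmax of the clamped rate located by a 0.01 °C grid scan plus bounded local
refinement (xatol 10⁻⁷); missing T_L/T_H are the zero crossings of the raw
curve nearest below/above T_opt, bracketed by 0.5 °C coarse stepping within
120 °C and polished with Brent's method. No finite crossing (linear above,
lactin-1/logan-6/β-type below, Taylor both sides) yields an undefined
threshold, not an error. Reported thresholds are conventionally rounded to
two decimals in tabular output; library calls return full precision.

A caveat inherited from the published parameter tables: the *Te. remus*
Lactin-type blocks are hypersensitive to rounding because the two
exponentials nearly cancel (ρ ≈ 1/Δ). With the printed four-significant-
figure values the Lactin-2 lower zero sits near −20 °C (not the printed
5.70 °C) and the Lactin-1/2 rate scale is inflated roughly a hundredfold;
T_opt, by contrast, is insensitive and matches. The package evaluates the
printed numbers as given rather than back-solving hidden digits.

## Fitting and selection

The linear model is fitted by OLS on all provided points (normal equations);
T_L = −a/b and K = 1/b follow in closed form. Nonlinear models use
scipy's trust-region-reflective least squares from a seeded Latin-hypercube
sample (default 200 starts) over wide per-parameter boxes — T_L ∈ [−20, 20],
T_H ∈ [30, 50], m ∈ [1, 50], positive scales — plus one data-informed anchor
start; the converged fit with minimal SSE wins, ties going to the first
found. Multi-start matters here: with five observations and four parameters
the Brière-2 objective is nearly saturated and sits on a flat ridge in *m*.
Fits operate on mean rates (one point per temperature), which reproduces the
published linear block exactly and fixes that ambiguity empirically.

Statistics use the SSE conventions S = √(SSE/(n−k)),
AIC = n·ln(SSE/n) + 2(k+1), BIC = n·ln(SSE/n) + (k+1)·ln(n), counting the
error variance as an estimated parameter; Δ-values are taken against the
per-comparison minimum. S is reported undefined when n ≤ k (the
five-parameter Shi fit on five points), and all statistics are suppressed
when n < k.

Plausibility screening marks each defined threshold '+' if it lies in the
species' closed acceptance window — *Te. remus*: T_L [6, 15], T_opt
[32, 34], T_H [34, 36] °C; *T. foersteri*: T_L [8, 15], T_opt [30, 32],
T_H [32, 33] °C — '−' outside, '•' when undefined. The screen is strict by
design: reference accuracy tables assembled by expert judgment admit values
slightly (0.1–2 °C) outside these windows, so mark-for-mark agreement with
such tables is not expected everywhere; the deterministic rule is preferred
over per-cell tolerances reverse-engineered from any particular table.
Selection is lexicographic: most '+' marks, then lowest ΔAIC, then fewest
parameters (then name, for determinism).

## Phenology

Daily rate is the mean of the rates at the daily minimum and maximum — no
sine-interpolated degree-day variants. Accumulation starts 1 January with an
empty accumulator, resets with carry at each completed unit, and therefore
totals exactly the plain sum of daily rates (asserted to 10⁻⁹); generations
are reported fractionally. Years are treated in isolation (no carry-over),
on a 365-day climatological year with leap days dropped. Exceedance counts
use strict `tmin < T_L` and inclusive `tmax ≥ T_H`.

Climatologies are per-cell, per-day-of-year means over the supplied years;
missing (cell, year, day) combinations are a hard error. Delta-change
scenarios hold one uniform annual offset per cell, computed as (consensus)
future minus current mean annual temperature, where mean annual temperature
is the mean of daily (tmin+tmax)/2 and a consensus is the mean over the
supplied climate-model projections. NetCDF-format archives are out of scope
as downloads; gridded data enter either as long-format delimited text or as
in-memory xarray Datasets behind the same contract.

## Synthetic data

The rearing-experiment generator perturbs development *time*
multiplicatively — time = (1/r_true)(1 + ε), ε ~ N(0, cv²) — with defaults
of five temperatures (15–35 °C), 20 replicates and cv = 5%, matching the
design and the 1–5% relative standard errors of typical rearing tables;
temperatures with non-positive true rate are recorded as censored
(no emergence). The climate generator draws independent cells with annual
means spanning 12–24 °C (the study region's cold highlands to warm
lowlands), a 6 °C seasonal sinusoid peaking mid-January (southern
hemisphere), a 10 °C diurnal range and 1.5 °C day-to-day noise; the noise is
mean-centred per cell so the configured annual mean is exact. It does not
simulate spatial correlation, weather persistence, asymmetric diurnal
cycles, or elevation effects — passing tests demonstrate correctness of the
accumulation and scenario arithmetic, not skill of any model on real
station data.

Monte-Carlo recovery experiments use eight temperatures (14–35 °C in 3 °C
steps, a denser design than the five-treatment rearing table so that both
thresholds are bracketed), 20 replicates, cv = 5%, 100 seeded replicate
fits with 24–32 multi-starts each; threshold recovery is summarized by the
median absolute error. Problem sizes throughout (multi-start counts,
replicate counts, grid sizes) were chosen once as the smallest designs that
make the corresponding check statistically meaningful.

## Known limitations

Asymptotic parameter SEs, bootstrap intervals, replicate-level likelihood
fitting and humidity/photoperiod covariates are not implemented. Voltinism
assumes development alone limits generations — no host availability,
diapause, or host–parasitoid synchrony. Real-grid reproductions require the
external daily-climate archives; within this package, climate-dependent
results are property-checked on synthetic grids instead.
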