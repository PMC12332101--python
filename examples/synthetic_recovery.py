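"""Closed-loop check: simulate a rearing experiment, refit, recover the truth.

Generates mean development times from a known Briere-2 curve at eight
constant temperatures (20 replicates each, 5% multiplicative noise on the
times), fits the same model by seeded multi-start least squares, and
compares the recovered thermal thresholds with the generating ones.
"""

import thermodev as td

true = td.reference_parameters("telenomus_remus")["briere2"]
cfg = td.DevSimConfig(params=true,
                      temperatures=(14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 32.0, 35.0),
                      replicates=20, cv=0.05, seed=123)
data = td.gen_dev_data(cfg)
print("simulated mean development times (days):")
for t, d, se in zip(data.temperatures, data.dev_times, data.se):
    print(f"  {t:5.1f} degC  {d:6.2f} +/- {se:.2f}")

fit = td.fit_nonlinear(data, "briere2", n_starts=100, seed=0)
print("\nparameter       true      recovered")
for key in ("a", "m", "t_l", "t_h"):
    print(f"  {key:6s} {true[key]:12.6g} {fit.params[key]:12.6g}")
print(f"\n|T_L error| = {abs(fit.params['t_l'] - true['t_l']):.2f} degC, "
      f"|T_H error| = {abs(fit.params['t_h'] - true['t_h']):.2f} degC")
print("Threshold errors well under 1.5 degC indicate the experiment design "
      "(8 temperatures, 20 replicates) identifies the thermal window.")
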