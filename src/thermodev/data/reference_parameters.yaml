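# Published parameter sets for the egg-adult development rate of the two egg
# parasitoids, one block per model, with the thermal-threshold values as
# printed in the source fits (explicit parameters and derived values alike).
# Units: rates d^-1, temperatures degC, thermal constant k in degree-days.
# Note: the printed taylor "t_l" is the Gaussian spread parameter reported in
# the lower-threshold slot of the source table, not a developmental zero.
telenomus_remus:
  linear:
    params: {a: -0.06, b: 5.65e-3}
    thresholds: {t_l: 11.16, k: 176.94}
  beta16:
    params: {c_m: 0.130, t_l: -17.89, t_h: 40.07, t_opt: 32.96}
    thresholds: {t_l: -17.89, t_opt: 32.96, t_h: 40.07}
  beta_type:
    params: {rho: 1.4e-3, a: 4.16, beta: 3.90}
    thresholds: {t_opt: 34.05, t_h: 41.60}
  briere1:
    params: {a: 6.51e-5, t_l: 11.73, t_h: 40.53}
    thresholds: {t_l: 11.73, t_opt: 33.80, t_h: 40.53}
  briere2:
    params: {a: 1.69e-4, m: 14.22, t_l: 8.72, t_h: 35.04}
    thresholds: {t_l: 8.72, t_opt: 34.00, t_h: 35.04}
  kontodimas:
    params: {alpha: 1.63e-5, t_l: 9.50, t_h: 46.79}
    thresholds: {t_l: 9.50, t_opt: 34.40, t_h: 46.79}
  lactin1:
    params: {rho: 0.17, delta: 5.60, t_h: 38.53}
    thresholds: {t_opt: 32.90, t_h: 38.53}
  lactin2:
    params: {rho: 0.16, delta: 6.11, lam: -0.008, t_h: 39.03}
    thresholds: {t_l: 5.70, t_opt: 32.90, t_h: 39.03}
  logan6:
    params: {phi: 8.0e-3, rho: 0.17, delta: 5.46, t_h: 38.53}
    thresholds: {t_opt: 32.90, t_h: 38.53}
  performance2:
    params: {c: 6.78e-3, k: 3.43, t_l: 12.63, t_h: 35.49}
    thresholds: {t_l: 12.63, t_opt: 34.20, t_h: 35.49}
  shi:
    params: {c: 9.22, k1: 7.0e-4, k2: 2.95, t_l: 12.66, t_h: 35.57}
    thresholds: {t_l: 12.66, t_opt: 34.20, t_h: 35.57}
  taylor:
    params: {r_m: 0.126, t_opt: 33.44, t_sigma: 9.39}
    thresholds: {t_l: 9.39, t_opt: 33.44}
trichogramma_foersteri:
  linear:
    params: {a: -0.05, b: 6.15e-3}
    thresholds: {t_l: 9.55, k: 162.43}
  beta16:
    params: {c_m: 0.117, t_l: 5.88, t_h: 40.62, t_opt: 30.06}
    thresholds: {t_l: 5.88, t_opt: 30.06, t_h: 40.62}
  beta_type:
    params: {rho: 3.4e-3, a: 3.89, beta: 3.30}
    thresholds: {t_opt: 29.90, t_h: 38.90}
  briere1:
    params: {a: 7.65e-5, t_l: 9.20, t_h: 36.11}
    thresholds: {t_l: 9.20, t_opt: 30.00, t_h: 36.11}
  briere2:
    params: {a: 1.20e-4, m: 3.98, t_l: 7.5, t_h: 33.81}
    thresholds: {t_l: 7.5, t_opt: 30.00, t_h: 33.81}
  kontodimas:
    params: {alpha: 1.99e-5, t_l: 7.47, t_h: 41.55}
    thresholds: {t_l: 7.47, t_opt: 30.20, t_h: 41.55}
  lactin1:
    params: {rho: 0.16, delta: 6.07, t_h: 35.94}
    thresholds: {t_opt: 29.90, t_h: 35.94}
  lactin2:
    params: {rho: 5.9e-3, delta: 1.88, lam: -1.06, t_h: 38.66}
    thresholds: {t_l: 10.10, t_opt: 30.10, t_h: 38.66}
  logan6:
    params: {phi: 1.9e-3, rho: 0.16, delta: 5.91, t_h: 35.94}
    thresholds: {t_opt: 29.90, t_h: 35.94}
  performance2:
    params: {c: 6.56e-3, k: 0.63, t_l: 10.10, t_h: 34.36}
    thresholds: {t_l: 10.10, t_opt: 30.20, t_h: 34.36}
  shi:
    params: {c: 0.20, k1: 4.97e-2, k2: 8.57, t_l: 11.87, t_h: 32.22}
    thresholds: {t_l: 11.87, t_opt: 31.60, t_h: 32.22}
  taylor:
    params: {r_m: 0.116, t_opt: 29.99, t_sigma: 9.28}
    thresholds: {t_l: 9.28, t_opt: 29.99}
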