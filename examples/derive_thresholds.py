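"""Derive thermal thresholds (T_L, T_opt, T_H, K) from published parameters.

Loads the packaged published parameter sets for both parasitoids and runs
the numerical threshold derivation: explicit parameters pass through, the
optimum comes from a dense grid scan with local refinement, and missing
zeros are located by bracketed root search (or reported as undefined where
the functional form has none, e.g. the Gaussian Taylor curve).
"""

import thermodev as td

for species in ("telenomus_remus", "trichogramma_foersteri"):
    print(f"\n{species}")
    for name, params in td.reference_parameters(species).items():
        thr = td.derive_thresholds(params)
        fmt = lambda x: "   --" if x is None else f"{x:6.2f}"
        print(f"  {name:13s} T_L={fmt(thr.t_l)}  T_opt={fmt(thr.t_opt)}  "
              f"T_H={fmt(thr.t_h)}  K={fmt(thr.k)}")
print("\nTemperatures in degC; K in degree-days (linear model only). "
      "'--' marks thresholds the model form does not define.")
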