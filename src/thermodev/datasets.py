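"""Packaged reference data: rearing observations and published parameter sets.

``telenomus_remus_development`` loads the packaged constant-temperature
egg-to-adult development table for the southern-Brazil *Telenomus remus*
lineage (five temperatures, 20 replicates each). ``reference_parameters``
and ``reference_thresholds`` expose the published per-model parameter sets
and printed threshold values for both parasitoids (*Te. remus* and
*Trichogramma foersteri*); these drive threshold derivation, plausibility
screening and voltinism runs without refitting.

Parameter files round-trip through :func:`load_parameter_file` /
:func:`save_parameter_file` (YAML, one block per species per model).
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import yaml

from .fitting import DevelopmentDataset
from .models import ModelParams, ThermalThresholds, make_params

__all__ = [
    "SPECIES",
    "telenomus_remus_development",
    "reference_parameters",
    "reference_thresholds",
    "load_parameter_file",
    "save_parameter_file",
]

SPECIES = ("telenomus_remus", "trichogramma_foersteri")

_PRINTED = "printed-in-source"


def _data_path(name: str):
    return resources.files("thermodev.data").joinpath(name)


def telenomus_remus_development() -> DevelopmentDataset:
    """The packaged *Te. remus* egg-to-adult development table."""
    with resources.as_file(_data_path("telenomus_remus_egg_adult.csv")) as p:
        return DevelopmentDataset.from_csv(p)


def _parse_blocks(raw: Mapping) -> dict[str, dict[str, ModelParams]]:
    out: dict[str, dict[str, ModelParams]] = {}
    for species, models in raw.items():
        out[species] = {
            name: make_params(name, block["params"] if "params" in block else block)
            for name, block in models.items()}
    return out


def load_parameter_file(path) -> dict[str, dict[str, ModelParams]]:
    """Read a species → model → parameters mapping from YAML."""
    with open(path) as fh:
        return _parse_blocks(yaml.safe_load(fh))


def save_parameter_file(params: Mapping[str, Mapping[str, ModelParams]],
                        path) -> None:
    """Write a species → model → parameters mapping to YAML (round-trips
    exactly up to YAML float formatting)."""
    doc = {
        species: {name: {"params": {k: float(v) for k, v in p.values.items()}}
                  for name, p in models.items()}
        for species, models in params.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _reference_raw() -> dict:
    with resources.as_file(_data_path("reference_parameters.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


def reference_parameters(species: str | None = None):
    """Published parameter sets, as ``ModelParams`` per model.

    With ``species=None`` a species → model → params mapping is returned.
    """
    parsed = _parse_blocks(_reference_raw())
    return parsed if species is None else parsed[species]


def reference_thresholds(species: str) -> dict[str, ThermalThresholds]:
    """Thermal-threshold values exactly as printed in the source fits.

    These include values the source derived from its (unrounded) fits, so
    they are the appropriate input for reproducing its plausibility
    screening. Note the taylor entry reports the Gaussian spread parameter in
    the lower-threshold slot, following the source table.
    """
    raw = _reference_raw()[species]
    out: dict[str, ThermalThresholds] = {}
    for name, block in raw.items():
        thr = block.get("thresholds", {})
        prov = {key: (_PRINTED if key in thr else "undefined-by-model")
                for key in ("t_l", "t_opt", "t_h", "k")}
        out[name] = ThermalThresholds(
            t_l=thr.get("t_l"), t_opt=thr.get("t_opt"),
            t_h=thr.get("t_h"), k=thr.get("k"), provenance=prov)
    return out
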