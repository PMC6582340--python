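"""Flat key/value config files for model and simulation parameters.

Format: one ``key = value`` pair per line, ``#`` starts a comment, keys
use the field names of :class:`~searchkin.kinetics.ModelParameters`,
:class:`~searchkin.kinetics.LandscapeParameters` and
:class:`~searchkin.montecarlo.SimConfig`.  Units follow the dataclasses
(SI seconds/meters, energies in k_B*T).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

from .errors import InvalidParameterError
from .kinetics import LandscapeParameters, ModelParameters
from .montecarlo import SimConfig

__all__ = ["load_config", "model_parameters_from", "landscape_from",
           "sim_config_from"]


def load_config(path) -> dict[str, float]:
    """Parse a flat config file into a {key: float} dict."""
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidParameterError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = float(value)
        except ValueError:
            raise InvalidParameterError(
                f"{path}:{lineno}: non-numeric value {value!r} for "
                f"{key!r}") from None
    return out


def _pick(cls, mapping: dict, overrides: dict):
    names = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in mapping.items() if k in names}
    for k, v in overrides.items():
        if v is not None:
            kwargs[k] = v
    return cls(**kwargs)


def model_parameters_from(mapping: dict, **overrides) -> ModelParameters:
    """Build ModelParameters from a config dict, with keyword overrides."""
    return _pick(ModelParameters, mapping, overrides)


def landscape_from(mapping: dict, **overrides) -> LandscapeParameters:
    """Build LandscapeParameters from a config dict (chi/dg_max/e_ns
    required in the union of the two sources)."""
    names = {"chi", "dg_max", "e_ns", "sigma_max"}
    merged = {k: v for k, v in mapping.items() if k in names}
    merged.update({k: v for k, v in overrides.items() if v is not None})
    missing = {"chi", "dg_max", "e_ns"} - merged.keys()
    if missing:
        raise InvalidParameterError(
            f"missing landscape parameters: {sorted(missing)}")
    return LandscapeParameters(**merged)


def sim_config_from(mapping: dict, **overrides) -> SimConfig:
    """Build a SimConfig from a config dict, with keyword overrides."""
    cfg = dict(mapping)
    for key in ("genome_length", "target_position", "n_trials", "rng_seed",
                "start_position"):
        if key in cfg:
            cfg[key] = int(cfg[key])
    return _pick(SimConfig, cfg, overrides)
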