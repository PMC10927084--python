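"""Run configuration: YAML in, validated RunConfig out.

Keys carry their units in the name (dt_ms, t_end_ms) to prevent unit
mistakes.  Every value records whether it came from the file or from the
defaults, and the effective config can be re-serialized losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import ModelParameters, control_parameters, apply_scaling
from .protocols import StimulusProtocol, ClampDirective

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown keys or invalid values in a run configuration."""


_DEFAULTS = {
    "variant": "original",          # original | flattened
    "alpha": {},                    # name -> multiplicative factor
    "overrides": {},                # direct ModelParameters field overrides
    "protocol": {
        "kind": "single",
        "amplitude_pApF": 40.0,
        "duration_ms": 1.0,
        "s1_interval_ms": 1000.0,
        "s2_interval_ms": 2000.0,
        "n_s1": 1,
    },
    "clamps": [],                   # list of clamp blocks
    "integration": {
        "dt_ms": 0.01,
        "t_end_ms": 10000.0,
        "store_every_ms": 1.0,
    },
    "analysis": {
        "ead_amplitude_threshold_mV": 1.0,
        "repol_threshold_mV": -75.0,
    },
    "seed": 0,
    "outdir": "eadkit_out",
}

_CLAMP_KEYS = {"target", "mode", "t_on_ms", "t_off_ms", "value", "scale",
               "end_value"}


@dataclass
class RunConfig:
    variant: str
    alpha: dict
    overrides: dict
    protocol: dict
    clamps: list
    integration: dict
    analysis: dict
    seed: int
    outdir: str
    provenance: dict = field(default_factory=dict)

    def to_parameters(self) -> ModelParameters:
        base = control_parameters(fss_flattened=(self.variant == "flattened"))
        if self.overrides:
            base = base.replace(**self.overrides)
        if self.alpha:
            return apply_scaling(base, self.alpha)
        return base

    def to_protocol(self) -> StimulusProtocol:
        p = self.protocol
        return StimulusProtocol(
            kind=p["kind"], amplitude=p["amplitude_pApF"],
            duration=p["duration_ms"], s1_interval=p["s1_interval_ms"],
            s2_interval=p["s2_interval_ms"], n_s1=p["n_s1"])

    def to_clamps(self) -> list:
        out = []
        for c in self.clamps:
            out.append(ClampDirective(
                target=c["target"], mode=c.get("mode", "constant"),
                t_on=c.get("t_on_ms", 0.0), t_off=c.get("t_off_ms", 1e12),
                value=c.get("value"), scale=c.get("scale", 1.0),
                end_value=c.get("end_value")))
        return out

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("provenance")
        return d


def _merge(defaults: dict, user: dict, path: str, provenance: dict):
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            uval = user.get(key, {})
            if not isinstance(uval, dict):
                raise ConfigError(f"'{path}{key}' must be a mapping")
            out[key] = _merge(dval, uval, f"{path}{key}.", provenance)
        elif key in user:
            out[key] = user[key]
            provenance[f"{path}{key}"] = "user"
        else:
            out[key] = dval
            provenance[f"{path}{key}"] = "default"
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys under '{path or 'top level'}': "
                          f"{sorted(unknown)}")
    return out


def load_config(path=None, data: dict | None = None) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Missing keys take their defaults; unknown keys are an error.  An empty
    file yields the all-defaults configuration (control model, single
    stimulus, dt = 0.01 ms).
    """
    if data is None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    provenance: dict = {}
    data = dict(data)
    user_clamps = data.pop("clamps", None)
    # alpha and overrides are open mappings (validated downstream)
    open_maps = {}
    for key in ("alpha", "overrides"):
        if key in data:
            if not isinstance(data[key], dict):
                raise ConfigError(f"'{key}' must be a mapping")
            open_maps[key] = dict(data.pop(key))
            provenance[key] = "user"
        else:
            open_maps[key] = {}
            provenance[key] = "default"
    merged = _merge({k: v for k, v in _DEFAULTS.items()
                     if k not in ("clamps", "alpha", "overrides")},
                    data, "", provenance)
    merged["alpha"] = open_maps["alpha"]
    merged["overrides"] = open_maps["overrides"]
    clamps = []
    if user_clamps:
        for i, c in enumerate(user_clamps):
            unknown = set(c) - _CLAMP_KEYS
            if unknown:
                raise ConfigError(f"unknown clamp keys: {sorted(unknown)}")
            clamps.append(dict(c))
        provenance["clamps"] = "user"
    else:
        provenance["clamps"] = "default"

    cfg = RunConfig(variant=merged["variant"], alpha=dict(merged["alpha"]),
                    overrides=dict(merged["overrides"]),
                    protocol=merged["protocol"], clamps=clamps,
                    integration=merged["integration"],
                    analysis=merged["analysis"], seed=int(merged["seed"]),
                    outdir=str(merged["outdir"]), provenance=provenance)
    # validation
    if cfg.variant not in ("original", "flattened"):
        raise ConfigError(f"unknown variant {cfg.variant!r}")
    if cfg.integration["dt_ms"] <= 0:
        raise ConfigError("dt_ms must be positive")
    if cfg.integration["t_end_ms"] <= 0:
        raise ConfigError("t_end_ms must be positive")
    for name in cfg.alpha:
        if name not in ("k_max", "J_Caslmyo", "P_Ca", "G_Ks", "I_NCX_bar"):
            raise ConfigError(f"unknown alpha key {name!r}")
    cfg.to_parameters()   # surfaces bad overrides / negative alphas early
    return cfg
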