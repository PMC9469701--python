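"""Run configuration: YAML (or JSON) files driving the CLI and scripts.

A config may carry any of:

``model``        "twocpt" | "onecpt"
``parameters``   parameter declarations (see build_parameter_space)
``ode``          rtol / atol / max_num_step
``regimen``      RegimenSpec fields for the simulate subcommand
``truth``        parameter values used when simulating
``sigma``        residual scale used when simulating
``hmc``          chains / warmup / sampling / target_accept / path_length
``allometry``    exp_clearance / exp_volume / ref_weight
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .odes import OdeSettings
from .paramspace import ParameterSpace, build_parameter_space
from .simulate import RegimenSpec

__all__ = ["load_config", "space_from_config", "ode_settings_from_config", "regimen_from_config"]


def load_config(path: str | Path) -> dict:
    """Parse a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def space_from_config(config: dict, model: str = "twocpt") -> ParameterSpace:
    if config.get("parameters"):
        return build_parameter_space(config["parameters"])
    from .posterior import default_onecpt_space, default_twocpt_space

    return default_twocpt_space() if model == "twocpt" else default_onecpt_space()


def ode_settings_from_config(config: dict) -> OdeSettings:
    return OdeSettings.from_config(config.get("ode", {}))


def regimen_from_config(config: dict) -> RegimenSpec:
    spec = config.get("regimen", {})
    fields = {k: tuple(v) if isinstance(v, list) else v for k, v in spec.items()}
    return RegimenSpec(**fields)
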