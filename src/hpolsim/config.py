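"""Run configuration: YAML schema, validation and assembly.

A run config has up to four sections::

    parameters:           # optional
      file: params.tsv    # or inline overrides:
      overrides: {Cl_E2: 31.02}
    gnrh:                 # optional; default = packaged parametric driver
      mode: parametric | tabulated
      file: gnrh.csv                  # tabulated
      interpolation: linear | cubic
      baseline: 12.0                  # parametric
      pulses: [[155, 55, 150], ...]
      period_days: 365
    options:              # optional; any SimulationOptions field
      duration_days: 365
    scenario:             # optional
      name: trenbolone
      variant: both

Unknown keys anywhere are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .engine import SimulationOptions
from .gnrh import GnRHDriver, ParametricGnRH, TabulatedGnRH, default_gnrh_driver
from .parameters import ModelParameters, apply_perturbation, default_parameters, load_parameters
from .scenarios import Scenario, trenbolone_scenario

__all__ = ["RunConfig", "parse_config"]

_OPTION_FIELDS = {f.name for f in dataclasses.fields(SimulationOptions)} - {"simplified_vtg"}
_GNRH_KEYS = {"mode", "file", "interpolation", "periodic", "baseline", "pulses", "period_days"}
_PARAM_KEYS = {"file", "overrides"}
_SCENARIO_KEYS = {"name", "variant"}
_TOP_KEYS = {"parameters", "gnrh", "options", "scenario", "seed", "log_level"}


@dataclass
class RunConfig:
    """Fully-resolved run specification."""

    params: ModelParameters
    gnrh: GnRHDriver
    options: SimulationOptions
    scenario: Scenario | None = None
    seed: int = 0
    log_level: str = "INFO"

    def gated_multipliers(self):
        return self.scenario.gated if self.scenario is not None else ()

    def effective_params(self) -> ModelParameters:
        return self.scenario.apply(self.params) if self.scenario is not None else self.params


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}")


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; defaults fill absent sections."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, str(path))

    psec = raw.get("parameters") or {}
    _reject_unknown(psec, _PARAM_KEYS, "parameters section")
    if "file" in psec:
        params = load_parameters(Path(psec["file"]).expanduser())
    else:
        params = default_parameters()
    if psec.get("overrides"):
        overrides = dict(psec["overrides"])
        values = params.to_dict()
        unknown = set(overrides) - set(values)
        if unknown:
            raise ValueError(f"unknown parameter override(s): {sorted(unknown)}")
        values.update({k: float(v) for k, v in overrides.items()})
        params = ModelParameters(**values)

    gsec = raw.get("gnrh") or {}
    _reject_unknown(gsec, _GNRH_KEYS, "gnrh section")
    mode = gsec.get("mode", "parametric")
    if mode == "parametric":
        kwargs = {}
        if "baseline" in gsec:
            kwargs["baseline"] = float(gsec["baseline"])
        if "pulses" in gsec:
            kwargs["pulses"] = tuple(tuple(map(float, p)) for p in gsec["pulses"])
        if "period_days" in gsec:
            kwargs["period_days"] = float(gsec["period_days"])
        gnrh = ParametricGnRH(**kwargs) if kwargs else default_gnrh_driver()
    elif mode == "tabulated":
        if "file" not in gsec:
            raise ValueError("gnrh.mode=tabulated requires gnrh.file")
        gnrh = TabulatedGnRH.from_file(
            Path(gsec["file"]).expanduser(),
            interpolation=gsec.get("interpolation", "linear"),
            periodic=bool(gsec.get("periodic", True)),
        )
    else:
        raise ValueError(f"unknown gnrh mode {mode!r}")

    osec = raw.get("options") or {}
    _reject_unknown(osec, _OPTION_FIELDS, "options section")
    options = SimulationOptions(**osec)

    scenario = None
    ssec = raw.get("scenario") or {}
    if ssec:
        _reject_unknown(ssec, _SCENARIO_KEYS, "scenario section")
        if ssec.get("name") != "trenbolone":
            raise ValueError(f"unknown scenario {ssec.get('name')!r}; available: trenbolone")
        scenario = trenbolone_scenario(ssec.get("variant", "both"))

    return RunConfig(
        params=params, gnrh=gnrh, options=options, scenario=scenario,
        seed=int(raw.get("seed", 0)), log_level=str(raw.get("log_level", "INFO")),
    )
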