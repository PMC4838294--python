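"""Stressor scenarios expressed as parameter perturbations.

A scenario is a named set of multiplicative parameter changes, some
unconditional and some gated on the developmental state of the clutch.
The packaged trenbolone scenario reproduces a continuous-exposure
androgen challenge: stage-4/5 E2 synthesis reduced to 54%, FSH release
quadrupled while the clutch is predominantly pre-vitellogenic, and —
depending on the variant — E2 plasma clearance increased 41% and/or mVTG
synthesis reduced to 60%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .parameters import ModelParameters, ParameterPerturbation, apply_perturbation

__all__ = ["Scenario", "trenbolone_scenario", "prevtg_majority_gate"]

GateFn = Callable[[np.ndarray], float]


def _smoothstep(x: float) -> float:
    x = min(max(x, 0.0), 1.0)
    return x * x * (3.0 - 2.0 * x)


def prevtg_majority_gate(center: float = 0.5, band: float = 0.05) -> GateFn:
    """Smooth indicator that the clutch is mostly pre-vitellogenic.

    Returns a gate on the stage-proportion vector that is 1 when
    ``S_1 + S_2`` is above ``center + band/2``, 0 below ``center - band/2``
    and smoothly interpolated in between, keeping the right-hand side
    continuous.
    """

    def gate(S: np.ndarray) -> float:
        x = float(S[0] + S[1])
        return _smoothstep((x - (center - band / 2.0)) / band)

    return gate


@dataclass(frozen=True)
class Scenario:
    """Named stressor: unconditional multipliers plus stage-gated multipliers."""

    name: str
    multipliers: dict[str, float] = field(default_factory=dict)
    gated: tuple[tuple[str, float, GateFn], ...] = ()

    def __post_init__(self) -> None:
        ParameterPerturbation(self.multipliers)  # validates names and positivity
        for pname, factor, _gate in self.gated:
            ParameterPerturbation({pname: factor})

    def apply(self, base: ModelParameters) -> ModelParameters:
        """Parameter set with the unconditional multipliers applied."""
        return apply_perturbation(base, self.multipliers)


_TREN_VARIANTS = ("synthesis_only", "+clearance", "+mvtg", "both")


def trenbolone_scenario(variant: str = "both") -> Scenario:
    """Continuous trenbolone exposure scenario.

    All variants reduce the stage-4 and stage-5 E2 secretion clearances to
    54% and quadruple FSH release while stages 1-2 dominate.  Variant
    ``"+clearance"`` additionally raises E2 plasma clearance by 41%,
    ``"+mvtg"`` reduces mVTG synthesis to 60%, and ``"both"`` applies both;
    ``"synthesis_only"`` applies neither.
    """
    if variant not in _TREN_VARIANTS:
        raise ValueError(f"unknown trenbolone variant {variant!r}; choose from {_TREN_VARIANTS}")
    multipliers = {"Cl_E2_S4": 0.54, "Cl_E2_S5": 0.54}
    if variant in ("+clearance", "both"):
        multipliers["Cl_E2"] = 1.41
    if variant in ("+mvtg", "both"):
        multipliers["ks_mVTG"] = 0.6
    gated = (("ks_FSH", 4.0, prevtg_majority_gate()),)
    return Scenario(name=f"trenbolone/{variant}", multipliers=multipliers, gated=gated)
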