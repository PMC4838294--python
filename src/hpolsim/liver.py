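"""Liver subsystem: estrogen-receptor signalling and vitellogenin synthesis.

Circulating E2 binds the hepatic nuclear estrogen receptor R; the complex
ER both up-regulates its own receptor mRNA (mR, auto-induction) and drives
transcription of the vitellogenin mRNA mVTG.  Translation of VTG is
super-linear in mVTG — each transcript is translated many times — which is
captured by the power law ``(mVTG / N_mVTG)^gamma`` with N_mVTG the
nondimensionalising scale.  Liver VTG (VTG_L) is secreted into plasma
(VTG_P), exchanges reversibly with peripheral tissues (VTG_N) and leaves
the plasma through total-body clearance and ovarian sequestration Seq(t).

A reduced variant replaces the whole receptor/transcription cascade with a
single delayed-E2 production term for plasma VTG (transit chain on E2),
useful when hepatic data are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DelaySpec
from .parameters import ModelParameters

__all__ = [
    "LiverState",
    "SimplifiedVtgParams",
    "liver_derivatives",
    "simplified_vtg_derivatives",
    "DEFAULT_K_E2_VTG",
    "DEFAULT_VTG_DELAY_HOURS",
]

# Gain of the reduced delayed-E2 -> plasma-VTG model, calibrated once on the
# baseline run so the reduced model reproduces the full hepatic cascade's
# plasma-VTG peak timing (within days) and ovulation time (within ~4 days);
# the peak *magnitude* runs lower because the reduced model lacks the
# liver reservoir and translational power law that amplify the transient
# post-maturation spike.  Delay of the E2->VTG transit chain in hours.
DEFAULT_K_E2_VTG = 220.0  # (ng/ml)^-1 * (mg/ml) * ml/hr/kg
DEFAULT_VTG_DELAY_HOURS = 100.0


@dataclass
class LiverState:
    """Hepatic receptor/transcript states and the three VTG pools."""

    mR: float  # pg/ug RNA
    R: float  # fmol/g liver
    ER: float  # fmol/g liver
    mVTG: float  # pg/ug RNA
    VTG_L: float  # mg/g liver
    VTG_N: float  # mg/ml
    VTG_P: float  # mg/ml

    def __post_init__(self) -> None:
        for name in ("mR", "R", "ER", "mVTG", "VTG_L", "VTG_N", "VTG_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SimplifiedVtgParams:
    """Gain and delay of the reduced delayed-E2 VTG production model."""

    k_E2_VTG: float = DEFAULT_K_E2_VTG
    delay: DelaySpec = DelaySpec(DEFAULT_VTG_DELAY_HOURS, 5)

    def __post_init__(self) -> None:
        if not self.k_E2_VTG > 0:
            raise ValueError("k_E2_VTG must be positive")


def liver_derivatives(
    state: LiverState, E2: float, Seq: float, params: ModelParameters
) -> LiverState:
    """Right-hand sides of the seven hepatic/VTG balances (per hour).

    The E2-receptor association flux ``k_on,ER * E2 * R`` moves mass from R
    to ER and appears with opposite signs in the two balances, so the total
    receptor pool changes only through synthesis and degradation.
    """
    if min(E2, Seq) < 0:
        raise ValueError("E2 and Seq must be non-negative")
    binding = params.kon_ER * E2 * state.R
    d_mR = params.ks_mR * (1.0 + params.alpha_mR_ER * state.ER) - params.kd_mR * state.mR
    d_R = params.ks_R * state.mR - params.kd_R * state.R - binding + params.koff_ER * state.ER
    d_ER = binding - (params.koff_ER + params.kd_ER) * state.ER
    d_mVTG = (
        params.ks_mVTG * (1.0 + params.alpha_mVTG_ER * state.ER)
        - params.kd_mVTG * state.mVTG
    )
    d_VTG_L = (
        params.ks_VTG * (max(state.mVTG, 0.0) / params.N_mVTG) ** params.gamma
        - params.kr_VTG * state.VTG_L
    )
    d_VTG_N = (
        params.Cl_VTG_trans * state.VTG_P - params.Cl_VTG_trans * state.VTG_N
    ) / params.V_VTGN
    d_VTG_P = (
        params.kr_VTG * params.w_L * state.VTG_L
        + params.Cl_VTG_trans * state.VTG_N
        - (params.Cl_VTG_trans + Seq + params.Cl_VTG) * state.VTG_P
    ) / params.V_VTGP

    deriv = LiverState.__new__(LiverState)
    deriv.mR = d_mR
    deriv.R = d_R
    deriv.ER = d_ER
    deriv.mVTG = d_mVTG
    deriv.VTG_L = d_VTG_L
    deriv.VTG_N = d_VTG_N
    deriv.VTG_P = d_VTG_P
    return deriv


def simplified_vtg_derivatives(
    VTG_P: float,
    VTG_N: float,
    E2_delayed: float,
    Seq: float,
    params: ModelParameters,
    svp: SimplifiedVtgParams,
) -> tuple[float, float]:
    """Reduced VTG model: delayed-E2 production straight into plasma.

    Returns (dVTG_P/dt, dVTG_N/dt); the plasma/peripheral exchange of the
    full model is retained.
    """
    if min(VTG_P, VTG_N, E2_delayed, Seq) < 0:
        raise ValueError("inputs must be non-negative")
    d_VTG_P = (
        svp.k_E2_VTG * E2_delayed
        + params.Cl_VTG_trans * VTG_N
        - (params.Cl_VTG_trans + Seq + params.Cl_VTG) * VTG_P
    ) / params.V_VTGP
    d_VTG_N = (params.Cl_VTG_trans * VTG_P - params.Cl_VTG_trans * VTG_N) / params.V_VTGN
    return d_VTG_P, d_VTG_N
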