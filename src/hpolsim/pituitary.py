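"""Pituitary subsystem: gonadotropin synthesis, storage and release.

GnRH drives synthesis of the beta-subunit mRNAs mFSH and mLH.  FSH is
released continuously (its plasma level tracks mFSH through a clearance-
volume balance), while LH accumulates in the pituitary behind a
dopaminergic block.  The block is modelled as a per-unit-LH requirement of
D2 receptors whose abundance is proportional to circulating E2 and DHP:
release occurs only for the "unblocked" excess

    Theta = LH_Pit - N_E2*[E2] - N_DHP*[DHP]

and only while E2 exceeds the permissive threshold T_E2,LH (a steep Hill
gate).  Because the release rate constant k_r,LH is very large, release in
practice behaves as a spillover that pins LH_Pit at the block level while
the gate is open — this produces both the premature LH rise and the
pre-ovulatory surge as E2 declines.

Positive feedback of E2 on mLH synthesis acts through a transit-compartment
chain with total delay D_E2,mLH.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DelaySpec, HillSpec, hill_inhibitory, hill_stimulatory, transit_chain_derivatives
from .parameters import ModelParameters

__all__ = [
    "PituitaryState",
    "lh_release_rate",
    "lh_release_rate_alt",
    "pituitary_derivatives",
]


@dataclass
class PituitaryState:
    """Pituitary and plasma gonadotropin states plus the E2->mLH delay chain."""

    mFSH: float  # pg/ug RNA
    mLH: float  # pg/ug RNA
    LH_Pit: float  # ng/mg pituitary
    FSH_P: float  # ng/ml
    LH_P: float  # ng/ml
    e2_chain: np.ndarray  # delayed E2 feeding mLH synthesis, ng/ml

    def __post_init__(self) -> None:
        for name in ("mFSH", "mLH", "LH_Pit", "FSH_P", "LH_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.e2_chain = np.asarray(self.e2_chain, dtype=float)
        if np.any(self.e2_chain < 0):
            raise ValueError("E2 delay chain must be non-negative")


def lh_release_rate(
    LH_Pit: float, E2: float, DHP: float, params: ModelParameters
) -> float:
    """Dopamine-block spillover release function.

    ``max(Theta, 0) * H+(E2, T_E2,LH, n_E2,LH)`` with
    ``Theta = LH_Pit - N_E2*E2 - N_DHP*DHP``.  Units: ng/mg pituitary of
    releasable LH (multiplied by k_r,LH in the balance equations).
    """
    if min(LH_Pit, E2, DHP) < 0:
        raise ValueError("LH_Pit, E2 and DHP must be non-negative")
    theta = LH_Pit - params.N_E2 * E2 - params.N_DHP * DHP
    if theta <= 0.0:
        return 0.0
    gate = hill_stimulatory(E2, HillSpec(params.T_E2_LH, params.n_E2_LH))
    return theta * gate


def lh_release_rate_alt(
    LH_Pit: float, E2: float, S_6: float, S_FOM: float, params: ModelParameters
) -> float:
    """Stage-restricted alternative release function.

    Release is proportional to pituitary LH, confined to late vitellogenesis
    and final maturation (S_6 + S_FOM) and opened by *declining* E2 through
    the inhibitory Hill gate.
    """
    if not (0 <= S_6 <= 1 and 0 <= S_FOM <= 1):
        raise ValueError("stage proportions must lie in [0, 1]")
    gate = hill_inhibitory(E2, HillSpec(params.T_E2_LH, params.n_E2_LH))
    return (S_6 + S_FOM) * gate * LH_Pit


def pituitary_derivatives(
    state: PituitaryState,
    gnrh_value: float,
    dhp: float,
    e2: float,
    params: ModelParameters,
    *,
    release_function: str = "spillover",
    S_6: float = 0.0,
    S_FOM: float = 0.0,
) -> tuple[PituitaryState, float]:
    """Right-hand sides of the five pituitary/plasma balances and the E2 chain.

    Returns ``(derivatives, R_LH)`` where derivatives is a
    :class:`PituitaryState`-shaped container of time derivatives (per hour)
    and ``R_LH`` the evaluated release function.  ``release_function``
    selects the spillover model (default) or the stage-restricted
    alternative ("stage_gated"), for which the stage proportions S_6 and
    S_FOM must be supplied.
    """
    e2_delayed = float(state.e2_chain[-1])
    if release_function == "spillover":
        r_lh = lh_release_rate(state.LH_Pit, e2, dhp, params)
    elif release_function == "stage_gated":
        r_lh = lh_release_rate_alt(state.LH_Pit, e2, S_6, S_FOM, params)
    else:
        raise ValueError(f"unknown release_function {release_function!r}")

    d_mFSH = params.ks_mFSH * (1.0 + params.alpha_mFSH_GnRH * gnrh_value) - params.kd_mFSH * state.mFSH
    d_mLH = (
        params.ks_mLH
        * (1.0 + params.alpha_mLH_GnRH * gnrh_value + params.alpha_mLH_E2 * e2_delayed)
        - params.kd_mLH * state.mLH
    )
    d_FSH_P = (
        params.w_Pit * params.ks_FSH * state.mFSH - params.Cl_FSH * state.FSH_P
    ) / params.V_FSH
    d_LH_Pit = params.ks_LH * state.mLH - params.kd_LH * state.LH_Pit - params.kr_LH * r_lh
    d_LH_P = (params.w_Pit * params.kr_LH * r_lh - params.Cl_LH * state.LH_P) / params.V_LH

    chain_spec = DelaySpec(params.D_E2_mLH, len(state.e2_chain))
    d_chain = transit_chain_derivatives(state.e2_chain, e2, chain_spec)

    deriv = PituitaryState.__new__(PituitaryState)
    deriv.mFSH = d_mFSH
    deriv.mLH = d_mLH
    deriv.LH_Pit = d_LH_Pit
    deriv.FSH_P = d_FSH_P
    deriv.LH_P = d_LH_P
    deriv.e2_chain = d_chain
    return deriv, r_lh
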