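"""Ovary subsystem: oocyte staging, growth, steroidogenesis and ovulation.

The clutch of oocytes is summarised by the mean diameter O_Avg (a state
variable) and the diameter variance O_Var (an algebraic quantity).  At any
instant the population of diameters is taken to be Weibull with moments
(O_Avg, O_Var); the seven developmental stages are the probability masses
between fixed boundary diameters s_1..s_6, with stage 1 on [0, s_1] and
final oocyte maturation (FOM) above s_6.

O_Var is itself a stage-weighted mixture of per-stage maximal variances,
which makes Eqs. "stages from variance" and "variance from stages" mutually
dependent; :func:`self_consistent_variance` resolves the pair as a damped
fixed point in the variance.

Vitellogenic oocytes (stages 3-6) sequester plasma VTG at a clearance that
is boosted by circulating FSH; sequestered VTG drives the vitellogenic part
of diameter growth.  Steroid output is stage-weighted and driven by
*delayed* gonadotropins: FSH (delay D_FSH,E2) drives E2, LH (delay
D_LH,DHP) drives DHP.  Ovulation is declared when DHP and the FOM fraction
simultaneously exceed their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    DelaySpec,
    HillSpec,
    WeibullParams,
    hill_stimulatory,
    transit_chain_derivatives,
    weibull_cdf,
    weibull_from_moments,
)
from .parameters import ModelParameters

__all__ = [
    "StageDistribution",
    "OvaryState",
    "stage_proportions",
    "oocyte_variance",
    "self_consistent_variance",
    "sequestration_rate",
    "ovary_derivatives",
    "ovulation_check",
]

STAGE_NAMES = ("S_1", "S_2", "S_3", "S_4", "S_5", "S_6", "S_FOM")


@dataclass(frozen=True)
class StageDistribution:
    """Proportions of the clutch in stages 1..6 and FOM, plus the fitted Weibull."""

    proportions: tuple[float, ...]  # (S_1,...,S_6, S_FOM)
    weibull: WeibullParams
    boundaries: tuple[float, ...]  # (s_1,...,s_6), mm

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        if p.shape != (7,):
            raise ValueError("need 7 stage proportions (stages 1-6 and FOM)")
        if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError(f"stage proportions must be in [0,1] and sum to 1, got {p}")

    @property
    def S(self) -> np.ndarray:
        return np.asarray(self.proportions)

    @property
    def S_FOM(self) -> float:
        return self.proportions[6]

    def vitellogenic_fraction(self) -> float:
        """S_3 + S_4 + S_5 + S_6 — the VTG-sequestering mass."""
        return float(sum(self.proportions[2:6]))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STAGE_NAMES, self.proportions))


@dataclass
class OvaryState:
    """Ovarian states: mean diameter, steroids and the two gonadotropin delay chains."""

    O_Avg: float  # mm
    E2: float  # ng/ml
    DHP: float  # ng/ml
    fsh_chain: np.ndarray  # delayed plasma FSH driving E2, ng/ml
    lh_chain: np.ndarray  # delayed plasma LH driving DHP, ng/ml

    def __post_init__(self) -> None:
        if not self.O_Avg > 0:
            raise ValueError("O_Avg must be positive")
        if self.E2 < 0 or self.DHP < 0:
            raise ValueError("hormone concentrations must be non-negative")
        self.fsh_chain = np.asarray(self.fsh_chain, dtype=float)
        self.lh_chain = np.asarray(self.lh_chain, dtype=float)


def stage_proportions(
    O_Avg: float, O_Var: float, params: ModelParameters
) -> StageDistribution:
    """Stage masses of a Weibull diameter distribution with the given moments.

    S_1 = F(s_1), S_j = F(s_j) - F(s_{j-1}) for j = 2..6, S_FOM = 1 - F(s_6).
    The coefficient of variation is clamped to the invertible shape range, so
    near-degenerate variances behave as point masses.
    """
    if not O_Avg > 0 or not O_Var > 0:
        raise ValueError("O_Avg and O_Var must be positive")
    wb = weibull_from_moments(O_Avg, O_Var, clip_cv=True)
    bounds = np.asarray(params.stage_boundaries())
    cdf = weibull_cdf(bounds, wb)
    props = np.empty(7)
    props[0] = cdf[0]
    props[1:6] = np.diff(cdf)
    props[6] = 1.0 - cdf[5]
    return StageDistribution(tuple(props), wb, tuple(bounds))


def oocyte_variance(S: StageDistribution, params: ModelParameters) -> float:
    """Stage-weighted diameter variance: sum_j alpha_OVar,Sj * S_j (mm^2)."""
    alphas = np.asarray(params.stage_variances())
    return float(alphas @ S.S)


def self_consistent_variance(
    O_Avg: float,
    params: ModelParameters,
    v_init: float = 0.02,
    *,
    tol: float = 1e-9,
    max_iter: int = 200,
    damping: float = 0.5,
) -> tuple[float, StageDistribution]:
    """Fixed point of variance -> stages -> stage-weighted variance.

    The staging Weibull needs a variance, but the model defines the variance
    as a stage-weighted mixture; the two are reconciled by damped iteration
    ``v <- (1-d) v + d * g(v)`` from ``v_init`` (tolerance ``tol``).
    Returns the converged variance and its stage distribution.
    """
    if not v_init > 0:
        raise ValueError("v_init must be positive")
    v = float(v_init)
    last = None
    for _ in range(max_iter):
        S = stage_proportions(O_Avg, v, params)
        g = oocyte_variance(S, params)
        new = (1.0 - damping) * v + damping * g
        if abs(new - v) <= tol * max(1.0, abs(v)):
            return new, stage_proportions(O_Avg, new, params)
        last, v = v, new
    raise ArithmeticError(
        f"variance fixed point did not converge for O_Avg={O_Avg}; "
        f"last iterates {last}, {v}"
    )


def sequestration_rate(
    FSH_P: float, S: StageDistribution, params: ModelParameters
) -> float:
    """Ovarian VTG uptake clearance Seq(t), ml/hr/kg.

    Basal clearance boosted up to two-fold by circulating FSH (Hill with
    threshold T_Seq,FSH, exponent 1) and scaled by the vitellogenic mass
    S_3 + ... + S_6.
    """
    if FSH_P < 0:
        raise ValueError("FSH_P must be non-negative")
    boost = 1.0 + hill_stimulatory(FSH_P, HillSpec(params.T_Seq_FSH, 1.0))
    return params.Cl_VTG_Seq * boost * S.vitellogenic_fraction()


def ovary_derivatives(
    state: OvaryState,
    FSH_P: float,
    LH_P: float,
    VTG_P: float,
    S: StageDistribution,
    params: ModelParameters,
) -> OvaryState:
    """Right-hand sides for O_Avg, E2, DHP and the two delay chains (per hour).

    Diameter growth has a constant non-vitellogenic term weighted by
    S_1 + S_2 + S_FOM and a VTG-sequestration term.  E2 production sums the
    stage clearances over stages 2-6 (plus the basal per-follicle rate) and
    is driven by the delayed FSH; DHP production sums stages 2-6 and FOM and
    is driven by the delayed LH, with no basal term.
    """
    fsh_delayed = float(state.fsh_chain[-1])
    lh_delayed = float(state.lh_chain[-1])
    seq = sequestration_rate(FSH_P, S, params)
    p = S.S

    d_OAvg = (
        params.k_NV_OAvg * (p[0] + p[1] + p[6])
        + params.k_V_OAvg * seq * VTG_P
    )

    cl_e2 = (
        params.Cl_E2_S2 * p[1]
        + params.Cl_E2_S3 * p[2]
        + params.Cl_E2_S4 * p[3]
        + params.Cl_E2_S5 * p[4]
        + params.Cl_E2_S6 * p[5]
    )
    d_E2 = (
        params.n_oocyte * (params.k_E2 + fsh_delayed * cl_e2) - params.Cl_E2 * state.E2
    ) / params.V_E2

    cl_dhp = (
        params.Cl_DHP_S2 * p[1]
        + params.Cl_DHP_S3 * p[2]
        + params.Cl_DHP_S4 * p[3]
        + params.Cl_DHP_S5 * p[4]
        + params.Cl_DHP_S6 * p[5]
        + params.Cl_DHP_SFOM * p[6]
    )
    d_DHP = (
        params.n_oocyte * lh_delayed * cl_dhp - params.Cl_DHP * state.DHP
    ) / params.V_DHP

    d_fsh_chain = transit_chain_derivatives(
        state.fsh_chain, FSH_P, DelaySpec(params.D_FSH_E2, len(state.fsh_chain))
    )
    d_lh_chain = transit_chain_derivatives(
        state.lh_chain, LH_P, DelaySpec(params.D_LH_DHP, len(state.lh_chain))
    )

    deriv = OvaryState.__new__(OvaryState)
    deriv.O_Avg = d_OAvg
    deriv.E2 = d_E2
    deriv.DHP = d_DHP
    deriv.fsh_chain = d_fsh_chain
    deriv.lh_chain = d_lh_chain
    return deriv


def ovulation_check(DHP: float, S_FOM: float, params: ModelParameters) -> bool:
    """True when both ovulation requirements hold: DHP >= DHP_final and S_FOM >= FOM_final."""
    return bool(DHP >= params.DHP_final and S_FOM >= params.FOM_final)
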