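"""Mathematical primitives shared by every subsystem of the axis model.

Three ingredients recur throughout the model: Hill functions for threshold
feedback, the Heaviside step for hard switches, and transit-compartment
chains (Erlang lags) for signal-transduction delays.  A fourth primitive,
moment-matched Weibull parameters, underlies the oocyte staging machinery:
the population of oocyte diameters at any instant is summarized by a
Weibull distribution whose mean and variance are prescribed, so the
(scale, shape) pair must be recovered from the first two moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "HillSpec",
    "DelaySpec",
    "WeibullParams",
    "hill_stimulatory",
    "hill_inhibitory",
    "heaviside",
    "transit_chain_derivatives",
    "weibull_from_moments",
    "weibull_cdf",
    "weibull_moments",
]


@dataclass(frozen=True)
class HillSpec:
    """Threshold ``T`` (in units of the input) and exponent ``n`` of a Hill term."""

    threshold: float
    exponent: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"Hill threshold must be positive, got {self.threshold}")
        if not self.exponent > 0:
            raise ValueError(f"Hill exponent must be positive, got {self.exponent}")


@dataclass(frozen=True)
class DelaySpec:
    """Total delay ``D`` in hours realised by ``m`` serial transit compartments.

    The per-compartment rate is ``m / D`` so the impulse response of the
    chain is an Erlang(m, m/D) density with mean exactly ``D``.
    """

    total_delay: float
    n_compartments: int = 5

    def __post_init__(self) -> None:
        if not self.total_delay > 0:
            raise ValueError(f"total_delay must be positive, got {self.total_delay}")
        if int(self.n_compartments) != self.n_compartments or self.n_compartments < 1:
            raise ValueError(f"n_compartments must be a positive integer, got {self.n_compartments}")

    @property
    def rate(self) -> float:
        """First-order rate (hr^-1) of each compartment."""
        return self.n_compartments / self.total_delay


@dataclass(frozen=True)
class WeibullParams:
    """Weibull scale ``l`` (mm) and shape ``k`` (dimensionless)."""

    scale: float
    shape: float

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"Weibull scale must be positive, got {self.scale}")
        if not self.shape > 0:
            raise ValueError(f"Weibull shape must be positive, got {self.shape}")

    @property
    def mean(self) -> float:
        return self.scale * math.exp(gammaln(1.0 + 1.0 / self.shape))

    @property
    def variance(self) -> float:
        k = self.shape
        g1 = gammaln(1.0 + 1.0 / k)
        g2 = gammaln(1.0 + 2.0 / k)
        return self.scale**2 * (math.exp(g2) - math.exp(2.0 * g1))


def hill_stimulatory(x, spec: HillSpec):
    """Stimulatory Hill term ``x^n / (x^n + T^n)``; accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input concentration must be non-negative")
    r = (x / spec.threshold) ** spec.exponent
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def hill_inhibitory(x, spec: HillSpec):
    """Inhibitory Hill term ``T^n / (x^n + T^n)`` = 1 - stimulatory."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Hill input concentration must be non-negative")
    r = (x / spec.threshold) ** spec.exponent
    out = 1.0 / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def heaviside(t):
    """Unit step: 0 for t <= 0, 1 for t > 0 (the value at 0 is 0)."""
    t = np.asarray(t, dtype=float)
    out = (t > 0).astype(float)
    return float(out) if out.ndim == 0 else out


def transit_chain_derivatives(chain_state, input_value: float, spec: DelaySpec) -> np.ndarray:
    """Time derivatives of a serial transit-compartment chain.

    The first compartment relaxes toward the driving ``input_value`` and each
    subsequent compartment toward its predecessor, all at rate ``m/D``.  Each
    compartment should be initialised to the driver's value at the start time.
    """
    chain_state = np.asarray(chain_state, dtype=float)
    if chain_state.shape != (spec.n_compartments,):
        raise ValueError(
            f"chain_state has length {chain_state.shape}, expected ({spec.n_compartments},)"
        )
    upstream = np.concatenate(([input_value], chain_state[:-1]))
    return spec.rate * (upstream - chain_state)


def _log_cv2_of_shape(k: float) -> float:
    """log of the squared coefficient of variation of a Weibull with shape k."""
    g1 = gammaln(1.0 + 1.0 / k)
    g2 = gammaln(1.0 + 2.0 / k)
    # CV^2 = Gamma(1+2/k)/Gamma(1+1/k)^2 - 1; computed in log space for stability
    ratio = math.exp(g2 - 2.0 * g1)
    return math.log(ratio - 1.0)


_K_LO = 0.05
_K_HI = 500.0
_LOG_CV2_AT_K_HI = _log_cv2_of_shape(_K_HI)
_LOG_CV2_AT_K_LO = _log_cv2_of_shape(_K_LO)


def weibull_from_moments(
    mean: float, variance: float, *, clip_cv: bool = False, rtol: float = 1e-10
) -> WeibullParams:
    """Invert (mean, variance) to Weibull (scale, shape).

    The squared coefficient of variation is a strictly decreasing function of
    the shape ``k``, so ``k`` is found by bracketed root-finding on ``log k``
    over ``k`` in [0.05, 500]; the scale then follows from the mean.  A CV
    outside the bracketable range raises a domain error unless ``clip_cv``
    is set, in which case the nearest bracket endpoint is used (this makes
    near-degenerate, vanishing-variance inputs well behaved).
    """
    if not mean > 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if not variance > 0:
        raise ValueError(f"variance must be positive, got {variance}")
    log_cv2 = math.log(variance) - 2.0 * math.log(mean)
    if log_cv2 >= _LOG_CV2_AT_K_LO or log_cv2 <= _LOG_CV2_AT_K_HI:
        if not clip_cv:
            raise ValueError(
                f"coefficient of variation {math.exp(0.5 * log_cv2):.4g} outside the "
                f"bracketable shape range k in [{_K_LO}, {_K_HI}]"
            )
        log_cv2 = min(max(log_cv2, _LOG_CV2_AT_K_HI * (1 - 1e-12)), _LOG_CV2_AT_K_LO * (1 - 1e-12))
        # endpoints are one-sided limits; nudge strictly inside the bracket
        if log_cv2 >= _LOG_CV2_AT_K_LO:
            log_cv2 = _LOG_CV2_AT_K_LO - 1e-9
        if log_cv2 <= _LOG_CV2_AT_K_HI:
            log_cv2 = _LOG_CV2_AT_K_HI + 1e-9

    def f(log_k: float) -> float:
        return _log_cv2_of_shape(math.exp(log_k)) - log_cv2

    try:
        log_k = brentq(f, math.log(_K_LO), math.log(_K_HI), xtol=1e-14, rtol=8.9e-16)
    except Exception as exc:  # pragma: no cover - diagnostics path
        raise ArithmeticError(
            f"Weibull moment inversion failed for mean={mean}, variance={variance}: {exc}"
        ) from exc
    k = math.exp(log_k)
    l = mean / math.exp(gammaln(1.0 + 1.0 / k))
    params = WeibullParams(scale=l, shape=k)
    if not clip_cv:
        if abs(params.mean - mean) > rtol * mean * 100 or abs(params.variance - variance) > max(
            rtol * variance * 100, 1e-300
        ):
            raise ArithmeticError(
                f"moment inversion did not converge: requested (mean={mean}, var={variance}), "
                f"got (mean={params.mean}, var={params.variance})"
            )
    return params


def weibull_cdf(x, params: WeibullParams):
    """CDF ``1 - exp(-(x/l)^k)`` of the Weibull distribution; x >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Weibull CDF argument must be non-negative")
    out = -np.expm1(-((x / params.scale) ** params.shape))
    return float(out) if out.ndim == 0 else out


def weibull_moments(params: WeibullParams) -> tuple[float, float]:
    """Convenience (mean, variance) of a :class:`WeibullParams`."""
    return params.mean, params.variance
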