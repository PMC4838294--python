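"""Calibration utilities: GnRH recovery from FSH, stage-boundary rescaling,
spline-decoupled subsystem fitting, and a synthetic-observation generator.

The hypothalamic drive is not observable; it is recovered from measured
plasma FSH by algebraically inverting the two linear balances that connect
them.  A smooth spline through the FSH observations gives FSH(t) and its
derivative, from which pituitary mFSH(t) follows, and from mFSH(t) the
GnRH(t) that must have produced it.  Negative excursions (spline overshoot
or sub-basal FSH) are clipped to zero and the clipped fraction reported.

Subsystem fitting follows the decoupling strategy used to parameterise the
model: spline the observed drivers, integrate only the small subsystem of
balances that they drive, and least-squares fit the free parameters of
that subsystem against its observed outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .gnrh import HOURS_PER_DAY, TabulatedGnRH
from .parameters import ModelParameters

__all__ = [
    "ObservedSeries",
    "calibrate_gnrh_from_fsh",
    "recalibrate_stage_boundaries",
    "fit_subsystem",
    "SubsystemFit",
    "make_synthetic_series",
    "SUBSYSTEMS",
]


@dataclass(frozen=True)
class ObservedSeries:
    """Sampled time series of one analyte: (day, value[, sd]) triples."""

    days: np.ndarray
    values: np.ndarray
    analyte: str
    units: str = ""
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if days.ndim != 1 or days.shape != values.shape:
            raise ValueError("days and values must be matching 1-d arrays")
        if np.any(np.diff(days) <= 0):
            raise ValueError("observation days must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("observed values must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.shape != days.shape or np.any(sd < 0):
                raise ValueError("sd must match days and be non-negative")
            object.__setattr__(self, "sd", sd)

    def spline(self) -> CubicSpline:
        return CubicSpline(self.days, self.values)

    @classmethod
    def from_file(cls, path, analyte: str = "", units: str = "") -> "ObservedSeries":
        arr = np.loadtxt(path, comments="#", ndmin=2)
        sd = arr[:, 2] if arr.shape[1] > 2 else None
        return cls(days=arr[:, 0], values=arr[:, 1], analyte=analyte, units=units, sd=sd)

    def to_file(self, path) -> None:
        cols = [self.days, self.values] + ([self.sd] if self.sd is not None else [])
        np.savetxt(path, np.column_stack(cols), header=f"{self.analyte} day value sd",
                   comments="# ")


def calibrate_gnrh_from_fsh(
    fsh: ObservedSeries,
    params: ModelParameters,
    *,
    n_grid: int = 721,
    strict: bool = False,
    max_clipped_fraction: float = 0.25,
) -> TabulatedGnRH:
    """Recover a tabulated GnRH driver from observed plasma FSH.

    Inverts, in order, the plasma FSH balance for pituitary mFSH(t)::

        mFSH = (V_FSH * dFSH/dt + Cl_FSH * FSH) / (w_Pit * k_s,FSH)

    and the mFSH balance for the drive::

        GnRH = ((dmFSH/dt + k_d,mFSH * mFSH) / k_s,mFSH - 1) / alpha_mFSH,GnRH

    on a uniform day grid spanning the observations.  Negative values are
    clipped to zero; a clipped fraction above ``max_clipped_fraction``
    raises in strict mode and warns otherwise.
    """
    if len(fsh.days) < 5:
        raise ValueError("need at least 5 FSH observations spanning the cycle")
    spline = fsh.spline()
    days = np.linspace(fsh.days[0], fsh.days[-1], n_grid)
    fsh_v = np.clip(spline(days), 0.0, None)
    dfsh_dt = spline(days, 1) / HOURS_PER_DAY  # per hour
    mfsh = (params.V_FSH * dfsh_dt + params.Cl_FSH * fsh_v) / (params.w_Pit * params.ks_FSH)
    mfsh_spline = CubicSpline(days, mfsh)
    dmfsh_dt = mfsh_spline(days, 1) / HOURS_PER_DAY
    gnrh = ((dmfsh_dt + params.kd_mFSH * mfsh) / params.ks_mFSH - 1.0) / params.alpha_mFSH_GnRH
    clipped = float(np.mean(gnrh < 0))
    if clipped > 0:
        msg = f"GnRH inversion clipped {clipped:.1%} of grid points to zero"
        if strict and clipped > max_clipped_fraction:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    gnrh = np.clip(gnrh, 0.0, None)
    return TabulatedGnRH(days=days, values=gnrh, interpolation="linear", periodic=True)


def recalibrate_stage_boundaries(
    O_M_target: float, params: ModelParameters
) -> tuple[float, float, float, float]:
    """Rescale the vitellogenic stage boundaries to a new maximum diameter.

    The default boundaries apportion the vitellogenic growth span — defined
    by the rule ``(s_6 - s_2) / O_M = 0.84`` — into per-stage fractions;
    those fractions are preserved and re-applied to ``O_M_target``:
    ``s_j(new) = s_2 + (sum_{i<=j} f_i) * O_M_target``.  Returns the new
    (s_3, s_4, s_5, s_6).
    """
    if not O_M_target > 0:
        raise ValueError("O_M_target must be positive")
    s = params.stage_boundaries()
    o_m_def = (s[5] - s[1]) / 0.84
    fractions = np.diff(s[1:]) / o_m_def  # f_3..f_6
    cumulative = np.cumsum(fractions)
    new = s[1] + cumulative * O_M_target
    if not np.all(np.diff(np.concatenate(([s[0], s[1]], new))) > 0):
        raise ValueError(f"O_M_target={O_M_target} produces non-increasing boundaries")
    return tuple(float(x) for x in new)


# ---------------------------------------------------------------------------
# spline-decoupled subsystem fitting


@dataclass
class SubsystemFit:
    """Outcome of a subsystem fit: estimates, residual and convergence flag."""

    estimates: dict[str, float]
    residual: float
    converged: bool
    message: str


def _e2_subsystem(params, drivers, t_hours, free):
    """Ovarian E2 balance driven by splined delayed-FSH and stage proportions."""
    fsh = drivers["FSH_delayed"]
    stages = {j: drivers[f"S_{j}"] for j in range(2, 7)}

    def rhs(t, y):
        cl = sum(getattr(free, f"Cl_E2_S{j}", getattr(params, f"Cl_E2_S{j}")) * max(stages[j](t), 0.0)
                 for j in range(2, 7))
        k_e2 = getattr(free, "k_E2", params.k_E2)
        cl_e2 = getattr(free, "Cl_E2", params.Cl_E2)
        return [(params.n_oocyte * (k_e2 + max(fsh(t), 0.0) * cl) - cl_e2 * y[0]) / params.V_E2]

    return rhs, ["E2"]


def _fsh_subsystem(params, drivers, t_hours, free):
    """Plasma FSH balance driven by splined pituitary mFSH."""
    mfsh = drivers["mFSH"]

    def rhs(t, y):
        ks = getattr(free, "ks_FSH", params.ks_FSH)
        cl = getattr(free, "Cl_FSH", params.Cl_FSH)
        return [(params.w_Pit * ks * max(mfsh(t), 0.0) - cl * y[0]) / params.V_FSH]

    return rhs, ["FSH_P"]


def _dhp_subsystem(params, drivers, t_hours, free):
    """Plasma DHP balance driven by splined delayed-LH and stage proportions."""
    lh = drivers["LH_delayed"]
    names = ["S_2", "S_3", "S_4", "S_5", "S_6", "S_FOM"]
    pnames = ["Cl_DHP_S2", "Cl_DHP_S3", "Cl_DHP_S4", "Cl_DHP_S5", "Cl_DHP_S6", "Cl_DHP_SFOM"]
    stages = [drivers[n] for n in names]

    def rhs(t, y):
        cl = sum(getattr(free, p, getattr(params, p)) * max(s(t), 0.0)
                 for p, s in zip(pnames, stages))
        cl_dhp = getattr(free, "Cl_DHP", params.Cl_DHP)
        return [(params.n_oocyte * max(lh(t), 0.0) * cl - cl_dhp * y[0]) / params.V_DHP]

    return rhs, ["DHP"]


SUBSYSTEMS: dict[str, Callable] = {
    "e2": _e2_subsystem,
    "fsh": _fsh_subsystem,
    "dhp": _dhp_subsystem,
}

_SUBSYSTEM_PARAMS = {
    "e2": {"k_E2", "Cl_E2", "Cl_E2_S2", "Cl_E2_S3", "Cl_E2_S4", "Cl_E2_S5", "Cl_E2_S6"},
    "fsh": {"ks_FSH", "Cl_FSH"},
    "dhp": {"Cl_DHP", "Cl_DHP_S2", "Cl_DHP_S3", "Cl_DHP_S4", "Cl_DHP_S5", "Cl_DHP_S6",
            "Cl_DHP_SFOM"},
}


def fit_subsystem(
    observed: Sequence[ObservedSeries],
    subsystem: str,
    free_params: Sequence[str],
    params: ModelParameters,
    *,
    x0: dict[str, float] | None = None,
) -> SubsystemFit:
    """Least-squares fit of selected parameters of one decoupled subsystem.

    ``observed`` must contain the subsystem's output analyte (fitted) and
    every driving input (splined).  Free parameters outside the subsystem
    raise.  Non-convergence is reported in the returned flag rather than
    raised.
    """
    if subsystem not in SUBSYSTEMS:
        raise KeyError(f"unknown subsystem {subsystem!r}; choose from {sorted(SUBSYSTEMS)}")
    bad = set(free_params) - _SUBSYSTEM_PARAMS[subsystem]
    if bad:
        raise ValueError(f"free parameter(s) {sorted(bad)} are not part of subsystem {subsystem!r}")
    by_name = {o.analyte: o for o in observed}
    builder = SUBSYSTEMS[subsystem]
    probe_rhs, outputs = builder(params, _SplineBag(by_name), None, SimpleFree({}))
    target = by_name.get(outputs[0])
    if target is None:
        raise ValueError(f"no observed series for subsystem output {outputs[0]!r}")
    t_obs_h = target.days * HOURS_PER_DAY

    x0 = dict(x0 or {})
    start = np.array([x0.get(p, getattr(params, p)) for p in free_params])

    def residuals(x):
        free = SimpleFree(dict(zip(free_params, x)))
        rhs, _ = builder(params, _SplineBag(by_name), t_obs_h, free)
        sol = solve_ivp(rhs, (t_obs_h[0], t_obs_h[-1]), [target.values[0]],
                        t_eval=t_obs_h, method="LSODA", rtol=1e-8, atol=1e-10)
        if not sol.success:
            return np.full_like(target.values, 1e6)
        return sol.y[0] - target.values

    res = least_squares(residuals, start, method="trf",
                        bounds=(np.zeros_like(start), np.inf), xtol=1e-12, ftol=1e-12)
    return SubsystemFit(
        estimates=dict(zip(free_params, (float(v) for v in res.x))),
        residual=float(np.sqrt(np.mean(res.fun**2))),
        converged=bool(res.success),
        message=res.message,
    )


class SimpleFree:
    """Attribute bag of the currently-trialled free parameter values."""

    def __init__(self, values: dict[str, float]):
        self.__dict__.update(values)


class _SplineBag:
    """Lazily splines observed series in hour units, keyed by analyte."""

    def __init__(self, by_name: dict[str, ObservedSeries]):
        self._by_name = by_name
        self._cache: dict[str, Callable] = {}

    def __getitem__(self, name: str) -> Callable:
        if name not in self._cache:
            if name not in self._by_name:
                raise KeyError(f"subsystem driver {name!r} not covered by observed series")
            obs = self._by_name[name]
            sp = CubicSpline(obs.days * HOURS_PER_DAY, obs.values)
            self._cache[name] = sp
        return self._cache[name]


def make_synthetic_series(
    result,
    variable: str,
    *,
    cadence_days: float = 14.0,
    noise_cv: float = 0.05,
    rng: np.random.Generator | None = None,
    analyte: str | None = None,
    units: str = "",
) -> ObservedSeries:
    """Sample a simulated trajectory at realistic cadence with lognormal noise.

    Used by the calibration and fitting tests so no external data set is
    ever required; ``noise_cv`` is the coefficient of variation of the
    multiplicative lognormal measurement error (0 for noise-free sampling).
    """
    rng = rng or np.random.default_rng(0)
    t = result.t_days
    pick = np.arange(0, len(t), max(1, int(round(cadence_days * 24 / np.median(np.diff(result.t_hours))))))
    days = t[pick]
    values = np.asarray(result.series(variable))[pick]
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        values = values * rng.lognormal(-0.5 * sigma**2, sigma, size=values.shape)
    return ObservedSeries(days=days, values=np.clip(values, 0.0, None),
                         analyte=analyte or variable, units=units)
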