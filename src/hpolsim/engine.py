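"""Whole-axis assembly and integration.

The full state vector concatenates the pituitary, ovary and liver states
(15 primary variables) with three transit-compartment chains: delayed E2
feeding mLH synthesis, delayed FSH feeding ovarian E2 production and
delayed LH feeding DHP production (plus a fourth, delayed E2 feeding
plasma VTG, when the reduced liver model is selected).  The system is
stiff — the LH release constant is ~1e5 larger than every other rate — so
integration uses an implicit/stiff method with event detection on the
ovulation criterion.

Because the stage distribution depends only on the mean diameter once the
boundaries and stage variances are fixed, ``simulate`` pre-tabulates the
self-consistent variance and the Weibull (scale, shape) on a fine diameter
grid and interpolates them with cubic splines inside the right-hand side;
the tabulation is accurate to ~1e-7 in the stage proportions and removes
all root-finding from the hot path.

Multi-cycle runs detect ovulation (first time the DHP and FOM-fraction
thresholds hold simultaneously) and, a configurable three weeks later,
reset the mean oocyte diameter to its cycle-start value; every other state
continues unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .core import DelaySpec, HillSpec, hill_stimulatory
from .gnrh import HOURS_PER_DAY, GnRHDriver, default_gnrh_driver
from .liver import LiverState, SimplifiedVtgParams, liver_derivatives, simplified_vtg_derivatives
from .ovary import (
    STAGE_NAMES,
    OvaryState,
    StageDistribution,
    ovary_derivatives,
    self_consistent_variance,
    sequestration_rate,
)
from .parameters import ModelParameters, default_parameters
from .pituitary import PituitaryState, pituitary_derivatives

__all__ = [
    "StateLayout",
    "SimulationOptions",
    "SimulationResult",
    "StagingTable",
    "default_initial_state",
    "assemble_rhs",
    "simulate",
    "find_extrema_lags",
    "lh_release_episodes",
]

PRIMARY_NAMES = (
    "mFSH", "mLH", "LH_Pit", "LH_P", "FSH_P",
    "O_Avg", "E2", "DHP",
    "mR", "R", "ER", "mVTG", "VTG_L", "VTG_N", "VTG_P",
)

# absolute-tolerance scale of each primary state (typical magnitude)
_ATOL_SCALE = {
    "mFSH": 1.0, "mLH": 10.0, "LH_Pit": 100.0, "LH_P": 1.0, "FSH_P": 1.0,
    "O_Avg": 1.0, "E2": 1.0, "DHP": 10.0,
    "mR": 10.0, "R": 1.0, "ER": 1.0, "mVTG": 1e4, "VTG_L": 10.0,
    "VTG_N": 1.0, "VTG_P": 1.0,
}


@dataclass(frozen=True)
class StateLayout:
    """Index bookkeeping for the concatenated state vector."""

    m: int = 5
    vtg_model: str = "full"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.vtg_model not in ("full", "simplified"):
            raise ValueError(f"vtg_model must be 'full' or 'simplified', got {self.vtg_model!r}")

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(PRIMARY_NAMES)}

    @property
    def n_primary(self) -> int:
        return len(PRIMARY_NAMES)

    @property
    def chains(self) -> tuple[str, ...]:
        base = ("e2_mlh", "fsh_e2", "lh_dhp")
        return base + (("e2_vtg",) if self.vtg_model == "simplified" else ())

    def chain_slice(self, name: str) -> slice:
        chains = self.chains
        if name not in chains:
            raise KeyError(name)
        start = self.n_primary + chains.index(name) * self.m
        return slice(start, start + self.m)

    @property
    def n_states(self) -> int:
        return self.n_primary + len(self.chains) * self.m

    def names(self) -> tuple[str, ...]:
        out = list(PRIMARY_NAMES)
        for c in self.chains:
            out.extend(f"{c}_tc{i+1}" for i in range(self.m))
        return tuple(out)

    def atol_vector(self, atol: float) -> np.ndarray:
        scale = [_ATOL_SCALE[n] for n in PRIMARY_NAMES]
        scale += [1.0] * (len(self.chains) * self.m)
        return atol * np.asarray(scale)


@dataclass(frozen=True)
class SimulationOptions:
    """Run configuration for :func:`simulate`.

    ``duration_days`` is the horizon; ``n_cycles`` (optional) stops the run
    after that many ovulations plus the post-spawn reset.  ``m`` is the
    number of compartments per delay chain.  ``release_function`` selects
    the spillover ("spillover") or stage-restricted ("stage_gated") LH
    release model; ``vtg_model`` the full hepatic cascade or the reduced
    delayed-E2 variant.  The mean diameter is reset ``reset_delay_days``
    after each ovulation.
    """

    duration_days: float = 365.0
    n_cycles: int | None = None
    rtol: float = 1e-6
    atol: float = 1e-8
    m: int = 5
    release_function: str = "spillover"
    vtg_model: str = "full"
    simplified_vtg: SimplifiedVtgParams = field(default_factory=SimplifiedVtgParams)
    reset_delay_days: float = 21.0
    solver: str = "LSODA"
    output_dt_hours: float = 1.0
    O_Avg_init: float = 0.15

    def __post_init__(self) -> None:
        if self.duration_days <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("durations and tolerances must be positive")
        if self.output_dt_hours <= 0 or self.reset_delay_days < 0:
            raise ValueError("invalid output grid or reset delay")

    def layout(self) -> StateLayout:
        return StateLayout(m=self.m, vtg_model=self.vtg_model)


class StagingTable:
    """Splined self-consistent staging as a function of the mean diameter.

    At construction the variance fixed point and the moment-matched Weibull
    (scale, shape) are computed on a fine O_Avg grid; evaluation interpolates
    scale and shape and forms the seven stage masses from the Weibull CDF at
    the boundaries, so the proportions are exact probabilities that sum to 1.
    """

    O_MIN = 0.02
    O_MAX = 10.0
    N_GRID = 1400

    def __init__(self, params: ModelParameters):
        self.boundaries = np.asarray(params.stage_boundaries())
        grid = np.linspace(self.O_MIN, self.O_MAX, self.N_GRID)
        v = np.empty_like(grid)
        l = np.empty_like(grid)
        k = np.empty_like(grid)
        v_prev = 0.02
        for i, o in enumerate(grid):
            v_prev, dist = self_consistent_variance(o, params, v_init=v_prev)
            v[i] = v_prev
            l[i] = dist.weibull.scale
            k[i] = dist.weibull.shape
        self.grid = grid
        self._v = CubicSpline(grid, v)
        self._logl = CubicSpline(grid, np.log(l))
        self._logk = CubicSpline(grid, np.log(k))

    def variance(self, O_Avg):
        o = np.clip(O_Avg, self.O_MIN, self.O_MAX)
        return self._v(o)

    def weibull_lk(self, O_Avg):
        o = np.clip(O_Avg, self.O_MIN, self.O_MAX)
        return np.exp(self._logl(o)), np.exp(self._logk(o))

    def stages(self, O_Avg):
        """Stage proportions; vectorised — returns shape (..., 7)."""
        o = np.asarray(O_Avg, dtype=float)
        l, k = self.weibull_lk(o)
        ratio = self.boundaries / np.expand_dims(np.asarray(l), -1)
        cdf = -np.expm1(-(ratio ** np.expand_dims(np.asarray(k), -1)))
        out = np.empty(o.shape + (7,))
        out[..., 0] = cdf[..., 0]
        out[..., 1:6] = np.diff(cdf, axis=-1)
        out[..., 6] = 1.0 - cdf[..., 5]
        return out

    def s_fom(self, O_Avg):
        l, k = self.weibull_lk(O_Avg)
        return np.exp(-((self.boundaries[-1] / l) ** k))


_STAGING_CACHE: dict[tuple, StagingTable] = {}


def _staging_table(params: ModelParameters) -> StagingTable:
    key = params.stage_boundaries() + params.stage_variances()
    if key not in _STAGING_CACHE:
        if len(_STAGING_CACHE) > 32:
            _STAGING_CACHE.clear()
        _STAGING_CACHE[key] = StagingTable(params)
    return _STAGING_CACHE[key]


@dataclass
class SimulationResult:
    """Hourly trajectories, derived observables and detected events.

    ``states`` has one row per grid time and one column per state in
    ``layout.names()``.  ``derived`` holds the stage proportions, O_Var,
    Seq and the LH release function on the same grid.  ``events`` is a list
    of (type, time_days) with type in {"ovulation", "reset",
    "lh_release_onset"}; ``no_ovulation`` flags a run whose horizon ended
    before the first ovulation.
    """

    t_hours: np.ndarray
    states: np.ndarray
    layout: StateLayout
    derived: dict[str, np.ndarray]
    events: list[tuple[str, float]]
    params: ModelParameters
    options: SimulationOptions
    no_ovulation: bool

    @property
    def t_days(self) -> np.ndarray:
        return self.t_hours / HOURS_PER_DAY

    def series(self, name: str) -> np.ndarray:
        if name in self.derived:
            return self.derived[name]
        names = self.layout.names()
        if name in names:
            return self.states[:, names.index(name)]
        raise KeyError(name)

    def ovulation_times_days(self) -> list[float]:
        return [t for kind, t in self.events if kind == "ovulation"]

    def to_frame(self):
        import pandas as pd

        data = {"time_days": self.t_days}
        for i, name in enumerate(self.layout.names()):
            data[name] = self.states[:, i]
        for name, series in self.derived.items():
            data[name] = series
        return pd.DataFrame(data)

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.events, columns=["event", "time_days"])


def default_initial_state(
    params: ModelParameters,
    gnrh: GnRHDriver | None = None,
    options: SimulationOptions | None = None,
) -> np.ndarray:
    """Cycle-start state: small pre-vitellogenic oocytes, basal hormone levels.

    The mean diameter starts at ``options.O_Avg_init`` (0.15 mm, almost all
    oocytes in stages 1-2).  mFSH/FSH and the mLH/LH_Pit cascade start at
    their closed-form steady states under GnRH(0) and basal E2; the hepatic
    receptor cascade starts at its E2-free steady state (ER = 0); DHP and
    plasma LH start at zero (no basal source); every transit chain is
    initialised to its driver's initial value.
    """
    gnrh = gnrh or default_gnrh_driver()
    options = options or SimulationOptions()
    layout = options.layout()
    g0 = float(gnrh(0.0))

    mFSH0 = params.ks_mFSH * (1.0 + params.alpha_mFSH_GnRH * g0) / params.kd_mFSH
    FSH0 = params.w_Pit * params.ks_FSH * mFSH0 / params.Cl_FSH
    E20 = params.n_oocyte * params.k_E2 / params.Cl_E2  # basal ovarian output
    mLH0 = (
        params.ks_mLH
        * (1.0 + params.alpha_mLH_GnRH * g0 + params.alpha_mLH_E2 * E20)
        / params.kd_mLH
    )
    LH_Pit0 = params.ks_LH * mLH0 / params.kd_LH
    mR0 = params.ks_mR / params.kd_mR
    R0 = params.ks_R * mR0 / params.kd_R

    y = np.zeros(layout.n_states)
    ix = layout.index
    y[ix["mFSH"]] = mFSH0
    y[ix["mLH"]] = mLH0
    y[ix["LH_Pit"]] = LH_Pit0
    y[ix["FSH_P"]] = FSH0
    y[ix["O_Avg"]] = options.O_Avg_init
    y[ix["E2"]] = E20
    y[ix["mR"]] = mR0
    y[ix["R"]] = R0
    y[ix["mVTG"]] = params.ks_mVTG / params.kd_mVTG
    # LH_P, DHP, ER, VTG_L, VTG_N, VTG_P: no basal source -> 0
    y[layout.chain_slice("e2_mlh")] = E20
    y[layout.chain_slice("fsh_e2")] = FSH0
    y[layout.chain_slice("lh_dhp")] = 0.0
    if layout.vtg_model == "simplified":
        y[layout.chain_slice("e2_vtg")] = E20
    return y


GateFn = Callable[[np.ndarray], float]


def assemble_rhs(
    params: ModelParameters,
    gnrh: GnRHDriver,
    options: SimulationOptions,
    gated_multipliers: Sequence[tuple[str, float, GateFn]] = (),
):
    """Build the full right-hand-side function f(t_hours, y) -> dy/dt.

    Computes the stage distribution and algebraic observables once per call
    and delegates to the pituitary, ovary and liver derivative functions.
    ``gated_multipliers`` are (parameter, factor, gate) triples whose factor
    is applied as ``factor ** gate(S)`` with the gate a smooth functional of
    the stage-proportion vector — used by stressor scenarios whose action is
    restricted to particular developmental windows.
    """
    layout = options.layout()
    table = _staging_table(params)
    ix = layout.index
    sl_e2mlh = layout.chain_slice("e2_mlh")
    sl_fshe2 = layout.chain_slice("fsh_e2")
    sl_lhdhp = layout.chain_slice("lh_dhp")
    sl_e2vtg = layout.chain_slice("e2_vtg") if layout.vtg_model == "simplified" else None

    # mutable working copy of the parameters for stage-gated scaling
    P = SimpleNamespace(**params.to_dict())
    base_values = {name: getattr(P, name) for name, _, _ in gated_multipliers}

    e2_spec = DelaySpec(params.D_E2_mLH, layout.m)
    fsh_spec = DelaySpec(params.D_FSH_E2, layout.m)
    lh_spec = DelaySpec(params.D_LH_DHP, layout.m)
    vtg_spec = options.simplified_vtg.delay if sl_e2vtg is not None else None

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        mFSH = max(y[ix["mFSH"]], 0.0)
        mLH = max(y[ix["mLH"]], 0.0)
        LH_Pit = max(y[ix["LH_Pit"]], 0.0)
        LH_P = max(y[ix["LH_P"]], 0.0)
        FSH_P = max(y[ix["FSH_P"]], 0.0)
        O_Avg = max(y[ix["O_Avg"]], StagingTable.O_MIN)
        E2 = max(y[ix["E2"]], 0.0)
        DHP = max(y[ix["DHP"]], 0.0)

        S = table.stages(O_Avg)
        for name, factor, gate in gated_multipliers:
            setattr(P, name, base_values[name] * factor ** float(gate(S)))

        dist = StageDistribution.__new__(StageDistribution)
        object.__setattr__(dist, "proportions", tuple(S))
        object.__setattr__(dist, "weibull", None)
        object.__setattr__(dist, "boundaries", None)

        pit = PituitaryState.__new__(PituitaryState)
        pit.mFSH, pit.mLH, pit.LH_Pit, pit.FSH_P, pit.LH_P = mFSH, mLH, LH_Pit, FSH_P, LH_P
        pit.e2_chain = y[sl_e2mlh]
        d_pit, r_lh = pituitary_derivatives(
            pit, float(gnrh(t)), DHP, E2, P,
            release_function=options.release_function, S_6=S[5], S_FOM=S[6],
        )

        ova = OvaryState.__new__(OvaryState)
        ova.O_Avg, ova.E2, ova.DHP = O_Avg, E2, DHP
        ova.fsh_chain = y[sl_fshe2]
        ova.lh_chain = y[sl_lhdhp]
        VTG_P = max(y[ix["VTG_P"]], 0.0)
        d_ova = ovary_derivatives(ova, FSH_P, LH_P, VTG_P, dist, P)

        dy = np.empty_like(y)
        dy[ix["mFSH"]] = d_pit.mFSH
        dy[ix["mLH"]] = d_pit.mLH
        dy[ix["LH_Pit"]] = d_pit.LH_Pit
        dy[ix["FSH_P"]] = d_pit.FSH_P
        dy[ix["LH_P"]] = d_pit.LH_P
        dy[sl_e2mlh] = d_pit.e2_chain
        dy[ix["O_Avg"]] = d_ova.O_Avg
        dy[ix["E2"]] = d_ova.E2
        dy[ix["DHP"]] = d_ova.DHP
        dy[sl_fshe2] = d_ova.fsh_chain
        dy[sl_lhdhp] = d_ova.lh_chain

        seq = sequestration_rate(FSH_P, dist, P)
        if sl_e2vtg is None:
            liv = LiverState.__new__(LiverState)
            liv.mR = max(y[ix["mR"]], 0.0)
            liv.R = max(y[ix["R"]], 0.0)
            liv.ER = max(y[ix["ER"]], 0.0)
            liv.mVTG = max(y[ix["mVTG"]], 0.0)
            liv.VTG_L = max(y[ix["VTG_L"]], 0.0)
            liv.VTG_N = max(y[ix["VTG_N"]], 0.0)
            liv.VTG_P = VTG_P
            d_liv = liver_derivatives(liv, E2, seq, P)
            dy[ix["mR"]] = d_liv.mR
            dy[ix["R"]] = d_liv.R
            dy[ix["ER"]] = d_liv.ER
            dy[ix["mVTG"]] = d_liv.mVTG
            dy[ix["VTG_L"]] = d_liv.VTG_L
            dy[ix["VTG_N"]] = d_liv.VTG_N
            dy[ix["VTG_P"]] = d_liv.VTG_P
        else:
            e2_vtg_delayed = max(y[sl_e2vtg][-1], 0.0)
            d_vtg_p, d_vtg_n = simplified_vtg_derivatives(
                VTG_P, max(y[ix["VTG_N"]], 0.0), e2_vtg_delayed, seq, P,
                options.simplified_vtg,
            )
            dy[ix["mR"]] = dy[ix["R"]] = dy[ix["ER"]] = 0.0
            dy[ix["mVTG"]] = dy[ix["VTG_L"]] = 0.0
            dy[ix["VTG_N"]] = d_vtg_n
            dy[ix["VTG_P"]] = d_vtg_p
            from .core import transit_chain_derivatives

            dy[sl_e2vtg] = transit_chain_derivatives(y[sl_e2vtg], E2, vtg_spec)

        if not np.all(np.isfinite(dy)):
            raise ArithmeticError(
                f"non-finite derivative at t={t / HOURS_PER_DAY:.3f} d; state snapshot: "
                f"{dict(zip(layout.names(), y))}"
            )
        return dy

    return rhs


def simulate(
    params: ModelParameters | None = None,
    gnrh: GnRHDriver | None = None,
    options: SimulationOptions | None = None,
    *,
    y0: np.ndarray | None = None,
    gated_multipliers: Sequence[tuple[str, float, GateFn]] = (),
) -> SimulationResult:
    """Integrate the axis over the requested horizon with ovulation detection.

    Ovulation is located by root-finding on
    ``min(DHP - DHP_final, S_FOM - FOM_final)`` crossing zero from below;
    ``reset_delay_days`` later the mean diameter is reset to its cycle-start
    value and integration continues, so multi-cycle runs produce repeated
    annual cycles.  Output is recorded on a fixed grid
    (``options.output_dt_hours``, hourly by default) regardless of the
    internal steps.  The run is deterministic given its inputs.
    """
    params = params or default_parameters()
    gnrh = gnrh or default_gnrh_driver()
    options = options or SimulationOptions()
    layout = options.layout()
    table = _staging_table(params)
    rhs = assemble_rhs(params, gnrh, options, gated_multipliers)
    if y0 is None:
        y0 = default_initial_state(params, gnrh, options)
    y0 = np.asarray(y0, dtype=float)
    if y0.shape != (layout.n_states,):
        raise ValueError(f"y0 has shape {y0.shape}, expected ({layout.n_states},)")

    ix = layout.index
    i_O = ix["O_Avg"]
    t_end = options.duration_days * HOURS_PER_DAY
    grid = np.arange(0.0, t_end + 0.5 * options.output_dt_hours, options.output_dt_hours)
    grid[-1] = min(grid[-1], t_end)
    atol_vec = layout.atol_vector(options.atol)

    def ovulation_event(t, y):
        s_fom = float(table.s_fom(max(y[i_O], StagingTable.O_MIN)))
        return min(y[ix["DHP"]] - params.DHP_final, s_fom - params.FOM_final)

    ovulation_event.terminal = True
    ovulation_event.direction = 1

    times: list[np.ndarray] = [grid[:1]]
    ys: list[np.ndarray] = [y0[None, :]]
    events: list[tuple[str, float]] = []
    t0 = 0.0
    y = y0.copy()
    pending_reset: float | None = None
    n_ovulations = 0

    while t0 < t_end - 1e-9:
        t_stop = t_end if pending_reset is None else min(pending_reset, t_end)
        seg_events = [ovulation_event] if pending_reset is None else []
        sol = solve_ivp(
            rhs, (t0, t_stop), y,
            method=options.solver, rtol=options.rtol, atol=atol_vec,
            dense_output=True, events=seg_events,
        )
        if sol.status < 0:
            raise ArithmeticError(
                f"solver failed at t={sol.t[-1] / HOURS_PER_DAY:.2f} d: {sol.message}; "
                f"last accepted state {dict(zip(layout.names(), sol.y[:, -1]))}"
            )
        seg_end = sol.t[-1]
        pts = grid[(grid > t0 + 1e-9) & (grid <= seg_end + 1e-9)]
        if pts.size:
            times.append(pts)
            ys.append(sol.sol(pts).T)

        if sol.status == 1 and seg_events:  # ovulation
            t_ov = float(sol.t_events[0][0])
            events.append(("ovulation", t_ov / HOURS_PER_DAY))
            n_ovulations += 1
            y = sol.y_events[0][0].copy()
            t0 = t_ov
            pending_reset = t_ov + options.reset_delay_days * HOURS_PER_DAY
            if options.n_cycles is not None and n_ovulations >= options.n_cycles:
                # run through the post-spawn reset, then stop early
                t_end = min(t_end, pending_reset)
        else:
            y = sol.sol(seg_end).copy()
            t0 = seg_end
            if pending_reset is not None and abs(seg_end - pending_reset) < 1e-6:
                y[i_O] = options.O_Avg_init
                events.append(("reset", seg_end / HOURS_PER_DAY))
                pending_reset = None

    t_arr = np.concatenate(times)
    y_arr = np.vstack(ys)

    # de-duplicate any repeated grid points from segment stitching
    keep = np.concatenate(([True], np.diff(t_arr) > 1e-9))
    t_arr, y_arr = t_arr[keep], y_arr[keep]

    derived = _derived_series(t_arr, y_arr, layout, table, params, gnrh, options)
    result = SimulationResult(
        t_hours=t_arr, states=y_arr, layout=layout, derived=derived,
        events=events, params=params, options=options,
        no_ovulation=(n_ovulations == 0),
    )
    for onset, _end, _peak in lh_release_episodes(result):
        events.append(("lh_release_onset", onset))
    events.sort(key=lambda e: e[1])
    return result


def _derived_series(t, y, layout, table, params, gnrh, options) -> dict[str, np.ndarray]:
    ix = layout.index
    O = np.clip(y[:, ix["O_Avg"]], StagingTable.O_MIN, None)
    S = table.stages(O)
    derived = {name: S[:, j] for j, name in enumerate(STAGE_NAMES)}
    derived["O_Var"] = np.asarray(table.variance(O))
    fsh = np.clip(y[:, ix["FSH_P"]], 0.0, None)
    boost = 1.0 + fsh / (fsh + params.T_Seq_FSH)
    derived["Seq"] = params.Cl_VTG_Seq * boost * S[:, 2:6].sum(axis=1)
    e2 = np.clip(y[:, ix["E2"]], 0.0, None)
    dhp = np.clip(y[:, ix["DHP"]], 0.0, None)
    lh_pit = np.clip(y[:, ix["LH_Pit"]], 0.0, None)
    if options.release_function == "spillover":
        theta = lh_pit - params.N_E2 * e2 - params.N_DHP * dhp
        gate = hill_stimulatory(e2, HillSpec(params.T_E2_LH, params.n_E2_LH))
        derived["R_LH"] = np.maximum(theta, 0.0) * gate
    else:
        from .core import hill_inhibitory

        gate = hill_inhibitory(e2, HillSpec(params.T_E2_LH, params.n_E2_LH))
        derived["R_LH"] = (S[:, 5] + S[:, 6]) * gate * lh_pit
    derived["GnRH"] = np.asarray(gnrh(t))
    return derived


def find_extrema_lags(
    t_days: np.ndarray,
    series_a: np.ndarray,
    series_b: np.ndarray,
    smoothing_window_days: float = 5.0,
) -> list[tuple[float, float, float]]:
    """Pair relative maxima of two series and report the lags in days.

    Both series are smoothed with a centred moving average of the given
    width, relative maxima located, and each maximum of ``a`` paired with
    the nearest *subsequent* maximum of ``b``.  Returns a list of
    (time_a, time_b, lag_days); empty if either series has no maxima.
    """
    t_days = np.asarray(t_days, dtype=float)
    if t_days.shape != np.shape(series_a) or t_days.shape != np.shape(series_b):
        raise ValueError("series must share the time grid")
    dt = np.median(np.diff(t_days))
    win = max(1, int(round(smoothing_window_days / dt)))
    kernel = np.ones(win) / win

    def smooth(x):
        pad = win // 2
        xp = np.pad(np.asarray(x, float), pad, mode="edge")
        return np.convolve(xp, kernel, mode="same")[pad:pad + len(x)] if pad else np.asarray(x, float)

    a_s, b_s = smooth(series_a), smooth(series_b)
    # find_peaks handles the flat-topped maxima a moving average produces
    distance = max(1, win)
    ia = find_peaks(a_s, distance=distance)[0]
    ib = find_peaks(b_s, distance=distance)[0]
    out = []
    for i in ia:
        later = ib[ib >= i]
        if later.size == 0:
            continue
        j = later[0]
        out.append((float(t_days[i]), float(t_days[j]), float(t_days[j] - t_days[i])))
    return out


def lh_release_episodes(
    result: SimulationResult, min_rate: float = 0.01, merge_gap_days: float = 5.0
) -> list[tuple[float, float, float]]:
    """Contiguous LH release episodes on the output grid.

    An episode is a run of grid points where the plasma-LH production rate
    ``w_Pit * k_r,LH * R_LH / V_LH`` exceeds ``min_rate`` (ng/ml/hr); runs
    separated by less than ``merge_gap_days`` are merged.  Returns
    (onset_day, end_day, peak_LH_P) per episode, in time order.
    """
    p = result.params
    rate = p.w_Pit * p.kr_LH * result.derived["R_LH"] / p.V_LH
    active = rate > min_rate
    t = result.t_days
    lh = result.series("LH_P")
    episodes = []
    i = 0
    n = len(t)
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            episodes.append([t[i], t[j]])
            i = j + 1
        else:
            i += 1
    merged: list[list[float]] = []
    for ep in episodes:
        if merged and ep[0] - merged[-1][1] < merge_gap_days:
            merged[-1][1] = ep[1]
        else:
            merged.append(ep)
    out = []
    for on, off in merged:
        mask = (t >= on) & (t <= off)
        out.append((float(on), float(off), float(lh[mask].max())))
    return out
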