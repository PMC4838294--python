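"""Density-based global sensitivity analysis (PAWN) over Sobol' samples.

Each parameter is varied within a ±20% box around its published value
using a scrambled Sobol' low-discrepancy sequence.  The model output is
collapsed to the scalar trajectory-deviation statistic: the sum over a
fixed variable list of the relative Euclidean-norm change of that
variable's hourly trajectory.  The PAWN index of a parameter is the
median (optionally maximum) Kolmogorov–Smirnov distance between the
unconditional output distribution and the conditional distributions
obtained by pinning that parameter at a set of conditioning values —
larger index, more influential parameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .parameters import ModelParameters, apply_perturbation, parameter_names

__all__ = [
    "SensitivityConfig",
    "SensitivityResult",
    "DEFAULT_OUTPUT_VARIABLES",
    "trajectory_deviation",
    "sobol_parameter_sample",
    "pawn_indices",
    "hpol_output_runner",
]

log = logging.getLogger(__name__)

# the 15 primary trajectories entering the scalar deviation statistic
DEFAULT_OUTPUT_VARIABLES = (
    "mFSH", "mLH", "FSH_P", "LH_Pit", "LH_P", "O_Avg", "E2", "DHP",
    "mR", "R", "ER", "mVTG", "VTG_L", "VTG_P", "VTG_N",
)


@dataclass(frozen=True)
class SensitivityConfig:
    """Sampling plan for the PAWN analysis.

    ``n_unconditional`` draws form the reference output distribution; for
    each parameter, ``n_conditioning`` pinned values are screened with
    ``n_conditional`` draws each.  ``fraction`` is the half-width of the
    relative perturbation box.  ``statistic`` is "median" (robust default)
    or "max" over conditioning values.
    """

    fraction: float = 0.2
    n_unconditional: int = 200
    n_conditioning: int = 5
    n_conditional: int = 40
    seed: int = 0
    horizon_days: float = 350.0
    variables: tuple[str, ...] = DEFAULT_OUTPUT_VARIABLES
    statistic: str = "median"
    max_failure_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if min(self.n_unconditional, self.n_conditioning, self.n_conditional) < 2:
            raise ValueError("all sample counts must be >= 2")
        if self.statistic not in ("median", "max"):
            raise ValueError("statistic must be 'median' or 'max'")


@dataclass
class SensitivityResult:
    """Per-parameter PAWN indices with the published ranking convention.

    ``ranks`` assigns 1 to the least sensitive parameter and ``n`` to the
    most sensitive (larger number = greater influence).
    """

    names: tuple[str, ...]
    indices: np.ndarray
    ranks: np.ndarray
    n_effective: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.indices)))

    def top(self, k: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(self.indices)[::-1][:k]
        return [(self.names[i], float(self.indices[i])) for i in order]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"parameter": self.names, "index": self.indices, "rank": self.ranks}
        ).sort_values("rank", ascending=False, ignore_index=True)


def trajectory_deviation(base, alt, variables: Sequence[str] = DEFAULT_OUTPUT_VARIABLES) -> float:
    """Scalar deviation of one run from a reference run.

    Sum over the listed variables of ``||f_alt - f_base||_2 / ||f_base||_2``
    on the shared hourly grid; variables whose reference norm is zero are
    skipped with a warning.  Zero iff the trajectories coincide.
    """
    if base.t_hours.shape != alt.t_hours.shape or not np.allclose(base.t_hours, alt.t_hours):
        raise ValueError("trajectory grids differ; deviations need a common grid")
    total = 0.0
    for name in variables:
        f0 = np.asarray(base.series(name), dtype=float)
        f1 = np.asarray(alt.series(name), dtype=float)
        n0 = float(np.linalg.norm(f0))
        if n0 == 0.0:
            warnings.warn(f"variable {name!r} has zero reference norm; skipped", stacklevel=2)
            continue
        total += float(np.linalg.norm(f1 - f0)) / n0
    return total


def sobol_parameter_sample(
    params: ModelParameters,
    fraction: float,
    n_samples: int,
    seed: int = 0,
    *,
    names: Sequence[str] | None = None,
    max_rejections: int = 10000,
) -> list[ModelParameters]:
    """Low-discrepancy samples of the parameter box value*(1 ± fraction).

    Draws a scrambled Sobol' sequence over the selected parameters
    (default: all) and maps each point to a multiplicatively perturbed
    parameter set.  Draws violating the structural invariants (e.g. stage
    boundaries out of order) are rejected and replaced; the rejection
    count is logged.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    names = tuple(names or parameter_names())
    sampler = qmc.Sobol(d=len(names), scramble=True, seed=seed)
    out: list[ModelParameters] = []
    rejected = 0
    while len(out) < n_samples:
        u = sampler.random(n_samples - len(out))
        factors = 1.0 - fraction + 2.0 * fraction * u
        for row in factors:
            try:
                out.append(apply_perturbation(params, dict(zip(names, row))))
            except (ValueError, KeyError):
                rejected += 1
                if rejected > max_rejections:
                    raise ArithmeticError(
                        f"too many invariant-violating draws ({rejected}); box too wide?"
                    )
    if rejected:
        log.info("sobol_parameter_sample: rejected %d invariant-violating draws", rejected)
    return out[:n_samples]


def _ks_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov statistic (sup distance of empirical CDFs)."""
    a = np.sort(a)
    b = np.sort(b)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def pawn_indices(
    runner: Callable[[Mapping[str, float]], float],
    bounds: Mapping[str, tuple[float, float]],
    config: SensitivityConfig,
) -> SensitivityResult:
    """PAWN sensitivity indices of a scalar-output model.

    ``runner`` maps {parameter name: value} to the scalar output; ``bounds``
    gives each parameter's (low, high) range.  For each parameter the KS
    distance between the unconditional output CDF and the conditional CDFs
    (parameter pinned at evenly-spaced conditioning quantiles, the rest
    Sobol'-sampled) is aggregated with the configured statistic.  Failed
    runs are dropped; more than ``max_failure_fraction`` failures aborts.
    """
    names = tuple(bounds)
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    d = len(names)

    def run_matrix(points: np.ndarray) -> np.ndarray:
        values, failures = [], 0
        for row in points:
            try:
                values.append(float(runner(dict(zip(names, row)))))
            except Exception:  # noqa: BLE001 - model failures are data here
                failures += 1
        if failures > config.max_failure_fraction * len(points):
            raise ArithmeticError(f"{failures}/{len(points)} model runs failed")
        return np.asarray(values)

    sampler = qmc.Sobol(d=d, scramble=True, seed=config.seed)
    u_uncond = sampler.random(config.n_unconditional)
    y_uncond = run_matrix(lo + (hi - lo) * u_uncond)

    indices = np.empty(d)
    for i in range(d):
        cond_q = (np.arange(config.n_conditioning) + 0.5) / config.n_conditioning
        ks = []
        for j, q in enumerate(cond_q):
            sub = qmc.Sobol(d=max(d - 1, 1), scramble=True,
                            seed=config.seed + 1000 * (i + 1) + j)
            u = sub.random(config.n_conditional)
            pts = np.empty((config.n_conditional, d))
            other = [c for c in range(d) if c != i]
            if other:
                pts[:, other] = lo[other] + (hi[other] - lo[other]) * u[:, : len(other)]
            pts[:, i] = lo[i] + (hi[i] - lo[i]) * q
            ks.append(_ks_distance(y_uncond, run_matrix(pts)))
        indices[i] = np.median(ks) if config.statistic == "median" else np.max(ks)

    ranks = np.empty(d, dtype=int)
    ranks[np.argsort(indices, kind="stable")] = np.arange(1, d + 1)
    return SensitivityResult(
        names=names, indices=indices, ranks=ranks,
        n_effective=config.n_unconditional, seed=config.seed,
    )


def hpol_output_runner(
    base_params: ModelParameters,
    gnrh,
    config: SensitivityConfig,
    *,
    options=None,
):
    """Build (runner, bounds) for a PAWN analysis of the axis model itself.

    The runner integrates the model under the perturbed parameters and
    returns the trajectory-deviation scalar against the base run over the
    configured horizon.  Intended for scaled-down desk analyses over a
    parameter subset; a full 79-parameter screen at publication sample
    sizes is a batch-scale computation.
    """
    from .engine import SimulationOptions, simulate

    options = options or SimulationOptions(duration_days=config.horizon_days)
    base_run = simulate(base_params, gnrh, options)

    def runner(values: Mapping[str, float]) -> float:
        p = base_params.to_dict()
        p.update(values)
        alt = simulate(ModelParameters(**p), gnrh, options)
        return trajectory_deviation(base_run, alt, config.variables)

    bounds = {
        n: (getattr(base_params, n) * (1 - config.fraction),
            getattr(base_params, n) * (1 + config.fraction))
        for n in parameter_names()
    }
    return runner, bounds
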