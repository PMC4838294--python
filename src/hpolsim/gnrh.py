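"""Hypothalamic forcing: the GnRH(t) driver.

GnRH is the model's only exogenous input, a non-negative unitless annual
signal secreted by the hypothalamus into the pituitary.  Two driver modes
are supported:

* **parametric** — a baseline plus smooth Gaussian pulse components with a
  fixed period (days).  The packaged default was calibrated once against
  the published seasonal pattern of pituitary FSH-beta expression and the
  downstream timing of the reproductive cycle; its coefficients are frozen
  in :data:`DEFAULT_PULSES`.
* **tabulated** — (day, value) pairs from a delimited text file, with
  linear or cubic-spline interpolation and optional periodic extension.
  This is the form produced by :func:`hpolsim.calibration.calibrate_gnrh_from_fsh`.

All drivers are callable in *hours* internally (``driver(t_hours)``); the
user-facing tables and pulse centers are in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

HOURS_PER_DAY = 24.0

__all__ = [
    "GnRHDriver",
    "ParametricGnRH",
    "TabulatedGnRH",
    "default_gnrh_driver",
    "DEFAULT_BASELINE",
    "DEFAULT_PULSES",
    "DEFAULT_PERIOD_DAYS",
]


class GnRHDriver:
    """Base class: a callable GnRH(t) with t in hours, returning >= 0."""

    period_days: float | None = None

    def __call__(self, t_hours):  # pragma: no cover - interface
        raise NotImplementedError

    def value_at_day(self, day):
        return self(np.asarray(day) * HOURS_PER_DAY)


# Calibrated default annual programme.  The three pulses shape the seasonal
# FSH wave: a broad early/mid-cycle component sustaining vitellogenesis, a
# component producing the first late-cycle FSH maximum, and a pre-spawning
# component whose decline, together with entry of the clutch into final
# maturation, collapses E2 and opens the LH release gate.  The period is
# the cycle length (~357 d) plus the three-week post-spawn recovery, which
# phase-locks successive cycles in multi-year runs.
DEFAULT_BASELINE = 6.0
DEFAULT_PULSES: tuple[tuple[float, float, float], ...] = (
    # (center day, width days, amplitude)
    (112.0, 45.0, 142.0),
    (188.0, 24.0, 136.0),
    (295.0, 28.0, 102.0),
)
DEFAULT_PERIOD_DAYS = 380.0


@dataclass(frozen=True)
class ParametricGnRH(GnRHDriver):
    """Baseline + Gaussian pulse components, periodically extended.

    ``pulses`` is a sequence of (center_day, width_days, amplitude); each
    contributes ``A * exp(-(d - c)^2 / (2 w^2))`` with ``d`` the day within
    the period.  Tails wrapping across the period boundary are included so
    the signal is smooth and periodic.
    """

    baseline: float = DEFAULT_BASELINE
    pulses: tuple[tuple[float, float, float], ...] = DEFAULT_PULSES
    period_days: float = DEFAULT_PERIOD_DAYS

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ValueError("baseline must be non-negative")
        for c, w, a in self.pulses:
            if w <= 0 or a < 0:
                raise ValueError(f"pulse (center={c}, width={w}, amplitude={a}) invalid")

    def __call__(self, t_hours):
        d = np.asarray(t_hours, dtype=float) / HOURS_PER_DAY
        d = np.mod(d, self.period_days)
        out = np.full_like(d, float(self.baseline))
        for c, w, a in self.pulses:
            # include the two neighbouring periodic images of each pulse
            for shift in (-self.period_days, 0.0, self.period_days):
                out = out + a * np.exp(-((d - (c + shift)) ** 2) / (2.0 * w * w))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TabulatedGnRH(GnRHDriver):
    """Driver interpolated from (day, value) samples.

    ``interpolation`` is "linear" or "cubic"; with ``periodic=True`` the
    sample window is tiled so multi-cycle runs see a periodic signal.
    Negative interpolant excursions are clipped to zero.
    """

    days: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"
    periodic: bool = True
    period_days: float | None = None
    _interp: object = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if days.ndim != 1 or days.shape != values.shape or days.size < 2:
            raise ValueError("need matching 1-d day/value arrays with >= 2 samples")
        if np.any(np.diff(days) <= 0):
            raise ValueError("sample days must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("GnRH values must be non-negative")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if self.periodic and self.period_days is None:
            object.__setattr__(self, "period_days", float(days[-1] - days[0]))
        if self.interpolation == "cubic":
            interp = CubicSpline(
                days, values, bc_type="periodic" if self._closed() else "natural"
            )
        elif self.interpolation == "linear":
            interp = interp1d(
                days, values, kind="linear", bounds_error=False,
                fill_value=(values[0], values[-1]),
            )
        else:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "_interp", interp)

    def _closed(self) -> bool:
        return self.periodic and np.isclose(self.values[0], self.values[-1])

    def __call__(self, t_hours):
        d = np.asarray(t_hours, dtype=float) / HOURS_PER_DAY
        if self.periodic:
            d = self.days[0] + np.mod(d - self.days[0], self.period_days)
        out = np.clip(self._interp(d), 0.0, None)
        return float(out) if out.ndim == 0 else out

    @classmethod
    def from_file(
        cls, path: str | Path, *, interpolation: str = "linear", periodic: bool = True
    ) -> "TabulatedGnRH":
        """Read two-column delimited text (day, value); '#' comments allowed."""
        arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (day, value)")
        return cls(days=arr[:, 0], values=arr[:, 1],
                   interpolation=interpolation, periodic=periodic)

    def to_file(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.days, self.values]),
                   header="day value", comments="# ")


def default_gnrh_driver() -> ParametricGnRH:
    """The packaged annual GnRH programme used by the baseline simulation."""
    return ParametricGnRH()
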