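"""Serialisation of simulation results to delimited text.

A result is written as two CSV files: the trajectory (one row per output
grid point, time in days, full float precision) and an events sidecar
``<stem>.events.csv``.  The round trip is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimulationOptions, SimulationResult, StateLayout
from .gnrh import HOURS_PER_DAY
from .ovary import STAGE_NAMES
from .parameters import ModelParameters

__all__ = ["write_result", "read_result", "events_path"]

_DERIVED = tuple(STAGE_NAMES) + ("O_Var", "Seq", "R_LH", "GnRH")


def events_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(".events.csv")


def write_result(result: SimulationResult, path: str | Path) -> None:
    """Write trajectory CSV plus events sidecar (and a small JSON header)."""
    path = Path(path)
    frame = result.to_frame()
    meta = {
        "m": result.layout.m,
        "vtg_model": result.layout.vtg_model,
        "no_ovulation": result.no_ovulation,
        "options": {
            k: v for k, v in vars(result.options).items()
            if isinstance(v, (int, float, str, bool))
        },
        "params": result.params.to_dict(),
    }
    with path.open("w") as fh:
        fh.write("# hpolsim-result " + json.dumps(meta) + "\n")
        frame.to_csv(fh, index=False, float_format="%.17g")
    result.events_frame().to_csv(events_path(path), index=False, float_format="%.17g")


def read_result(path: str | Path) -> SimulationResult:
    """Reconstruct a :class:`SimulationResult` written by :func:`write_result`."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("# hpolsim-result "):
            raise ValueError(f"{path}: not an hpolsim result file")
        meta = json.loads(header[len("# hpolsim-result "):])
        frame = pd.read_csv(fh, float_precision="round_trip")
    layout = StateLayout(m=int(meta["m"]), vtg_model=meta["vtg_model"])
    opt_kwargs = meta.get("options", {})
    options = SimulationOptions(**opt_kwargs) if opt_kwargs else SimulationOptions()
    params = ModelParameters(**meta["params"])
    # the output grid is uniform in hours; snap away day->hour float noise
    dt = float(options.output_dt_hours)
    t_hours = np.rint(frame["time_days"].to_numpy() * HOURS_PER_DAY / dt) * dt
    states = frame[list(layout.names())].to_numpy()
    derived = {name: frame[name].to_numpy() for name in _DERIVED if name in frame}
    ev_file = events_path(path)
    events: list[tuple[str, float]] = []
    if ev_file.exists():
        ev = pd.read_csv(ev_file)
        events = [(str(r.event), float(r.time_days)) for r in ev.itertuples()]
    return SimulationResult(
        t_hours=t_hours, states=states, layout=layout, derived=derived,
        events=events, params=params, options=options,
        no_ovulation=bool(meta["no_ovulation"]),
    )
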