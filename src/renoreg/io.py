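"""Trace export/import: tidy and wide CSV with a units header row.

Exports are deterministic — identical traces produce byte-identical
files — so runs can be diffed directly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import SimulationTrace

__all__ = ["export_trace", "read_trace"]

_UNITS = {"P": "mmHg", "V": "L", "q": "L/s", "time_s": "s"}


def export_trace(trace: SimulationTrace, path: str | Path,
                 fmt: str = "wide") -> Path:
    """Write a trace to CSV.

    ``fmt='wide'``: one column per signal (time_s, P:*, V:*, q:*) with a
    units row under the header and a metadata comment line on top.
    ``fmt='tidy'``: long format (time_s, variable, value, units).
    """
    path = Path(path)
    if fmt == "wide":
        frame = trace.to_wide_frame()
        units = [_UNITS.get(c.partition(":")[0], "") or _UNITS[c]
                 for c in frame.columns]
        meta = (f"# renoreg trace: heart_rate_bpm={trace.heart_rate!r} "
                f"dt_s={trace.dt!r} steps_per_beat={trace.steps_per_beat}\n")
        with path.open("w") as fh:
            fh.write(meta)
            fh.write(",".join(frame.columns) + "\n")
            fh.write(",".join(units) + "\n")
            frame.to_csv(fh, index=False, header=False)
    elif fmt == "tidy":
        trace.to_tidy_frame().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'wide' or 'tidy'")
    return path


def read_trace(path: str | Path) -> SimulationTrace:
    """Read a wide-format CSV written by :func:`export_trace`."""
    path = Path(path)
    with path.open() as fh:
        meta = fh.readline()
        if not meta.startswith("# renoreg trace:"):
            raise ValueError(f"{path} is not a renoreg wide trace file")
        kv = dict(item.split("=") for item in meta.split(":", 1)[1].split())
        frame = pd.read_csv(fh, skiprows=[1])
    comps = [c.partition(":")[2] for c in frame.columns if c.startswith("P:")]
    conns = [c.partition(":")[2] for c in frame.columns if c.startswith("q:")]
    return SimulationTrace(
        time=frame["time_s"].to_numpy(),
        pressures=frame[[f"P:{c}" for c in comps]].to_numpy(),
        volumes=frame[[f"V:{c}" for c in comps]].to_numpy(),
        flows=frame[[f"q:{c}" for c in conns]].to_numpy(),
        compartments=comps, connectors=conns,
        heart_rate=float(kv["heart_rate_bpm"]),
        dt=float(kv["dt_s"]),
        steps_per_beat=int(kv["steps_per_beat"]))
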