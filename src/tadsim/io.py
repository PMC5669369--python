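"""Readers and writers for trajectories, ethograms, curves and reports.

Conventions: time columns are always milliseconds, activities always
dimensionless.  Every writer embeds a provenance header (package version,
parameter-set hash, seed) as ``#``-prefixed comment lines; readers skip
them.  Writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import Ethogram
from .bifurcation import SNCurve
from .params import STATE_NAMES, ModelParams
from .simulate import SimulationResult

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_tidy_trajectory",
    "write_ethogram_bed",
    "write_ethogram_json",
    "read_ethogram_bed",
    "write_event_log",
    "write_sn_curve",
    "read_sn_curve",
    "write_report",
]


def _header(params: ModelParams | None, seed) -> str:
    from . import __version__

    h = params.config_hash() if params is not None else "none"
    return f"# tadsim v{__version__} config={h} seed={seed}\n"


def write_trajectory(result: SimulationResult, path: str | Path) -> None:
    """Wide-format CSV: one t_ms column plus one column per population."""
    path = Path(path)
    df = result.to_wide_frame()
    with open(path, "w") as fh:
        fh.write(_header(result.params, result.seed))
        df.to_csv(fh, index=False)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ("t_ms", *STATE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file lacks columns {missing}")
    return df


def write_tidy_trajectory(result: SimulationResult, path: str | Path) -> None:
    """Long-format CSV with columns t_ms, population, side, activity."""
    with open(path, "w") as fh:
        fh.write(_header(result.params, result.seed))
        result.to_tidy_frame().to_csv(fh, index=False)


def write_ethogram_bed(eth: Ethogram, path: str | Path,
                       params: ModelParams | None = None, seed=None) -> None:
    """BED-like interval file: t_start, t_end, label (tab separated)."""
    with open(path, "w") as fh:
        fh.write(_header(params, seed))
        for a, b, lab in eth.intervals:
            fh.write(f"{float(a)!r}\t{float(b)!r}\t{lab}\n")


def read_ethogram_bed(path: str | Path) -> Ethogram:
    intervals = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        a, b, lab = line.split("\t")
        intervals.append((float(a), float(b), lab))
    return Ethogram(intervals=intervals)


def write_ethogram_json(eth: Ethogram, path: str | Path,
                        params: ModelParams | None = None, seed=None) -> None:
    from . import __version__

    payload = {
        "version": __version__,
        "config": params.config_hash() if params else None,
        "seed": seed,
        "intervals": [
            {"t_start": a, "t_end": b, "label": lab} for a, b, lab in eth.intervals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_event_log(result: SimulationResult, path: str | Path) -> None:
    """JSON log of applied stimulus segments and controller actions."""
    from . import __version__

    payload = {
        "version": __version__,
        "config": result.params.config_hash(),
        "seed": result.seed,
        "dt_ms": result.dt,
        "stimulus": result.stimulus_log,
        "controller": result.controller_log,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_sn_curve(curve: SNCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# saddle-node curve b={curve.b!r} theta={curve.theta!r} "
                 f"k={curve.k!r} cusp_P={curve.cusp[0]!r} cusp_a={curve.cusp[1]!r}\n")
        curve.to_frame().to_csv(fh, index=False)


def read_sn_curve(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_report(report: dict, path: str | Path) -> None:
    def clean(o):
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        if isinstance(o, np.ndarray):
            return [float(v) for v in o]
        if isinstance(o, dict):
            return {k: clean(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [clean(v) for v in o]
        return o

    Path(path).write_text(json.dumps(clean(report), indent=1))
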