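"""Trajectory serialization: TSV tables with JSON metadata sidecars.

Deterministic outputs are tabulated in minutes, stochastic outputs in
seconds (each module's natural resolution); the unit is part of the
column name.  Every file gets a sidecar recording the parameters,
seed and config hash so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .gillespie import StochasticRun

__all__ = ["write_trajectory", "read_trajectory", "write_stochastic_run", "write_sidecar"]


def write_sidecar(path, metadata: dict) -> Path:
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=_jsonable))
    return side


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def write_trajectory(traj: Trajectory, path, metadata: Optional[dict] = None) -> Path:
    """Write a deterministic trajectory as TSV plus a JSON sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = dict(traj.meta)
    if metadata:
        meta.update(metadata)
    write_sidecar(path, meta)
    return path


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory TSV, checking the derived columns W and R."""
    df = pd.read_csv(path, sep="\t")
    w_cols = [c for c in df.columns if c.startswith("w_")]
    if w_cols and {"p", "W", "R"} <= set(df.columns):
        W = df[w_cols].sum(axis=1)
        if not np.allclose(W, df["W"], rtol=1e-8, atol=1e-8) or not np.allclose(
            W + df["p"], df["R"], rtol=1e-8, atol=1e-8
        ):
            raise ValueError(f"inconsistent derived columns in {path}")
    return df


def write_stochastic_run(run: StochasticRun, path, metadata: Optional[dict] = None) -> Path:
    """Write an SSA run as TSV (time in seconds) plus a JSON sidecar."""
    path = Path(path)
    data = {"time_s": run.times * 60.0}
    for i in range(run.n_synapses):
        data[f"w_{i + 1}"] = run.w[:, i]
    data["p"] = run.p
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
    meta = {
        "seed": run.seed,
        "slots": run.slots,
        "rates": run.rates,
        "event_counts": run.event_counts,
    }
    if metadata:
        meta.update(metadata)
    write_sidecar(path, meta)
    return path
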