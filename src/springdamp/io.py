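"""Plain-text I/O: long-format series tables and flat run configs.

All tabular files are comma-separated UTF-8 with a header row and '.' as the
decimal mark.  The long-format series schema is one row per observation:

    individual_id, measure, line, replicate, time, value[, provenance]

Configs are flat YAML key-value mappings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import Trajectory
from .preprocess import ObservationSeries

__all__ = [
    "LONG_COLUMNS",
    "read_long",
    "write_long",
    "series_from_frame",
    "frame_from_series",
    "write_trajectory",
    "load_config",
    "dump_config",
]

LONG_COLUMNS = ["individual_id", "measure", "line", "replicate", "time", "value"]


def read_long(path: str | Path) -> pd.DataFrame:
    """Read a long-format observation table, checking the required columns."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_long(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def series_from_frame(df: pd.DataFrame) -> list[ObservationSeries]:
    """Split a long-format frame into one series per individual x measure.

    Rows are sorted by time within each series; a ``provenance`` column equal
    to 'preprocessed' marks series as already preprocessed.
    """
    preprocessed_col = "provenance" in df.columns
    out = []
    for (ind, meas), g in df.groupby(["individual_id", "measure"], sort=True):
        g = g.sort_values("time")
        line = g["line"].iloc[0] if "line" in g else None
        rep = g["replicate"].iloc[0] if "replicate" in g else None
        is_pre = bool(preprocessed_col and (g["provenance"] == "preprocessed").all())
        out.append(ObservationSeries(
            individual_id=str(ind),
            measure=str(meas),
            times=g["time"].to_numpy(dtype=float),
            values=g["value"].to_numpy(dtype=float),
            line=None if pd.isna(line) else str(line),
            replicate=None if pd.isna(rep) else str(rep),
            is_preprocessed=is_pre,
        ))
    return out


def frame_from_series(
    series_list: list[ObservationSeries], provenance: str | None = None
) -> pd.DataFrame:
    """Stack series back into the long-format schema.

    ``provenance`` defaults to 'preprocessed' or 'raw' according to each
    series' flag.
    """
    rows = []
    for s in series_list:
        prov = provenance or ("preprocessed" if s.is_preprocessed else "raw")
        for t, v in zip(s.times, s.values):
            rows.append({
                "individual_id": s.individual_id,
                "measure": s.measure,
                "line": s.line,
                "replicate": s.replicate,
                "time": t,
                "value": v,
                "provenance": prov,
            })
    return pd.DataFrame(rows, columns=LONG_COLUMNS + ["provenance"])


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a delimited file with columns time, x, regime."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    trajectory.to_frame().to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a flat YAML key-value config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write the resolved run configuration (always including the seed)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in cfg.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(clean, fh, sort_keys=True)
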