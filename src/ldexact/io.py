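"""CSV/JSON writers and readers with reproducibility headers.

Every file starts with comment lines ``# key=value`` echoing the full
parameter set (and package version) that produced it, so a run can be
reproduced from the file alone.  Numbers are serialised with 17 significant
digits, making float round-trips lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import DistributionVector, TrajectoryRecord
from .kernel import PopulationParams
from .statespace import StateSpace

__all__ = [
    "write_frame",
    "read_frame",
    "params_header",
    "state_dump_frame",
    "trajectory_frame",
    "distribution_frame",
    "r2_distribution_frame",
]

_FLOAT_FMT = "%.17g"


def params_header(params: PopulationParams, **extra) -> dict:
    header = {
        "ldexact_version": __version__,
        "ne": params.ne,
        "c": params.c,
        "u": params.u,
        "v": params.v,
        "s": params.s,
        "maf_threshold": params.maf_threshold,
    }
    header.update(extra)
    return header


def write_frame(path: str | Path, frame: pd.DataFrame, header: Mapping | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            if isinstance(value, float):
                value = _FLOAT_FMT % value
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_frame(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a headered CSV back; returns (frame, header dict of strings)."""
    path = Path(path)
    header: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                header[key.strip()] = value.strip()
    # correctly-rounded parsing so 17-significant-digit writes round-trip
    frame = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    return frame, header


def state_dump_frame(space: StateSpace) -> pd.DataFrame:
    """Per-state table: counts, r2 (empty when indeterminate), flags, MAF."""
    r2 = np.where(space.determinate, space.r2, np.nan)
    return pd.DataFrame(
        {
            "f11": space.counts[:, 0],
            "f12": space.counts[:, 1],
            "f21": space.counts[:, 2],
            "f22": space.counts[:, 3],
            "r2": r2,
            "segregating_a": space.segregating_a,
            "segregating_b": space.segregating_b,
            "maf_b": space.maf_b,
        }
    )


def trajectory_frame(records: Sequence[TrajectoryRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "e_r2": [r.e_r2 for r in records],
            "e_r2_maf": [r.e_r2_maf for r in records],
            "sigma_d2": [r.sigma_d2 for r in records],
            "mass_determinate": [r.mass_determinate for r in records],
        }
    )


def distribution_frame(space: StateSpace, dist: DistributionVector) -> pd.DataFrame:
    """State-level distribution table (the data behind an r2-vs-frequency scatter)."""
    return pd.DataFrame(
        {
            "f11": space.counts[:, 0],
            "f12": space.counts[:, 1],
            "f21": space.counts[:, 2],
            "f22": space.counts[:, 3],
            "probability": dist.probs,
            "r2": np.where(space.determinate, space.r2, np.nan),
            "maf_b": space.maf_b,
        }
    )


def r2_distribution_frame(groups: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Long-format r2 distribution: columns r2, probability, group."""
    parts = []
    for group, (values, probs) in groups.items():
        parts.append(pd.DataFrame({"r2": values, "probability": probs, "group": group}))
    return pd.concat(parts, ignore_index=True)
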