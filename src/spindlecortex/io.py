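"""Delimited-text file formats for kymographs, tracks, tables and manifests.

Kymograph dialect: tab-separated matrix, first row = frame times (min),
first column = spatial coordinate (μm), cell (i, j) = intensity. Track
files are tab-separated tables with a ``t_min`` column. Floats are written
with 9 significant digits. Manifests are flat YAML (key: value).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import Kymograph, Trajectory

FLOAT_FMT = "%.9g"


def write_kymograph(kymo: Kymograph, path) -> None:
    df = pd.DataFrame(kymo.intensity, index=kymo.x, columns=kymo.t)
    df.index.name = "x_um"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_kymograph(path, dna_center=None, dna_half_extent=None,
                   normalization: str = "raw") -> Kymograph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Kymograph(
        x=df.index.to_numpy(dtype=float),
        t=np.asarray([float(c) for c in df.columns]),
        intensity=df.to_numpy(dtype=float),
        dna_center=dna_center, dna_half_extent=dna_half_extent,
        normalization=normalization,
    )


def write_track(traj: Trajectory, path, columns=("xn_um",),
                extra: dict | None = None) -> None:
    pos = traj.positions if traj.positions.ndim == 2 else traj.positions[:, None]
    data = {"t_min": traj.t}
    for k, col in enumerate(columns):
        data[col] = pos[:, k]
    for name, values in (extra or {}).items():
        data[name] = values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False,
                              float_format=FLOAT_FMT)


def read_track(path, columns=("xn_um",)) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    if "t_min" not in df.columns:
        raise ValueError(f"track file {path} lacks a t_min column")
    cols = [c for c in columns if c in df.columns]
    if not cols:
        raise ValueError(f"track file {path} lacks position columns {columns}")
    pos = df[cols].to_numpy(dtype=float)
    if pos.shape[1] == 1:
        pos = pos[:, 0]
    return Trajectory(df["t_min"].to_numpy(dtype=float), pos)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _pyify(obj):
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    return obj


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_pyify(manifest), sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
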