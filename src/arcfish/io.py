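"""File formats: multi-page TIFF stacks with JSON sidecars, CSV tables, ROI JSON.

Stacks are written channel-interleaved, z-major (page order z0c0, z0c1,
z1c0, ...) with a sidecar JSON recording voxel spacing and channel names.
All pixel coordinates are 0-based, y-down; z-plane indices 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .simulate import ImageStack

__all__ = [
    "write_stack", "read_stack",
    "write_truth", "read_truth",
    "write_counts", "read_counts",
    "write_rois", "read_rois",
]

PathLike = Union[str, Path]

TRUTH_COLUMNS = ["cell_id", "is_neuron", "e1", "e2", "z", "y", "x", "r"]
COUNT_COLUMNS = ["animal_id", "region", "condition", "pretreatment",
                 "neg", "nuc", "cyt", "dob"]


def write_stack(path: PathLike, stack: ImageStack) -> None:
    """Write (c, z, y, x) as interleaved pages plus a .json sidecar."""
    path = Path(path)
    c, z, y, x = stack.channels.shape
    pages = np.transpose(stack.channels, (1, 0, 2, 3)).reshape(z * c, y, x)
    tifffile.imwrite(path, pages.astype(np.float32))
    sidecar = {"z_step_um": stack.z_step, "channel_names": list(stack.channel_names),
               "n_channels": c, "n_planes": z, "page_order": "z-major, channel-interleaved"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: PathLike) -> ImageStack:
    path = Path(path)
    pages = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    c, z = meta["n_channels"], meta["n_planes"]
    channels = pages.reshape(z, c, pages.shape[-2], pages.shape[-1]).transpose(1, 0, 2, 3)
    return ImageStack(channels, z_step=meta["z_step_um"],
                      channel_names=tuple(meta["channel_names"]))


def write_truth(path: PathLike, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth CSV missing columns {sorted(missing)}")
    for col in ("is_neuron", "e1", "e2"):
        df[col] = df[col].astype(bool)
    return df


def write_counts(path: PathLike, counts_rows: pd.DataFrame) -> None:
    counts_rows.to_csv(path, index=False)


def read_counts(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts CSV missing columns {sorted(missing)}")
    return df


def write_rois(path: PathLike, rois: Sequence[tuple[str, Sequence]]) -> None:
    """ROI polygons as a JSON list of [name, [[x, y], ...]] in pixel coords."""
    data = [[name, [[float(x), float(y)] for x, y in poly]] for name, poly in rois]
    Path(path).write_text(json.dumps(data, indent=1))


def read_rois(path: PathLike) -> list[tuple[str, list[list[float]]]]:
    data = json.loads(Path(path).read_text())
    return [(name, poly) for name, poly in data]
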