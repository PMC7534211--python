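"""Reading and writing stacks, masks and per-cell tables.

Stacks are exchanged as one multipage TIFF per channel (filenames
``<stem>_dapi.tif`` etc.); label masks as 16-bit single-page TIFFs.
Per-cell tables are CSV with ``#``-prefixed metadata header lines
recording the texture settings used, so a table is self-describing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import tifffile

from .stacks import CHANNELS, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_label_mask",
    "read_label_mask",
    "write_cell_table",
    "read_cell_table",
]


def write_stack(stack: ImageStack, directory: Path, stem: str = "stack") -> Dict[str, Path]:
    """Write one multipage TIFF per channel; returns name -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for name in CHANNELS:
        path = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(path, stack[name], metadata={
            "axes": "ZYX",
            "pixel_size_um": stack.pixel_size_um,
            "z_spacing_um": stack.z_spacing_um,
        })
        paths[name] = path
    return paths


def read_stack(
    directory: Path, stem: str = "stack", pixel_size_um: float = 1.14, z_spacing_um: float = 5.0
) -> ImageStack:
    """Read the three per-channel TIFFs written by :func:`write_stack`."""
    directory = Path(directory)
    channels = {}
    for name in CHANNELS:
        path = directory / f"{stem}_{name}.tif"
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None, :, :]
        channels[name] = data
    return ImageStack(channels=channels, pixel_size_um=pixel_size_um, z_spacing_um=z_spacing_um)


def write_label_mask(labels: np.ndarray, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def read_label_mask(path: Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_cell_table(
    cells: pd.DataFrame, path: Path, metadata: Optional[Dict[str, object]] = None
) -> Path:
    """CSV with '#'-prefixed metadata lines before the header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        cells.to_csv(fh, index=False)
    return path


def read_cell_table(path: Path) -> pd.DataFrame:
    """Read a per-cell CSV, skipping metadata comment lines."""
    with open(path) as fh:
        text = "".join(line for line in fh if not line.startswith("#"))
    return pd.read_csv(_io.StringIO(text))
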