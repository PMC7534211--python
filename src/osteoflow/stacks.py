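"""In-memory containers for multichannel confocal data.

An :class:`ImageStack` holds the three acquisition channels (DAPI for
nuclei, phalloidin for filamentous actin, Runx-2 for the osteogenic
marker) as ``(planes, rows, cols)`` arrays; a :class:`ProjectionImage`
holds one 2-D image per channel after z-projection.  Coordinates are
0-based ``(row, col)`` with row increasing downward throughout the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

CHANNELS: Tuple[str, str, str] = ("dapi", "phalloidin", "runx2")


class ChannelError(ValueError):
    """A required channel is missing or channels disagree in shape."""


def _validate_channels(data: Dict[str, np.ndarray], ndim: int) -> None:
    for name in CHANNELS:
        if name not in data:
            raise ChannelError(f"missing channel: {name!r}")
    shapes = {name: data[name].shape for name in CHANNELS}
    if len(set(shapes.values())) != 1:
        raise ChannelError(f"channel shapes differ: {shapes}")
    first = next(iter(shapes.values()))
    if len(first) != ndim:
        raise ChannelError(f"expected {ndim}-D channel arrays, got shape {first}")


@dataclass
class ImageStack:
    """Three-channel z-stack; each channel is a (planes, rows, cols) array."""

    channels: Dict[str, np.ndarray]
    pixel_size_um: float = 1.14
    z_spacing_um: float = 5.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        _validate_channels(self.channels, ndim=3)

    @property
    def n_planes(self) -> int:
        return self.channels["dapi"].shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels["dapi"].shape[1:]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class ProjectionImage:
    """One 2-D greyscale image per channel, plus projection provenance."""

    channels: Dict[str, np.ndarray]
    pixel_size_um: float = 1.14
    method: str = "max"
    source: str = ""
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_channels(self.channels, ndim=2)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.channels["dapi"].shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __iter__(self) -> Iterator[np.ndarray]:
        return (self.channels[name] for name in CHANNELS)
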