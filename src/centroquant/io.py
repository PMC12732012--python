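"""Image containers and TIFF input/output.

The pipeline operates on 2D multi-channel fields (summed Z-stacks). Channels
are kept in a name -> raster mapping so downstream stages can ask for the
DNA, gamma-tubulin or target-protein plane by name rather than by index.
Coordinates are 0-based (row, column) throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError

__all__ = ["ImageStack", "CellLabelMap", "read_image", "write_image",
           "read_label_map", "write_label_map"]


@dataclass
class ImageStack:
    """Named multi-channel 2D intensity raster.

    Parameters
    ----------
    channels
        Mapping of channel name to 2D non-negative intensity array. All
        channels must share one shape.
    pixel_size
        Physical units per pixel (optional, informational).
    provenance
        Free-text note on where the image came from.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("ImageStack requires at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        distinct = set(shapes.values())
        if len(distinct) != 1:
            raise FormatError(f"channels disagree on shape: {shapes}")
        (shape,) = distinct
        if len(shape) != 2:
            raise FormatError(f"channels must be 2D, got shape {shape}")
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if np.any(arr < 0):
                raise FormatError(f"channel {name!r} contains negative intensities")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class CellLabelMap:
    """Integer-labeled raster partitioning the field into cells.

    ``labels == 0`` is background; ``labels == k`` (k > 0) is cell ``k``.
    ``source`` records which segmentation backend produced the map.
    """

    labels: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise FormatError(f"label map must be 2D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError(f"label map must be integer-typed, got {labels.dtype}")
        if labels.min() < 0:
            raise FormatError("label map contains negative labels")
        self.labels = labels

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, cell_id: int) -> np.ndarray:
        return self.labels == cell_id


def read_image(path, channel_names: list[str] | None = None) -> ImageStack:
    """Read a multi-plane TIFF into an :class:`ImageStack`.

    Planes are mapped to ``channel_names`` in storage order. When
    ``channel_names`` is None the channel names embedded at write time by
    :func:`write_image` are used.
    """
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 2D planes, got array of shape {data.shape}")
    if channel_names is None:
        channel_names = _embedded_channel_names(path)
        if channel_names is None:
            raise FormatError(f"{path}: no embedded channel names; pass channel_names")
    if data.shape[0] < len(channel_names):
        raise FormatError(
            f"{path}: {data.shape[0]} planes but {len(channel_names)} channel names"
        )
    if data.shape[0] > len(channel_names):
        raise FormatError(
            f"{path}: {data.shape[0]} planes exceed the {len(channel_names)} "
            "channel names given"
        )
    channels = {name: data[i] for i, name in enumerate(channel_names)}
    return ImageStack(channels=channels, provenance=f"read from {path}")


def write_image(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as a multi-plane TIFF.

    Channel order and names are embedded in the TIFF description so a
    round-trip through :func:`read_image` is lossless.
    """
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names])
    description = json.dumps({"channel_names": names})
    tifffile.imwrite(path, data, description=description,
                     photometric="minisblack")


def _embedded_channel_names(path) -> list[str] | None:
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
    if not desc:
        return None
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return None
    names = meta.get("channel_names")
    return list(names) if names else None


def read_label_map(path, source: str = "file") -> CellLabelMap:
    labels = tifffile.imread(path)
    return CellLabelMap(labels=labels.astype(np.int32), source=source)


def write_label_map(path, label_map: CellLabelMap) -> None:
    labels = label_map.labels
    if labels.max() >= 2 ** 16:
        raise FormatError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
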