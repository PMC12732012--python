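"""Fluorescence measurement: region means, polygon-ROI means, line scans.

Centrosomal abundance of the target protein is the arithmetic mean of the
target channel over a detected region's pixel set — no background
subtraction, matching the measurement the statistics downstream were built
on (an optional per-cell median subtraction is available). Manual-ROI means
reproduce the freehand-selection workflow used when automated segmentation
is not possible; membership is by pixel-center inclusion. Line scans sample
the raster by bilinear interpolation at unit spacing and are the basis of
the centriole "double-hump" readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage as ndi
from scipy.signal import find_peaks

from .detect import CentrosomeRegion
from .errors import ContractError, InputError
from .io import CellLabelMap, ImageStack

__all__ = ["MeasurementRecord", "LineProfile", "measure_mean_fluorescence",
           "measure_regions", "measure_roi_mean", "line_profile",
           "count_profile_peaks", "RECORD_COLUMNS"]

RECORD_COLUMNS = ["image_id", "cell_id", "centrosome_id", "mean_fluorescence",
                  "channel", "stage", "transfected", "review"]


@dataclass
class MeasurementRecord:
    """One (cell, centrosome) mean-fluorescence observation — the
    statistical unit. ``centrosome_id`` is None for ROI-level records.
    ``stage`` and ``transfected`` come from annotations or ground truth,
    never from pixels."""

    image_id: str
    cell_id: int
    centrosome_id: int | None
    mean_fluorescence: float
    channel: str
    stage: str = "unknown"
    transfected: bool = False
    review: str = "unreviewed"


@dataclass
class LineProfile:
    """Intensity samples at unit spacing along a segment (endpoints
    inclusive; ``len(samples) == ceil(length) + 1``)."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    samples: np.ndarray
    channel: str = ""

    @property
    def length(self) -> float:
        return math.dist(self.p0, self.p1)


def measure_mean_fluorescence(raster: np.ndarray,
                              region: CentrosomeRegion) -> float:
    """Arithmetic mean of ``raster`` over the region's pixel set."""
    raster = np.asarray(raster)
    if region.area == 0:
        raise ContractError("cannot measure an empty region")
    px = region.pixels
    if (px.min() < 0 or px[:, 0].max() >= raster.shape[0]
            or px[:, 1].max() >= raster.shape[1]):
        raise ContractError("region pixels fall outside the raster")
    return float(raster[px[:, 0], px[:, 1]].mean())


def measure_regions(stack: ImageStack, regions: list[CentrosomeRegion],
                    channel: str, image_id: str = "image",
                    stage_lookup: dict[int, str] | None = None,
                    transfected_lookup: dict[int, bool] | None = None,
                    subtract_cell_median: bool = False,
                    labels: CellLabelMap | None = None) -> pd.DataFrame:
    """Measure every region on one channel; returns the tidy records table.

    ``subtract_cell_median`` removes the per-cell median of the channel
    (a documented option; the default measurement is raw).
    """
    raster = np.asarray(stack.channel(channel), dtype=np.float64)
    medians: dict[int, float] = {}
    if subtract_cell_median:
        if labels is None:
            raise InputError("subtract_cell_median requires the cell label map")
        for cid in labels.cell_ids:
            medians[int(cid)] = float(np.median(raster[labels.labels == cid]))
    rows = []
    for r in regions:
        value = measure_mean_fluorescence(raster, r)
        if subtract_cell_median:
            value = max(value - medians.get(r.cell_id, 0.0), 0.0)
        stage = (stage_lookup or {}).get(r.cell_id, "unknown")
        transfected = (transfected_lookup or {}).get(r.cell_id, False)
        rows.append(dict(image_id=image_id, cell_id=r.cell_id,
                         centrosome_id=r.centrosome_id,
                         mean_fluorescence=value, channel=channel,
                         stage=stage, transfected=transfected,
                         review="unreviewed"))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def measure_roi_mean(raster: np.ndarray, polygon) -> float:
    """Mean intensity over pixels whose centers fall inside a simple polygon.

    ``polygon`` is an (N, 2) array of (x, y) vertices (x = column,
    y = row). Membership is strict interior (even-odd rule for simple
    polygons; centers exactly on the boundary are excluded).
    """
    raster = np.asarray(raster)
    verts = np.asarray(polygon, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise InputError("polygon must be an (N>=3, 2) vertex array")
    poly = shapely.Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise InputError("polygon is degenerate (self-intersecting or zero area)")
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(math.floor(minx)))
    c1 = min(raster.shape[1] - 1, int(math.ceil(maxx)))
    r0 = max(0, int(math.floor(miny)))
    r1 = min(raster.shape[0] - 1, int(math.ceil(maxy)))
    if c0 > c1 or r0 > r1:
        raise InputError("polygon selects no pixels (outside the raster)")
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cols.ravel().astype(float),
                                 rows.ravel().astype(float))
    if not inside.any():
        raise InputError("polygon selects no pixels")
    vals = raster[r0:r1 + 1, c0:c1 + 1].ravel()[inside]
    return float(vals.mean())


def line_profile(raster: np.ndarray, p0, p1, channel: str = "") -> LineProfile:
    """Bilinear line scan from ``p0`` to ``p1`` (row, col coordinates),
    sampled at unit spacing, endpoints inclusive."""
    raster = np.asarray(raster, dtype=np.float64)
    p0 = (float(p0[0]), float(p0[1]))
    p1 = (float(p1[0]), float(p1[1]))
    for p in (p0, p1):
        if not (0 <= p[0] <= raster.shape[0] - 1
                and 0 <= p[1] <= raster.shape[1] - 1):
            raise InputError(f"endpoint {p} lies outside the raster")
    length = math.dist(p0, p1)
    if length == 0:
        raise InputError("line-profile endpoints coincide")
    n = int(math.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = np.stack([p0[0] + t * (p1[0] - p0[0]),
                       p0[1] + t * (p1[1] - p0[1])])
    samples = ndi.map_coordinates(raster, coords, order=1, mode="nearest")
    return LineProfile(p0=p0, p1=p1, samples=samples, channel=channel)


def count_profile_peaks(profile: LineProfile,
                        min_prominence: float) -> int:
    """Number of local maxima with prominence >= ``min_prominence`` — a
    monotone or flat profile has none; a scan across a well-separated
    centriole pair has two (the double-hump)."""
    samples = np.asarray(profile.samples, dtype=np.float64)
    if samples.size < 3:
        raise InputError("profile needs at least 3 samples")
    idx, _ = find_peaks(samples, prominence=min_prominence)
    return int(idx.size)
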