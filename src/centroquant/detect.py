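"""Per-cell centrosome detection in the gamma-tubulin channel.

The detector composes five deterministic steps inside each segmented cell:

1. Gaussian blur of the whole gamma-tubulin raster (noise/debris rejection).
2. At most two local-intensity maxima per cell, greedily accepted in
   brightness order subject to a minimum pairwise distance of 6 px.
3. Region growing around each peak: the 8-connected flood, within the cell
   mask, of pixels at or above ``expansion_fraction`` (default 0.70) of the
   peak brightness.
4. Peaks closer than ``merge_distance`` (default 10 px, strict) are treated
   as one centrosome and their regions are unioned.
5. Regions below ``min_region_area`` (default 30 px) are discarded as noise.

Peak *locations* come from the blurred raster; peak brightness, expansion
thresholds and all downstream fluorescence measurements use the unblurred
raster by default, to avoid smoothing bias (``measure_on_blurred`` inverts
this). Distances are Euclidean in pixel units; ties in brightness are broken
toward the smallest (row, column) coordinate so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ContractError, FormatError, ParameterError
from .io import CellLabelMap, ImageStack

__all__ = ["DetectionConfig", "Peak", "CentrosomeRegion", "blur_channel",
           "find_peaks_in_cell", "expand_region", "merge_close_peaks",
           "filter_small_regions", "detect_centrosomes",
           "regions_to_dataframe", "regions_to_label_map"]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DetectionConfig:
    """Tuning surface of the detector; defaults are the validated values of
    the workflow this package implements."""

    blur_sigma: float = 2.0
    max_peaks_per_cell: int = 2
    min_peak_distance: float = 6.0
    expansion_fraction: float = 0.70
    merge_distance: float = 10.0
    min_region_area: int = 30
    measure_on_blurred: bool = False

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be non-negative")
        if not (0.0 < self.expansion_fraction <= 1.0):
            raise ParameterError("expansion_fraction must lie in (0, 1]")
        if self.max_peaks_per_cell < 1:
            raise ParameterError("max_peaks_per_cell must be at least 1")
        if self.min_peak_distance < 0 or self.merge_distance < 0:
            raise ParameterError("distances must be non-negative")
        if self.min_region_area < 0:
            raise ParameterError("min_region_area must be non-negative")


@dataclass(frozen=True)
class Peak:
    """One detected intensity maximum (0-based row/col)."""

    row: int
    col: int
    brightness: float
    low_contrast: bool = False

    @property
    def coord(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class CentrosomeRegion:
    """One detected centrosome: its owning cell, constituent peak(s) and
    pixel set (an (N, 2) array of row/col pairs, lexicographically sorted)."""

    cell_id: int
    centrosome_id: int
    peaks: list[Peak]
    pixels: np.ndarray

    @property
    def area(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def peak_brightness(self) -> float:
        return max(p.brightness for p in self.peaks)


def _sorted_pixels(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    return coords[order]


def blur_channel(raster: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smoothed copy (reflective boundary); ``sigma=0`` is the
    identity."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    raster = np.asarray(raster, dtype=np.float64)
    if sigma == 0:
        return raster.copy()
    return ndi.gaussian_filter(raster, sigma, mode="reflect")


def find_peaks_in_cell(blurred: np.ndarray, cell_mask: np.ndarray,
                       config: DetectionConfig) -> list[Peak]:
    """Ranked local maxima inside one cell mask.

    A pixel is a candidate when its value is >= all of its 8-neighbors that
    lie inside the mask; an 8-connected plateau of equal-valued candidates
    contributes a single candidate at its smallest (row, column) pixel.
    Candidates are sorted by (brightness desc, row, col) and accepted
    greedily subject to pairwise Euclidean distance >= ``min_peak_distance``,
    up to ``max_peaks_per_cell``.

    A candidate sitting at the mask's minimum value is a plateau with no
    intensity contrast at all (a flat background, not a spot); such
    candidates are flagged ``low_contrast`` and considered only when the
    mask offers no contrasted candidate (a completely flat mask then yields
    one flagged peak at the deterministic tie-break position).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ContractError("find_peaks_in_cell called with an empty mask")
    blurred = np.asarray(blurred, dtype=np.float64)

    neg_inf = -np.inf
    v = np.where(cell_mask, blurred, neg_inf)
    is_max = cell_mask.copy()
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.full_like(v, neg_inf)
            rs = slice(max(dr, 0), v.shape[0] + min(dr, 0))
            rd = slice(max(-dr, 0), v.shape[0] + min(-dr, 0))
            cs = slice(max(dc, 0), v.shape[1] + min(dc, 0))
            cd = slice(max(-dc, 0), v.shape[1] + min(-dc, 0))
            shifted[rd, cd] = v[rs, cs]
            is_max &= v >= shifted

    # Adjacent candidate pixels are necessarily equal-valued, so each
    # 8-connected component is one plateau; keep its lexicographic minimum.
    comp, n_comp = ndi.label(is_max, structure=_STRUCT8)
    mask_min = blurred[cell_mask].min()
    candidates = []
    if n_comp:
        coords = np.argwhere(comp > 0)
        order = np.lexsort((coords[:, 1], coords[:, 0]))
        seen: set[int] = set()
        for r, c in coords[order]:
            lab = comp[r, c]
            if lab in seen:
                continue
            seen.add(int(lab))
            val = blurred[r, c]
            candidates.append(Peak(int(r), int(c), float(val),
                                   low_contrast=bool(val <= mask_min)))
    candidates.sort(key=lambda p: (-p.brightness, p.row, p.col))
    contrasted = [p for p in candidates if not p.low_contrast]
    if contrasted:
        candidates = contrasted

    accepted: list[Peak] = []
    min_d2 = config.min_peak_distance ** 2
    for cand in candidates:
        if len(accepted) >= config.max_peaks_per_cell:
            break
        if all((cand.row - a.row) ** 2 + (cand.col - a.col) ** 2 >= min_d2
               for a in accepted):
            accepted.append(cand)
    return accepted


def expand_region(gamma: np.ndarray, peak: tuple[int, int],
                  cell_mask: np.ndarray, fraction: float) -> np.ndarray:
    """Grow a centrosome region around a peak.

    Returns the pixel set ((N, 2) sorted array) of the 8-connected component,
    within ``cell_mask``, of pixels with brightness >= ``fraction`` x the
    brightness at ``peak``; the component containing the peak. Always
    contains the peak itself.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    r, c = int(peak[0]), int(peak[1])
    if not (0 <= r < gamma.shape[0] and 0 <= c < gamma.shape[1]) \
            or not cell_mask[r, c]:
        raise ContractError(f"peak {peak} lies outside the cell mask")
    threshold = fraction * gamma[r, c]
    qualifying = (gamma >= threshold) & cell_mask
    comp, _ = ndi.label(qualifying, structure=_STRUCT8)
    return _sorted_pixels(np.argwhere(comp == comp[r, c]))


def merge_close_peaks(regions: list[CentrosomeRegion],
                      merge_distance: float) -> list[CentrosomeRegion]:
    """Union regions whose peaks lie closer than ``merge_distance``
    (strict inequality), under transitive closure.

    All regions must belong to one cell. Merged regions union their pixel
    sets and concatenate their peak lists (brightest first); the group is
    placed at the position of its first member so output order is stable.
    """
    if not regions:
        return []
    cell_ids = {r.cell_id for r in regions}
    if len(cell_ids) != 1:
        raise ContractError(f"regions span multiple cells: {sorted(cell_ids)}")
    n = len(regions)
    rows, cols = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d2min = min((pi.row - pj.row) ** 2 + (pi.col - pj.col) ** 2
                        for pi in regions[i].peaks for pj in regions[j].peaks)
            if d2min < merge_distance ** 2:
                rows += [i, j]
                cols += [j, i]
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_groups, membership = connected_components(graph, directed=False)

    merged: list[CentrosomeRegion] = []
    for g in sorted(set(membership), key=lambda g: int(np.argmax(membership == g))):
        members = [regions[i] for i in range(n) if membership[i] == g]
        peaks = sorted((p for m in members for p in m.peaks),
                       key=lambda p: (-p.brightness, p.row, p.col))
        pixels = _sorted_pixels(np.unique(
            np.vstack([m.pixels for m in members]), axis=0))
        merged.append(CentrosomeRegion(cell_id=members[0].cell_id,
                                       centrosome_id=0, peaks=peaks,
                                       pixels=pixels))
    return merged


def filter_small_regions(regions: list[CentrosomeRegion],
                         min_region_area: int) -> list[CentrosomeRegion]:
    """Drop regions with area < ``min_region_area`` (strict); order kept."""
    return [r for r in regions if r.area >= min_region_area]


def detect_centrosomes(stack: ImageStack, labels: CellLabelMap,
                       config: DetectionConfig | None = None,
                       gamma_channel: str = "gamma") -> list[CentrosomeRegion]:
    """Run the full per-cell detection over a segmented field.

    For every cell (ascending label order): blur -> peak finding -> region
    expansion -> merge -> size filter. Peaks flagged ``low_contrast`` (flat
    cells with nothing above their own background plateau) are skipped —
    there is nothing to expand a region around. Centrosome ids are assigned
    1..n per cell in detection order. Deterministic for identical inputs.
    """
    if config is None:
        config = DetectionConfig()
    try:
        gamma_raw = np.asarray(stack.channel(gamma_channel), dtype=np.float64)
    except FormatError:
        raise FormatError(
            f"detection requires a {gamma_channel!r} channel; "
            f"have {sorted(stack.channels)}"
        ) from None
    blurred = blur_channel(gamma_raw, config.blur_sigma)
    measure_raster = blurred if config.measure_on_blurred else gamma_raw

    lab = labels.labels
    objects = ndi.find_objects(lab)
    out: list[CentrosomeRegion] = []
    for cell_idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # Pad the bounding box so expansion can follow the region anywhere
        # inside the cell mask (masks are connected, so the bbox suffices;
        # a 1-px pad guards rounding at the slice edge).
        sl = tuple(slice(max(s.start - 1, 0), min(s.stop + 1, dim))
                   for s, dim in zip(sl, lab.shape))
        cell_mask = lab[sl] == cell_idx
        if not cell_mask.any():
            continue
        offset = np.array([s.start for s in sl])
        peaks = find_peaks_in_cell(blurred[sl], cell_mask, config)

        regions = []
        peaks = [p for p in peaks if not p.low_contrast]
        for k, peak in enumerate(peaks, start=1):
            brightness = float(measure_raster[sl][peak.row, peak.col])
            pixels = expand_region(measure_raster[sl], peak.coord, cell_mask,
                                   config.expansion_fraction)
            regions.append(CentrosomeRegion(
                cell_id=cell_idx, centrosome_id=k,
                peaks=[Peak(peak.row, peak.col, brightness, peak.low_contrast)],
                pixels=pixels))
        regions = merge_close_peaks(regions, config.merge_distance)
        regions = filter_small_regions(regions, config.min_region_area)
        for k, region in enumerate(regions, start=1):
            region.centrosome_id = k
            region.pixels = region.pixels + offset
            region.peaks = [Peak(p.row + offset[0], p.col + offset[1],
                                 p.brightness, p.low_contrast)
                            for p in region.peaks]
        out.extend(regions)
    return out


def regions_to_dataframe(regions: list[CentrosomeRegion]) -> pd.DataFrame:
    """Tabulate regions (peak coordinates are 0-based row/col of the
    brightest peak)."""
    rows = []
    for r in regions:
        p = r.peaks[0]
        rows.append(dict(cell_id=r.cell_id, centrosome_id=r.centrosome_id,
                         peak_row=p.row, peak_col=p.col,
                         peak_brightness=r.peak_brightness,
                         n_peaks=len(r.peaks), area=r.area))
    return pd.DataFrame(rows, columns=["cell_id", "centrosome_id", "peak_row",
                                       "peak_col", "peak_brightness",
                                       "n_peaks", "area"])


def regions_to_label_map(regions: list[CentrosomeRegion],
                         shape: tuple[int, int]) -> np.ndarray:
    """Raster with each region painted by a consecutive id (row order of
    :func:`regions_to_dataframe`)."""
    out = np.zeros(shape, dtype=np.int32)
    for i, r in enumerate(regions, start=1):
        out[r.pixels[:, 0], r.pixels[:, 1]] = i
    return out
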