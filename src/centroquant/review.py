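"""Review bookkeeping and the cell-eligibility filter feeding the statistics.

Detected centrosomes are labeled ``cell_number-centrosome_number`` for
visual review; a verdict table then removes false positives and may add
manually drawn regions for false negatives. After review, the
stage-comparison analysis keeps only cells with exactly two distinct
centrosomes, so that every cell contributes a balanced pair of nested
measurements to the random-intercept model. Review always runs before the
eligibility filter (the two are order-sensitive).

On synthetic data, :func:`annotations_from_truth` plays the role of the
human reviewer: a detected region whose peaks match no ground-truth spot of
its cell is a false positive.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError
from .quantify import RECORD_COLUMNS, measure_roi_mean

__all__ = ["ReviewAnnotation", "CellRecord", "parse_label", "apply_review",
           "select_two_centrosome_cells", "annotations_from_truth"]

# hyphen, en-dash or minus between the two numbers
_LABEL_RE = re.compile(r"^\s*(\d+)\s*[-–−]\s*(\d+)\s*$")

CONFIRMED = "confirmed"
FALSE_POSITIVE = "false_positive"


@dataclass
class ReviewAnnotation:
    """One review verdict.

    ``label`` is ``cell_number-centrosome_number`` (hyphen or en-dash). A
    ``confirmed`` or ``false_positive`` verdict must reference an existing
    record; an annotation with ``polygon`` set is an addition — a manually
    drawn region for a false-negative centrosome of an existing cell, to be
    measured and appended.
    """

    label: str
    verdict: str = CONFIRMED
    polygon: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.verdict not in (CONFIRMED, FALSE_POSITIVE):
            raise AnnotationError(f"unknown verdict {self.verdict!r}")


@dataclass
class CellRecord:
    """Per-cell summary after review: eligibility for the stage comparison
    requires exactly two centrosomes."""

    image_id: str
    cell_id: int
    stage: str
    n_centrosomes: int

    @property
    def eligible(self) -> bool:
        return self.n_centrosomes == 2


def parse_label(label: str) -> tuple[int, int]:
    m = _LABEL_RE.match(str(label))
    if not m:
        raise AnnotationError(
            f"label {label!r} does not parse as cell_number-centrosome_number")
    return int(m.group(1)), int(m.group(2))


def apply_review(records: pd.DataFrame,
                 annotations: list[ReviewAnnotation],
                 raster: np.ndarray | None = None,
                 channel: str = "target",
                 image_id: str | None = None) -> pd.DataFrame:
    """Apply review verdicts to a measurement table.

    False-positive records are dropped; addition polygons are measured on
    ``raster`` and appended as confirmed records; surviving reviewed records
    are marked ``confirmed``. Annotations referencing unknown cells raise
    :class:`AnnotationError` listing every orphan label.
    """
    out = records.copy()
    known_cells = set(out.cell_id.astype(int))
    keyed = {(int(c), int(k)): i
             for i, (c, k) in enumerate(zip(out.cell_id, out.centrosome_id))}

    orphans = []
    drops: list[int] = []
    confirms: list[int] = []
    additions = []
    for ann in annotations:
        cell, cent = parse_label(ann.label)
        if ann.polygon is not None:
            if cell not in known_cells:
                orphans.append(ann.label)
                continue
            if (cell, cent) in keyed:
                raise AnnotationError(
                    f"addition {ann.label!r} collides with an existing centrosome")
            additions.append((cell, cent, ann.polygon))
        else:
            idx = keyed.get((cell, cent))
            if idx is None:
                orphans.append(ann.label)
            elif ann.verdict == FALSE_POSITIVE:
                drops.append(idx)
            else:
                confirms.append(idx)
    if orphans:
        raise AnnotationError(
            f"annotations reference unknown (cell, centrosome) pairs: {orphans}")

    review_col = out.columns.get_loc("review")
    for idx in confirms:
        out.iat[idx, review_col] = CONFIRMED
    if drops:
        out = out.drop(out.index[drops])

    if additions:
        if raster is None:
            raise InputError("addition annotations require the image raster")
        template = records.iloc[0]
        new_rows = []
        for cell, cent, polygon in additions:
            cell_rows = records.loc[records.cell_id == cell]
            stage = cell_rows.stage.iloc[0] if not cell_rows.empty else "unknown"
            transfected = bool(cell_rows.transfected.iloc[0]) \
                if not cell_rows.empty else False
            new_rows.append(dict(
                image_id=image_id or template.image_id, cell_id=cell,
                centrosome_id=cent,
                mean_fluorescence=measure_roi_mean(raster, polygon),
                channel=channel, stage=stage, transfected=transfected,
                review=CONFIRMED))
        out = pd.concat([out, pd.DataFrame(new_rows, columns=RECORD_COLUMNS)],
                        ignore_index=False)
    return out.reset_index(drop=True)


def select_two_centrosome_cells(records: pd.DataFrame):
    """Keep only cells whose post-review centrosome count is exactly 2.

    Returns ``(filtered_records, summary)`` where ``summary`` maps each
    stage (plus ``"total"``) to the before/after tallies
    ``{cells_before, peaks_before, cells_after, peaks_after}``; after the
    filter, ``peaks_after == 2 * cells_after`` by construction.
    """
    if records.empty:
        empty = {"total": dict(cells_before=0, peaks_before=0,
                               cells_after=0, peaks_after=0)}
        return records.copy(), empty

    counts = (records.groupby(["image_id", "cell_id"], sort=True)
              .agg(n=("centrosome_id", "size"), stage=("stage", "first")))
    eligible = counts.index[counts.n == 2]
    keep = records.set_index(["image_id", "cell_id"]).index.isin(eligible)
    filtered = records.loc[keep].reset_index(drop=True)

    summary: dict[str, dict[str, int]] = {}
    for stage, sub in counts.groupby("stage", sort=True):
        kept = sub.loc[sub.n == 2]
        summary[str(stage)] = dict(
            cells_before=int(len(sub)), peaks_before=int(sub.n.sum()),
            cells_after=int(len(kept)), peaks_after=int(kept.n.sum()))
    summary["total"] = {
        key: sum(s[key] for stage, s in summary.items() if stage != "total")
        for key in ("cells_before", "peaks_before", "cells_after",
                    "peaks_after")}
    return filtered, summary


def annotations_from_truth(regions, spots: pd.DataFrame,
                           tol: float = 4.0) -> list[ReviewAnnotation]:
    """Emulate the reviewer on synthetic data.

    A region is confirmed when at least one of its peaks lies within ``tol``
    pixels of a ground-truth spot of the same cell, otherwise it is a false
    positive (typically a background fluctuation picked up as a second
    peak in a one-centrosome cell).
    """
    annotations = []
    for region in regions:
        cell_spots = spots.loc[spots.cell_id == region.cell_id]
        ok = any(
            math.dist((p.row, p.col), (s.row, s.col)) <= tol
            for p in region.peaks
            for s in cell_spots.itertuples())
        annotations.append(ReviewAnnotation(
            label=f"{region.cell_id}-{region.centrosome_id}",
            verdict=CONFIRMED if ok else FALSE_POSITIVE))
    return annotations
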