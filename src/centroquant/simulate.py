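"""Synthetic multi-channel fluorescence fields with ground truth.

The simulator emulates the images the pipeline was designed for: a field of
non-overlapping cells, each carrying a centriole pair visible as 1-2
diffraction-limited spots in the gamma-tubulin channel. The same spot
positions appear in a target-protein channel whose amplitude depends on
cell-cycle stage: mitotic centrosomes carry ``1/stage_fold`` of the
interphase target amplitude (default fold 2, i.e. mitotic signal halved).
A DNA channel holds nuclear blobs (condensed bars for mitotic cells) and is
rendered for segmentation and visual sanity only — stage labels always come
from the ground-truth table, never from pixels.

Geometry conventions: interphase cells carry one centriole pair separated by
a few pixels (sometimes unresolvable, sometimes resolvable but close enough
that the detector merges the pair into one centrosome); mitotic cells carry
two well-separated spindle poles. This reproduces the mixture of one- and
two-centrosome cells that the downstream eligibility filter acts on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InfeasibleTallyError, ParameterError, PlacementError
from .io import CellLabelMap, ImageStack

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_field",
    "generate_peak_count_table",
    "peak_counts_to_records",
    "simulate_measurement_records",
    "cell_polygon",
]

INTERPHASE = "interphase"
MITOSIS = "mitosis"


@dataclass
class SimulationParams:
    """Parameters of one synthetic field.

    Amplitudes are in arbitrary intensity units above background; lengths in
    pixels. ``centriole_separation_range`` governs interphase centriole
    pairs, ``mitotic_separation_range`` the distance between spindle poles.
    ``stage_fold`` is the interphase/mitotic target-amplitude ratio.
    ``mitotic_gamma_factor`` optionally brightens mitotic gamma-tubulin spots
    (real mitotic centrosomes recruit more pericentriolar material); the
    default leaves gamma stage-independent.
    """

    field_shape: tuple[int, int] = (800, 800)
    n_cells: int = 24
    cell_radius_range: tuple[float, float] = (28.0, 40.0)
    fraction_mitotic: float = 0.4
    centriole_separation_range: tuple[float, float] = (3.0, 16.0)
    mitotic_separation_range: tuple[float, float] = (20.0, 40.0)
    spot_sigma: float = 4.0
    gamma_amplitude: float = 400.0
    target_amplitude_interphase: float = 600.0
    stage_fold: float = 2.0
    background_level: float = 8.0
    cytoplasm_level: float = 20.0
    nucleus_amplitude: float = 300.0
    noise_model: str = "gaussian"
    noise_scale: float = 6.0
    golgi_clutter: bool = True
    gamma_debris_rate: float = 0.6
    mitotic_gamma_factor: float = 1.0
    cell_amplitude_cv: float = 0.10
    spot_amplitude_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise_model {self.noise_model!r}")
        if not (0.0 <= self.fraction_mitotic <= 1.0):
            raise ParameterError("fraction_mitotic must lie in [0, 1]")
        if self.stage_fold <= 0:
            raise ParameterError("stage_fold must be positive")
        for name in ("cell_radius_range", "centriole_separation_range",
                     "mitotic_separation_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ParameterError(f"{name} must be a non-negative (lo, hi) range")
        for name in ("spot_sigma", "gamma_amplitude", "target_amplitude_interphase",
                     "background_level", "cytoplasm_level", "noise_scale",
                     "gamma_debris_rate", "mitotic_gamma_factor"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be at least 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_shape"] = list(self.field_shape)
        for k in ("cell_radius_range", "centriole_separation_range",
                  "mitotic_separation_range"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for k in ("field_shape", "cell_radius_range", "centriole_separation_range",
                  "mitotic_separation_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Truth tables for one synthetic field.

    ``cells`` has one row per cell (cell_id, stage, center_row, center_col,
    radius); ``spots`` one row per rendered centriole/pole spot (cell_id,
    spot_id, row, col, gamma_amplitude, target_amplitude) with sub-pixel
    centers. ``label_map`` repeats the footprint raster for convenience.
    """

    cells: pd.DataFrame
    spots: pd.DataFrame
    label_map: np.ndarray
    params: SimulationParams | None = None

    def write(self, directory) -> None:
        directory = Path(directory)
        self.cells.to_csv(directory / "truth_cells.csv", index=False)
        self.spots.to_csv(directory / "truth_spots.csv", index=False)

    def stage_of(self, cell_id: int) -> str:
        row = self.cells.loc[self.cells.cell_id == cell_id]
        if row.empty:
            raise KeyError(f"no cell {cell_id} in ground truth")
        return row.stage.iloc[0]


def _render_gaussian(img: np.ndarray, center: tuple[float, float],
                     amplitude: float, sigma: float, truncate: float = 4.0) -> None:
    """Add an isotropic 2D Gaussian, evaluated analytically per pixel and
    truncated at ``truncate * sigma``."""
    h, w = img.shape
    cr, cc = center
    r = truncate * sigma
    r0, r1 = max(0, int(math.floor(cr - r))), min(h, int(math.ceil(cr + r)) + 1)
    c0, c1 = max(0, int(math.floor(cc - r))), min(w, int(math.ceil(cc + r)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None] - cr
    cols = np.arange(c0, c1)[None, :] - cc
    d2 = rows ** 2 + cols ** 2
    patch = amplitude * np.exp(-d2 / (2.0 * sigma ** 2))
    patch[d2 > r ** 2] = 0.0
    img[r0:r1, c0:c1] += patch


def _render_bar(img: np.ndarray, center: tuple[float, float], angle: float,
                amplitude: float, sigma_long: float, sigma_short: float) -> None:
    """Anisotropic Gaussian bar (condensed mitotic chromatin)."""
    h, w = img.shape
    cr, cc = center
    r = 4.0 * max(sigma_long, sigma_short)
    r0, r1 = max(0, int(math.floor(cr - r))), min(h, int(math.ceil(cr + r)) + 1)
    c0, c1 = max(0, int(math.floor(cc - r))), min(w, int(math.ceil(cc + r)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None] - cr
    cols = np.arange(c0, c1)[None, :] - cc
    u = rows * math.cos(angle) + cols * math.sin(angle)
    v = -rows * math.sin(angle) + cols * math.cos(angle)
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -(u ** 2 / (2 * sigma_long ** 2) + v ** 2 / (2 * sigma_short ** 2))
    )


def _place_cells(params: SimulationParams, rng: np.random.Generator):
    h, w = params.field_shape
    lo, hi = params.cell_radius_range
    centers, radii = [], []
    max_attempts = 500 * params.n_cells
    attempts = 0
    gap = 4.0
    while len(centers) < params.n_cells:
        if attempts >= max_attempts:
            density = sum(math.pi * r ** 2 for r in radii) / (h * w)
            raise PlacementError(
                f"placed only {len(centers)}/{params.n_cells} cells after "
                f"{max_attempts} attempts (area fill so far {density:.2f}); "
                "reduce n_cells or cell_radius_range for this field_shape"
            )
        attempts += 1
        r = rng.uniform(lo, hi)
        if 2 * r + 2 > min(h, w):
            raise PlacementError(
                f"cell radius {r:.0f} px cannot fit in field {params.field_shape}"
            )
        cr = rng.uniform(r + 1, h - r - 1)
        cc = rng.uniform(r + 1, w - r - 1)
        ok = all((cr - pr) ** 2 + (cc - pc) ** 2 > (r + prr + gap) ** 2
                 for (pr, pc), prr in zip(centers, radii))
        if ok:
            centers.append((cr, cc))
            radii.append(r)
    return centers, radii


def _spot_pair(center, radius, separation, rng, perinuclear: bool):
    """Sample two spot centers inside the footprint (margin 3 px)."""
    cr, cc = center
    margin = radius - 3.0
    for _ in range(200):
        theta = rng.uniform(0, 2 * math.pi)
        if perinuclear:
            off = rng.uniform(0.0, 0.35 * radius)
            phi = rng.uniform(0, 2 * math.pi)
            pcr = cr + off * math.cos(phi)
            pcc = cc + off * math.sin(phi)
        else:
            pcr, pcc = cr, cc
        dr = 0.5 * separation * math.cos(theta)
        dc = 0.5 * separation * math.sin(theta)
        s1 = (pcr + dr, pcc + dc)
        s2 = (pcr - dr, pcc - dc)
        if all((sr - cr) ** 2 + (sc - cc) ** 2 <= margin ** 2 for sr, sc in (s1, s2)):
            return s1, s2
    # Dense geometry: fall back to a centered pair with capped separation.
    sep = min(separation, 2 * margin - 1)
    theta = rng.uniform(0, 2 * math.pi)
    dr, dc = 0.5 * sep * math.cos(theta), 0.5 * sep * math.sin(theta)
    return (cr + dr, cc + dc), (cr - dr, cc - dc)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplicative jitter."""
    if cv <= 0:
        return 1.0
    s = math.sqrt(math.log(1.0 + cv ** 2))
    return float(rng.lognormal(-0.5 * s ** 2, s))


def generate_field(params: SimulationParams):
    """Render one synthetic field.

    Returns
    -------
    (ImageStack, CellLabelMap, GroundTruth)
        Channels ``dna``, ``gamma``, ``target``; the label map equals the
        ground-truth footprints; the truth tables are complete. Identical
        params (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.field_shape
    centers, radii = _place_cells(params, rng)
    n = params.n_cells

    n_mitotic = int(round(params.fraction_mitotic * n))
    stages = np.array([MITOSIS] * n_mitotic + [INTERPHASE] * (n - n_mitotic))
    stages = stages[rng.permutation(n)]

    labels = np.zeros((h, w), dtype=np.int32)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    for i, ((cr, ccen), r) in enumerate(zip(centers, radii), start=1):
        disc = (rr - cr) ** 2 + (cc - ccen) ** 2 <= r ** 2
        labels[disc] = i

    dna = np.full((h, w), params.background_level, dtype=np.float64)
    gamma = np.full((h, w), params.background_level, dtype=np.float64)
    target = np.full((h, w), params.background_level, dtype=np.float64)
    target[labels > 0] += params.cytoplasm_level

    cell_rows, spot_rows = [], []
    for i in range(n):
        cell_id = i + 1
        center, radius = centers[i], radii[i]
        stage = stages[i]
        mitotic = stage == MITOSIS
        cell_factor = _lognormal_factor(rng, params.cell_amplitude_cv)

        sep_range = (params.mitotic_separation_range if mitotic
                     else params.centriole_separation_range)
        separation = rng.uniform(*sep_range)
        s1, s2 = _spot_pair(center, radius, separation, rng,
                            perinuclear=not mitotic)

        base_target = params.target_amplitude_interphase / (
            params.stage_fold if mitotic else 1.0)
        base_gamma = params.gamma_amplitude * (
            params.mitotic_gamma_factor if mitotic else 1.0)
        for spot_id, (sr, sc) in enumerate((s1, s2), start=1):
            g_amp = base_gamma * _lognormal_factor(rng, params.spot_amplitude_cv)
            t_amp = (base_target * cell_factor
                     * _lognormal_factor(rng, params.spot_amplitude_cv))
            _render_gaussian(gamma, (sr, sc), g_amp, params.spot_sigma)
            _render_gaussian(target, (sr, sc), t_amp, params.spot_sigma)
            spot_rows.append(dict(cell_id=cell_id, spot_id=spot_id,
                                  row=sr, col=sc,
                                  gamma_amplitude=g_amp, target_amplitude=t_amp))

        # DNA: one soft nucleus for interphase, two condensed bars (a
        # metaphase plate) for mitosis. Visual/segmentation use only.
        if mitotic:
            axis = math.atan2(s2[0] - s1[0], s2[1] - s1[1])
            plate = axis + math.pi / 2
            for side in (-1.0, 1.0):
                bc = (center[0] + side * 1.8 * math.sin(plate + math.pi / 2),
                      center[1] + side * 1.8 * math.cos(plate + math.pi / 2))
                _render_bar(dna, bc, plate, params.nucleus_amplitude * 1.5,
                            sigma_long=0.30 * radius, sigma_short=2.5)
        else:
            _render_gaussian(dna, center, params.nucleus_amplitude,
                             sigma=0.40 * radius)

        # Small bright specks in the gamma channel: the debris the blur step
        # and the minimum-area filter exist to reject.
        n_debris = rng.poisson(params.gamma_debris_rate)
        for _ in range(n_debris):
            phi = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.8 * radius)
            pos = (center[0] + rad * math.sin(phi), center[1] + rad * math.cos(phi))
            amp = rng.uniform(0.3, 0.6) * params.gamma_amplitude
            _render_gaussian(gamma, pos, amp, sigma=1.0)

        # Golgi-like perinuclear clutter in the target channel, kept clear
        # of the spot centers.
        if params.golgi_clutter:
            n_clutter = rng.integers(3, 7)
            for _ in range(n_clutter):
                for _try in range(30):
                    phi = rng.uniform(0, 2 * math.pi)
                    rad = rng.uniform(0.40, 0.65) * radius
                    pos = (center[0] + rad * math.sin(phi),
                           center[1] + rad * math.cos(phi))
                    clear = all(
                        (pos[0] - sr) ** 2 + (pos[1] - sc) ** 2
                        >= (3.5 * params.spot_sigma) ** 2
                        for sr, sc in (s1, s2))
                    if clear:
                        break
                else:
                    continue
                amp = rng.uniform(0.15, 0.30) * params.target_amplitude_interphase
                _render_gaussian(target, pos, amp, sigma=2.5)

        cell_rows.append(dict(cell_id=cell_id, stage=stage,
                              center_row=center[0], center_col=center[1],
                              radius=radius))

    channels = {"dna": dna, "gamma": gamma, "target": target}
    if params.noise_model == "gaussian":
        for name in channels:
            noisy = channels[name] + rng.normal(0.0, params.noise_scale,
                                                size=(h, w))
            channels[name] = np.clip(noisy, 0.0, None)
    elif params.noise_model == "poisson":
        for name in channels:
            channels[name] = rng.poisson(channels[name]).astype(np.float64)

    channels = {k: v.astype(np.float32) for k, v in channels.items()}
    stack = ImageStack(channels=channels,
                       provenance=f"centroquant simulation seed={params.seed}")
    truth = GroundTruth(cells=pd.DataFrame(cell_rows),
                        spots=pd.DataFrame(spot_rows),
                        label_map=labels, params=params)
    return stack, CellLabelMap(labels=labels, source="ground_truth"), truth


def generate_peak_count_table(tallies: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Reconstruct per-cell peak counts from per-stage (cells, peaks) tallies.

    Each cell carries 1 or 2 peaks (the detector's contract), so a tally of
    ``n_cells`` cells with ``n_peaks`` total peaks has the unique solution of
    ``k = n_peaks - n_cells`` two-peak cells and ``n_cells - k`` one-peak
    cells. Raises :class:`InfeasibleTallyError` when no {1,2}-valued
    assignment exists.
    """
    rows = []
    cell_id = 1
    for stage, (n_cells, n_peaks) in tallies.items():
        if n_cells < 0 or n_peaks < 0:
            raise InfeasibleTallyError(f"{stage}: negative tally")
        if n_peaks < n_cells or n_peaks > 2 * n_cells:
            raise InfeasibleTallyError(
                f"{stage}: {n_peaks} peaks over {n_cells} cells has no "
                "per-cell assignment with counts in {1, 2}"
            )
        k = n_peaks - n_cells
        for i in range(n_cells):
            rows.append(dict(stage=stage, cell_id=cell_id,
                             n_peaks=2 if i < k else 1))
            cell_id += 1
    return pd.DataFrame(rows, columns=["stage", "cell_id", "n_peaks"])


def peak_counts_to_records(counts: pd.DataFrame,
                           image_id: str = "tally") -> pd.DataFrame:
    """Expand a per-cell peak-count table into per-centrosome measurement
    records (placeholder fluorescence), one row per peak."""
    rows = []
    for _, cell in counts.iterrows():
        for j in range(int(cell.n_peaks)):
            rows.append(dict(image_id=image_id, cell_id=int(cell.cell_id),
                             centrosome_id=j + 1, mean_fluorescence=0.0,
                             channel="target", stage=cell.stage,
                             transfected=False, review="unreviewed"))
    return pd.DataFrame(rows)


def simulate_measurement_records(n_cells_per_stage: int,
                                 mean_interphase: float,
                                 stage_effect: float,
                                 sigma_u: float,
                                 sigma_e: float,
                                 n_per_cell: int = 2,
                                 seed: int = 0) -> pd.DataFrame:
    """Record-level generator for the random-intercept model.

    Draws ``y_ij = beta0 + beta1 * 1[mitosis] + u_i + e_ij`` with
    ``u_i ~ N(0, sigma_u^2)`` per cell and ``e_ij ~ N(0, sigma_e^2)`` per
    centrosome, two centrosomes per cell by default. Used for statistical
    calibration where rendering pixels would add nothing.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cell_id = 1
    for stage in (INTERPHASE, MITOSIS):
        for _ in range(n_cells_per_stage):
            u = rng.normal(0.0, sigma_u)
            mu = mean_interphase + (stage_effect if stage == MITOSIS else 0.0) + u
            for j in range(n_per_cell):
                rows.append(dict(image_id="sim", cell_id=cell_id,
                                 centrosome_id=j + 1,
                                 mean_fluorescence=mu + rng.normal(0.0, sigma_e),
                                 channel="target", stage=stage,
                                 transfected=False, review="confirmed"))
            cell_id += 1
    return pd.DataFrame(rows)


def cell_polygon(truth: GroundTruth, cell_id: int,
                 n_vertices: int = 24) -> np.ndarray:
    """Polygon (x, y vertex array) tracing a cell footprint, for exercising
    the manual-ROI measurement path on synthetic data."""
    row = truth.cells.loc[truth.cells.cell_id == cell_id]
    if row.empty:
        raise KeyError(f"no cell {cell_id} in ground truth")
    cr, cc, r = (row.center_row.iloc[0], row.center_col.iloc[0],
                 row.radius.iloc[0] - 0.5)
    angles = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    xs = cc + r * np.cos(angles)
    ys = cr + r * np.sin(angles)
    return np.column_stack([xs, ys])
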