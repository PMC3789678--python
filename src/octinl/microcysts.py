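"""Detection and topography of hyporeflective INL microcysts.

A microcyst is a well-circumscribed dark space confined to the INL band,
elongated perpendicular to the retinal layers.  Detection thresholds
pixels of the INL band against a rolling local INL median (robust to
lateral shading), keeps connected components that are large enough, fully
inside the band, at least near-round-to-axially-elongated, and whose rim is
distinctly brighter than their interior ("well-circumscribed"), then
localizes each kept component on the radial grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, median_filter
from skimage import measure

from .bscan import BScan
from .protocol import RadialProtocol
from .segmentation import LayerBoundaries

log = logging.getLogger(__name__)

CYST_COLUMNS = [
    "slice_index",
    "line",
    "centroid_col_px",
    "centroid_row_px",
    "eccentricity_um",
    "area_px2",
    "area_um2",
    "axial_um",
    "lateral_um",
    "contrast",
]


@dataclass
class CystDetectionParams:
    hypo_fraction: float = 0.35  # candidate if below (1 - c) * local INL median
    median_window_columns: int = 201
    min_area_px: int = 6
    min_elongation: float = 0.8  # axial extent >= this * lateral extent (um)
    min_rim_contrast: float = 1.3
    rim_dilation_px: int = 2
    band_margin_px: float = 0.5
    vessel_margin_columns: int = 2  # exclusion halo around vessel shadows


@dataclass
class MicrocystSet:
    """Detected cysts of one eye (possibly empty)."""

    cysts: pd.DataFrame  # one row per cyst, CYST_COLUMNS
    subject: str = ""
    eye: str = ""

    @property
    def count(self) -> int:
        return len(self.cysts)

    @property
    def has_microcysts(self) -> bool:
        return self.count > 0


def _local_inl_median(
    scan: BScan, band: np.ndarray, window: int
) -> np.ndarray:
    """Per-column local median intensity of the INL band, smoothed laterally."""
    col_med = np.full(scan.n_ascans, np.nan)
    has = band.any(axis=0)
    if has.any():
        px = np.where(band[:, has], scan.pixels[:, has], np.nan)
        col_med[has] = np.nanmedian(px, axis=0)
    cols = np.arange(scan.n_ascans)
    ok = np.isfinite(col_med)
    if not ok.any():
        return np.full(scan.n_ascans, np.nan)
    col_med[~ok] = np.interp(cols[~ok], cols[ok], col_med[ok])
    win = min(window, 2 * (scan.n_ascans // 2) - 1)
    return median_filter(col_med, size=win, mode="nearest")


def detect_microcysts(
    scan: BScan,
    boundaries: LayerBoundaries,
    params: CystDetectionParams | None = None,
    protocol: RadialProtocol | None = None,
) -> MicrocystSet:
    """Find INL microcysts on one B-scan.

    Regions where the INL boundaries failed are excluded from the search
    (logged), never searched with fabricated boundaries.
    """
    params = params or CystDetectionParams()
    protocol = protocol or RadialProtocol()
    empty = MicrocystSet(
        cysts=pd.DataFrame(columns=CYST_COLUMNS), subject=scan.subject, eye=scan.eye
    )
    if boundaries.failed["GCLIPL_INL"] or boundaries.failed["INL_OPL"]:
        log.warning("INL boundaries failed on slice %d; cyst search skipped",
                    scan.slice_index)
        return empty

    top = boundaries.depths["GCLIPL_INL"]
    bot = boundaries.depths["INL_OPL"]
    rows = np.arange(scan.depth_px, dtype=float)[:, None]
    m = params.band_margin_px
    band = (rows >= top[None, :] + m) & (rows + 1.0 <= bot[None, :] - m)
    # columns darkened by vessel shadows mimic cysts; exclude them (+halo)
    vess = boundaries.provenance.copy()
    if vess.any() and params.vessel_margin_columns:
        vess = binary_dilation(vess, iterations=params.vessel_margin_columns)
    band &= ~vess[None, :]
    if not band.any():
        return empty

    local_med = _local_inl_median(scan, band, params.median_window_columns)
    thr = (1.0 - params.hypo_fraction) * local_med[None, :]
    candidates = band & (scan.pixels < thr)
    if not candidates.any():
        return empty

    labels = measure.label(candidates, connectivity=2)
    records = []
    ax_um = scan.axial_um_per_px
    lat_um = scan.lateral_um_per_px
    for region in measure.regionprops(labels):
        if region.area < params.min_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        axial = (r1 - r0) * ax_um
        lateral = (c1 - c0) * lat_um
        if axial < params.min_elongation * lateral:
            continue
        comp = labels == region.label
        rim = binary_dilation(comp, iterations=params.rim_dilation_px) & ~comp & band
        interior = float(scan.pixels[comp].mean())
        if not rim.any() or interior <= 0:
            continue
        contrast = float(scan.pixels[rim].mean()) / interior
        if contrast < params.min_rim_contrast:
            continue
        rc, cc = region.centroid
        # template lateral coordinate: mirror OS scans
        x_um = (cc + 0.5 - boundaries.fovea_column - 0.5) * lat_um
        side_img = 1 if x_um >= 0 else -1
        side = side_img if scan.laterality == "OD" else -side_img
        line = protocol.line_for(scan.slice_index, side)
        med_here = float(local_med[int(round(cc))])
        depth_contrast = (
            max(0.0, min(1.0, 1.0 - interior / med_here)) if med_here > 0 else 1.0
        )
        records.append(
            {
                "slice_index": scan.slice_index,
                "line": line,
                "centroid_col_px": cc,
                "centroid_row_px": rc,
                "eccentricity_um": abs(x_um),
                "area_px2": int(region.area),
                "area_um2": float(region.area * ax_um * lat_um),
                "axial_um": axial,
                "lateral_um": lateral,
                "contrast": depth_contrast,
            }
        )
    return MicrocystSet(
        cysts=pd.DataFrame(records, columns=CYST_COLUMNS),
        subject=scan.subject,
        eye=scan.eye,
    )


def merge_eye_cysts(per_slice: list[MicrocystSet], subject: str = "", eye: str = "") -> MicrocystSet:
    """Concatenate per-slice detections into one eye-level set."""
    frames = [s.cysts for s in per_slice if len(s.cysts)]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CYST_COLUMNS)
    )
    return MicrocystSet(cysts=table, subject=subject, eye=eye)


@dataclass
class CohortCystSummary:
    n_eyes: int
    n_eyes_with_cysts: int
    prevalence_pct: int  # nearest integer percent
    quadrant_counts: dict[str, int]
    mean_axial_um: float
    mean_lateral_um: float


def cohort_cyst_summary(
    eye_sets: list[MicrocystSet], protocol: RadialProtocol | None = None
) -> CohortCystSummary:
    """Cohort prevalence and topography of detected microcysts.

    Prevalence is 100 x (eyes with at least one cyst) / (eyes analyzed),
    reported to the nearest integer percent.  Raises on zero analyzed eyes.
    """
    protocol = protocol or RadialProtocol()
    if not eye_sets:
        raise ValueError("prevalence undefined: zero analyzed eyes")
    n_pos = sum(1 for s in eye_sets if s.has_microcysts)
    quad = {q: 0 for q in
            ("supero-nasal", "infero-nasal", "supero-temporal", "infero-temporal")}
    axial, lateral = [], []
    for s in eye_sets:
        for _, row in s.cysts.iterrows():
            quad[protocol.quadrant_of_line(int(row.line))] += 1
            axial.append(row.axial_um)
            lateral.append(row.lateral_um)
    return CohortCystSummary(
        n_eyes=len(eye_sets),
        n_eyes_with_cysts=n_pos,
        prevalence_pct=int(round(100.0 * n_pos / len(eye_sets))),
        quadrant_counts=quad,
        mean_axial_um=float(np.mean(axial)) if axial else float("nan"),
        mean_lateral_um=float(np.mean(lateral)) if lateral else float("nan"),
    )
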