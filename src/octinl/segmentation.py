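"""Automated retinal layer segmentation of paramacular radial B-scans.

Pipeline per scan: scan quality gate -> vessel shadow detection and removal
-> multiple-size median filtering -> Canny edge detection with quantile
hysteresis thresholds -> conversion of the edge/gradient field into four
ordered, non-crossing boundary curves (ILM, RNFL/GCL-IPL, GCL-IPL/INL,
INL/OPL) by per-boundary dynamic-programming shortest paths.

Tracing order and bands: the ILM is found first (coarse intensity crossing
refined by DP), then the strong outer ONL/RPE step is traced as a deep
anchor; the flat INL/OPL interface is traced in a band a fixed anatomical
distance above that anchor, which keeps the weak GCL-IPL/INL edge from
being confused with the much stronger OPL/ONL edge in severely thinned
eyes.  RNFL/GCL-IPL and GCL-IPL/INL are then traced in bands between ILM
and INL/OPL.  Bands collapse gracefully at the fovea where the inner layers
converge; ordering (ILM <= RNFL/GCL-IPL <= GCL-IPL/INL <= INL/OPL) holds at
every column by construction.

Coordinates: row 0 is the vitreous (top), depth increases downward,
boundary depth is a fractional pixel at each column centre, 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter1d
from skimage import feature

from .bscan import BScan

log = logging.getLogger(__name__)

BOUNDARY_NAMES = ("ILM", "RNFL_GCLIPL", "GCLIPL_INL", "INL_OPL")

_BIG = 1e6


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain (all config-overridable)."""

    # (axial, lateral) windows: narrow axially so thin bands survive,
    # increasingly wide laterally because boundaries are laterally smooth
    median_sizes: tuple[tuple[int, int], ...] = ((3, 3), (3, 7), (3, 15))
    canny_sigma_px: float = 2.0
    trace_sigma_px: float = 1.2  # narrower gradient for localization
    canny_high_quantile: float = 0.90
    canny_low_fraction: float = 0.5  # low threshold = fraction of high threshold
    vessel_window: int = 61
    vessel_k: float = 2.5
    vessel_dilate: int = 2
    vessel_min_run_um: float = 20.0  # isolated speckle dips are not vessels
    dp_lambda: float = 0.15  # smoothness penalty per pixel of jump
    dp_max_jump: int = 3
    edge_bonus: float = 0.05
    # anatomical search bands, um
    rnfl_max_um: float = 85.0
    min_gcl_gap_um: float = 12.0
    outer_band_um: tuple[float, float] = (60.0, 330.0)  # ONL/RPE below ILM
    inl_opl_above_outer_um: tuple[float, float] = (90.0, 165.0)


@dataclass
class LayerBoundaries:
    """Ordered boundary depth curves for one B-scan.

    ``provenance`` marks columns whose image data was interpolated under a
    detected vessel shadow; ``failed`` flags boundaries for which no
    admissible path existed (deeper boundaries of a failed one are failed
    too, never fabricated).
    """

    depths: dict[str, np.ndarray]  # name -> (W,) fractional pixel rows
    provenance: np.ndarray  # (W,) bool, True = interpolated under vessel
    failed: dict[str, bool]
    fovea_column: float
    outer_reference: np.ndarray | None = None  # traced ONL/RPE anchor

    def __post_init__(self) -> None:
        arrs = [self.depths[n] for n in BOUNDARY_NAMES if n in self.depths]
        for a, b in zip(arrs, arrs[1:]):
            if np.any(b - a < -1e-6):
                raise ValueError("boundary ordering violated")

    def thickness_um(self, upper: str, lower: str, axial_um_per_px: float) -> np.ndarray:
        return (self.depths[lower] - self.depths[upper]) * axial_um_per_px


@dataclass
class QualityThresholds:
    snr_db: float = 25.0
    centration_limit_um: float = 500.0
    uniformity_range: tuple[float, float] = (0.8, 1.25)


@dataclass
class QualityReport:
    snr_db: float
    centration_offset_um: float
    brightness_uniformity: float
    passed: bool


# ---------------------------------------------------------------------------
# coarse landmarks


def _coarse_ilm(image: np.ndarray) -> np.ndarray:
    """First strong downward intensity crossing per column (integer rows)."""
    bg = float(np.quantile(image, 0.10))
    peak = float(np.quantile(image, 0.99))
    th = bg + 0.30 * (peak - bg)
    above = image > th
    first = np.argmax(above, axis=0).astype(float)
    none = ~above.any(axis=0)
    if none.all():
        return np.zeros(image.shape[1])
    if none.any():
        cols = np.arange(image.shape[1])
        first[none] = np.interp(cols[none], cols[~none], first[~none])
    # robust smoothing against isolated speckle hits
    return median_filter(first, size=15, mode="nearest")


def find_fovea_column(ilm_depth: np.ndarray, margin_frac: float = 0.08) -> float:
    """Pit column = deepest point of the (smoothed) ILM away from the edges."""
    w = len(ilm_depth)
    m = max(int(margin_frac * w), 1)
    smooth = gaussian_filter1d(ilm_depth, sigma=max(w / 100.0, 2.0), mode="nearest")
    return float(m + np.argmax(smooth[m : w - m]))


def _retina_band(image: np.ndarray, extent_px: int) -> tuple[np.ndarray, np.ndarray]:
    """(per-column retina top row, band height) used for SNR and vessel stats."""
    top = _coarse_ilm(image)
    return top, np.full(image.shape[1], extent_px)


# ---------------------------------------------------------------------------
# quality gate


def quality_check(
    scan: BScan, thresholds: QualityThresholds | None = None
) -> QualityReport:
    """Operationalized scan quality gate: SNR, centration, brightness uniformity.

    SNR is 10*log10(retina-band signal power / background power) with signal
    measured above the background mean and background power taken as the
    variance of the vitreous region above the retina.  A scan with zero
    background variance reports +inf SNR and passes the SNR criterion.
    """
    thresholds = thresholds or QualityThresholds()
    img = scan.pixels
    extent_px = int(round(350.0 / scan.axial_um_per_px))
    top, _ = _retina_band(img, extent_px)
    rows = np.arange(img.shape[0])[:, None]
    in_band = (rows >= top[None, :]) & (rows < (top + extent_px)[None, :])
    above = rows < np.maximum(top - int(10 / scan.axial_um_per_px), 1)[None, :]
    bg = img[above]
    band = img[in_band]
    bg_mean = float(bg.mean()) if bg.size else 0.0
    bg_power = float(bg.var()) if bg.size else 0.0
    sig_power = float(np.mean((band - bg_mean) ** 2)) if band.size else 0.0
    snr_db = float("inf") if bg_power == 0 else 10.0 * np.log10(sig_power / bg_power)

    fovea = find_fovea_column(_coarse_ilm(img))
    centration = abs(fovea - (img.shape[1] - 1) / 2.0) * scan.lateral_um_per_px

    half = img.shape[1] // 2
    left = img[:, :half][in_band[:, :half]]
    right = img[:, half:][in_band[:, half:]]
    uniformity = float(left.mean() / right.mean()) if right.size and right.mean() > 0 \
        else float("inf")

    lo, hi = thresholds.uniformity_range
    passed = (
        snr_db > thresholds.snr_db
        and centration <= thresholds.centration_limit_um
        and lo <= uniformity <= hi
    )
    return QualityReport(snr_db, centration, uniformity, bool(passed))


# ---------------------------------------------------------------------------
# vessel shadows


def detect_vessel_shadows(scan: BScan, config: SegmentationConfig | None = None) -> np.ndarray:
    """Columns whose retina-band mean intensity drops well below its neighbours.

    A column is flagged when its band mean falls more than ``k`` robust SDs
    below a rolling median of column means; flagged runs are dilated.  The
    band is the *outer* retina (well below the INL): a vessel shadow
    attenuates the full column down to the RPE, whereas an INL microcyst
    darkens only the inner retina, so banding deep separates the two.  The
    statistic is scale-free, so a global intensity rescaling leaves the
    flagged set unchanged.  Returns a sorted integer array (possibly empty).
    """
    config = config or SegmentationConfig()
    img = scan.pixels
    ax = scan.axial_um_per_px
    # one global band: per-column band edges would jitter across the bright
    # RPE and masquerade as intensity dips
    top = int(round(float(np.median(_coarse_ilm(img))) + 190.0 / ax))
    extent_px = int(round(160.0 / ax))
    rows = np.arange(img.shape[0])[:, None]
    in_band = (rows >= top) & (rows < top + extent_px)
    in_band = np.broadcast_to(in_band, img.shape)
    col_mean = np.where(in_band, img, 0.0).sum(axis=0) / np.maximum(
        in_band.sum(axis=0), 1
    )
    win = min(config.vessel_window, 2 * (img.shape[1] // 2) - 1)
    rolling = median_filter(col_mean, size=win, mode="nearest")
    resid = col_mean - rolling
    mad = float(np.median(np.abs(resid - np.median(resid))))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        return np.array([], dtype=int)
    flagged = resid < -config.vessel_k * robust_sd
    min_run = max(2, int(round(config.vessel_min_run_um / scan.lateral_um_per_px)))
    if flagged.any():
        # drop runs shorter than the minimum plausible shadow width
        padded = np.concatenate([[False], flagged, [False]])
        starts = np.flatnonzero(padded[1:] & ~padded[:-1])
        ends = np.flatnonzero(~padded[1:] & padded[:-1])
        for s, e in zip(starts, ends):
            if e - s < min_run:
                flagged[s:e] = False
    if config.vessel_dilate > 0 and flagged.any():
        d = config.vessel_dilate
        idx = np.flatnonzero(flagged)
        for i in idx:
            flagged[max(0, i - d) : i + d + 1] = True
    return np.flatnonzero(flagged)


def remove_vessels(scan: BScan, columns: np.ndarray) -> BScan:
    """Replace flagged columns by per-row linear interpolation between neighbours.

    Unflagged columns are bit-identical to the input.  Runs touching the
    image edge are filled by nearest-neighbour extension (logged).
    """
    columns = np.asarray(columns, dtype=int)
    if columns.size == 0:
        return scan
    w = scan.n_ascans
    bad = np.zeros(w, dtype=bool)
    bad[columns] = True
    if bad.all():
        raise ValueError("all columns flagged as vessels; nothing to interpolate from")
    if bad[0] or bad[-1]:
        log.info("vessel run touches the image edge; nearest-neighbour fill used")
    good = np.flatnonzero(~bad)
    img = scan.pixels.copy()
    # np.interp clamps outside the good range = nearest-neighbour extension
    img[:, bad] = np.array(
        [np.interp(np.flatnonzero(bad), good, row[good]) for row in scan.pixels]
    )
    out = BScan(
        pixels=img,
        axial_um_per_px=scan.axial_um_per_px,
        lateral_um_per_px=scan.lateral_um_per_px,
        slice_index=scan.slice_index,
        fovea_column=scan.fovea_column,
        laterality=scan.laterality,
        subject=scan.subject,
        eye=scan.eye,
    )
    return out


# ---------------------------------------------------------------------------
# filtering and edges


def multiscale_median_filter(
    image: np.ndarray,
    sizes: tuple[int | tuple[int, int], ...] = ((3, 3), (3, 7), (3, 15)),
) -> np.ndarray:
    """Sequential 2-D median filtering with increasing window sizes.

    Each size is either an odd integer (square window) or an (axial,
    lateral) pair of odd integers.  Axially narrow windows preserve thin
    retinal bands (a square window taller than a band erases it) while wide
    lateral windows exploit the lateral smoothness of the layers.
    """
    norm: list[tuple[int, int]] = []
    for s in sizes:
        pair = (s, s) if np.isscalar(s) else tuple(s)
        if len(pair) != 2 or any(v < 3 or v % 2 == 0 for v in pair):
            raise ValueError(
                f"median window sizes must be odd and >= 3, got {s}"
            )
        norm.append(pair)
    out = image
    for pair in norm:
        out = median_filter(out, size=pair, mode="nearest")
    return out


def canny_boundaries(
    image: np.ndarray,
    low_frac: float = 0.5,
    high_quantile: float = 0.90,
    sigma: float = 2.0,
) -> np.ndarray:
    """Canny edge map with hysteresis thresholds set from gradient quantiles.

    The high threshold is the ``high_quantile`` of the Gaussian-gradient
    magnitude; the low threshold is ``low_frac`` times the high threshold.
    Quantile thresholds make the edge map invariant to global gain changes.
    A constant image yields an empty edge map.
    """
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    gr = gaussian_filter1d(image, sigma, axis=0, order=1, mode="nearest")
    gc = gaussian_filter1d(image, sigma, axis=1, order=1, mode="nearest")
    mag = np.hypot(gr, gc)
    high = float(np.quantile(mag, high_quantile))
    if high <= 0:
        return np.zeros(image.shape, dtype=bool)
    low = low_frac * high
    return feature.canny(image, sigma=sigma, low_threshold=low, high_threshold=high)


def row_gradient(image: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Signed axial intensity gradient (positive = brighter with depth)."""
    return gaussian_filter1d(image, sigma, axis=0, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# dynamic-programming boundary tracing


def _dp_path(cost: np.ndarray, lam: float, max_jump: int) -> np.ndarray:
    """Minimum-cost left-to-right path through ``cost`` with |row step| <= max_jump."""
    H, W = cost.shape
    acc = cost[:, 0].copy()
    back = np.zeros((H, W), dtype=np.int8)
    jumps = range(-max_jump, max_jump + 1)
    for c in range(1, W):
        best = np.full(H, np.inf)
        arg = np.zeros(H, dtype=np.int8)
        for dr in jumps:
            shifted = np.full(H, np.inf)
            if dr == 0:
                shifted = acc
            elif dr > 0:
                shifted[dr:] = acc[:-dr]
            else:
                shifted[:dr] = acc[-dr:]
            cand = shifted + lam * abs(dr)
            better = cand < best
            best[better] = cand[better]
            arg[better] = dr
        acc = cost[:, c] + best
        back[:, c] = arg
    path = np.zeros(W, dtype=int)
    path[-1] = int(np.argmin(acc))
    for c in range(W - 1, 0, -1):
        path[c - 1] = path[c] - back[path[c], c]
    return path


def _trace_in_band(
    grad: np.ndarray,
    edges: np.ndarray | None,
    sign: int,
    floor: np.ndarray,
    ceil: np.ndarray,
    config: SegmentationConfig,
) -> np.ndarray | None:
    """DP-trace one boundary inside per-column [floor, ceil] rows.

    Cost favours rows with a strong gradient of the expected polarity (plus
    a small bonus on Canny edge pixels); a smoothness penalty discourages
    jumps.  Returns fractional rows, or None when no admissible band exists.
    """
    H, W = grad.shape
    floor = np.clip(np.round(floor).astype(int), 0, H - 1)
    ceil = np.clip(np.round(ceil).astype(int), 0, H - 1)
    ceil = np.maximum(ceil, floor)
    band_h = int((ceil - floor).max()) + 1
    if band_h <= 0:
        return None

    rows = np.arange(band_h)[:, None] + floor[None, :]
    rows_clipped = np.minimum(rows, H - 1)
    cols = np.broadcast_to(np.arange(W)[None, :], rows.shape)
    signed = sign * grad[rows_clipped, cols]
    cost = -np.clip(signed, 0.0, None)
    if edges is not None:
        cost -= config.edge_bonus * edges[rows_clipped, cols]
    cost[rows > ceil[None, :]] = _BIG
    path_rel = _dp_path(cost, config.dp_lambda, config.dp_max_jump)
    path = path_rel + floor

    # sub-pixel refinement: quadratic fit of the signed gradient around the peak
    refined = path.astype(float)
    r = path
    ok = (r >= 1) & (r <= H - 2) & (r > floor) & (r < ceil)
    idx = np.flatnonzero(ok)
    if idx.size:
        c = np.arange(W)[idx]
        g0 = sign * grad[r[idx] - 1, c]
        g1 = sign * grad[r[idx], c]
        g2 = sign * grad[r[idx] + 1, c]
        denom = g0 - 2 * g1 + g2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * (g0 - g2) / denom
        delta = np.where(np.isfinite(delta), np.clip(delta, -0.5, 0.5), 0.0)
        refined[idx] = r[idx] + delta
    # gradient peaks at pixel-centre index d - 0.5 for a boundary at depth d
    return np.clip(refined + 0.5, floor, ceil)


def trace_layer_boundaries(
    edges: np.ndarray,
    grad: np.ndarray,
    scan: BScan,
    config: SegmentationConfig | None = None,
    vessel_columns: np.ndarray | None = None,
) -> LayerBoundaries:
    """Convert the edge/gradient field into four ordered boundary curves.

    Boundaries that admit no path are flagged failed together with all
    deeper boundaries; a partial result is returned, never fabricated.
    """
    config = config or SegmentationConfig()
    img_for_landmarks = scan.pixels
    # normalize gradient scale so the smoothness penalty (and hence the
    # traced paths) are invariant to global gain changes
    g_scale = float(np.quantile(np.abs(grad), 0.995))
    if g_scale > 0:
        grad = grad / g_scale
    H, W = grad.shape
    ax = scan.axial_um_per_px

    failed = {n: False for n in BOUNDARY_NAMES}
    depths: dict[str, np.ndarray] = {}

    # 1) ILM: coarse crossing refined by DP in a narrow band
    coarse = _coarse_ilm(img_for_landmarks)
    band = 10.0
    ilm = _trace_in_band(
        grad, edges, +1, coarse - band, coarse + band, config
    )
    if ilm is None:
        raise ValueError("no admissible ILM path; scan too degraded to segment")
    depths["ILM"] = ilm
    fovea = scan.fovea_column if scan.fovea_column is not None else \
        find_fovea_column(ilm)

    # 2) deep anchor: strong ONL/RPE step traced below the ILM
    lo, hi = config.outer_band_um
    outer = _trace_in_band(
        grad, None, +1, ilm + lo / ax, np.minimum(ilm + hi / ax, H - 2), config
    )

    # 3) INL/OPL: a fixed anatomical distance above the outer anchor
    if outer is not None:
        a, b = config.inl_opl_above_outer_um
        inl_opl = _trace_in_band(
            grad, edges, +1, outer - b / ax, outer - a / ax, config
        )
    else:
        inl_opl = None
    if inl_opl is None:
        for n in ("INL_OPL", "GCLIPL_INL", "RNFL_GCLIPL"):
            failed[n] = True
        log.warning("outer anchor not found; inner boundaries failed")
        inl_opl = np.minimum(ilm + 170.0 / ax, H - 1.0)
    inl_opl = np.maximum(inl_opl, ilm)  # ordering guard at the pit
    depths["INL_OPL"] = inl_opl

    # 4) RNFL/GCL-IPL between ILM and INL/OPL
    rnfl_ceiling = np.minimum(ilm + config.rnfl_max_um / ax, inl_opl - 2.0)
    rnfl = _trace_in_band(
        grad, edges, -1, ilm + 1.0, np.maximum(rnfl_ceiling, ilm + 1.0), config
    )
    if rnfl is None:
        failed["RNFL_GCLIPL"] = failed["GCLIPL_INL"] = True
        rnfl = ilm + 1.0
    rnfl = np.clip(rnfl, ilm, inl_opl)
    depths["RNFL_GCLIPL"] = rnfl

    # 5) GCL-IPL/INL between RNFL/GCL-IPL and INL/OPL
    gcl_floor = rnfl + config.min_gcl_gap_um / ax
    gcl = _trace_in_band(
        grad, edges, -1, np.minimum(gcl_floor, inl_opl - 1.0),
        np.maximum(inl_opl - 1.0, np.minimum(gcl_floor, inl_opl - 1.0)), config
    )
    if gcl is None:
        failed["GCLIPL_INL"] = True
        gcl = inl_opl - 1.0
    gcl = np.clip(gcl, rnfl, inl_opl)
    depths["GCLIPL_INL"] = gcl

    provenance = np.zeros(W, dtype=bool)
    if vessel_columns is not None and len(vessel_columns):
        provenance[np.asarray(vessel_columns, dtype=int)] = True

    return LayerBoundaries(
        depths=depths,
        provenance=provenance,
        failed=failed,
        fovea_column=float(fovea),
        outer_reference=outer,
    )


# ---------------------------------------------------------------------------
# orchestration


def segment_bscan(
    scan: BScan, config: SegmentationConfig | None = None
) -> LayerBoundaries:
    """Full per-scan chain: vessels -> median filtering -> Canny -> tracing."""
    config = config or SegmentationConfig()
    vessels = detect_vessel_shadows(scan, config)
    cleaned = remove_vessels(scan, vessels)
    filtered = multiscale_median_filter(cleaned.pixels, config.median_sizes)
    edges = canny_boundaries(
        filtered,
        low_frac=config.canny_low_fraction,
        high_quantile=config.canny_high_quantile,
        sigma=config.canny_sigma_px,
    )
    grad = row_gradient(filtered, sigma=config.trace_sigma_px)
    cleaned_scan = BScan(
        pixels=filtered,
        axial_um_per_px=scan.axial_um_per_px,
        lateral_um_per_px=scan.lateral_um_per_px,
        slice_index=scan.slice_index,
        fovea_column=scan.fovea_column,
        laterality=scan.laterality,
    )
    return trace_layer_boundaries(edges, grad, cleaned_scan, config, vessels)
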