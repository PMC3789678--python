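"""Render retina phantoms into synthetic OCT B-scans with ground truth.

The forward model is deliberately simple (no interferometric physics): each
layer band is filled with its base reflectivity using exact partial-volume
coverage at fractional boundaries, optional INL microcysts are stamped in as
hyporeflective ellipses, the column is blurred axially by a Gaussian PSF,
vessel shadows multiply whole columns by an attenuation factor, and
multiplicative gamma speckle is applied.  Frame averaging of the scanner is
represented only by the speckle shape parameter (high shape = many averaged
frames = low residual speckle).

Rendering is pure given (phantom, acquisition, seed): repeated calls are
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .bscan import BScan
from .phantom import BOUNDARIES, GeometryError, RetinaPhantom
from .protocol import DEFAULT_CYST_LINES, RadialProtocol

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AcquisitionModel:
    """Scanner geometry and noise model of one radial scan set."""

    axial_um_per_px: float = 3.9
    scan_length_um: float = 4500.0
    ascan_count: int = 1536
    depth_px: int = 320
    speckle_shape: float | None = 100.0  # gamma shape; None disables speckle
    shadow_columns: tuple[tuple[float, float, float], ...] = ()
    psf_axial_sigma_um: float = 4.0
    background_level: float = 0.05
    lateral_um_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.lateral_um_per_px is None:
            object.__setattr__(
                self, "lateral_um_per_px", self.scan_length_um / self.ascan_count
            )
        if abs(self.ascan_count * self.lateral_um_per_px - self.scan_length_um) \
                > self.lateral_um_per_px:
            raise ValueError("ascan_count x lateral pitch must match scan length "
                             "within one pixel")
        for x0, w, a in self.shadow_columns:
            if not 0 < a <= 1:
                raise ValueError(f"shadow attenuation must be in (0, 1], got {a}")
            if w <= 0:
                raise ValueError("shadow width must be positive")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (or None)")

    @property
    def depth_um(self) -> float:
        return self.depth_px * self.axial_um_per_px

    def x_um(self) -> np.ndarray:
        """Lateral coordinate (um, fovea-centred template) of each column."""
        n = self.ascan_count
        return (np.arange(n) + 0.5 - n / 2) * self.lateral_um_per_px


@dataclass(frozen=True)
class CystSpec:
    """Generator-side description of INL microcysts for one affected eye.

    Cysts are elongated perpendicular to the retinal layers (axial extent >
    lateral extent), confined to the INL, and concentrated on the nasal
    radial lines between 0.75 and 2.0 mm from the fovea.
    """

    count_range: tuple[int, int] = (3, 10)
    eccentricity_range_um: tuple[float, float] = (750.0, 2000.0)
    allowed_radial_lines: tuple[int, ...] = DEFAULT_CYST_LINES
    axial_extent_um: tuple[float, float] = (28.0, 42.0)
    lateral_extent_um: tuple[float, float] = (14.0, 28.0)
    intensity_drop: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.intensity_drop <= 1:
            raise ValueError("intensity_drop must be in (0, 1]")
        if self.count_range[0] > self.count_range[1] or self.count_range[0] < 0:
            raise ValueError("invalid count_range")
        if self.axial_extent_um[1] <= self.lateral_extent_um[0]:
            raise ValueError("axial extents must be able to exceed lateral extents")


@dataclass(frozen=True)
class CystPlan:
    """One planned cyst: where it goes and how big it is."""

    line: int
    slice_index: int
    side: int
    eccentricity_um: float
    axial_um: float
    lateral_um: float
    intensity_drop: float

    @property
    def x_um(self) -> float:
        return self.side * self.eccentricity_um


def plan_cysts(
    phantom: RetinaPhantom,
    spec: CystSpec,
    rng: np.random.Generator,
    protocol: RadialProtocol | None = None,
    fit_margin_um: float = 6.0,
) -> list[CystPlan]:
    """Draw cyst locations/sizes that fit inside the phantom's INL band.

    A cyst that cannot fit inside the INL at any sampled allowed location is
    skipped with a log entry rather than silently misplaced.
    """
    protocol = protocol or phantom.protocol
    half = protocol.slice_length_um / 2
    lo, hi = spec.eccentricity_range_um
    if not (0 < lo < hi <= half):
        raise ValueError("eccentricity range must lie within the scanned half-line")
    count = int(rng.integers(spec.count_range[0], spec.count_range[1] + 1))
    plans: list[CystPlan] = []
    for _ in range(count):
        placed = False
        for _attempt in range(30):
            axial = float(rng.uniform(*spec.axial_extent_um))
            lateral = float(rng.uniform(*spec.lateral_extent_um))
            if lateral >= axial:  # enforce perpendicular elongation
                lateral = 0.9 * axial
            line = int(rng.choice(spec.allowed_radial_lines))
            k, side = protocol.slice_side_for(line)
            ecc = float(rng.uniform(lo + lateral / 2, hi - lateral / 2))
            x = phantom.fovea_center_um + side * ecc
            inl = float(
                phantom.layer_thickness("INL", k, np.asarray([x]))[0]
            )
            if inl < axial + fit_margin_um:
                continue
            if any(
                p.slice_index == k and abs(p.x_um - side * ecc) < 0.8 * (p.lateral_um + lateral)
                for p in plans
            ):
                continue  # avoid heavy overlap so per-cyst bookkeeping stays clean
            plans.append(
                CystPlan(line, k, side, ecc, axial, lateral, spec.intensity_drop)
            )
            placed = True
            break
        if not placed:
            log.warning("cyst skipped: no allowed location with INL thick enough")
    return plans


def _fill_layers(
    phantom: RetinaPhantom, slice_index: int, acq: AcquisitionModel
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Partial-volume fill of layer bands; returns clean image + truth (px)."""
    x = acq.x_um()  # template coordinates, shared with the phantom
    depths_um = phantom.boundaries_at(slice_index, x)
    truth_px = {n: d / acq.axial_um_per_px for n, d in depths_um.items()}
    for name, d in truth_px.items():
        if d.min() <= 0 or d.max() >= acq.depth_px:
            raise GeometryError(
                f"boundary {name} leaves the image depth range "
                f"(depth_px={acq.depth_px})"
            )

    refl = phantom.layer_reflectivity
    # region stack: (top_px, bottom_px, reflectivity)
    names = list(BOUNDARIES)
    tops = [np.zeros(acq.ascan_count)] + [truth_px[n] for n in names]
    bots = [truth_px[n] for n in names] + [np.full(acq.ascan_count, acq.depth_px)]
    vals = (
        [acq.background_level]
        + [refl["RNFL"], refl["GCLIPL"], refl["INL"], refl["OPL"], refl["ONL"],
           refl["RPE"]]
        + [refl["below"]]
    )
    # vitreous sits between image top and ILM
    vals[0] = refl.get("vitreous", acq.background_level)

    rows = np.arange(acq.depth_px, dtype=float)[:, None]
    img = np.zeros((acq.depth_px, acq.ascan_count))
    for top, bot, v in zip(tops, bots, vals):
        cover = np.clip(np.minimum(rows + 1.0, bot[None, :])
                        - np.maximum(rows, top[None, :]), 0.0, 1.0)
        img += v * cover
    return img, truth_px


def inject_microcysts(
    clean_image: np.ndarray,
    truth_px: dict[str, np.ndarray],
    plans: list[CystPlan],
    acq: AcquisitionModel,
    inl_reflectivity: float,
    slice_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Stamp planned cysts of one slice into a clean image.

    Each cyst is an ellipse with its major axis axial, centred midway through
    the INL band and clipped to lie strictly inside it; the returned boolean
    mask records every cyst pixel.
    """
    img = clean_image.copy()
    mask = np.zeros(img.shape, dtype=bool)
    top = truth_px["GCLIPL_INL"]
    bot = truth_px["INL_OPL"]
    rows = np.arange(img.shape[0], dtype=float)[:, None]
    cols = np.arange(img.shape[1], dtype=float)[None, :]
    for p in plans:
        if p.slice_index != slice_index:
            continue
        c0 = p.x_um / acq.lateral_um_per_px - 0.5 + acq.ascan_count / 2
        ci = int(round(c0))
        if not 0 <= ci < img.shape[1]:
            continue
        r0 = 0.5 * (top[ci] + bot[ci])
        a_ax = 0.5 * p.axial_um / acq.axial_um_per_px
        a_lat = max(0.5 * p.lateral_um / acq.lateral_um_per_px, 0.6)
        ell = ((rows + 0.5 - r0) / a_ax) ** 2 + ((cols + 0.5 - c0) / a_lat) ** 2 <= 1.0
        band = (rows >= top[None, :] + 0.5) & (rows + 1.0 <= bot[None, :] - 0.5)
        cyst = ell & band
        img[cyst] = (1.0 - p.intensity_drop) * inl_reflectivity
        mask |= cyst
    return img, mask


def render_bscan(
    phantom: RetinaPhantom,
    slice_index: int,
    acq: AcquisitionModel,
    seed: int | None = 0,
    cysts: list[CystPlan] | None = None,
    shadows: tuple[tuple[float, float, float], ...] | None = None,
) -> tuple[BScan, dict[str, np.ndarray], np.ndarray]:
    """Render one radial slice.

    Returns ``(scan, truth, cyst_mask)`` where ``truth`` maps each boundary
    name to its depth in (fractional) pixels per column — the same 0-based
    row-at-column-centre convention the segmenter uses.
    """
    if not 0 <= slice_index < phantom.protocol.n_slices:
        raise ValueError(f"slice_index must be in 0..{phantom.protocol.n_slices - 1}")
    rng = np.random.default_rng(seed)
    img, truth_px = _fill_layers(phantom, slice_index, acq)

    mask = np.zeros(img.shape, dtype=bool)
    if cysts:
        img, mask = inject_microcysts(
            img, truth_px, cysts, acq, phantom.layer_reflectivity["INL"], slice_index
        )

    sigma_px = acq.psf_axial_sigma_um / acq.axial_um_per_px
    if sigma_px > 0:
        img = gaussian_filter1d(img, sigma_px, axis=0, mode="nearest")

    use_shadows = acq.shadow_columns if shadows is None else shadows
    x = acq.x_um()
    for x0, w, a in use_shadows:
        sel = np.abs(x - x0) <= w / 2
        img[:, sel] *= a

    if acq.speckle_shape is not None and np.isfinite(acq.speckle_shape):
        img = img * rng.gamma(acq.speckle_shape, 1.0 / acq.speckle_shape, img.shape)

    img = np.clip(img, 0.0, 1.0)
    scan = BScan(
        pixels=img,
        axial_um_per_px=acq.axial_um_per_px,
        lateral_um_per_px=acq.lateral_um_per_px,
        slice_index=slice_index,
    )
    return scan, truth_px, mask


def render_eye(
    phantom: RetinaPhantom,
    acq: AcquisitionModel,
    seed: int | None = 0,
    cysts: list[CystPlan] | None = None,
    shadows_per_slice: list[tuple[tuple[float, float, float], ...]] | None = None,
    laterality: str = "OD",
    subject: str = "",
    eye: str = "",
) -> tuple[list[BScan], list[dict[str, np.ndarray]], list[np.ndarray]]:
    """Render a full radial scan set (all slices) for one eye.

    Left eyes ("OS") are mirrored laterally, as delivered by a scanner; the
    ground truth is mirrored identically so it stays in image coordinates.
    """
    root = np.random.default_rng(seed)
    scans, truths, masks = [], [], []
    for k in range(phantom.protocol.n_slices):
        sh = None if shadows_per_slice is None else shadows_per_slice[k]
        s, t, m = render_bscan(
            phantom, k, acq, seed=int(root.integers(2**31)), cysts=cysts, shadows=sh
        )
        if laterality == "OS":
            s = BScan(
                pixels=np.ascontiguousarray(s.pixels[:, ::-1]),
                axial_um_per_px=s.axial_um_per_px,
                lateral_um_per_px=s.lateral_um_per_px,
                slice_index=k,
                laterality="OS",
            )
            t = {n: v[::-1].copy() for n, v in t.items()}
            m = np.ascontiguousarray(m[:, ::-1])
        s.subject, s.eye, s.laterality = subject, eye, laterality
        scans.append(s)
        truths.append(t)
        masks.append(m)
    return scans, truths, masks


def swell_inl(
    phantom: RetinaPhantom,
    plans: list[CystPlan],
    sigma_um: float = 250.0,
    amp_frac: float = 0.35,
    min_amp_um: float = 6.0,
) -> RetinaPhantom:
    """Return a phantom whose INL is locally thickened around each cyst.

    Microcystic change is modelled as edema: besides the hyporeflective
    spaces themselves, the INL swells smoothly around each cyst (Gaussian
    lateral profile, amplitude proportional to the cyst's axial extent).
    The layers above the INL shift upward; the flat INL/OPL interface is
    unchanged.  This is what makes a cyst-bearing eye measurably thicker in
    the INL than the same eye rendered without cysts.
    """
    import copy

    out = copy.deepcopy(phantom)
    x = out.x_ref_um
    for p in plans:
        amp = max(min_amp_um, amp_frac * p.axial_um)
        bump = amp * np.exp(-0.5 * ((x - p.x_um) / sigma_um) ** 2)
        for name in ("GCLIPL_INL", "RNFL_GCLIPL", "ILM"):
            out.boundary_profiles[name][p.slice_index] -= bump
    return out


def inject_cysts_into_eye(
    phantom: RetinaPhantom,
    spec: CystSpec,
    rng: np.random.Generator,
) -> tuple[RetinaPhantom, list[CystPlan]]:
    """Eye-level cyst model: plan cysts, swell the INL around them.

    Returns the swollen phantom and the plans to pass to :func:`render_eye`.
    With an empty plan (count_range=(0,0)) the phantom is returned unchanged.
    """
    plans = plan_cysts(phantom, spec, rng)
    if not plans:
        return phantom, plans
    return swell_inl(phantom, plans), plans


def random_shadows(
    rng: np.random.Generator,
    n_range: tuple[int, int] = (2, 5),
    half_um: float = 2250.0,
    avoid_center_um: float = 400.0,
    width_um: tuple[float, float] = (25.0, 60.0),
    attenuation: tuple[float, float] = (0.35, 0.7),
) -> tuple[tuple[float, float, float], ...]:
    """Draw a plausible set of vessel shadows for one slice (none at the fovea)."""
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    out = []
    for _ in range(n):
        side = rng.choice([-1.0, 1.0])
        x0 = side * rng.uniform(avoid_center_um, half_um - 100.0)
        out.append((float(x0), float(rng.uniform(*width_um)),
                    float(rng.uniform(*attenuation))))
    return tuple(out)
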