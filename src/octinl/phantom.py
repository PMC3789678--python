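"""Layered retina phantoms for synthetic radial OCT scan sets.

A phantom is a stack of smooth, non-crossing boundary depth curves over the
lateral axis of each radial slice, plus a base reflectivity per layer band.
The three measured inner bands (RNFL, combined GCL/IPL, INL) have
configurable target mean thicknesses over the 36-point paramacular grid and
thin smoothly to ~zero inside the foveal pit; the outer bands (OPL, ONL,
RPE) are laterally uniform and serve as segmentation anchors and SNR
banding, matching their appearance on averaged B-scans.

Depth is measured in micrometres from the top of the image (vitreous side);
a larger depth is further into the retina.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import RadialProtocol

#: boundary names, strictly ordered in depth (top to bottom)
BOUNDARIES = (
    "ILM",
    "RNFL_GCLIPL",
    "GCLIPL_INL",
    "INL_OPL",
    "OPL_ONL",
    "ONL_RPE",
    "RPE_BASE",
)

#: the boundaries the segmenter reports (inner retina)
INNER_BOUNDARIES = BOUNDARIES[:4]

#: layer bands between consecutive boundaries, top to bottom
LAYERS = ("RNFL", "GCLIPL", "INL", "OPL", "ONL", "RPE")

#: the three measured layers
MEASURED_LAYERS = ("RNFL", "GCLIPL", "INL")

DEFAULT_REFLECTIVITY = {
    "vitreous": 0.05,
    "RNFL": 0.80,
    "GCLIPL": 0.42,
    "INL": 0.26,
    "OPL": 0.55,
    "ONL": 0.14,
    "RPE": 0.85,
    "below": 0.10,
}


class GeometryError(ValueError):
    """Requested layer stack cannot fit in the available depth."""


@dataclass
class PhantomSpec:
    """Inputs of :func:`make_layer_geometry`.

    ``target_um`` are the desired mean thicknesses of the measured layers
    over the 36-point grid.  ``line_scale`` optionally modulates a layer's
    thickness per radial line (length-12 arrays on the right-eye template),
    which is how topographically structured cohorts (e.g. nasal-only
    GCL/IPL loss) are constructed.
    """

    target_um: dict[str, float] = field(
        default_factory=lambda: {"RNFL": 32.2, "GCLIPL": 98.1, "INL": 39.6}
    )
    opl_um: float = 28.0
    onl_um: float = 80.0
    rpe_um: float = 22.0
    inl_opl_depth_um: float = 430.0
    pit_radius_um: float = 450.0
    pit_floor: float = 0.02
    fovea_center_um: float = 0.0
    undulation_frac: float = 0.03
    undulation_period_um: float = 1100.0
    line_scale: dict[str, np.ndarray] = field(default_factory=dict)
    reflectivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTIVITY)
    )
    max_depth_um: float = 690.0
    min_top_margin_um: float = 60.0
    n_ref_columns: int = 1536


@dataclass
class RetinaPhantom:
    """Rendered-geometry ground truth for one eye's radial scan set."""

    boundary_profiles: dict[str, np.ndarray]  # name -> (n_slices, n_ref) depth um
    layer_reflectivity: dict[str, float]
    fovea_center_um: float
    pit_depth_um: float
    pit_radius_um: float
    x_ref_um: np.ndarray  # (n_ref,) lateral coordinate of reference columns
    protocol: RadialProtocol
    spec: PhantomSpec

    def boundaries_at(self, slice_index: int, x_um: np.ndarray) -> dict[str, np.ndarray]:
        """Boundary depths (um) interpolated at lateral positions ``x_um``."""
        return {
            name: np.interp(x_um, self.x_ref_um, prof[slice_index])
            for name, prof in self.boundary_profiles.items()
        }

    def layer_thickness(
        self, layer: str, slice_index: int, x_um: np.ndarray
    ) -> np.ndarray:
        """True thickness (um) of a layer band at lateral positions ``x_um``."""
        i = LAYERS.index(layer)
        top = self.boundary_profiles[BOUNDARIES[i]][slice_index]
        bot = self.boundary_profiles[BOUNDARIES[i + 1]][slice_index]
        return np.interp(x_um, self.x_ref_um, bot - top)

    def thickness_at_grid_point(self, layer: str, line: int, ecc_um: float) -> float:
        """True thickness at one 36-point grid location."""
        k, side = self.protocol.slice_side_for(line)
        x = self.fovea_center_um + side * ecc_um
        return float(self.layer_thickness(layer, k, np.asarray([x]))[0])

    def grid_mean_thickness(self, layer: str) -> float:
        vals = [
            self.thickness_at_grid_point(layer, line, ecc)
            for line, _, ecc in self.protocol.grid_points()
        ]
        return float(np.mean(vals))


def _pit_factor(x_um: np.ndarray, center: float, radius: float, floor: float) -> np.ndarray:
    """Smooth thinning factor: ~``floor`` at the fovea, 1 outside the pit."""
    if radius <= 0:
        return np.ones_like(x_um)
    u = np.abs(x_um - center) / radius
    return floor + (1.0 - floor) * (1.0 - np.exp(-(u**4)))


def _blend_sides(s_neg: float, s_pos: float, x_um: np.ndarray, center: float,
                 width_um: float = 120.0) -> np.ndarray:
    """Blend per-half-line scale factors smoothly across the fovea."""
    w = 1.0 / (1.0 + np.exp(-(x_um - center) / width_um))
    return s_neg + (s_pos - s_neg) * w


def make_layer_geometry(
    spec: PhantomSpec | None = None,
    seed: int | None = 0,
    protocol: RadialProtocol | None = None,
) -> RetinaPhantom:
    """Build a retina phantom whose grid-mean layer thicknesses hit their targets.

    The measured inner layers are thinned inside the foveal pit and carry a
    small seeded smooth undulation; each layer's thickness field is then
    rescaled so its mean over the 36 grid points equals the requested target
    exactly (well within the 2 % contract).  Raises :class:`GeometryError`,
    naming the offending layer, if the stack cannot fit above
    ``max_depth_um`` with the requested top margin.
    """
    spec = spec or PhantomSpec()
    protocol = protocol or RadialProtocol()
    rng = np.random.default_rng(seed)

    for layer, t in spec.target_um.items():
        if layer not in MEASURED_LAYERS:
            raise ValueError(f"unknown target layer {layer!r}")
        if t < 0:
            raise GeometryError(f"target thickness of {layer} is negative")

    n = spec.n_ref_columns
    L = protocol.slice_length_um
    dx = L / n
    x = (np.arange(n) + 0.5 - n / 2) * dx

    pit = _pit_factor(x, spec.fovea_center_um, spec.pit_radius_um, spec.pit_floor)

    # per-layer thickness fields, (n_slices, n_ref), in um
    thickness: dict[str, np.ndarray] = {}
    for layer in MEASURED_LAYERS:
        target = spec.target_um.get(layer, 0.0)
        field_ = np.zeros((protocol.n_slices, n))
        if target > 0:
            scale = np.asarray(spec.line_scale.get(layer, np.ones(protocol.n_lines)),
                               dtype=float)
            if scale.shape != (protocol.n_lines,):
                raise ValueError(f"line_scale[{layer}] must have length "
                                 f"{protocol.n_lines}")
            for k in range(protocol.n_slices):
                s_pos = scale[protocol.line_for(k, +1) - 1]
                s_neg = scale[protocol.line_for(k, -1) - 1]
                prof = pit * _blend_sides(s_neg, s_pos, x, spec.fovea_center_um)
                phase = rng.uniform(0, 2 * np.pi)
                prof = prof * (
                    1.0
                    + spec.undulation_frac
                    * np.sin(2 * np.pi * x / spec.undulation_period_um + phase)
                )
                field_[k] = np.clip(prof, 0.0, None)
        thickness[layer] = field_

    # normalize so the 36-point grid mean equals the target exactly
    grid_xs: dict[int, list[float]] = {k: [] for k in range(protocol.n_slices)}
    for line, _, ecc in protocol.grid_points():
        k, side = protocol.slice_side_for(line)
        grid_xs[k].append(spec.fovea_center_um + side * ecc)
    for layer in MEASURED_LAYERS:
        target = spec.target_um.get(layer, 0.0)
        if target <= 0:
            continue
        samples = [
            np.interp(gx, x, thickness[layer][k])
            for k, xs in grid_xs.items()
            for gx in xs
        ]
        realized = float(np.mean(samples))
        if realized <= 0:
            raise GeometryError(f"layer {layer} vanished at every grid point")
        thickness[layer] *= target / realized

    # stack boundaries upward from the flat INL/OPL interface
    base = spec.inl_opl_depth_um
    profiles: dict[str, np.ndarray] = {}
    ones = np.ones((protocol.n_slices, n))
    profiles["INL_OPL"] = base * ones
    profiles["GCLIPL_INL"] = profiles["INL_OPL"] - thickness["INL"]
    profiles["RNFL_GCLIPL"] = profiles["GCLIPL_INL"] - thickness["GCLIPL"]
    profiles["ILM"] = profiles["RNFL_GCLIPL"] - thickness["RNFL"]
    profiles["OPL_ONL"] = (base + spec.opl_um) * ones
    profiles["ONL_RPE"] = (base + spec.opl_um + spec.onl_um) * ones
    profiles["RPE_BASE"] = (base + spec.opl_um + spec.onl_um + spec.rpe_um) * ones

    # feasibility: name the first inner layer whose addition overflows the margin
    budget = base - spec.min_top_margin_um
    for layer in ("INL", "GCLIPL", "RNFL"):
        budget -= float(thickness[layer].max(initial=0.0))
        if budget < 0:
            raise GeometryError(
                f"sum of layer thicknesses exceeds image depth: adding layer "
                f"{layer} pushes the ILM above the {spec.min_top_margin_um} um "
                f"top margin"
            )
    if float(profiles["RPE_BASE"].max()) > spec.max_depth_um:
        raise GeometryError(
            "sum of layer thicknesses exceeds image depth: outer retina "
            f"(RPE base) deeper than max_depth_um={spec.max_depth_um}"
        )

    ilm = profiles["ILM"]
    pit_depth = float(ilm[0].max() - np.median(ilm[0]))
    return RetinaPhantom(
        boundary_profiles=profiles,
        layer_reflectivity=dict(spec.reflectivity),
        fovea_center_um=spec.fovea_center_um,
        pit_depth_um=pit_depth,
        pit_radius_um=spec.pit_radius_um,
        x_ref_um=x,
        protocol=protocol,
        spec=spec,
    )
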