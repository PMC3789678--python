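"""36-point paramacular thickness grid from traced layer boundaries.

Each of the 12 radial half-lines contributes 3 sample points at fixed
eccentricities from the fovea; at each point the layer thickness is the
boundary separation (converted to um) averaged over a small column window
to suppress single-column segmentation jitter.  Points over failed
boundaries or beyond the scan edge are marked invalid, never extrapolated.

Left eyes are mirrored to the right-eye template at this stage: the lateral
axis of an "OS" scan is flipped so nasal/temporal line semantics match the
template convention in :mod:`octinl.protocol`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import RadialProtocol
from .segmentation import LayerBoundaries

LAYER_PAIRS = {
    "RNFL": ("ILM", "RNFL_GCLIPL"),
    "GCLIPL": ("RNFL_GCLIPL", "GCLIPL_INL"),
    "INL": ("GCLIPL_INL", "INL_OPL"),
}

GRID_COLUMNS = ["line", "ecc_index", "ecc_um", "layer", "thickness_um", "valid"]


@dataclass
class ThicknessGrid:
    """Per-eye 36-point x 3-layer thickness table.

    ``table`` is a long-format DataFrame with one row per (line,
    eccentricity, layer); exactly ``n_lines x points_per_halfline`` entries
    per layer.
    """

    table: pd.DataFrame
    subject: str = ""
    eye: str = ""
    laterality: str = "OD"

    def layer_values(self, layer: str, valid_only: bool = True) -> np.ndarray:
        t = self.table[self.table.layer == layer]
        if valid_only:
            t = t[t.valid]
        return t.thickness_um.to_numpy()

    def n_invalid(self) -> int:
        per_point = self.table.groupby(["line", "ecc_index"]).valid.all()
        return int((~per_point).sum())


def sample_grid(
    boundaries_per_slice: list[LayerBoundaries],
    protocol: RadialProtocol,
    axial_um_per_px: float,
    lateral_um_per_px: float,
    laterality: str = "OD",
    window_columns: int = 5,
    subject: str = "",
    eye: str = "",
) -> ThicknessGrid:
    """Sample the 36-point grid from one eye's traced radial slices."""
    if len(boundaries_per_slice) != protocol.n_slices:
        raise ValueError(
            f"need {protocol.n_slices} segmented slices, got "
            f"{len(boundaries_per_slice)}"
        )
    half_w = window_columns // 2
    rows = []
    for line, j, ecc in protocol.grid_points():
        k, side = protocol.slice_side_for(line)
        lb = boundaries_per_slice[k]
        n_cols = len(lb.depths["ILM"])
        # mirror OS scans onto the right-eye template
        image_side = side if laterality == "OD" else -side
        col = lb.fovea_column + image_side * ecc / lateral_um_per_px
        ci = int(np.clip(round(col), half_w, n_cols - 1 - half_w))
        # the outermost eccentricity sits at the scan edge: clamp the window
        # inside the image, but only by up to one window width
        in_range = abs(ci - col) <= window_columns
        window = slice(ci - half_w, ci + half_w + 1) if in_range else slice(0, 0)
        for layer, (upper, lower) in LAYER_PAIRS.items():
            ok = in_range and not lb.failed[upper] and not lb.failed[lower]
            if ok:
                th = float(
                    np.mean(
                        (lb.depths[lower][window] - lb.depths[upper][window])
                        * axial_um_per_px
                    )
                )
            else:
                th = np.nan
            rows.append(
                {
                    "line": line,
                    "ecc_index": j,
                    "ecc_um": ecc,
                    "layer": layer,
                    "thickness_um": th,
                    "valid": bool(ok),
                }
            )
    table = pd.DataFrame(rows, columns=GRID_COLUMNS)
    return ThicknessGrid(table=table, subject=subject, eye=eye, laterality=laterality)


@dataclass
class EyeSummary:
    """Per-layer mean thickness of one eye over the valid grid entries."""

    mean_um: dict[str, float]
    n_invalid: int
    analyzable: bool


def eye_summary(grid: ThicknessGrid, min_valid: int = 30) -> EyeSummary:
    """Average each layer over the valid grid points.

    An eye with fewer than ``min_valid`` of the 36 points valid is flagged
    unanalyzable (mirroring the quality exclusion of the protocol); its
    means are still reported over whatever points exist.
    """
    n_points = grid.table.groupby(["line", "ecc_index"]).ngroups
    n_invalid = grid.n_invalid()
    means = {}
    for layer in LAYER_PAIRS:
        vals = grid.layer_values(layer)
        means[layer] = float(np.mean(vals)) if len(vals) else float("nan")
    return EyeSummary(
        mean_um=means,
        n_invalid=n_invalid,
        analyzable=(n_points - n_invalid) >= min_valid,
    )


def grid_truth_from_phantom(phantom, protocol: RadialProtocol | None = None) -> pd.DataFrame:
    """Ground-truth thickness table at the grid coordinates of a phantom."""
    protocol = protocol or phantom.protocol
    rows = []
    for line, j, ecc in protocol.grid_points():
        for layer in LAYER_PAIRS:
            rows.append(
                {
                    "line": line,
                    "ecc_index": j,
                    "ecc_um": ecc,
                    "layer": layer,
                    "thickness_um": phantom.thickness_at_grid_point(layer, line, ecc),
                    "valid": True,
                }
            )
    return pd.DataFrame(rows, columns=GRID_COLUMNS)
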