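"""B-scan container and plain-file image I/O.

One :class:`BScan` is a single radial OCT slice: a depth x lateral intensity
array in [0, 1] with its physical calibration.  Images are stored on disk as
16-bit grayscale TIFF (one file per slice) and rescaled to [0, 1] on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class BScan:
    pixels: np.ndarray  # (depth_px, n_ascans), float in [0, 1]
    axial_um_per_px: float
    lateral_um_per_px: float
    slice_index: int = 0
    fovea_column: float | None = None
    laterality: str = "OD"  # OD = right eye; OS scans are mirrored on sampling
    subject: str = ""
    eye: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ValueError("calibration must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD' or 'OS'")
        self.pixels = px

    @property
    def depth_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]

    def column_of(self, x_um: float) -> float:
        """Fractional column index of lateral position ``x_um`` (0 = fovea side edge)."""
        return x_um / self.lateral_um_per_px - 0.5 + self.n_ascans / 2


def save_bscan_tiff(scan: BScan, path: str | Path) -> Path:
    """Write a scan as 16-bit grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.round(scan.pixels * 65535.0).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "axial_um_per_px": scan.axial_um_per_px,
            "lateral_um_per_px": scan.lateral_um_per_px,
            "slice_index": scan.slice_index,
            "laterality": scan.laterality,
        },
    )
    return path


def load_bscan_tiff(
    path: str | Path,
    axial_um_per_px: float | None = None,
    lateral_um_per_px: float | None = None,
    slice_index: int | None = None,
    laterality: str | None = None,
) -> BScan:
    """Read a 16-bit (or 8-bit) grayscale TIFF back into a :class:`BScan`.

    Calibration is taken from the TIFF metadata written by
    :func:`save_bscan_tiff` unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2-D image")
    info = np.iinfo(data.dtype) if np.issubdtype(data.dtype, np.integer) else None
    pixels = data.astype(float) / (info.max if info else 1.0)
    ax = axial_um_per_px if axial_um_per_px is not None else meta.get("axial_um_per_px")
    lat = (lateral_um_per_px if lateral_um_per_px is not None
           else meta.get("lateral_um_per_px"))
    if ax is None or lat is None:
        raise ValueError(f"{path}: calibration missing from metadata and not supplied")
    return BScan(
        pixels=np.clip(pixels, 0.0, 1.0),
        axial_um_per_px=float(ax),
        lateral_um_per_px=float(lat),
        slice_index=int(slice_index if slice_index is not None
                        else meta.get("slice_index", 0)),
        laterality=str(laterality if laterality is not None
                       else meta.get("laterality", "OD")),
    )
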