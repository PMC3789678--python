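"""Radial acquisition protocol and paramacular grid conventions.

The macular radial protocol acquires 6 B-scan slices through the foveal
center, each 4.5 mm long and rotated in 30 degree steps, giving 12 radial
half-lines around the fovea.  Layer thickness is sampled at 3 eccentricities
along each half-line, for a 36-point paramacular grid; the points closest to
the fovea are excluded because the inner layers converge there.

Line numbering (fixed convention, documented so topographic statements such
as "cysts on lines 5-9" are reproducible):

* everything is expressed on a *right-eye template*; left eyes are mirrored
  laterally before sampling so nasal/temporal semantics are preserved,
* line 1 points along the temporal horizontal, numbering increases
  counterclockwise, so line ``l`` points at angle ``(l - 1) * 30`` degrees,
* slice ``k`` (0-based) carries line ``k + 1`` on its positive lateral axis
  and line ``k + 7`` on its negative axis,
* quadrants by angle ``a`` of the line: supero-temporal ``0 <= a < 90``,
  supero-nasal ``90 <= a < 180``, infero-nasal ``180 <= a < 270``,
  infero-temporal ``270 <= a < 360``.  The nasal hemifield is lines 5-9.
"""

from __future__ import annotations

from dataclasses import dataclass, field


QUADRANTS = ("supero-temporal", "supero-nasal", "infero-nasal", "infero-temporal")

#: lines whose quadrant is nasal (supero- or infero-nasal)
NASAL_LINES = frozenset({4, 5, 6, 7, 8, 9})

#: default radial lines eligible for microcyst injection: the supero- and
#: infero-nasal lines between 120 and 240 degrees
DEFAULT_CYST_LINES = (5, 6, 7, 8, 9)


@dataclass(frozen=True)
class RadialProtocol:
    """Geometry of the radial scan pattern and of the 36-point grid."""

    n_slices: int = 6
    angular_step_deg: float = 30.0
    slice_length_um: float = 4500.0
    points_per_halfline: int = 3
    eccentricities_um: tuple[float, ...] = (750.0, 1500.0, 2250.0)
    excluded_central_points: int = 5

    def __post_init__(self) -> None:
        if self.n_slices * self.angular_step_deg != 180.0:
            raise ValueError(
                "n_slices x angular_step_deg must cover 180 deg of slice "
                f"orientations, got {self.n_slices} x {self.angular_step_deg}"
            )
        ecc = self.eccentricities_um
        if len(ecc) != self.points_per_halfline:
            raise ValueError("eccentricities_um must list one value per point")
        if any(e <= 0 for e in ecc) or any(b <= a for a, b in zip(ecc, ecc[1:])):
            raise ValueError("eccentricities must be positive and strictly increasing")
        if max(ecc) > self.slice_length_um / 2:
            raise ValueError("max eccentricity exceeds the scanned half-line")

    @property
    def n_lines(self) -> int:
        return 2 * self.n_slices

    @property
    def n_grid_points(self) -> int:
        return self.n_lines * self.points_per_halfline

    def line_angle_deg(self, line: int) -> float:
        """Angle of a radial line on the right-eye template, CCW from temporal."""
        self._check_line(line)
        return ((line - 1) * self.angular_step_deg) % 360.0

    def line_for(self, slice_index: int, side: int) -> int:
        """Radial line carried by ``slice_index`` on lateral side ``+1``/``-1``."""
        if not 0 <= slice_index < self.n_slices:
            raise ValueError(f"slice_index must be in 0..{self.n_slices - 1}")
        if side not in (+1, -1):
            raise ValueError("side must be +1 or -1")
        return slice_index + 1 if side == +1 else slice_index + 1 + self.n_slices

    def slice_side_for(self, line: int) -> tuple[int, int]:
        """Inverse of :meth:`line_for`: (slice_index, side) of a line."""
        self._check_line(line)
        if line <= self.n_slices:
            return line - 1, +1
        return line - 1 - self.n_slices, -1

    def quadrant_of_line(self, line: int) -> str:
        a = self.line_angle_deg(line)
        return QUADRANTS[int(a // 90.0) % 4]

    def is_nasal(self, line: int) -> bool:
        return self.quadrant_of_line(line).endswith("nasal")

    def grid_points(self):
        """Iterate (line, eccentricity_index, eccentricity_um) over the grid."""
        for line in range(1, self.n_lines + 1):
            for j, ecc in enumerate(self.eccentricities_um, start=1):
                yield line, j, ecc

    def _check_line(self, line: int) -> None:
        if not 1 <= line <= self.n_lines:
            raise ValueError(f"line must be in 1..{self.n_lines}")
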