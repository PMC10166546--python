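"""The 24-2 perimetry test-point grid.

The Humphrey 24-2 program tests 54 locations covering the central 24 degrees
(27 degrees nasally).  Two of them fall on the physiologic blind spot and are
excluded from all analysis, leaving 52 active points.  Everything in this
package (records, archetypes, plots) uses the same fixed ordering of those 52
points: raster order as on a standard 24-2 printout, superior row first,
each row left to right.

Coordinates are degrees of visual angle in right-eye (OD) orientation:
positive x is temporal (the blind spot sits at x = +15), positive y superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# (y, [x positions]) per printout row, superior to inferior.
_ROWS: tuple[tuple[int, tuple[int, ...]], ...] = (
    (21, (-9, -3, 3, 9)),
    (15, (-15, -9, -3, 3, 9, 15)),
    (9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-3, (-27, -21, -15, -9, -3, 3, 9, 15, 21)),
    (-9, (-21, -15, -9, -3, 3, 9, 15, 21)),
    (-15, (-15, -9, -3, 3, 9, 15)),
    (-21, (-9, -3, 3, 9)),
)

N_POINTS = 54
N_ACTIVE = 52
BLIND_SPOT_INDICES = frozenset({26, 35})  # 1-based raster indices, x=+15, y=+/-3


@dataclass(frozen=True)
class Grid242:
    """The 24-2 layout: 54 (index, x, y) points and the blind-spot indices.

    ``laterality_convention`` records the orientation of the x axis:
    ``"OD"`` (the default) means positive x is temporal for a right eye.
    :meth:`mirrored` flips x for users who pool left eyes into right-eye
    orientation.
    """

    points: tuple[tuple[int, int, int], ...] = field(default=None)  # type: ignore[assignment]
    blind_spot_indices: frozenset[int] = BLIND_SPOT_INDICES
    laterality_convention: str = "OD"

    def __post_init__(self) -> None:
        if self.points is None:
            pts = []
            idx = 1
            for y, xs in _ROWS:
                for x in xs:
                    pts.append((idx, x, y))
                    idx += 1
            object.__setattr__(self, "points", tuple(pts))
        if len(self.points) != N_POINTS:
            raise ValueError(f"expected {N_POINTS} points, got {len(self.points)}")
        if len(self.blind_spot_indices) != 2:
            raise ValueError("expected exactly 2 blind-spot indices")

    @property
    def active_indices(self) -> tuple[int, ...]:
        """1-based raster indices of the 52 analysed points, in fixed order."""
        return tuple(i for i, _, _ in self.points if i not in self.blind_spot_indices)

    @property
    def active_coords(self) -> np.ndarray:
        """(52, 2) array of (x, y) degrees for the active points."""
        return np.array(
            [(x, y) for i, x, y in self.points if i not in self.blind_spot_indices],
            dtype=float,
        )

    def mirrored(self) -> "Grid242":
        """Horizontally reflected grid (OS fields viewed in OD orientation)."""
        pts = tuple((i, -x, y) for i, x, y in self.points)
        conv = "OS" if self.laterality_convention == "OD" else "OD"
        return Grid242(points=pts, blind_spot_indices=self.blind_spot_indices,
                       laterality_convention=conv)


#: The canonical grid instance used throughout the package.
GRID = Grid242()
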