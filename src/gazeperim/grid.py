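"""Test-location grids: the standard 24-2 lattice and the adapted tablet grid.

The 24-2 pattern is the reference lattice of standard automated perimetry:
54 points on a 6 deg lattice offset 3 deg from both meridians, reaching
|x| <= 21, |y| <= 21 with row widths shrinking vertically, plus two nasal
points at 27 deg eccentricity.

The tablet measurement grid keeps every 24-2 point that fits on the screen
(|x| <= 21, |y| <= 15), drops the four innermost points (+-3, +-3) — too close
to fixation for a low-cost eye-tracker to resolve — and adds four points at
(+-10, +-10), for 44 locations in total, each tested four times.  The
inclusion box is inferred: it is the unique axis-aligned sub-box of the 24-2
whose filtered count, minus the four central points, plus the four added
points, equals 44; it is locked by test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from .errors import GridError


class GridLocation(NamedTuple):
    id: int
    x_deg: float
    y_deg: float


@dataclass(frozen=True)
class MeasurementGrid:
    """An ordered set of test locations with a per-location repetition count."""

    locations: tuple[GridLocation, ...]
    reps_per_location: int = 4

    def __len__(self) -> int:
        return len(self.locations)

    def coordinates(self) -> list[tuple[float, float]]:
        return [(loc.x_deg, loc.y_deg) for loc in self.locations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.locations, columns=["id", "x_deg", "y_deg"])

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)


# Half-width of each 24-2 row, keyed by |y|: |x| <= limit at that row.
_ROW_XLIMIT = {3: 21, 9: 21, 15: 15, 21: 9}


def build_24_2(laterality: str) -> tuple[GridLocation, ...]:
    """The 54 locations of the 24-2 pattern, in field coordinates.

    Rows lie at y in {+-3, +-9, +-15, +-21} with x on the 6-deg lattice offset
    3 deg from the vertical meridian.  The two extra nasal points sit at 27 deg
    eccentricity on the y = +-3 rows: at x = -27 for a right eye (nasal field
    is leftward) and x = +27 for a left eye.
    """
    if laterality not in ("left", "right"):
        raise GridError(f"laterality must be 'left' or 'right', got {laterality!r}")
    pts: list[tuple[float, float]] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        limit = _ROW_XLIMIT[abs(y)]
        pts.extend((x, y) for x in range(-limit, limit + 1, 6))
    nasal_x = -27.0 if laterality == "right" else 27.0
    pts.extend([(nasal_x, 3.0), (nasal_x, -3.0)])
    pts.sort(key=lambda p: (-p[1], p[0]))
    return tuple(GridLocation(i, float(x), float(y)) for i, (x, y) in enumerate(pts))


def build_measurement_grid(reps_per_location: int = 4) -> MeasurementGrid:
    """The adapted 44-location suprathreshold grid.

    Laterality-free: it contains no nasal-asymmetric points, so one grid
    serves both eyes.
    """
    base = {(loc.x_deg, loc.y_deg) for loc in build_24_2("right")}
    kept = {(x, y) for (x, y) in base
            if abs(x) <= 21 and abs(y) <= 15 and not (abs(x) == 3 and abs(y) == 3)}
    kept |= {(10.0, 10.0), (10.0, -10.0), (-10.0, 10.0), (-10.0, -10.0)}
    ordered = sorted(kept, key=lambda p: (-p[1], p[0]))
    locs = tuple(GridLocation(i, x, y) for i, (x, y) in enumerate(ordered))
    return MeasurementGrid(locations=locs, reps_per_location=reps_per_location)
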