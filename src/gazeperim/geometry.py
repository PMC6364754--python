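"""Units, coordinate frames and conversions for tablet-based perimetry.

Two unit systems meet here: physical screen coordinates in centimeters, and
visual angle in degrees at a given viewing distance.  All public interfaces
use degrees; radians appear only inside trigonometric calls.

Conventions
-----------
* Angular coordinates are per-axis: ``theta = atan(offset_cm / distance_cm)``
  independently for x and y.  This flat-screen approximation is what a tablet
  display can physically realize; it is accurate to well under 0.1 deg for the
  eccentricities used here (<= 21 deg) and is documented as approximate
  beyond ~15 deg.
* x is positive rightward in visual space, y positive upward, for both eyes.
* Retinal (fixation-centered) positions are per-axis differences of
  screen-frame angular positions: stimulus angle minus gaze angle.
* Stimulus attenuation follows the Humphrey Field Analyzer (HFA) decibel
  convention: 0 dB is the maximal 10,000 apostilb stimulus, and
  ``asb = pi * cd/m^2``, so ``dB = 10 * log10(10000 / (pi * L))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InvalidGeometryError, InvalidLuminanceError

#: Conversion factor between apostilbs and cd/m^2 (asb = pi * cd/m^2).
ASB_PER_CDM2 = math.pi

#: The HFA reference stimulus: 0 dB attenuation == 10,000 asb.
MAX_STIMULUS_ASB = 10_000.0


class AngularPoint(NamedTuple):
    """A 2-D position in visual degrees (x rightward, y upward).

    Whether the point is screen-centered or fixation-centered (retinal) is
    carried by context; frames are never mixed without explicit conversion.
    """

    x_deg: float
    y_deg: float

    def __add__(self, other):  # type: ignore[override]
        return AngularPoint(self.x_deg + other[0], self.y_deg + other[1])

    def __sub__(self, other):
        return AngularPoint(self.x_deg - other[0], self.y_deg - other[1])

    def distance_to(self, other) -> float:
        """Euclidean angular distance in degrees."""
        return math.hypot(self.x_deg - other[0], self.y_deg - other[1])


@dataclass(frozen=True)
class ScreenModel:
    """Physical display geometry.

    Defaults describe a 12.3-inch tablet screen (25.4 x 16.9 cm) viewed at a
    nominal 50 cm, which subtends 28.5 x 19.2 degrees of visual angle.
    """

    width_cm: float = 25.4
    height_cm: float = 16.9
    nominal_distance_cm: float = 50.0

    def __post_init__(self):
        if min(self.width_cm, self.height_cm, self.nominal_distance_cm) <= 0:
            raise InvalidGeometryError("screen dimensions and distance must be positive")

    def angular_extent(self, distance_cm: float | None = None) -> tuple[float, float]:
        """Full angular span (width_deg, height_deg) at a viewing distance."""
        d = self.nominal_distance_cm if distance_cm is None else distance_cm
        if d <= 0:
            raise InvalidGeometryError(f"viewing distance must be positive, got {d}")
        w = 2.0 * math.degrees(math.atan(self.width_cm / 2.0 / d))
        h = 2.0 * math.degrees(math.atan(self.height_cm / 2.0 / d))
        return w, h

    def contains(self, point: AngularPoint, distance_cm: float | None = None,
                 margin_deg: float = 0.0) -> bool:
        """True if an angular position lies on the screen at this distance.

        ``margin_deg`` shrinks the usable area (e.g. by a stimulus radius so
        the whole stimulus fits).
        """
        w, h = self.angular_extent(distance_cm)
        return (abs(point.x_deg) <= w / 2.0 - margin_deg
                and abs(point.y_deg) <= h / 2.0 - margin_deg)


def angular_position(x_cm: float, y_cm: float, distance_cm: float) -> AngularPoint:
    """Angular position (screen frame) of a physical offset from screen center."""
    if distance_cm <= 0:
        raise InvalidGeometryError(f"viewing distance must be positive, got {distance_cm}")
    return AngularPoint(math.degrees(math.atan(x_cm / distance_cm)),
                        math.degrees(math.atan(y_cm / distance_cm)))


def cm_from_angle(point: AngularPoint, distance_cm: float) -> tuple[float, float]:
    """Inverse of :func:`angular_position`: physical offset in cm."""
    if distance_cm <= 0:
        raise InvalidGeometryError(f"viewing distance must be positive, got {distance_cm}")
    return (distance_cm * math.tan(math.radians(point[0])),
            distance_cm * math.tan(math.radians(point[1])))


def stimulus_diameter_cm(size_deg: float, distance_cm: float) -> float:
    """On-screen diameter of a stimulus of fixed angular size.

    Scaling the drawn size with the momentary viewing distance keeps the
    retinal size of the target constant while the head moves freely.
    """
    if size_deg < 0 or distance_cm <= 0:
        raise InvalidGeometryError(
            f"need size_deg >= 0 and distance_cm > 0, got {size_deg}, {distance_cm}")
    return 2.0 * distance_cm * math.tan(math.radians(size_deg / 2.0))


def luminance_to_hfa_db(luminance_cdm2: float) -> float:
    """HFA decibel attenuation equivalent of a stimulus luminance.

    dB = 10 * log10(10000 asb / stimulus asb). A 300 cd/m^2 target maps to
    ~10.26 dB, i.e. roughly a 10 dB HFA target.
    """
    if luminance_cdm2 <= 0:
        raise InvalidLuminanceError(f"luminance must be positive, got {luminance_cdm2}")
    return 10.0 * math.log10(MAX_STIMULUS_ASB / (ASB_PER_CDM2 * luminance_cdm2))


def hfa_db_to_luminance(attenuation_db: float) -> float:
    """Inverse of :func:`luminance_to_hfa_db` (cd/m^2)."""
    return MAX_STIMULUS_ASB / ASB_PER_CDM2 * 10.0 ** (-attenuation_db / 10.0)
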