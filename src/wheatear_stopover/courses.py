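"""Compass-course geometry on a spherical Earth.

Three predicted migration directions are in play for a bird leaving a
stopover site toward a distant goal: the initial bearing of the great circle
(orthodrome, the shortest path, whose bearing changes en route), the rhumb
line (loxodrome, a constant geographic bearing computed via the Mercator
latitude), and the constant magnetic course, obtained from a geographic
bearing by subtracting the local magnetic declination (east positive, so
geographic = magnetic + declination).

A sphere rather than an ellipsoid is used throughout: predictions are quoted
to whole degrees and the difference is far below that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "GeoPoint",
    "Bearing",
    "UndefinedCourseError",
    "great_circle_course",
    "rhumb_course",
    "magnetic_geographic",
    "WALES_DECLINATION",
]

#: Magnetic declination at Wales, Alaska, mid-August 2010 (deg east).
WALES_DECLINATION = 11.19


class UndefinedCourseError(ValueError):
    """The course is undefined (coincident, antipodal or polar endpoints)."""


def _norm_lon(lon: float) -> float:
    """Normalize longitude to (-180, 180]."""
    lon = (lon + 180.0) % 360.0 - 180.0
    return 180.0 if lon == -180.0 else lon


@dataclass(frozen=True)
class GeoPoint:
    lat: float  # deg, +N
    lon: float  # deg, +E

    def __post_init__(self) -> None:
        if abs(self.lat) > 90:
            raise ValueError("latitude out of range")
        object.__setattr__(self, "lon", _norm_lon(self.lon))


@dataclass(frozen=True)
class Bearing:
    value: float  # deg clockwise from north, [0, 360)
    frame: Literal["geographic", "magnetic"] = "geographic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", self.value % 360.0)


def great_circle_course(origin: GeoPoint, dest: GeoPoint) -> Bearing:
    """Initial bearing of the great circle from origin to destination."""
    phi1, phi2 = math.radians(origin.lat), math.radians(dest.lat)
    dlon = math.radians(_norm_lon(dest.lon - origin.lon))
    if origin == dest:
        raise UndefinedCourseError("coincident points")
    if math.isclose(origin.lat, -dest.lat) and math.isclose(
        abs(_norm_lon(dest.lon - origin.lon)), 180.0
    ):
        raise UndefinedCourseError("antipodal points")
    y = math.sin(dlon) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon)
    return Bearing(math.degrees(math.atan2(y, x)))


def rhumb_course(origin: GeoPoint, dest: GeoPoint) -> Bearing:
    """Constant geographic bearing (loxodrome) from origin to destination.

    Uses the Mercator-latitude difference and the shortest signed longitude
    difference; undefined when the origin sits on a pole.
    """
    if abs(origin.lat) == 90.0:
        raise UndefinedCourseError("rhumb course undefined from a pole")
    if origin == dest:
        raise UndefinedCourseError("coincident points")
    phi1, phi2 = math.radians(origin.lat), math.radians(dest.lat)
    dlon = math.radians(_norm_lon(dest.lon - origin.lon))
    dpsi = math.log(math.tan(math.pi / 4 + phi2 / 2) / math.tan(math.pi / 4 + phi1 / 2))
    return Bearing(math.degrees(math.atan2(dlon, dpsi)))


def magnetic_geographic(
    bearing: Bearing, declination: float, to_frame: Literal["geographic", "magnetic"]
) -> Bearing:
    """Convert a bearing between magnetic and geographic frames.

    ``declination`` is east-positive; geographic = magnetic + declination.
    Converting to the frame the bearing is already in returns it unchanged.
    """
    if bearing.frame == to_frame:
        return bearing
    if to_frame == "geographic":
        return Bearing(bearing.value + declination, "geographic")
    return Bearing(bearing.value - declination, "magnetic")
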