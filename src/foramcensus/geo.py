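"""Spherical geodesy and the minutes-as-decimals coordinate repair.

Distances use the haversine formula on a sphere of radius 6371.0 km — the
radius that reproduces the duplicate-detection distance thresholds used
throughout the pipeline (2.621 km between 0.5'N 0.5'W and 0.5'S 0.5'E;
0.5242 km for the 0.1' pair) to four significant figures, which an
ellipsoidal model does not.

The minutes-as-decimals repair undoes a common digitisation error in legacy
position records: coordinates given as degrees and minutes copied as if the
minutes were decimal fractions of a degree (10 deg 30' recorded as 10.30).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

#: Sphere radius in kilometres.
EARTH_RADIUS_KM = 6371.0

#: Maximum distance for a pair with identical names to count as a plain
#: duplicate: the span between 0.5'N 0.5'W and 0.5'S 0.5'E across the equator.
PLAIN_DISTANCE_KM = 2.621

#: Maximum distance for a different-name duplicate: the span between
#: 0.1'N 0.1'W and 0.1'S 0.1'E across the equator.
DIFFERENT_NAME_DISTANCE_KM = 0.5242

#: Minimum displacement for a coordinate repair to be credible — an
#: ill-transformation of at least 5 minutes (about 3.7 km at the equator).
TRANSFORM_DISTANCE_KM = 3.7


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float
    lat_precision: int = 6  # reliable decimal places, per axis
    lon_precision: int = 6

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range")


def _coords(point) -> tuple:
    if isinstance(point, GeoPoint):
        return point.latitude, point.longitude
    lat, lon = point
    if lat is None or lon is None or not (-90.0 <= lat <= 90.0
                                          and -180.0 <= lon <= 180.0):
        raise ValueError(f"invalid coordinates {point!r}")
    return lat, lon


def distance_km(a, b) -> float:
    """Great-circle (haversine) distance in km between two points."""
    lat1, lon1 = _coords(a)
    lat2, lon2 = _coords(b)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = (math.sin(dphi / 2.0) ** 2
         + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2)
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def minutes_as_decimal_fix(coordinate: float,
                           decimals: int = 6) -> float | None:
    """Reinterpret the decimal fraction of a coordinate as arc minutes.

    For a value with integer part D and fractional part f the repaired value
    is D + (f*100)/60, sign preserved.  Valid only when f*100 < 60 (minutes
    beyond 59 cannot have been minutes); returns ``None`` otherwise.
    Fractional parts are extracted after rounding at ``decimals`` places to
    avoid phantom minutes from binary float representation.
    """
    sign = -1.0 if coordinate < 0 else 1.0
    a = abs(coordinate)
    whole = math.floor(a)
    frac = round(a - whole, decimals)
    minutes = round(frac * 100.0, max(0, decimals - 2))
    if minutes >= 60.0:
        return None
    return sign * (whole + minutes / 60.0)


def transform_displacement_km(before, after) -> float:
    """Distance in km by which a coordinate repair moved a sample."""
    return distance_km(before, after)


def enumerate_transform_combinations(pos_a, pos_b) -> list:
    """All repair/keep combinations for the four coordinates of a pair.

    Each combination repairs a subset of {lat_a, lon_a, lat_b, lon_b} of size
    at most two (more than two mis-transformed coordinates is deemed
    implausible) and skips subsets containing an unrepairable coordinate.
    Returns a list of ``(mask, (lat_a, lon_a), (lat_b, lon_b))`` tuples where
    ``mask`` is the tuple of repaired coordinate indices; the identity
    combination (empty mask) comes first.
    """
    lat_a, lon_a = _coords(pos_a)
    lat_b, lon_b = _coords(pos_b)
    coords = [lat_a, lon_a, lat_b, lon_b]
    fixed = [minutes_as_decimal_fix(c) for c in coords]
    combos = []
    for size in (0, 1, 2):
        for mask in itertools.combinations(range(4), size):
            if any(fixed[i] is None for i in mask):
                continue
            cand = list(coords)
            for i in mask:
                cand[i] = fixed[i]
            combos.append((mask, (cand[0], cand[1]), (cand[2], cand[3])))
    return combos


def decimal_places(value: float) -> int:
    """Number of decimal places in the shortest repr of a float."""
    text = repr(float(value))
    if "e" in text or "E" in text:
        return 6
    if "." in text:
        frac = text.split(".", 1)[1]
        return 0 if frac == "0" else len(frac)
    return 0
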