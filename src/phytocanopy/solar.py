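"""Solar geometry on local solar time.

Standard declination / equation-of-time astronomy (Spencer's Fourier
series), sufficient for hourly canopy radiation work (the stated accuracy
budget is 0.5 degrees against a published ephemeris).  Hours are local
*solar* hours: solar noon is 12.0 by construction, so no longitude or
timezone correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["SolarGeometry", "sun_position", "day_length", "daylight_hours"]

DEFAULT_LATITUDE = 39.93  # deg N, the study site (39 deg 56 min N)


@dataclass
class SolarGeometry:
    latitude: float
    doy: int
    hour: float
    zenith: float        # deg, 0 = overhead
    azimuth: float       # deg, clockwise from north
    declination: float   # deg
    sunrise: float       # local solar hour
    sunset: float

    @property
    def elevation(self) -> float:
        return 90.0 - self.zenith

    @property
    def is_daylight(self) -> bool:
        return self.zenith < 90.0

    def beam_direction(self) -> np.ndarray:
        """Unit propagation vector (sun -> ground), z-up scene frame.

        Scene x = row direction is taken as east, y as north.
        """
        z = math.radians(self.zenith)
        a = math.radians(self.azimuth)
        # vector pointing toward the sun:
        sx = math.sin(z) * math.sin(a)   # east
        sy = math.sin(z) * math.cos(a)   # north
        sz = math.cos(z)
        return -np.array([sx, sy, sz])


def _declination_deg(doy: int) -> float:
    # Spencer (1971) Fourier series
    g = 2.0 * math.pi * (doy - 1) / 365.0
    d = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
         - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
         - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    return math.degrees(d)


def day_length(latitude: float, doy: int) -> tuple[float, float]:
    """(sunrise, sunset) in local solar hours; (12, 12) for polar night."""
    phi = math.radians(latitude)
    dec = math.radians(_declination_deg(doy))
    cosH = -math.tan(phi) * math.tan(dec)
    if cosH >= 1.0:
        return 12.0, 12.0
    if cosH <= -1.0:
        return 0.0, 24.0
    H = math.degrees(math.acos(cosH)) / 15.0
    return 12.0 - H, 12.0 + H


def sun_position(latitude: float, doy: int, hour: float) -> SolarGeometry:
    """Sun zenith/azimuth at a local solar hour."""
    if not 1 <= doy <= 366:
        raise ValueError("DOY must be in [1, 366]")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of range")
    phi = math.radians(latitude)
    dec = math.radians(_declination_deg(doy))
    H = math.radians(15.0 * (hour - 12.0))
    cosz = math.sin(phi) * math.sin(dec) + math.cos(phi) * math.cos(dec) * math.cos(H)
    cosz = min(1.0, max(-1.0, cosz))
    zen = math.degrees(math.acos(cosz))
    sinz = math.sqrt(max(0.0, 1.0 - cosz * cosz))
    if sinz < 1e-12:
        az = 180.0
    else:
        sin_az = -math.cos(dec) * math.sin(H) / sinz
        cos_az = (math.sin(dec) - math.sin(phi) * cosz) / (math.cos(phi) * sinz)
        az = math.degrees(math.atan2(sin_az, cos_az)) % 360.0
    sr, ss = day_length(latitude, doy)
    return SolarGeometry(latitude=latitude, doy=doy, hour=hour, zenith=zen,
                         azimuth=az, declination=math.degrees(dec),
                         sunrise=sr, sunset=ss)


def daylight_hours(latitude: float, doy: int) -> list[int]:
    """Integer local solar hours from ceil(sunrise) to floor(sunset)."""
    sr, ss = day_length(latitude, doy)
    return list(range(math.ceil(sr), math.floor(ss) + 1))
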