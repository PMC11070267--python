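"""Independent low-precision solar ephemeris used only as a test oracle.

Implements the Astronomical Almanac / Michalsky (1988) approximation:
right ascension and declination from the mean longitude and mean anomaly,
hour angle from Greenwich mean sidereal time.  Accurate to about 0.01 deg
over 1950-2050.  Deliberately a different formulation from the package's
NOAA/Meeus-class algorithm (no equation-of-time path, no nutation term), so
agreement between the two is a genuine cross-check.
"""

import numpy as np

_DEG = np.pi / 180.0


def solar_elevation_almanac(lat_deg: float, lon_deg: float, epoch_s) -> np.ndarray:
    """Geometric solar elevation (degrees) from epoch seconds UTC."""
    t = np.asarray(epoch_s, dtype=float)
    n = t / 86400.0 + 2440587.5 - 2451545.0  # days since J2000.0

    L = np.mod(280.460 + 0.9856474 * n, 360.0)
    g = np.mod(357.528 + 0.9856003 * n, 360.0) * _DEG
    lam = (L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g)) * _DEG
    eps = (23.439 - 0.0000004 * n) * _DEG

    decl = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))

    gmst_h = np.mod(18.697374558 + 24.06570982441908 * n, 24.0)
    lmst = gmst_h * 15.0 * _DEG + lon_deg * _DEG
    ha = lmst - ra

    latr = lat_deg * _DEG
    sin_el = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(ha)
    return np.arcsin(np.clip(sin_el, -1.0, 1.0)) / _DEG
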