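"""Independent reference implementations used only as test oracles.

The sun-position oracle follows the USNO "Almanac for Computers"
approximation (mean longitude / mean anomaly polynomial in days since
J2000), a different published algorithm from the one the package
implements, accurate to ~0.01 deg — an independent cross-check for
declination and the equation of time.
"""

import numpy as np
import pandas as pd


def _days_since_j2000(t):
    ns = pd.Timestamp(t).value
    return (ns / 1e9 - 946728000.0) / 86400.0


def usno_sun(t):
    """(declination deg, equation of time minutes) by the USNO almanac formulas."""
    n = _days_since_j2000(t)
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = np.radians(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.radians(23.439 - 0.0000004 * n)
    decl = np.degrees(np.arcsin(np.sin(eps) * np.sin(lam)))
    alpha = np.degrees(np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))) % 360.0
    eot = 4.0 * (((L - alpha) + 180.0) % 360.0 - 180.0)
    return decl, eot


def brute_force_medoid(lons, lats):
    """Exhaustive medoid via sklearn's haversine (independent distance code)."""
    from sklearn.metrics.pairwise import haversine_distances

    pts = np.radians(np.column_stack([lats, lons]))
    d = haversine_distances(pts) * 6371.0
    sums = d.sum(axis=1)
    return int(np.argmin(sums))
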