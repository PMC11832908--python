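"""Geodetic <-> transverse-Mercator (UTM) coordinate conversion on WGS84.

Grid occupancy needs a metric planar frame; occurrence tables carry decimal
degrees. This module implements the exact-to-machine-precision Krüger series
form of the transverse Mercator projection (6th order in the third
flattening), the formulation used by modern geodesy libraries; within a UTM
zone the truncation error is far below a millimetre, i.e. irrelevant at the
kilometre grid scales used here.

Projections are named by compact identifiers:

- ``"utm32n"`` etc.: UTM zone 1-60, hemisphere ``n``/``s`` (scale 0.9996,
  false easting 500 km, false northing 10 000 km in the south);
- ``"planar"``: the identity — coordinates are already metric planar
  (lon -> x, lat -> y), for pre-projected inputs.
"""

from __future__ import annotations

import re

import numpy as np

__all__ = ["geodetic_to_projected", "projected_to_geodetic", "utm_forward", "utm_inverse"]

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = np.sqrt(_F * (2.0 - _F))
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_S = 10_000_000.0

_N = _F / (2.0 - _F)
# Rectifying radius
_ABAR = _A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

# Krüger series coefficients, 6th order in the third flattening n.
_ALPHA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 5 * _N**3 / 16 + 41 * _N**4 / 180
        - 127 * _N**5 / 288 + 7891 * _N**6 / 37800,
        13 * _N**2 / 48 - 3 * _N**3 / 5 + 557 * _N**4 / 1440
        + 281 * _N**5 / 630 - 1983433 * _N**6 / 1935360,
        61 * _N**3 / 240 - 103 * _N**4 / 140 + 15061 * _N**5 / 26880
        + 167603 * _N**6 / 181440,
        49561 * _N**4 / 161280 - 179 * _N**5 / 168 + 6601661 * _N**6 / 7257600,
        34729 * _N**5 / 80640 - 3418889 * _N**6 / 1995840,
        212378941 * _N**6 / 319334400,
    ]
)
_BETA = np.array(
    [
        _N / 2 - 2 * _N**2 / 3 + 37 * _N**3 / 96 - _N**4 / 360
        - 81 * _N**5 / 512 + 96199 * _N**6 / 604800,
        _N**2 / 48 + _N**3 / 15 - 437 * _N**4 / 1440
        + 46 * _N**5 / 105 - 1118711 * _N**6 / 3870720,
        17 * _N**3 / 480 - 37 * _N**4 / 840 - 209 * _N**5 / 4480
        + 5569 * _N**6 / 90720,
        4397 * _N**4 / 161280 - 11 * _N**5 / 504 - 830251 * _N**6 / 7257600,
        4583 * _N**5 / 161280 - 108847 * _N**6 / 3991680,
        20648693 * _N**6 / 638668800,
    ]
)
# Conformal -> geodetic latitude series.
_DELTA = np.array(
    [
        2 * _N - 2 * _N**2 / 3 - 2 * _N**3 + 116 * _N**4 / 45
        + 26 * _N**5 / 45 - 2854 * _N**6 / 675,
        7 * _N**2 / 3 - 8 * _N**3 / 5 - 227 * _N**4 / 45
        + 2704 * _N**5 / 315 + 2323 * _N**6 / 945,
        56 * _N**3 / 15 - 136 * _N**4 / 35 - 1262 * _N**5 / 105
        + 73814 * _N**6 / 2835,
        4279 * _N**4 / 630 - 332 * _N**5 / 35 - 399572 * _N**6 / 14175,
        4174 * _N**5 / 315 - 144838 * _N**6 / 6237,
        601676 * _N**6 / 22275,
    ]
)
_J = np.arange(1, 7)


def _tm_forward(lon_rad, lat_rad, lon0_rad):
    """Krüger-series transverse Mercator, unit scale, no false origin."""
    dlon = lon_rad - lon0_rad
    s = np.sin(lat_rad)
    t = np.sinh(np.arctanh(s) - _E * np.arctanh(_E * s))
    xi_p = np.arctan2(t, np.cos(dlon))
    eta_p = np.arcsinh(np.sin(dlon) / np.sqrt(t**2 + np.cos(dlon) ** 2))
    two_j_xi = 2.0 * _J[:, None] * xi_p[None, :]
    two_j_eta = 2.0 * _J[:, None] * eta_p[None, :]
    xi = xi_p + np.sum(_ALPHA[:, None] * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta = eta_p + np.sum(_ALPHA[:, None] * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)
    return _ABAR * eta, _ABAR * xi  # x (east), y (north)


def _tm_inverse(x, y, lon0_rad):
    eta = x / _ABAR
    xi = y / _ABAR
    two_j_xi = 2.0 * _J[:, None] * xi[None, :]
    two_j_eta = 2.0 * _J[:, None] * eta[None, :]
    xi_p = xi - np.sum(_BETA[:, None] * np.sin(two_j_xi) * np.cosh(two_j_eta), axis=0)
    eta_p = eta - np.sum(_BETA[:, None] * np.cos(two_j_xi) * np.sinh(two_j_eta), axis=0)
    chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
    lat = chi + np.sum(_DELTA[:, None] * np.sin(2.0 * _J[:, None] * chi[None, :]), axis=0)
    lon = lon0_rad + np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    return lon, lat


def utm_forward(lon, lat, zone: int, northern: bool = True):
    """Project decimal-degree lon/lat to UTM easting/northing (metres)."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon0 = np.radians(6.0 * zone - 183.0)
    x, y = _tm_forward(np.radians(lon), np.radians(lat), lon0)
    easting = _FALSE_EASTING + _K0 * x
    northing = _K0 * y + (0.0 if northern else _FALSE_NORTHING_S)
    return easting, northing


def utm_inverse(easting, northing, zone: int, northern: bool = True):
    """Invert UTM easting/northing (metres) to decimal-degree lon/lat."""
    easting = np.atleast_1d(np.asarray(easting, dtype=float))
    northing = np.atleast_1d(np.asarray(northing, dtype=float))
    x = (easting - _FALSE_EASTING) / _K0
    y = (northing - (0.0 if northern else _FALSE_NORTHING_S)) / _K0
    lon0 = np.radians(6.0 * zone - 183.0)
    lon, lat = _tm_inverse(x, y, lon0)
    return np.degrees(lon), np.degrees(lat)


_UTM_RE = re.compile(r"^utm(\d{1,2})([ns])$")


def _parse(projection: str):
    m = _UTM_RE.match(projection.lower())
    if m:
        zone = int(m.group(1))
        if not 1 <= zone <= 60:
            raise ValueError(f"UTM zone out of range in {projection!r}")
        return zone, m.group(2) == "n"
    if projection.lower() == "planar":
        return None
    raise ValueError(f"unknown projection identifier {projection!r}")


def geodetic_to_projected(lon, lat, projection: str):
    """Project lon/lat arrays under a named projection; returns (x, y) metres."""
    parsed = _parse(projection)
    if parsed is None:
        return (
            np.atleast_1d(np.asarray(lon, dtype=float)),
            np.atleast_1d(np.asarray(lat, dtype=float)),
        )
    zone, northern = parsed
    return utm_forward(lon, lat, zone, northern)


def projected_to_geodetic(x, y, projection: str):
    """Invert a named projection; returns (lon, lat) decimal degrees."""
    parsed = _parse(projection)
    if parsed is None:
        return (
            np.atleast_1d(np.asarray(x, dtype=float)),
            np.atleast_1d(np.asarray(y, dtype=float)),
        )
    zone, northern = parsed
    return utm_inverse(x, y, zone, northern)


def in_validity_domain(lon, lat, projection: str):
    """Boolean mask of points inside the projection's sensible domain.

    For UTM: latitude within [-84, 84] and longitude within 15 degrees of the
    zone's central meridian (UTM distortion grows fast beyond the zone, and
    points further out are almost certainly data errors). ``planar`` accepts
    any finite coordinates.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    finite = np.isfinite(lon) & np.isfinite(lat)
    parsed = _parse(projection)
    if parsed is None:
        return finite
    zone, _ = parsed
    lon0 = 6.0 * zone - 183.0
    dlon = (lon - lon0 + 180.0) % 360.0 - 180.0
    return finite & (np.abs(lat) <= 84.0) & (np.abs(dlon) <= 15.0)
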