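"""Geodesic distance on the WGS84 ellipsoid.

Trajectory mileage, place-cluster radii and speed estimates all rest on
point-to-point geodesic distances.  The workhorse here is Vincenty's
inverse formula, an iterative solution of the geodesic problem on an
oblate ellipsoid that is accurate to well under a millimetre whenever it
converges.  Vincenty's iteration is known to stall for nearly antipodal
pairs; for those we fall back to the Lambert/Andoyer first-order
flattening correction (accurate to ~10 m), which is more than adequate
for the sub-continental scales of daily human mobility.
"""

from __future__ import annotations

import numpy as np

#: WGS84 semi-major axis (metres)
WGS84_A = 6_378_137.0
#: WGS84 flattening
WGS84_F = 1.0 / 298.257223563
#: WGS84 semi-minor axis (metres)
WGS84_B = WGS84_A * (1.0 - WGS84_F)


class GeodesicConvergenceError(RuntimeError):
    """Vincenty's iteration failed to converge and no fallback was allowed."""


def _lambert_andoyer(lat1, lon1, lat2, lon2):
    """First-order flattening correction to the great-circle distance.

    Closed form (always defined), used only for near-antipodal pairs
    where Vincenty's lambda-iteration does not converge.
    """
    f = WGS84_F
    b1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    b2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    dlon = np.radians(lon2 - lon1)
    cos_sigma = np.clip(
        np.sin(b1) * np.sin(b2) + np.cos(b1) * np.cos(b2) * np.cos(dlon), -1.0, 1.0
    )
    sigma = np.arccos(cos_sigma)
    p = (b1 + b2) / 2.0
    q = (b2 - b1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (sigma - np.sin(sigma)) * np.sin(p) ** 2 * np.cos(q) ** 2 / np.cos(sigma / 2.0) ** 2
        y = (sigma + np.sin(sigma)) * np.cos(p) ** 2 * np.sin(q) ** 2 / np.sin(sigma / 2.0) ** 2
    x = np.where(np.isfinite(x), x, 0.0)
    y = np.where(np.isfinite(y), y, 0.0)
    return WGS84_A * (sigma - f / 2.0 * (x + y))


def vincenty_distance(lat1, lon1, lat2, lon2, *, max_iter: int = 200,
                      tol: float = 1e-12, fallback: bool = True):
    """Geodesic distance in metres between WGS84 coordinates.

    Accepts scalars or broadcastable arrays of latitudes/longitudes in
    degrees and returns metres (scalar in, scalar out).  Symmetric in
    its endpoints and exactly zero for coincident points.

    Parameters
    ----------
    fallback : bool
        When Vincenty's iteration fails to converge (nearly antipodal
        endpoints), use the Lambert/Andoyer closed form instead of
        raising :class:`GeodesicConvergenceError`.
    """
    lat1, lon1, lat2, lon2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    )
    scalar = lat1.ndim == 0
    lat1, lon1, lat2, lon2 = (np.atleast_1d(a) for a in (lat1, lon1, lat2, lon2))
    for name, lat in (("lat1", lat1), ("lat2", lat2)):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError(f"{name} outside [-90, 90] degrees")
    for name, lon in (("lon1", lon1), ("lon2", lon2)):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError(f"{name} outside [-180, 180] degrees")

    f = WGS84_F
    a, b = WGS84_A, WGS84_B
    U1 = np.arctan((1.0 - f) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1.0 - f) * np.tan(np.radians(lat2)))
    L = np.radians(lon2 - lon1)
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)

    lam = L.copy()
    active = np.ones(lam.shape, dtype=bool)
    sin_sigma = np.zeros_like(lam)
    cos_sigma = np.ones_like(lam)
    sigma = np.zeros_like(lam)
    cos_sq_alpha = np.ones_like(lam)
    cos2sm = np.ones_like(lam)
    coincident = np.zeros(lam.shape, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        sin_lam, cos_lam = np.sin(lam), np.cos(lam)
        t1 = cosU2 * sin_lam
        t2 = cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        ss = np.sqrt(t1 * t1 + t2 * t2)
        cs = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        newly_coincident = active & (ss == 0.0)
        coincident |= newly_coincident
        active &= ~newly_coincident
        sig = np.arctan2(ss, cs)
        with np.errstate(divide="ignore", invalid="ignore"):
            sin_alpha = np.where(ss != 0.0, cosU1 * cosU2 * sin_lam / ss, 0.0)
        csa = 1.0 - sin_alpha**2
        with np.errstate(divide="ignore", invalid="ignore"):
            c2sm = np.where(csa != 0.0, cs - 2.0 * sinU1 * sinU2 / np.where(csa == 0, 1, csa), 0.0)
        C = f / 16.0 * csa * (4.0 + f * (4.0 - 3.0 * csa))
        lam_new = L + (1.0 - C) * f * sin_alpha * (
            sig + C * ss * (c2sm + C * cs * (-1.0 + 2.0 * c2sm**2))
        )
        upd = active
        converged = upd & (np.abs(lam_new - lam) < tol)
        lam = np.where(upd, lam_new, lam)
        sin_sigma = np.where(upd, ss, sin_sigma)
        cos_sigma = np.where(upd, cs, cos_sigma)
        sigma = np.where(upd, sig, sigma)
        cos_sq_alpha = np.where(upd, csa, cos_sq_alpha)
        cos2sm = np.where(upd, c2sm, cos2sm)
        active &= ~converged

    failed = active
    if failed.any() and not fallback:
        idx = np.argwhere(failed)[0]
        raise GeodesicConvergenceError(
            f"Vincenty failed to converge for pair at index {tuple(idx)} "
            "(nearly antipodal endpoints); pass fallback=True to use the "
            "Lambert/Andoyer approximation"
        )

    u_sq = cos_sq_alpha * (a * a - b * b) / (b * b)
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = B * sin_sigma * (
        cos2sm
        + B / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos2sm**2)
            - B / 6.0 * cos2sm * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos2sm**2)
        )
    )
    dist = b * A * (sigma - delta_sigma)
    dist = np.where(coincident, 0.0, dist)
    if failed.any():
        dist = np.where(failed, _lambert_andoyer(lat1, lon1, lat2, lon2), dist)
    return float(dist[0]) if scalar else dist


def consecutive_distances(lat, lon, **kwargs):
    """Distances (metres) between consecutive points of a track.

    Returns an array of length ``len(lat) - 1``.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if lat.size < 2:
        return np.zeros(0)
    return np.asarray(vincenty_distance(lat[:-1], lon[:-1], lat[1:], lon[1:], **kwargs))
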