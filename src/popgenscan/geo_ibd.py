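"""Geodesic distances (Vincenty inverse, WGS84) and Mantel isolation-by-distance tests.

Straight-line distances between sampling sites use Vincenty's iterative
inverse solution on the WGS84 ellipsoid; along-shore (perimeter) distances
are obtained by summing successive legs through intermediate sites.
Isolation by distance is tested by the Mantel matrix-permutation test:
Pearson correlation of the lower triangles of a genetic- and a
geographic-distance matrix, with a null built by simultaneous row/column
permutation of one matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("popgenscan.geo_ibd")

# WGS84 ellipsoid
WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)


@dataclass(frozen=True)
class GeoSite:
    """A sampling site: code plus WGS84 decimal-degree coordinates."""

    code: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of range")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix-correlation test outcome."""

    r: float
    p: float
    n_perm: int
    seed: int


class VincentyConvergenceError(RuntimeError):
    """Raised when the inverse iteration fails (near-antipodal points; no fallback)."""


def vincenty_inverse(
    a: GeoSite,
    b: GeoSite,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> float:
    """Geodesic distance in metres between two sites (Vincenty inverse, WGS84).

    Iterates the difference in longitude on the auxiliary sphere to *tol*
    radians (default 1e-12, i.e. sub-millimetre).  Symmetric in its
    arguments; identical points return exactly 0.
    """
    if (a.lat, a.lon) == (b.lat, b.lon):
        return 0.0
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    L = math.radians(b.lon - a.lon)
    U1 = math.atan((1.0 - WGS84_F) * math.tan(phi1))
    U2 = math.atan((1.0 - WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0  # coincident on the auxiliary sphere
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial geodesic
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = WGS84_F / 16.0 * cos2_alpha * (4.0 + WGS84_F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise VincentyConvergenceError(
            f"no convergence between {a.code} and {b.code} after {max_iter} iterations "
            "(near-antipodal points; no fallback implemented)"
        )

    u2 = cos2_alpha * (WGS84_A**2 - WGS84_B**2) / WGS84_B**2
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = (
        B
        * sin_sigma
        * (
            cos_2sigma_m
            + B
            / 4.0
            * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
                - B
                / 6.0
                * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma**2)
                * (-3.0 + 4.0 * cos_2sigma_m**2)
            )
        )
    )
    return WGS84_B * A * (sigma - delta_sigma)


def perimeter_distance(sites: Sequence[GeoSite]) -> float:
    """Along-route distance: sum of successive geodesic legs through *sites*."""
    if len(sites) < 2:
        raise ValueError("perimeter distance needs at least two sites")
    return sum(vincenty_inverse(a, b) for a, b in zip(sites[:-1], sites[1:]))


def geo_distance_matrix(sites: Sequence[GeoSite]) -> pd.DataFrame:
    """Symmetric straight-line distance matrix (metres) between sites."""
    n = len(sites)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = vincenty_inverse(sites[i], sites[j])
    labels = [s.code for s in sites]
    return pd.DataFrame(out, index=labels, columns=labels)


def load_sites(path) -> list[GeoSite]:
    """Read a sites TSV (code, lat, lon)."""
    df = pd.read_csv(path, sep="\t")
    return [
        GeoSite(code=str(r.iloc[0]), lat=float(r.iloc[1]), lon=float(r.iloc[2]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _lower_triangle(mat: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(mat.shape[0], k=-1)
    return mat[i, j]


def mantel_test(
    matA: pd.DataFrame,
    matB: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int = 0,
) -> MantelResult:
    """Two-sided Mantel test of matrix covariation.

    ``r`` is the Pearson correlation of corresponding lower-triangle
    entries; the null permutes rows and columns of the second matrix
    simultaneously; the empirical p-value is
    ``(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.
    """
    if list(matA.index) != list(matA.columns) or list(matB.index) != list(matB.columns):
        raise ValueError("distance matrices must be square with matching label order")
    if list(matA.index) != list(matB.index):
        raise ValueError(f"label mismatch: {list(matA.index)} vs {list(matB.index)}")
    n = matA.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    A = matA.to_numpy(dtype=float)
    B = matB.to_numpy(dtype=float)
    x = _lower_triangle(A)
    if np.std(x) == 0 or np.std(_lower_triangle(B)) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    x = (x - x.mean()) / x.std()

    def corr_with(Bperm: np.ndarray) -> float:
        y = _lower_triangle(Bperm)
        sd = y.std()
        if sd == 0:
            return 0.0
        y = (y - y.mean()) / sd
        return float(np.mean(x * y))

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr_with(B[np.ix_(perm, perm)])) >= abs(r_obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)
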