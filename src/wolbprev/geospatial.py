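"""Country-midpoint geography and ellipsoidal distances (Meeus method).

Screens are located only to country; geographic distance between two groups
of screens is the distance between the countries' estimated midpoints.
Distances use Meeus's ellipsoidal approximation on the WGS84 ellipsoid,
which corrects the great-circle distance for the Earth's flattening and is
accurate to well under 1% of a full geodesic for midpoint-scale work.

A packaged table of approximate country centroids (with continent labels
for the continental tabulation) ships with the module; it can be replaced
by any CSV with columns country, latitude, longitude[, continent].
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GeoPoint",
    "DistanceMatrix",
    "meeus_distance",
    "load_centroids",
    "country_distance_matrix",
    "WGS84_A",
    "WGS84_F",
]

WGS84_A = 6378137.0  # equatorial radius, meters
WGS84_F = 1.0 / 298.257223563  # flattening


@dataclass(frozen=True)
class GeoPoint:
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix (meters or branch-length units)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in pos]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def meeus_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Ellipsoidal distance in meters between two points, Meeus's method.

    The formula evaluates the great-circle distance on a sphere of
    intermediate radius and applies first-order flattening corrections in
    the mean latitude F and half-difference G.  Exactly zero for identical
    points; symmetric by construction.
    """
    lat1, lon1 = np.radians([a.latitude, a.longitude])
    lat2, lon2 = np.radians([b.latitude, b.longitude])
    F = (lat1 + lat2) / 2.0
    G = (lat1 - lat2) / 2.0
    L = (lon1 - lon2) / 2.0
    sinG2, cosG2 = np.sin(G) ** 2, np.cos(G) ** 2
    sinF2, cosF2 = np.sin(F) ** 2, np.cos(F) ** 2
    sinL2, cosL2 = np.sin(L) ** 2, np.cos(L) ** 2
    S = sinG2 * cosL2 + cosF2 * sinL2
    C = cosG2 * cosL2 + sinF2 * sinL2
    if S == 0.0:  # identical points
        return 0.0
    w = np.arctan(np.sqrt(S / C))
    R = np.sqrt(S * C) / w
    D = 2.0 * w * WGS84_A
    H1 = (3.0 * R - 1.0) / (2.0 * C)
    H2 = (3.0 * R + 1.0) / (2.0 * S)
    return float(D * (1.0 + WGS84_F * H1 * sinF2 * cosG2 - WGS84_F * H2 * cosF2 * sinG2))


def load_centroids(path=None) -> pd.DataFrame:
    """Load a country-centroid table (country, latitude, longitude, continent).

    With no path, the packaged approximate centroids are returned.  These
    midpoints are rough single-point summaries of whole countries; analyses
    that depend on exact midpoints should pass their own table.
    """
    if path is None:
        ref = resources.files("wolbprev.data").joinpath("country_centroids.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required = {"country", "latitude", "longitude"}
    if not required <= set(df.columns):
        raise ValueError(f"centroid table must have columns {sorted(required)}")
    if "continent" not in df.columns:
        df["continent"] = "NC"
    return df


def country_distance_matrix(countries: list[str], centroids: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Meeus distances between country midpoints, in input order."""
    lut = {
        row["country"]: GeoPoint(row["latitude"], row["longitude"])
        for _, row in centroids.iterrows()
    }
    missing = [c for c in countries if c not in lut]
    if missing:
        raise KeyError(f"countries missing from centroid table: {missing}")
    pts = [lut[c] for c in countries]
    n = len(pts)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = meeus_distance(pts[i], pts[j])
    return DistanceMatrix(list(countries), d)
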