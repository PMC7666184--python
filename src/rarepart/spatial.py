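"""Spatial eigenvector predictors (PCNM) from site coordinates.

Principal Coordinates of Neighbour Matrices takes the inter-site distance
matrix, truncates it at a threshold t (default: the longest edge of the
minimum spanning tree, which keeps the neighbour graph connected), replaces
every distance above t by 4t, and extracts the positive-eigenvalue axes of a
principal-coordinates analysis of the truncated matrix.  The resulting
eigenvectors are orthogonal, centred spatial patterns ordered from broadest
to finest scale; they serve as the spatial predictor block W in variation
partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datamodel import SiteCoordinates

__all__ = [
    "PCNMBasis",
    "PCNM",
    "pairwise_distances",
    "mst_truncation",
    "pcnm",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class PCNMBasis:
    """Positive spatial eigenvectors with their eigenvalues and truncation."""

    vectors: np.ndarray          # n_sites x k, column j scaled to norm sqrt(eigenvalue j)
    eigenvalues: np.ndarray      # k positive reals, descending
    truncation: float            # distance threshold in input units
    metric_used: str             # "euclidean" | "haversine_km"
    site_ids: list[str] | None = None

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def to_csv(self, path: str | Path) -> None:
        """CSV with site label column and V1..Vk; eigenvalues and truncation
        in commented header lines."""
        path = Path(path)
        n, k = self.vectors.shape
        labels = self.site_ids if self.site_ids is not None else [str(i) for i in range(n)]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# metric={self.metric_used} truncation={self.truncation:.17g}\n")
            for j in range(k):
                fh.write(f"# eigenvalue V{j + 1}={self.eigenvalues[j]:.17g}\n")
            fh.write("site," + ",".join(f"V{j + 1}" for j in range(k)) + "\n")
            for i in range(n):
                row = ",".join(f"{v:.17g}" for v in self.vectors[i])
                fh.write(f"{labels[i]},{row}\n")


def _haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lon = np.radians(lon)
    lat = np.radians(lat)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    h = np.clip(h, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))
    np.fill_diagonal(d, 0.0)
    return d


def pairwise_distances(coords: SiteCoordinates) -> np.ndarray:
    """Symmetric inter-site distance matrix.

    Planar coordinates use the Euclidean metric; longitude/latitude use
    great-circle (haversine) distance in kilometres on a sphere of radius
    6371.0088 km.
    """
    if coords.n_sites < 3:
        raise ValueError("need at least 3 sites")
    if coords.crs_mode == "lonlat":
        return _haversine_matrix(coords.x, coords.y)
    pts = np.column_stack([coords.x, coords.y])
    return squareform(pdist(pts, metric="euclidean"))


def mst_truncation(dist: np.ndarray) -> float:
    """Longest edge of a minimum spanning tree over the full distance graph.

    This is the smallest threshold that keeps every site connected to its
    neighbour graph; with tied edge weights the multiset of MST edge weights
    is unique, so the result is deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    mst = minimum_spanning_tree(dist)
    return float(mst.data.max())


def pcnm(dist: np.ndarray, truncation: float | None = None) -> PCNMBasis:
    """PCNM basis from a distance matrix.

    Distances above the truncation t are set to 4t, the truncated matrix is
    Gower-centred (−½ J D² J), and eigenvectors with positive eigenvalue
    (> 1e-9 × the largest) are kept, each scaled to norm sqrt(eigenvalue).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if truncation is None:
        truncation = mst_truncation(dist)
    t = float(truncation)
    if t <= 0:
        raise ValueError("truncation must be positive")
    D = np.where(dist <= t, dist, 4.0 * t)
    np.fill_diagonal(D, 0.0)
    A = -0.5 * D * D
    # Gower double-centring
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    keep = evals > 1e-9 * evals[0] if evals[0] > 0 else np.zeros(n, dtype=bool)
    if not np.any(keep):
        raise ValueError("degenerate geometry: no positive PCNM eigenvalues")
    evals = evals[keep]
    evecs = evecs[:, keep] * np.sqrt(evals)[None, :]
    return PCNMBasis(
        vectors=evecs,
        eigenvalues=evals,
        truncation=t,
        metric_used="euclidean",
    )


class PCNM(TransformerMixin, BaseEstimator):
    """PCNM spatial filters as a scikit-learn transformer.

    ``fit`` takes a :class:`SiteCoordinates` (or an ``(n, 2)`` array of
    planar coordinates) and computes the basis; ``transform`` returns the
    eigenvector matrix for those same sites.  There is no out-of-sample
    extension — PCNM filters are tied to the sampled site set.

    Parameters
    ----------
    truncation : float, optional
        Distance threshold; defaults to the longest minimum-spanning-tree
        edge of the inter-site distance graph.

    Attributes
    ----------
    basis_ : PCNMBasis
    vectors_ : ndarray of shape (n_sites, k)
    eigenvalues_ : ndarray of shape (k,)
    truncation_ : float
    """

    def __init__(self, truncation: float | None = None):
        self.truncation = truncation

    def fit(self, X, y=None):
        if isinstance(X, SiteCoordinates):
            coords = X
            metric = "haversine_km" if X.crs_mode == "lonlat" else "euclidean"
            site_ids = X.site_ids
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("expected SiteCoordinates or an (n, 2) array")
            coords = SiteCoordinates(
                [str(i) for i in range(arr.shape[0])], arr[:, 0], arr[:, 1]
            )
            metric = "euclidean"
            site_ids = None
        dist = pairwise_distances(coords)
        basis = pcnm(dist, truncation=self.truncation)
        basis.metric_used = metric
        basis.site_ids = list(site_ids) if site_ids is not None else None
        self.basis_ = basis
        self.vectors_ = basis.vectors
        self.eigenvalues_ = basis.eigenvalues
        self.truncation_ = basis.truncation
        self.n_features_in_ = 2
        return self

    def transform(self, X=None) -> np.ndarray:
        check_is_fitted(self)
        return self.vectors_

    def fit_transform(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X).transform(X)
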