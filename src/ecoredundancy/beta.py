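"""Pairwise taxonomic and functional β-diversity (Jaccard).

Taxonomic dissimilarity between two sites is the classic Jaccard index
on species sets.  Functional dissimilarity replaces species counts
with convex-hull volumes in the reduced trait space: with hull volumes
V_a, V_b and intersection volume V_s,

    d = ((V_a - V_s) + (V_b - V_s)) / (V_a + V_b - V_s).

Sites need at least ``min_species`` unique trait-space points and a
full-dimensional hull to enter the functional computation; excluded
sites are reported alongside the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .trait_space import TraitSpace

__all__ = [
    "DissimilarityMatrix",
    "taxonomic_jaccard",
    "hull_volume",
    "hull_intersection_volume",
    "functional_jaccard",
]

PAIR_WARN_LIMIT = 2_000_000


class DegenerateGeometryError(ValueError):
    """Point set does not span a full-dimensional hull."""


@dataclass
class DissimilarityMatrix:
    """Symmetric site × site dissimilarity with provenance tag."""

    matrix: pd.DataFrame
    facet: str  # "taxonomic" | "functional"
    excluded_sites: list = field(default_factory=list)

    @property
    def sites(self) -> list:
        return list(self.matrix.index)

    def condensed(self) -> pd.DataFrame:
        """Long-format table (site_i, site_j, d) over unordered pairs."""
        ids = self.sites
        rows = []
        m = self.matrix.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], m[i, j]))
        return pd.DataFrame(rows, columns=["site_i", "site_j", "d"])


def taxonomic_jaccard(community: pd.DataFrame) -> DissimilarityMatrix:
    """Jaccard dissimilarity (b + c)/(a + b + c) between all site pairs.

    Pairs where both sites are empty have no defined dissimilarity and
    are returned as NaN.
    """
    occ = community.to_numpy(dtype=bool)
    inter = (occ.astype(np.int32) @ occ.astype(np.int32).T).astype(float)
    richness = occ.sum(axis=1).astype(float)
    union = richness[:, None] + richness[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(
        matrix=pd.DataFrame(d, index=community.index, columns=community.index),
        facet="taxonomic",
    )


def hull_volume(points: np.ndarray) -> float:
    """Convex hull volume of a full-dimensional point set.

    Raises :class:`DegenerateGeometryError` for too few or degenerate
    (lower-dimensional) points.
    """
    points = np.unique(np.asarray(points, dtype=float), axis=0)
    m = points.shape[1]
    if points.shape[0] < m + 1:
        raise DegenerateGeometryError(
            f"need at least {m + 1} unique points in {m}D, got {points.shape[0]}"
        )
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc


def _interior_point(halfspaces: np.ndarray) -> np.ndarray | None:
    """Chebyshev centre of Ax + b <= 0; None if empty/lower-dimensional."""
    a = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    norms = np.linalg.norm(a, axis=1)
    n_dim = a.shape[1]
    # maximize r s.t. a x + r||a|| + b <= 0
    c = np.zeros(n_dim + 1)
    c[-1] = -1.0
    a_ub = np.hstack([a, norms[:, None]])
    res = linprog(c, A_ub=a_ub, b_ub=-b, bounds=[(None, None)] * n_dim + [(0, None)])
    if not res.success or res.x[-1] <= 1e-10:
        return None
    return res.x[:-1]


def hull_intersection_volume(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Volume of the intersection of the convex hulls of two point sets.

    The facet inequalities of both hulls are pooled and a strictly
    interior point is found by a Chebyshev-centre linear program; the
    half-space intersection is then re-hulled for its volume.  Returns
    0 when the hulls are disjoint or meet in a lower-dimensional set.
    """
    pa = np.unique(np.asarray(points_a, dtype=float), axis=0)
    pb = np.unique(np.asarray(points_b, dtype=float), axis=0)
    try:
        ha = ConvexHull(pa)
        hb = ConvexHull(pb)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate input hull: {exc}") from exc
    halfspaces = np.vstack([ha.equations, hb.equations])
    centre = _interior_point(halfspaces)
    if centre is None:
        return 0.0
    try:
        hs = HalfspaceIntersection(halfspaces, centre)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def functional_jaccard(
    community: pd.DataFrame,
    space: TraitSpace,
    m_axes: int = 2,
    min_species: int = 5,
) -> DissimilarityMatrix:
    """Functional Jaccard dissimilarity between all retained site pairs.

    Sites with fewer than ``min_species`` unique trait-space points, or
    whose points are degenerate in ``m_axes`` dimensions, are excluded
    from the matrix and listed in ``excluded_sites``.
    """
    if m_axes >= min_species:
        raise ValueError(
            f"m_axes={m_axes} needs at least m_axes+1 points; min_species={min_species} "
            "must exceed m_axes"
        )
    coords = space.coordinates.reindex(community.columns).to_numpy()[:, :m_axes]
    if np.isnan(coords).any():
        raise KeyError("community species missing from trait space")

    occ = community.to_numpy(dtype=bool)
    site_points: list[np.ndarray | None] = []
    volumes: list[float] = []
    retained_idx = []
    excluded = []
    for i, site in enumerate(community.index):
        pts = np.unique(coords[occ[i]], axis=0)
        if pts.shape[0] < min_species:
            excluded.append(site)
            site_points.append(None)
            volumes.append(np.nan)
            continue
        try:
            v = hull_volume(pts)
        except DegenerateGeometryError:
            excluded.append(site)
            site_points.append(None)
            volumes.append(np.nan)
            continue
        retained_idx.append(i)
        site_points.append(pts)
        volumes.append(v)

    n = len(retained_idx)
    n_pairs = n * (n - 1) // 2
    if n_pairs > PAIR_WARN_LIMIT:
        warnings.warn(
            f"{n_pairs} site pairs requested; this will be slow", RuntimeWarning,
            stacklevel=2,
        )
    ids = [community.index[i] for i in retained_idx]
    d = np.zeros((n, n))
    for a in range(n):
        ia = retained_idx[a]
        for b in range(a + 1, n):
            ib = retained_idx[b]
            if np.array_equal(site_points[ia], site_points[ib]):
                d[a, b] = d[b, a] = 0.0
                continue
            vs = hull_intersection_volume(site_points[ia], site_points[ib])
            va, vb = volumes[ia], volumes[ib]
            vs = min(vs, va, vb)  # guard numerical overshoot
            union = va + vb - vs
            d[a, b] = d[b, a] = (union - vs) / union if union > 0 else np.nan
    return DissimilarityMatrix(
        matrix=pd.DataFrame(d, index=ids, columns=ids),
        facet="functional",
        excluded_sites=excluded,
    )
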