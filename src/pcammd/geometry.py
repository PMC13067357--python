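"""Signed-area barycentric coordinates and point/triangle geometry.

All functions are vectorized over leading axes: a "point" argument may be
a single 2-vector or an ``(..., 2)`` stack, and triangles are ``(3, 2)``
arrays (or stacks thereof where noted).  Barycentric coordinates are
computed as ratios of signed triangle areas, never by matrix inversion:
for vertex ``i`` the weight is the area of the sub-triangle spanned by
the point and the opposite edge, divided by the full triangle area, with
``(i, j, k)`` cyclic.  The three weights sum to one identically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "signed_area",
    "barycentric",
    "centroid_distance",
    "edge_distance",
    "point_triangle_distance",
    "project_to_nearest_edge",
]


def signed_area(a, b, c):
    """Signed area of triangle ``(a, b, c)``; positive if counter-clockwise.

    Half the determinant ``|ax ay 1; bx by 1; cx cy 1|``.  Broadcasts over
    leading axes of the three points.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    return 0.5 * (
        (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
        - (c[..., 0] - a[..., 0]) * (b[..., 1] - a[..., 1])
    )


def barycentric(p, tri, degeneracy_tol: float = 1e-9):
    """Area-ratio barycentric coordinates of ``p`` in triangle ``tri``.

    Parameters
    ----------
    p : (..., 2) array
    tri : (3, 2) array
    degeneracy_tol : float
        Minimum |area| (squared input units) below which the triangle is
        rejected as degenerate.

    Returns
    -------
    (..., 3) array of coordinates summing to 1 (up to round-off).
    """
    p = np.asarray(p, dtype=float)
    tri = np.asarray(tri, dtype=float)
    v0, v1, v2 = tri[0], tri[1], tri[2]
    denom = signed_area(v0, v1, v2)
    if abs(denom) <= degeneracy_tol:
        raise ValueError(f"degenerate triangle (|area| = {abs(denom):.3g})")
    lam0 = signed_area(p, v1, v2) / denom
    lam1 = signed_area(p, v2, v0) / denom
    lam2 = signed_area(p, v0, v1) / denom
    return np.stack([lam0, lam1, lam2], axis=-1)


def centroid_distance(p, tri):
    """Euclidean distance from ``p`` to the vertex mean of ``tri``."""
    p = np.asarray(p, dtype=float)
    centroid = np.asarray(tri, dtype=float).mean(axis=0)
    return np.linalg.norm(p - centroid, axis=-1)


def edge_distance(p, va, vb):
    """Distance from ``p`` to segment ``va-vb`` and the clamped parameter.

    Returns ``(distance, t_star)`` where the closest segment point is
    ``(1 - t_star) * va + t_star * vb`` with ``t_star`` clamped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    va = np.asarray(va, dtype=float)
    vb = np.asarray(vb, dtype=float)
    d = vb - va
    denom = np.einsum("...i,...i", d, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, np.einsum("...i,...i", p - va, d) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    foot = va + t[..., None] * d
    return np.linalg.norm(p - foot, axis=-1), t


def point_triangle_distance(p, tri):
    """Distance from ``p`` to the closed triangle ``tri`` (0 if inside)."""
    p = np.asarray(p, dtype=float)
    tri = np.asarray(tri, dtype=float)
    lam = barycentric(p, tri)
    inside = np.all(lam >= 0.0, axis=-1) & np.all(lam <= 1.0, axis=-1)
    dists = [edge_distance(p, tri[i], tri[(i + 1) % 3])[0] for i in range(3)]
    edge_min = np.min(np.stack(dists, axis=-1), axis=-1)
    return np.where(inside, 0.0, edge_min)


def project_to_nearest_edge(p, triangles):
    """Project ``p`` onto the nearest point of the union of triangle edges.

    Parameters
    ----------
    p : (..., 2) array
    triangles : (K, 3, 2) array

    Returns
    -------
    projected : (..., 2) array
        Closest boundary point across all edges of all triangles.
    domain_index : (...) int array
        Owning triangle.  Exact distance ties are resolved by the
        smallest centroid distance, then the lowest triangle index.
    """
    p = np.asarray(p, dtype=float)
    triangles = np.asarray(triangles, dtype=float)
    K = triangles.shape[0]

    dists = np.empty(p.shape[:-1] + (K, 3))
    feet = np.empty(p.shape[:-1] + (K, 3, 2))
    for k in range(K):
        for e in range(3):
            va, vb = triangles[k, e], triangles[k, (e + 1) % 3]
            d, t = edge_distance(p, va, vb)
            dists[..., k, e] = d
            feet[..., k, e, :] = va + t[..., None] * (vb - va)

    flat_d = dists.reshape(p.shape[:-1] + (K * 3,))
    dmin = flat_d.min(axis=-1)

    centroids = triangles.mean(axis=1)  # (K, 2)
    cdist = np.linalg.norm(p[..., None, :] - centroids, axis=-1)  # (..., K)
    # lexicographic selection: exact-minimal edge distance, then centroid
    # distance of the owning triangle, then declaration order
    is_min = flat_d == dmin[..., None]  # (..., K*3)
    cdist_edges = np.repeat(cdist, 3, axis=-1)
    masked = np.where(is_min, cdist_edges, np.inf)
    choice = masked.argmin(axis=-1)  # first occurrence wins ties

    flat_feet = feet.reshape(p.shape[:-1] + (K * 3, 2))
    projected = np.take_along_axis(flat_feet, choice[..., None, None], axis=-2)[..., 0, :]
    domain_index = choice // 3
    return projected, domain_index
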