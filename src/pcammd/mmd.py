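"""Multimaterial decomposition estimators.

Two voxel-wise three-material decomposition methods over a shared
triangle library:

``BarycentricMMD``
    The classical benchmark.  For each voxel it solves the 3x3 linear
    system (two attenuation equations plus the volume-conservation row)
    domain by domain in declaration order and keeps the first feasible
    solution (all fractions in [0, 1]).  If no domain is feasible it
    falls back to the domain nearest in attenuation space and returns
    that domain's raw solution, which may contain fractions outside
    [0, 1] -- the documented pathology of the method under noise.

``PCAMMD``
    Rotates measurements and library vertices into the principal-axis
    frame of the voxel cloud, then assigns each voxel geometrically in
    three passes: (1) interior containment with area-ratio barycentric
    coordinates, choosing the containing triangle with the smallest
    centroid distance; (2) edge adherence within a tolerance; (3)
    orthogonal projection onto the nearest triangle edge, recomputing
    the coordinates at the projected point.  Every voxel therefore
    receives fractions in [0, 1] summing to one, by construction.

Both follow the scikit-learn estimator protocol (``fit`` /
``transform`` on an ``(N, 2)`` measurement matrix); ``decompose``
additionally returns per-voxel assignment metadata.  Module-level
functions wrap the estimators for whole dual-energy volumes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import geometry
from .materials import MaterialDomain, MaterialLibrary, build_default_library
from .pca import PCAModel, fit_pca, pca_transform

__all__ = [
    "BCResult",
    "PCAMMDResult",
    "BarycentricMMD",
    "PCAMMD",
    "solve_triplet",
    "hausdorff_fallback",
    "decompose_bc",
    "decompose_pca",
]

#: Feasibility slack on the [0, 1] bound of the benchmark method,
#: absorbing round-off at triangle edges.
FEASIBILITY_TOL = 1e-9


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------
@dataclasses.dataclass
class BCResult:
    """Per-voxel output of the benchmark method.

    fractions : (N, n_materials); rows sum to 1, but entries may fall
    outside [0, 1] wherever ``feasible`` is False.
    """

    fractions: np.ndarray
    chosen_domain: np.ndarray
    feasible: np.ndarray
    material_names: tuple[str, ...]


@dataclasses.dataclass
class PCAMMDResult:
    """Per-voxel output of the PCA method.

    Every fraction lies in [0, 1] and each row sums to 1.  ``pass_used``
    records which geometric pass assigned the voxel; ``projected_point``
    is the PCA-space point actually decomposed (the measurement itself
    for passes 1-2, the edge projection for pass 3).
    """

    fractions: np.ndarray
    chosen_domain: np.ndarray
    pass_used: np.ndarray
    projected_point: np.ndarray
    material_names: tuple[str, ...]


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------
def solve_triplet(mu, domain: MaterialDomain, lib: MaterialLibrary) -> np.ndarray:
    """Solve the 3x3 attenuation system for one voxel in one domain.

    Rows: low-energy attenuation, high-energy attenuation, and the
    volume-conservation constraint (fractions sum to one).  The solution
    is unique for a non-degenerate triangle and is *not* clipped: values
    outside [0, 1] signal that ``mu`` lies outside the triangle.
    """
    mu = np.asarray(mu, dtype=float)
    verts = np.array([lib.material(name).vertex for name in domain.vertices])
    A = np.vstack([verts.T, np.ones(3)])
    b = np.array([mu[0], mu[1], 1.0])
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate domain {domain.label!r}: {exc}") from exc


def hausdorff_fallback(mu, lib: MaterialLibrary) -> int:
    """Index of the domain whose closed triangle is nearest to ``mu``.

    For a single point against a point set the directed Hausdorff
    distance reduces to the minimum Euclidean distance.  Ties go to the
    earliest declared domain.
    """
    if len(lib.domains) == 0:
        raise ValueError("library has no domains")
    mu = np.asarray(mu, dtype=float)
    dists = [geometry.point_triangle_distance(mu, tri) for tri in lib.triangles()]
    return int(np.argmin(dists))


# ---------------------------------------------------------------------------
# benchmark estimator
# ---------------------------------------------------------------------------
class BarycentricMMD(TransformerMixin, BaseEstimator):
    """First-feasible triangle search with a nearest-triangle fallback.

    Parameters
    ----------
    library : MaterialLibrary, optional
        Defaults to the built-in six-material library.  Declaration
        order of the domains is the search priority.
    feasibility_tol : float
        Fractions within ``[-tol, 1 + tol]`` count as feasible.
    """

    def __init__(self, library: MaterialLibrary | None = None,
                 feasibility_tol: float = FEASIBILITY_TOL):
        self.library = library
        self.feasibility_tol = feasibility_tol

    def fit(self, X=None, y=None):
        lib = self.library if self.library is not None else build_default_library()
        self.library_ = lib
        verts = lib.triangles()  # (K, 3, 2)
        systems = np.concatenate(
            [verts.transpose(0, 2, 1), np.ones((verts.shape[0], 1, 3))], axis=1
        )  # (K, 3, 3): rows = low, high, ones
        self.solvers_ = np.linalg.inv(systems)  # (K, 3, 3)
        self.n_features_in_ = 2
        if X is not None:
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != 2:
                raise ValueError("expected an (N, 2) measurement matrix")
        return self

    def decompose(self, X) -> BCResult:
        if not hasattr(self, "library_"):
            self.fit(None)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (N, 2) measurement matrix")
        lib = self.library_
        tol = self.feasibility_tol
        n = X.shape[0]
        K = len(lib.domains)
        aug = np.concatenate([X, np.ones((n, 1))], axis=1)  # (N, 3)

        alphas = np.einsum("kij,nj->nki", self.solvers_, aug)  # (N, K, 3)
        feasible_k = np.all(alphas >= -tol, axis=2) & np.all(alphas <= 1 + tol, axis=2)

        any_feasible = feasible_k.any(axis=1)
        first_feasible = feasible_k.argmax(axis=1)  # first True in order

        # fallback: nearest closed triangle (first minimum wins ties)
        triangles = lib.triangles()
        need = ~any_feasible
        chosen = first_feasible.copy()
        if np.any(need):
            dists = np.stack(
                [geometry.point_triangle_distance(X[need], tri) for tri in triangles],
                axis=1,
            )
            chosen[need] = dists.argmin(axis=1)

        picked = np.take_along_axis(alphas, chosen[:, None, None], axis=1)[:, 0, :]
        fractions = np.zeros((n, len(lib.materials)))
        vidx = lib.domain_vertex_indices()  # (K, 3)
        np.put_along_axis(fractions, vidx[chosen], picked, axis=1)
        return BCResult(
            fractions=fractions,
            chosen_domain=chosen,
            feasible=any_feasible,
            material_names=lib.material_names,
        )

    def transform(self, X) -> np.ndarray:
        """Per-voxel volume fractions, one column per library material."""
        return self.decompose(X).fractions


# ---------------------------------------------------------------------------
# PCA estimator
# ---------------------------------------------------------------------------
class PCAMMD(TransformerMixin, BaseEstimator):
    """Three-pass geometric decomposition in the principal-axis frame.

    Parameters
    ----------
    library : MaterialLibrary, optional
    epsilon_inside : float
        Containment slack on barycentric coordinates in pass 1.
    epsilon_edge : float
        Edge-adherence tolerance (same units as the measurements) in
        pass 2.
    rotation : {"pca", "identity"}
        "pca" fits the principal axes on the measurements passed to
        ``fit``; "identity" skips the rotation.  The assignment and the
        fractions are provably identical either way (the rotation is
        rigid); "identity" exists for single-point studies and tests.
    chunk_size : int
        Voxels processed per vectorized block, bounding peak memory.
    """

    def __init__(self, library: MaterialLibrary | None = None,
                 epsilon_inside: float = 1e-6, epsilon_edge: float = 1e-6,
                 rotation: str = "pca", chunk_size: int = 1 << 18):
        self.library = library
        self.epsilon_inside = epsilon_inside
        self.epsilon_edge = epsilon_edge
        self.rotation = rotation
        self.chunk_size = chunk_size

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None):
        lib = self.library if self.library is not None else build_default_library()
        self.library_ = lib
        if self.rotation == "pca":
            self.pca_ = fit_pca(X)
        elif self.rotation == "identity":
            self.pca_ = PCAModel(mean=np.zeros(2), eigenvectors=np.eye(2),
                                 eigenvalues=np.zeros(2))
        else:
            raise ValueError(f"unknown rotation {self.rotation!r}")

        self.mean_ = self.pca_.mean
        self.components_ = self.pca_.eigenvectors.T  # rows = principal axes
        self.explained_variance_ = self.pca_.eigenvalues
        self.vertices_pca_ = pca_transform(self.pca_, lib.vertex_matrix())
        self.triangles_pca_ = self.vertices_pca_[lib.domain_vertex_indices()]
        areas = geometry.signed_area(
            self.triangles_pca_[:, 0], self.triangles_pca_[:, 1], self.triangles_pca_[:, 2]
        )
        for k, area in enumerate(areas):
            if abs(area) <= 1e-9:
                raise ValueError(
                    f"domain {lib.domains[k].label!r} degenerate after PCA projection"
                )
        self.areas_pca_ = areas
        self.centroids_pca_ = self.triangles_pca_.mean(axis=1)
        self.n_features_in_ = 2
        return self

    # -- decomposition ---------------------------------------------------
    def decompose(self, X) -> PCAMMDResult:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (N, 2) measurement matrix")
        if not hasattr(self, "triangles_pca_"):
            raise RuntimeError("estimator is not fitted")
        n = X.shape[0]
        lib = self.library_
        M = len(lib.materials)
        fractions = np.empty((n, M))
        chosen = np.empty(n, dtype=np.int64)
        pass_used = np.empty(n, dtype=np.int8)
        projected = np.empty((n, 2))
        step = max(int(self.chunk_size), 1)
        for lo in range(0, n, step):
            hi = min(lo + step, n)
            f, c, p, q = self._decompose_block(X[lo:hi])
            fractions[lo:hi] = f
            chosen[lo:hi] = c
            pass_used[lo:hi] = p
            projected[lo:hi] = q
        return PCAMMDResult(
            fractions=fractions,
            chosen_domain=chosen,
            pass_used=pass_used,
            projected_point=projected,
            material_names=lib.material_names,
        )

    def _lambdas(self, P):
        """Area-ratio barycentric coordinates of P against every triangle.

        P: (n, 2) PCA-space points -> (n, K, 3).
        """
        tri = self.triangles_pca_  # (K, 3, 2)
        p = P[:, None, :]  # (n, 1, 2)
        lam = np.empty((P.shape[0], tri.shape[0], 3))
        for i in range(3):
            vj = tri[:, (i + 1) % 3]  # (K, 2)
            vk = tri[:, (i + 2) % 3]
            # signed_area(p, vj, vk) broadcast over (n, K)
            lam[:, :, i] = 0.5 * (
                (vj[:, 0] - p[..., 0]) * (vk[:, 1] - p[..., 1])
                - (vk[:, 0] - p[..., 0]) * (vj[:, 1] - p[..., 1])
            ) / self.areas_pca_
        return lam

    @staticmethod
    def _clip_renormalize(lam):
        """Clamp rows to [0, 1] and renormalize, touching only out-of-range rows."""
        out = lam.copy()
        bad = (out < 0.0) | (out > 1.0)
        rows = bad.any(axis=-1)
        if np.any(rows):
            clipped = np.clip(out[rows], 0.0, 1.0)
            clipped /= clipped.sum(axis=-1, keepdims=True)
            out[rows] = clipped
        return out

    def _decompose_block(self, X):
        eps = self.epsilon_inside
        P = pca_transform(self.pca_, X)  # (n, 2)
        n = P.shape[0]
        K = self.triangles_pca_.shape[0]

        lam = self._lambdas(P)  # (n, K, 3)
        lamsum = lam.sum(axis=2)
        inside = (
            np.all(lam >= -eps, axis=2)
            & np.all(lam <= 1 + eps, axis=2)
            & (np.abs(lamsum - 1.0) < 1e-6)
        )
        cdist = np.linalg.norm(P[:, None, :] - self.centroids_pca_, axis=2)  # (n, K)

        chosen = np.full(n, -1, dtype=np.int64)
        pass_used = np.zeros(n, dtype=np.int8)
        projected = P.copy()

        # Pass 1: containing triangle with the smallest centroid distance
        p1 = inside.any(axis=1)
        if np.any(p1):
            masked = np.where(inside[p1], cdist[p1], np.inf)
            chosen[p1] = masked.argmin(axis=1)
            pass_used[p1] = 1

        # Pass 2: edge-adhering triangles
        rest = ~p1
        if np.any(rest):
            Pr = P[rest]
            edge_d = np.empty((Pr.shape[0], K, 3))
            edge_t = np.empty((Pr.shape[0], K, 3))
            tri = self.triangles_pca_
            for k in range(K):
                for e in range(3):
                    d, t = geometry.edge_distance(Pr, tri[k, e], tri[k, (e + 1) % 3])
                    edge_d[:, k, e] = d
                    edge_t[:, k, e] = t
            adhere = (edge_d < self.epsilon_edge).any(axis=2)  # (nr, K)
            p2_local = adhere.any(axis=1)
            rest_idx = np.flatnonzero(rest)
            if np.any(p2_local):
                idx = rest_idx[p2_local]
                masked = np.where(adhere[p2_local], cdist[idx], np.inf)
                chosen[idx] = masked.argmin(axis=1)
                pass_used[idx] = 2

            # Pass 3: projection onto the nearest edge of any triangle
            p3_local = ~p2_local
            if np.any(p3_local):
                idx = rest_idx[p3_local]
                d3 = edge_d[p3_local].reshape(idx.size, K * 3)
                t3 = edge_t[p3_local].reshape(idx.size, K * 3)
                dmin = d3.min(axis=1)
                is_min = d3 == dmin[:, None]
                cdist_edges = np.repeat(cdist[idx], 3, axis=1)
                choice = np.where(is_min, cdist_edges, np.inf).argmin(axis=1)
                dom = choice // 3
                edge = choice % 3
                va = tri[dom, edge]
                vb = tri[dom, (edge + 1) % 3]
                tstar = np.take_along_axis(t3, choice[:, None], axis=1)[:, 0]
                foot = va + tstar[:, None] * (vb - va)
                chosen[idx] = dom
                pass_used[idx] = 3
                projected[idx] = foot

        # recompute coordinates at the decomposed point (the measurement
        # itself for passes 1-2, the edge projection for pass 3) and
        # gather the chosen triangle's row for every voxel
        lam_all = self._lambdas(projected)  # (n, K, 3)
        picked = np.take_along_axis(lam_all, chosen[:, None, None], axis=1)[:, 0, :]
        picked = self._clip_renormalize(picked)

        fractions = np.zeros((n, len(self.library_.materials)))
        vidx = self.library_.domain_vertex_indices()
        np.put_along_axis(fractions, vidx[chosen], picked, axis=1)
        return fractions, chosen, pass_used, projected

    def transform(self, X) -> np.ndarray:
        """Per-voxel volume fractions, one column per library material."""
        return self.decompose(X).fractions

    def predict(self, X) -> np.ndarray:
        """Per-voxel index of the assigned domain."""
        return self.decompose(X).chosen_domain


# ---------------------------------------------------------------------------
# volume-level wrappers
# ---------------------------------------------------------------------------
def decompose_bc(volume, lib: MaterialLibrary | None = None):
    """Run the benchmark method on a dual-energy volume.

    Returns ``(FractionMaps, BCResult)``; the fraction maps share the
    volume grid, the result carries flat per-voxel metadata.
    """
    from .io import FractionMaps  # local import: io depends on materials only

    est = BarycentricMMD(library=lib).fit(None)
    res = est.decompose(volume.as_points())
    maps = FractionMaps.from_flat(
        res.fractions, volume, est.library_, method="bc_mmd",
        metadata={
            "feasible": res.feasible.reshape(volume.shape),
            "chosen_domain": res.chosen_domain.reshape(volume.shape),
        },
    )
    return maps, res


def decompose_pca(volume, lib: MaterialLibrary | None = None,
                  epsilon_inside: float = 1e-6, epsilon_edge: float = 1e-6,
                  mask=None):
    """Run the PCA method on a dual-energy volume.

    The principal axes are fitted on all voxels of the volume (or on the
    optional boolean ``mask``); the decomposition itself always covers
    every voxel.
    """
    from .io import FractionMaps

    points = volume.as_points()
    fit_points = points if mask is None else points[np.asarray(mask).ravel()]
    est = PCAMMD(
        library=lib, epsilon_inside=epsilon_inside, epsilon_edge=epsilon_edge
    ).fit(fit_points)
    res = est.decompose(points)
    maps = FractionMaps.from_flat(
        res.fractions, volume, est.library_, method="pca_mmd",
        metadata={
            "pass_used": res.pass_used.reshape(volume.shape),
            "chosen_domain": res.chosen_domain.reshape(volume.shape),
        },
    )
    return maps, res
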