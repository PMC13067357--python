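"""Benchmark barycentric decomposition: solve, fallback, and pathology."""

import numpy as np
import pytest

from pcammd.geometry import point_triangle_distance
from pcammd.io import DualEnergyVolume
from pcammd.materials import MaterialBasis, MaterialDomain, MaterialLibrary
from pcammd.mmd import BarycentricMMD, decompose_bc, hausdorff_fallback, solve_triplet
from pcammd.phantom import PhantomSpec, render_dual_energy

from conftest import random_triangle


def library_from_triangles(triangles):
    """One material per unique vertex, one domain per triangle."""
    mats, names = [], []
    for t, tri in enumerate(triangles):
        row = []
        for v, (x, y) in enumerate(tri):
            name = f"m{t}_{v}"
            mats.append(MaterialBasis(name, float(x), float(y)))
            row.append(name)
        names.append(tuple(row))
    domains = tuple(MaterialDomain(row, label=f"d{t}") for t, row in enumerate(names))
    return MaterialLibrary((70.0, 150.0), tuple(mats), domains)


class TestSolveTriplet:
    def test_vertex_identity(self, lib):
        dom = lib.domains[lib.domain_index_by_vertices(("water", "air", "iodine"))]
        mu = lib.material("iodine").vertex
        alpha = solve_triplet(mu, dom, lib)
        expect = [1.0 if v == "iodine" else 0.0 for v in dom.vertices]
        assert alpha == pytest.approx(expect, abs=1e-12)

    def test_centroid_symmetry(self, lib):
        dom = lib.domains[0]
        verts = np.array([lib.material(v).vertex for v in dom.vertices])
        alpha = solve_triplet(verts.mean(axis=0), dom, lib)
        assert alpha == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_matches_least_squares_oracle(self, rng):
        for _ in range(20):
            tri = random_triangle(rng)
            sub = library_from_triangles([tri])
            mu = rng.uniform(-1500, 1500, 2)
            alpha = solve_triplet(mu, sub.domains[0], sub)
            A = np.vstack([tri.T, np.ones(3)])
            oracle, *_ = np.linalg.lstsq(A, np.array([mu[0], mu[1], 1.0]), rcond=None)
            assert np.abs(alpha - oracle).max() < 1e-10


class TestHausdorffFallback:
    def test_unique_nearest_triangle(self):
        sub = library_from_triangles([
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            np.array([[100.0, 100.0], [101.0, 100.0], [100.0, 101.0]]),
        ])
        assert hausdorff_fallback((2.0, 0.0), sub) == 0
        assert hausdorff_fallback((99.0, 100.0), sub) == 1

    def test_tie_broken_by_declaration_order(self):
        tri = np.array([[1.0, -1.0], [2.0, -1.0], [2.0, 1.0]])
        mirrored = tri * [-1.0, 1.0]
        sub = library_from_triangles([tri, mirrored])
        # origin is equidistant from both triangles
        assert hausdorff_fallback((0.0, 0.0), sub) == 0

    def test_empty_library_rejected(self, lib):
        empty = MaterialLibrary(lib.energies, lib.materials, ())
        with pytest.raises(ValueError, match="no domains"):
            hausdorff_fallback((0.0, 0.0), empty)

    def test_matches_dense_sampling_oracle(self, rng, lib):
        tris = lib.triangles()
        ts = np.linspace(0, 1, 100_000)
        boundary, owner = [], []
        for k, tri in enumerate(tris):
            for e in range(3):
                va, vb = tri[e], tri[(e + 1) % 3]
                boundary.append(va + ts[:, None] * (vb - va))
                owner.append(np.full(ts.size, k))
        boundary = np.concatenate(boundary)
        owner = np.concatenate(owner)
        for _ in range(50):
            p = rng.uniform(-6000, 6000, 2)
            if any(point_triangle_distance(p, tri) == 0 for tri in tris):
                continue
            k = hausdorff_fallback(p, lib)
            d_k = point_triangle_distance(p, tris[k])
            d_oracle = np.linalg.norm(boundary - p, axis=1).min()
            assert d_k <= d_oracle + 1e-6


class TestDecompose:
    def test_pure_rod_and_water_voxels(self, lib):
        iodine = lib.material("iodine").vertex
        X = np.array([iodine, [0.0, 0.0]])
        res = BarycentricMMD(library=lib).fit(None).decompose(X)
        i_iod = lib.material_index("iodine")
        i_wat = lib.material_index("water")
        assert res.fractions[0, i_iod] == pytest.approx(1.0, abs=1e-9)
        assert res.fractions[1, i_wat] == pytest.approx(1.0, abs=1e-9)
        assert res.feasible.all()

    def test_outside_point_is_unphysical(self, lib):
        # far above every triangle: high-energy HU >> low-energy HU
        res = BarycentricMMD(library=lib).fit(None).decompose(np.array([[0.0, 800.0]]))
        assert not res.feasible[0]
        assert (res.fractions[0] < -1e-9).any() or (res.fractions[0] > 1 + 1e-9).any()
        assert res.fractions[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_first_feasible_in_declaration_order(self, lib):
        # a point on the shared water-collagen edge lies in several
        # domains; the benchmark must pick the earliest declared one
        water = lib.material("water").vertex
        collagen = lib.material("collagen").vertex
        p = 0.5 * (water + collagen)
        res = BarycentricMMD(library=lib).fit(None).decompose(p[None])
        candidates = [
            k for k, tri in enumerate(lib.triangles())
            if point_triangle_distance(p, tri) == 0
        ]
        assert len(candidates) >= 2
        assert res.chosen_domain[0] == min(candidates)

    def test_volume_wrapper_all_water(self, lib):
        vol = DualEnergyVolume(low=np.zeros((2, 4, 4)), high=np.zeros((2, 4, 4)))
        maps, res = decompose_bc(vol, lib)
        assert maps.fraction("water") == pytest.approx(np.ones((2, 4, 4)))
        assert maps.method == "bc_mmd"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grids differ"):
            DualEnergyVolume(low=np.zeros((2, 4, 4)), high=np.zeros((2, 4, 5)))

    def test_fractions_always_sum_to_one(self, rng, lib):
        X = rng.uniform(-2500, 2500, size=(500, 2))
        res = BarycentricMMD(library=lib).fit(None).decompose(X)
        assert np.abs(res.fractions.sum(axis=1) - 1.0).max() < 1e-9

    def test_feasible_fractions_within_bounds(self, rng, lib):
        X = rng.uniform(-1000, 600, size=(2000, 2))
        res = BarycentricMMD(library=lib).fit(None).decompose(X)
        ok = res.fractions[res.feasible]
        assert ok.min() >= -1e-9 and ok.max() <= 1 + 1e-9

    def test_vectorized_equals_scalar_reference(self, rng, lib):
        X = rng.uniform(-2000, 2000, size=(200, 2))
        est = BarycentricMMD(library=lib).fit(None)
        res = est.decompose(X)
        tol = est.feasibility_tol
        for i, mu in enumerate(X):
            chosen = None
            for k, dom in enumerate(lib.domains):
                alpha = solve_triplet(mu, dom, lib)
                if np.all(alpha >= -tol) and np.all(alpha <= 1 + tol):
                    chosen, expect_feasible = k, True
                    break
            if chosen is None:
                chosen, expect_feasible = hausdorff_fallback(mu, lib), False
            alpha = solve_triplet(mu, lib.domains[chosen], lib)
            assert res.chosen_domain[i] == chosen
            assert res.feasible[i] == expect_feasible
            expect = np.zeros(len(lib.materials))
            for name, a in zip(lib.domains[chosen].vertices, alpha):
                expect[lib.material_index(name)] = a
            assert np.abs(res.fractions[i] - expect).max() < 1e-9

    def test_noisy_phantom_produces_unphysical_voxels(self, lib):
        spec = PhantomSpec(grid=(2, 64, 64), size_class="small",
                           noise_sigma_ref=(200.0, 200.0), seed=7)
        vol, _ = render_dual_energy(spec, lib)
        _, res = decompose_bc(vol, lib)
        assert (~res.feasible).any()
        assert res.fractions.min() < -1e-9 or res.fractions.max() > 1 + 1e-9
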