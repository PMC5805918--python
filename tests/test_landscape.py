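"""Interpolation, DNEB, eigenvector-following, pathways, disconnectivity."""
import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ionhydrate import forcefield as ff
from ionhydrate import landscape as ls
from ionhydrate import optimize as opt
from ionhydrate.energy import ClusterPotential

from conftest import random_cluster


class DoubleWell1D:
    """U(x) = (x^2 - 1)^2: minima at +-1 (U=0), saddle at 0 (U=1)."""

    def energy_gradient(self, x):
        u = float((x[0] ** 2 - 1) ** 2)
        g = np.array([4 * x[0] * (x[0] ** 2 - 1)])
        return u, g

    def energy(self, x):
        return self.energy_gradient(x)[0]


class TwoGaussianWells2D:
    """Two unit-depth Gaussian wells at (+-1, 0); saddle at the origin with
    energy -2/e, known analytically by symmetry."""

    def energy_gradient(self, x):
        e = 0.0
        g = np.zeros(2)
        for cx in (1.0, -1.0):
            d = np.array([x[0] - cx, x[1]])
            w = np.exp(-(d @ d))
            e -= w
            g += 2 * d * w
        return e, g

    def energy(self, x):
        return self.energy_gradient(x)[0]


class TestInterpolation:
    def test_endpoints_exact(self, water_sp, rng):
        a = random_cluster((water_sp,) * 3, rng)
        b = random_cluster((water_sp,) * 3, rng)
        path = ls.interpolate_path(a, b, n_images=5, align=False)
        assert np.allclose(path[0].coords, a.coords)
        assert np.allclose(np.vstack(path[-1].site_positions()),
                           np.vstack(b.site_positions()), atol=1e-10)

    def test_identical_endpoints(self, water_sp, rng):
        a = random_cluster((water_sp,) * 2, rng)
        path = ls.interpolate_path(a, a, n_images=4, align=False)
        for img in path:
            assert np.allclose(img.coords, a.coords, atol=1e-12)

    def test_slerp_midpoint_of_90_degree_rotation(self, water_sp):
        a = ff.ClusterConfig((water_sp,), np.zeros((1, 3)), np.zeros((1, 3)))
        b = ff.ClusterConfig(
            (water_sp,), np.zeros((1, 3)),
            Rotation.from_euler("z", 90, degrees=True).as_rotvec()[None, :],
        )
        path = ls.interpolate_path(a, b, n_images=1, align=False)
        mid = Rotation.from_rotvec(path[1].orientations[0])
        expected = Rotation.from_euler("z", 45, degrees=True)
        assert (mid.inv() * expected).magnitude() < 1e-10

    def test_species_mismatch_rejected(self, water_sp, sulfite_sp, rng):
        a = random_cluster((water_sp,) * 2, rng)
        b = random_cluster((sulfite_sp, water_sp), rng)
        with pytest.raises(ValueError):
            ls.interpolate_path(a, b, 3)

    def test_align_recovers_transformed_copy(self, sulfite_sp, water_sp, rng):
        a = random_cluster((sulfite_sp,) + (water_sp,) * 4, rng)
        R = Rotation.random(random_state=4)
        perm = [0] + list(1 + np.random.default_rng(2).permutation(4))
        b = a.copy()
        b.translations = R.apply(a.translations[perm]) + np.array([2.0, -1.0, 3.0])
        b.orientations = (R * Rotation.from_rotvec(a.orientations[perm])).as_rotvec()
        b.species_list = tuple(a.species_list[i] for i in perm)
        b2 = ls.align_clusters(a, b)
        assert np.abs(
            np.vstack(a.site_positions()) - np.vstack(b2.site_positions())
        ).max() < 1e-10


class TestDNEB:
    def test_identical_endpoints_no_candidates(self):
        pot = DoubleWell1D()
        res = ls.dneb(pot, np.array([1.0]), np.array([1.0]))
        assert res.candidates == []

    def test_recovers_1d_double_well_barrier(self):
        pot = DoubleWell1D()
        res = ls.dneb(pot, np.array([-1.0]), np.array([1.0]), n_images=9,
                      tol=1e-5, maxiter=3000)
        assert len(res.candidates) == 1
        assert pot.energy(res.candidates[0]) == pytest.approx(1.0, abs=1e-3)

    def test_water_trimer_candidate_above_endpoints(self, water_sp):
        pot = ClusterPotential((water_sp,) * 3)
        minima = []
        for i in range(25):
            c = random_cluster((water_sp,) * 3, np.random.default_rng(50 + i))
            m, e = opt.local_minimize(c, 1e-5)
            minima.append((e, m))
        minima.sort(key=lambda t: t[0])
        (ea, a) = minima[0]
        (eb, b) = next((e, m) for e, m in minima if e > ea + 1e-3)
        b2 = ls.align_clusters(a, b)
        interp = ls.make_cluster_interpolator(a.species_list)
        res = ls.dneb(pot, a.coords, b2.coords, interpolator=interp)
        assert res.candidates
        # each refined saddle must lie above both minima it connects
        quench = ls._cluster_quench(a.species_list, 1e-5)
        for cand in res.candidates:
            ef = ls.hybrid_ef_refine(pot, cand, tol=1e-5, check_index=False)
            if not ef.converged:
                continue
            (xp, ep), (xm, em) = ls.fall_off(pot, ef.x, ef.eigenvector, quench=quench)
            assert ef.energy >= max(ep, em) - 1e-8


class TestHybridEF:
    def test_converges_to_analytic_saddle(self):
        pot = TwoGaussianWells2D()
        ef = ls.hybrid_ef_refine(pot, np.array([0.15, 0.1]), tol=1e-9)
        assert ef.converged
        assert np.abs(ef.x).max() < 1e-4
        assert ef.energy == pytest.approx(-2 / np.e, abs=1e-4)
        assert ef.n_negative == 1

    def test_refinement_is_idempotent_at_saddle(self):
        pot = TwoGaussianWells2D()
        ef1 = ls.hybrid_ef_refine(pot, np.array([0.2, -0.05]), tol=1e-9)
        ef2 = ls.hybrid_ef_refine(pot, ef1.x, tol=1e-9)
        assert np.abs(ef2.x - ef1.x).max() < 1e-6

    def test_falls_off_to_both_minima(self):
        pot = TwoGaussianWells2D()
        ef = ls.hybrid_ef_refine(pot, np.array([0.1, 0.02]), tol=1e-9)
        (xp, ep), (xm, em) = ls.fall_off(pot, ef.x, ef.eigenvector)
        xs = sorted([xp[0], xm[0]])
        assert xs[0] == pytest.approx(-0.9575, abs=1e-3)
        assert xs[1] == pytest.approx(0.9575, abs=1e-3)

    def test_minimum_candidate_rejected(self):
        pot = TwoGaussianWells2D()
        ef = ls.hybrid_ef_refine(pot, np.array([1.05, 0.0]), tol=1e-9, maxiter=40)
        # starting in a well bottom: either walks out to the true saddle or
        # reports failure; it must never return a fake saddle at a minimum
        if ef.converged:
            assert ef.eigenvalue < 0
            assert np.abs(ef.x[0]) < 1e-3


def _toy_landscape(rng, n_minima, n_ts):
    ldb = ls.LandscapeDB(dedup_tolerance=1e-12)
    energies = np.sort(rng.uniform(-10, -5, n_minima))
    for e in energies:
        ldb.add_minimum(float(e), None)
    for _ in range(n_ts):
        i, j = rng.integers(n_minima), rng.integers(n_minima)
        if i == j:
            continue
        e_ts = max(ldb.minima[i][0], ldb.minima[j][0]) + float(rng.uniform(0.1, 4.0))
        ldb.add_transition_state(e_ts, (int(i), int(j)))
    return ldb


def _brute_minimax(ldb):
    """All-pairs min-max TS energy by dynamic-programming closure."""
    n = len(ldb.minima)
    INF = np.inf
    W = np.full((n, n), INF)
    for i in range(n):
        W[i, i] = -INF
    for ts in ldb.transition_states:
        i, j = ts.connected_minima
        if i == j:
            continue
        W[i, j] = min(W[i, j], ts.energy)
        W[j, i] = W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                W[i, j] = min(W[i, j], max(W[i, k], W[k, j]))
    return W


class TestPathways:
    def test_empty_path_for_same_minimum(self, rng):
        ldb = _toy_landscape(rng, 5, 8)
        pw = ls.extract_pathway(ldb, 2, 2)
        assert pw.transition_states == [] and pw.barrier == 0.0

    def test_three_minima_chain_matches_enumeration(self):
        ldb = ls.LandscapeDB(dedup_tolerance=1e-12)
        for e in (-10.0, -9.0, -9.5):
            ldb.add_minimum(e, None)
        ldb.add_transition_state(-7.0, (0, 1))
        ldb.add_transition_state(-8.0, (1, 2))
        ldb.add_transition_state(-5.0, (0, 2))  # direct but higher
        pw = ls.extract_pathway(ldb, 0, 2)
        assert pw.minima == [0, 1, 2]
        assert pw.barrier == pytest.approx(-7.0 - (-10.0))
        assert pw.first_ts_energy == pytest.approx(-7.0)

    def test_minimax_matches_brute_force_on_random_toys(self, rng):
        for trial in range(5):
            ldb = _toy_landscape(rng, 12, 30)
            W = _brute_minimax(ldb)
            for i, j in itertools.combinations(range(12), 2):
                connected = np.isfinite(W[i, j])
                if not connected:
                    with pytest.raises(ValueError):
                        ls.extract_pathway(ldb, i, j)
                    continue
                pw = ls.extract_pathway(ldb, i, j)
                assert ldb.minima[i][0] + pw.barrier == pytest.approx(W[i, j])

    def test_barrier_identity_between_directions(self, rng):
        ldb = _toy_landscape(rng, 8, 20)
        gm = ldb.gm_id()
        comp = ldb.gm_component()
        other = next(iter(comp - {gm}), None)
        if other is None:
            pytest.skip("toy landscape came out disconnected")
        f = ls.extract_pathway(ldb, gm, other).barrier
        b = ls.extract_pathway(ldb, other, gm).barrier
        assert f - b == pytest.approx(
            ldb.minima[other][0] - ldb.minima[gm][0], abs=1e-10
        )


class TestDisconnectivity:
    def test_single_minimum_single_branch(self):
        ldb = ls.LandscapeDB()
        ldb.add_minimum(-5.0, None)
        tree = ls.build_disconnectivity(ldb, 0.35)
        assert all(len(level) == 1 for level in tree.superbasins)

    def test_superbasins_match_brute_force_minimax(self, rng):
        for trial in range(4):
            ldb = _toy_landscape(rng, 40, 90)
            W = _brute_minimax(ldb)
            tree = ls.build_disconnectivity(ldb, delta_e=0.5)
            E = ldb.energies
            for li, level in enumerate(tree.superbasins):
                lev = tree.levels[li]
                # same-superbasin iff minimax barrier energy <= level
                membership = {}
                for bi, sb in enumerate(level):
                    for m in sb:
                        membership[m] = bi
                for i, j in itertools.combinations(range(40), 2):
                    if E[i] > lev or E[j] > lev:
                        continue
                    together = membership[i] == membership[j]
                    assert together == bool(W[i, j] <= lev)

    def test_merge_order_stable_under_level_spacing(self, rng):
        ldb = _toy_landscape(rng, 10, 25)
        t1 = ls.build_disconnectivity(ldb, 0.2)
        t2 = ls.build_disconnectivity(ldb, 0.6)
        # any two minima merged at some level of the coarse tree are merged
        # at every fine level above that energy
        for li, level in enumerate(t2.superbasins):
            for sb in level:
                for i, j in itertools.combinations(sorted(sb), 2):
                    for lj, lev in enumerate(t1.levels):
                        if lev >= t2.levels[li]:
                            m = {m: bi for bi, s in enumerate(t1.superbasins[lj])
                                 for m in s}
                            if i in m and j in m:
                                assert m[i] == m[j]

    def test_tree_export_shapes(self, rng):
        ldb = _toy_landscape(rng, 6, 10)
        tree = ls.build_disconnectivity(ldb, 0.4)
        d = tree.to_dict()
        assert len(d["levels"]) == len(d["superbasins"])
        segs = tree.segments()
        assert all({"level", "minima", "lowest"} <= set(s) for s in segs)
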