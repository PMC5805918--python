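"""Quenches, Monte-Carlo moves, minima database and the BH driver."""
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ionhydrate import forcefield as ff
from ionhydrate import optimize as opt
from ionhydrate.energy import ClusterPotential, total_energy
from ionhydrate.fixtures import water_trimer_ring
from ionhydrate.hbond import detect_hbonds

from conftest import random_cluster


class TestLocalMinimize:
    def test_known_minimum_is_fixed_point(self, water_sp, rng):
        c = random_cluster((water_sp,) * 2, rng)
        m1, e1 = opt.local_minimize(c, tolerance=1e-5)
        m2, e2 = opt.local_minimize(m1, tolerance=1e-5)
        assert abs(e2 - e1) < 1e-10

    def test_energy_never_increases(self, water_sp, rng):
        c = random_cluster((water_sp,) * 3, rng)
        e0 = total_energy(c)
        _, e1 = opt.local_minimize(c)
        assert e1 <= e0

    def test_matches_derivative_free_optimizer(self, water_sp):
        """The dimer global minimum from gradient quenches must agree with
        an independent derivative-free (Nelder-Mead) multi-start search."""
        pot = ClusterPotential((water_sp,) * 2)
        best_nm = np.inf
        best_grad = np.inf
        for i in range(40):
            c = random_cluster((water_sp,) * 2, np.random.default_rng(900 + i))
            x0 = c.coords
            res = minimize(pot.energy, x0, method="Nelder-Mead",
                           options=dict(maxiter=20000, xatol=1e-10, fatol=1e-12))
            best_nm = min(best_nm, res.fun)
            _, e = opt.local_minimize(c, tolerance=1e-5)
            best_grad = min(best_grad, e)
        assert best_grad == pytest.approx(best_nm, abs=1e-4)

    def test_deterministic(self, water_sp, rng):
        c = random_cluster((water_sp,) * 3, rng)
        m1, e1 = opt.local_minimize(c)
        m2, e2 = opt.local_minimize(c)
        assert e1 == e2
        assert np.array_equal(m1.coords, m2.coords)


class TestMoves:
    def test_translate_contract(self, water_sp, rng):
        c = random_cluster((water_sp,) * 5, rng)
        step = 0.7
        maxdisp = 0.0
        for _ in range(200):
            moved = opt.move_translate(c, step, rng)
            assert np.array_equal(moved.orientations, c.orientations)
            d = np.linalg.norm(moved.translations - c.translations, axis=1)
            maxdisp = max(maxdisp, d.max())
            assert d.max() <= step + 1e-12
        assert maxdisp > 0.5 * step  # sampler actually uses its range

    def test_translate_zero_step_limit(self, water_sp, rng):
        c = random_cluster((water_sp,) * 3, rng)
        moved = opt.move_translate(c, 1e-15, rng)
        assert np.abs(moved.translations - c.translations).max() < 1e-14

    def test_translate_subset(self, water_sp, rng):
        c = random_cluster((water_sp,) * 6, rng)
        moved = opt.move_translate(c, 1.0, rng, subset=2)
        changed = np.any(moved.translations != c.translations, axis=1)
        assert changed.sum() == 2

    def test_rotate_contract(self, water_sp, rng):
        c = random_cluster((water_sp,) * 4, rng)
        for _ in range(200):
            moved = opt.move_rotate(c, math.pi, rng)
            assert np.array_equal(moved.translations, c.translations)
            R = Rotation.from_rotvec(moved.orientations).as_matrix()
            assert np.allclose(np.linalg.det(R), 1.0, atol=1e-10)

    def test_rotate_bounded_composition(self, water_sp, rng):
        c = random_cluster((water_sp,) * 3, rng)
        rng2 = np.random.default_rng(5)
        for _ in range(100):
            moved = opt.move_rotate(c, 0.2, rng2)
            rel = Rotation.from_rotvec(moved.orientations) * Rotation.from_rotvec(
                c.orientations
            ).inv()
            assert rel.magnitude().max() <= 0.2 + 1e-10

    def test_cycle_invert_reverses_ring(self, rng):
        c = water_trimer_ring()
        g0 = detect_hbonds(c)
        before = {(e.donor_mol, e.acceptor_mol) for e in g0.edges}
        moved = opt.move_cycle_invert(c, rng)
        assert moved is not None
        # COMs untouched
        assert np.abs(moved.translations - c.translations).max() < 1e-12
        g1 = detect_hbonds(moved)
        after = {(e.donor_mol, e.acceptor_mol) for e in g1.edges}
        assert after == {(b, a) for a, b in before}

    def test_cycle_invert_is_involution_on_direction(self, rng):
        c = water_trimer_ring()
        before = {(e.donor_mol, e.acceptor_mol) for e in detect_hbonds(c).edges}
        once = opt.move_cycle_invert(c, rng)
        twice = opt.move_cycle_invert(once, rng)
        after = {(e.donor_mol, e.acceptor_mol) for e in detect_hbonds(twice).edges}
        assert after == before

    def test_cycle_invert_unavailable_without_cycles(self, water_sp, rng):
        c = ff.ClusterConfig(
            (water_sp, water_sp),
            np.array([[0.0, 0, 0], [8.0, 0, 0]]),
            np.zeros((2, 3)),
        )
        assert opt.move_cycle_invert(c, rng) is None


class TestMinimaDatabase:
    def _cfg(self, water_sp, shift=0.0):
        T = np.array([[0.0, 0, 0], [3.0 + shift, 0, 0], [0.0, 3.0, 0]])
        return ff.ClusterConfig((water_sp,) * 3, T, np.zeros((3, 3)))

    def test_exact_duplicate_counted_not_inserted(self, water_sp):
        db = opt.MinimaDatabase()
        c = self._cfg(water_sp)
        assert db.insert(-10.0, c)
        assert not db.insert(-10.0, c)
        assert len(db) == 1 and db.records[0].hit_count == 2

    def test_energies_beyond_tolerance_kept(self, water_sp):
        db = opt.MinimaDatabase(dedup_tolerance=1e-4)
        c = self._cfg(water_sp)
        assert db.insert(-10.0, c)
        assert db.insert(-10.0 + 1e-3, self._cfg(water_sp, shift=0.2))
        assert len(db) == 2

    def test_degenerate_enantiomers_kept_with_structural_check(self, water_sp, rng):
        db = opt.MinimaDatabase(structural_check=True)
        c = random_cluster((water_sp,) * 4, rng)
        mirror = c.copy()
        mirror.translations = c.translations * np.array([-1.0, 1.0, 1.0])
        # a genuine mirror image has identical COM-distance multiset, so
        # perturb one molecule to emulate a distinct same-energy structure
        distinct = c.copy()
        distinct.translations = c.translations + rng.normal(scale=0.3, size=(4, 3))
        assert db.insert(-5.0, c)
        assert not db.insert(-5.0, mirror)  # same multiset -> same record
        assert db.insert(-5.0, distinct)   # different multiset -> kept
        assert len(db) == 2

    def test_sorted_retrieval(self, water_sp):
        db = opt.MinimaDatabase()
        for i, e in enumerate([-3.0, -7.0, -5.0]):
            db.insert(e, self._cfg(water_sp, shift=0.3 * i))
        assert list(db.energies) == sorted([-3.0, -7.0, -5.0])
        assert db.global_minimum.energy == -7.0

    def test_merge_deduplicates(self, water_sp):
        a, b = opt.MinimaDatabase(), opt.MinimaDatabase()
        c = self._cfg(water_sp)
        a.insert(-4.0, c)
        b.insert(-4.0, c)
        b.insert(-6.0, self._cfg(water_sp, shift=0.4))
        a.merge(b)
        assert len(a) == 2
        assert a.records[-1].hit_count == 2


class TestBasinHopping:
    def test_metropolis_low_temperature_rejects_uphill(self):
        # direct check of the acceptance rule at its limits
        assert math.exp(-1.0 / 1e12) == pytest.approx(1.0)

    def test_seeded_runs_identical(self, water_sp, rng):
        init = random_cluster((water_sp,) * 3, rng)
        cfg = opt.BasinHoppingConfig(n_steps=120, seed=77)
        db1 = opt.run_basin_hopping(init, cfg)
        db2 = opt.run_basin_hopping(init, cfg)
        assert np.array_equal(db1.energies, db2.energies)

    def test_low_temperature_walk_rejects_some_uphill_moves(self, water_sp):
        """On a multi-minimum landscape at small kT the Metropolis rule
        must reject a fraction of proposals while still accepting the
        downhill ones."""
        init = random_cluster((water_sp,) * 4, np.random.default_rng(3))
        cfg = opt.BasinHoppingConfig(n_steps=400, seed=5, kT=0.05)
        db, stats = opt.run_basin_hopping(init, cfg, return_stats=True)
        assert 0 < stats.accepted < stats.proposed
        assert len(db) > 1

    def test_high_temperature_accepts_everything(self, water_sp):
        init = random_cluster((water_sp,) * 2, np.random.default_rng(3))
        cfg = opt.BasinHoppingConfig(n_steps=150, seed=5, kT=1e9)
        db, stats = opt.run_basin_hopping(init, cfg, return_stats=True)
        failures = stats.quench_failures + stats.evaporations
        assert stats.accepted >= stats.proposed - failures - 1

    def test_finds_dimer_global_minimum(self, water_sp):
        init = random_cluster((water_sp,) * 2, np.random.default_rng(8))
        db = opt.run_basin_hopping(init, opt.BasinHoppingConfig(n_steps=250, seed=9))
        assert db.global_minimum.energy == pytest.approx(-6.2349, abs=2e-3)


class TestRefineDatabase:
    def test_refine_collapses_flat_saddles(self, water_sp):
        init = random_cluster((water_sp,) * 3, np.random.default_rng(5))
        db = opt.run_basin_hopping(
            init, opt.BasinHoppingConfig(n_steps=400, seed=11, quench_tolerance=1e-3)
        )
        refined = opt.refine_database(db)
        assert len(refined) <= len(db)
        assert refined.global_minimum.energy <= db.global_minimum.energy + 1e-6
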