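"""Boltzmann weighting, ensemble means and the ion displacement ratio."""
import math

import numpy as np
import pytest

from ionhydrate import forcefield as ff
from ionhydrate import observables as obs
from ionhydrate.constants import ATOMIC_MASSES, K_BOLTZMANN
from ionhydrate.optimize import MinimaDatabase


def _db_with_energies(water_sp, energies):
    db = MinimaDatabase(dedup_tolerance=1e-12, structural_check=False)
    for i, e in enumerate(energies):
        T = np.array([[0.0, 0, 0], [3.0 + 0.31 * i, 0, 0]])
        db.insert(e, ff.ClusterConfig((water_sp,) * 2, T, np.zeros((2, 3))))
    return db


class TestWeights:
    def test_single_minimum(self, water_sp):
        w, _ = obs.boltzmann_weights(_db_with_energies(water_sp, [-5.0]))
        assert w == pytest.approx([1.0])

    def test_degenerate_pair(self, water_sp):
        w, _ = obs.boltzmann_weights(_db_with_energies(water_sp, [-5.0, -5.0 + 1e-9]))
        assert w == pytest.approx([0.5, 0.5], abs=1e-6)

    def test_three_minima_against_direct_formula(self, water_sp):
        """Direct evaluation of exp(-dU/kT)/Z at 130 K for dU = 0, 0.5, 1.0."""
        kT = 0.0019872 * 130.0
        raw = [math.exp(-du / kT) for du in (0.0, 0.5, 1.0)]
        Z = sum(raw)
        expected = [r / Z for r in raw]
        db = _db_with_energies(water_sp, [-10.0, -9.5, -9.0])
        w, _ = obs.boltzmann_weights(db, obs.WeightingScheme(130.0))
        assert w == pytest.approx(expected, rel=1e-10)

    def test_windows(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -8.0, -3.0])
        w_all, r_all = obs.boltzmann_weights(db, obs.WeightingScheme(130, "all"))
        assert len(r_all) == 3
        _, r_k = obs.boltzmann_weights(db, obs.WeightingScheme(130, "k_lowest", k=2))
        assert len(r_k) == 2
        _, r_cut = obs.boltzmann_weights(db, obs.WeightingScheme(130, "cutoff", cutoff=5.0))
        assert len(r_cut) == 2  # -3.0 lies 7 above the GM

    def test_zero_temperature_limit(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.9, -9.0])
        w, _ = obs.boltzmann_weights(db, obs.WeightingScheme(temperature=1e-6))
        assert w[0] == pytest.approx(1.0)

    def test_infinite_temperature_limit(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.0, -8.0])
        w, _ = obs.boltzmann_weights(db, obs.WeightingScheme(temperature=1e12))
        assert w == pytest.approx([1 / 3] * 3, abs=1e-6)

    def test_log_domain_stability_for_huge_gaps(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -10.0 + 1e4])
        w, _ = obs.boltzmann_weights(db, obs.WeightingScheme(130.0))
        assert np.isfinite(w).all()
        assert w[0] == pytest.approx(1.0)

    def test_weights_sum_to_one(self, water_sp, rng):
        db = _db_with_energies(water_sp, sorted(rng.uniform(-20, -10, 12)))
        w, _ = obs.boltzmann_weights(db)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestMeanEnergyPerWater:
    def test_single_minimum_exact(self, water_sp):
        db = _db_with_energies(water_sp, [-9.0])
        assert obs.mean_energy_per_water(db) == pytest.approx(-4.5)

    def test_bounded_by_window_extremes(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.7, -9.1])
        val = obs.mean_energy_per_water(db, obs.WeightingScheme(500.0))
        assert -10.0 / 2 <= val <= -9.1 / 2

    def test_composition_with_weight_oracle(self, water_sp):
        energies = [-10.0, -9.5, -9.0]
        kT = K_BOLTZMANN * 130.0
        raw = [math.exp(-(e - energies[0]) / kT) for e in energies]
        Z = sum(raw)
        expected = sum(w / Z * e for w, e in zip(raw, energies)) / 2
        db = _db_with_energies(water_sp, energies)
        assert obs.mean_energy_per_water(db, obs.WeightingScheme(130.0)) == pytest.approx(
            expected, rel=1e-12
        )


class TestDisplacementRatio:
    def _cluster(self, sulfite_sp, water_sp, ion_pos):
        T = np.array([ion_pos, [3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        return ff.ClusterConfig((sulfite_sp, water_sp, water_sp), T, np.zeros((3, 3)))

    def test_ion_at_water_com_gives_zero(self, sulfite_sp, water_sp):
        c = self._cluster(sulfite_sp, water_sp, [0.0, 0.0, 0.0])
        assert obs.displacement_ratio(c) == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance_at_large_separation(self, sulfite_sp, water_sp):
        # molecules are rigid, so only COM coordinates can be scaled; at
        # separations where the internal extent is negligible the ratio is
        # scale-invariant
        T = np.array([[30.0, 10.0, 0.0], [0.0, 25.0, 0.0], [0.0, -25.0, 0.0]])
        c = ff.ClusterConfig((sulfite_sp, water_sp, water_sp), T, np.zeros((3, 3)))
        r1 = obs.displacement_ratio(c)
        scaled = c.copy()
        scaled.translations = c.translations * 2.7
        assert obs.displacement_ratio(scaled) == pytest.approx(r1, rel=0.02)

    def test_hand_computed_point_mass_fixture(self, water_sp):
        """Three-molecule fixture checked against an explicit hand
        computation treating each site with its atomic mass."""
        sp_ion = ff.sulfite()
        T = np.array([[2.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]])
        c = ff.ClusterConfig((sp_ion, water_sp, water_sp), T, np.zeros((3, 3)))
        # independent computation from raw site positions and masses
        pts, ms = [], []
        pos = c.site_positions()
        for i, sp in enumerate(c.species_list):
            for j, s in enumerate(sp.sites):
                if s.mass > 0:
                    pts.append(pos[i][j])
                    ms.append(s.mass)
        pts, ms = np.array(pts), np.array(ms)
        com = (ms[:, None] * pts).sum(0) / ms.sum()
        rg = math.sqrt(float((ms * ((pts - com) ** 2).sum(1)).sum() / ms.sum()))
        water_com = np.array([0.0, 0.0, 0.0])  # symmetric pair
        r = np.linalg.norm(T[0] - water_com)
        assert obs.displacement_ratio(c) == pytest.approx(r / rg, rel=1e-10)

    def test_requires_ion_and_waters(self, water_sp):
        c = ff.ClusterConfig((water_sp,) * 2, np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]],
                             np.zeros((2, 3)))
        with pytest.raises(ValueError):
            obs.displacement_ratio(c)


class TestWeightedStatistic:
    def test_constant_function(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.0, -8.5])
        assert obs.weighted_statistic(db, lambda r: 4.2) == pytest.approx(4.2)

    def test_linearity(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.3, -8.8])
        f = lambda r: r.energy
        g = lambda r: r.energy**2
        fg = obs.weighted_statistic(db, lambda r: f(r) + g(r))
        assert fg == pytest.approx(
            obs.weighted_statistic(db, f) + obs.weighted_statistic(db, g), rel=1e-12
        )

    def test_zero_everywhere_gives_zero(self, water_sp):
        db = _db_with_energies(water_sp, [-10.0, -9.0])
        assert obs.weighted_statistic(db, lambda r: 0.0) == 0.0
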