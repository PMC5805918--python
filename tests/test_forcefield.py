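"""Species geometry, charges and rigid-body pose plumbing."""
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ionhydrate import forcefield as ff


def apex_height_by_construction(L, theta_deg):
    """Independent pyramid-height oracle: find the half-cone angle alpha for
    which three bond vectors at polar angle alpha, 120 deg apart in azimuth,
    subtend the requested inter-bond angle; measure the apex height above
    the oxygen plane directly."""
    theta = math.radians(theta_deg)

    def interbond_minus_target(alpha):
        b1 = np.array([math.sin(alpha), 0.0, -math.cos(alpha)])
        b2 = np.array(
            [math.sin(alpha) * math.cos(2 * math.pi / 3),
             math.sin(alpha) * math.sin(2 * math.pi / 3),
             -math.cos(alpha)]
        )
        return float(np.dot(b1, b2)) - math.cos(theta)

    alpha = brentq(interbond_minus_target, 1e-6, math.pi / 2 - 1e-6)
    b = L * np.array([math.sin(alpha), 0.0, -math.cos(alpha)])
    return -b[2]  # apex at origin; oxygens sit |b_z| below it


class TestPyramidGeometry:
    def test_chlorate_height_matches_printed_value(self, chlorate_sp):
        h = ff.pyramid_apex_height(1.48, 105.8)
        assert h == pytest.approx(0.58, abs=0.005)

    def test_derived_height_agrees_with_explicit_construction(self):
        for L, theta in [(1.48, 105.8), (1.9, 106.0), (1.2, 95.0)]:
            assert ff.pyramid_apex_height(L, theta) == pytest.approx(
                apex_height_by_construction(L, theta), abs=1e-9
            )

    def test_sulfite_printed_height_is_inconsistent_with_L_and_theta(self):
        # the derived height for L=1.9, theta=106 is ~0.735, not 0.76;
        # supplying the printed height warns rather than errors
        h = ff.pyramid_apex_height(1.9, 106.0)
        assert h == pytest.approx(0.7348, abs=1e-3)
        with pytest.warns(UserWarning):
            ff.sulfite(apex_height=0.76)

    def test_planar_limit(self):
        assert ff.pyramid_apex_height(1.5, 120.0) == pytest.approx(0.0, abs=1e-7)

    def test_bond_geometry_of_built_species(self, chlorate_sp):
        body = chlorate_sp.body_positions
        apex, oxys = body[0], body[1:]
        lengths = np.linalg.norm(oxys - apex, axis=1)
        assert lengths == pytest.approx([1.48] * 3, abs=1e-10)
        v = oxys - apex
        cos = v @ v.T / np.outer(lengths, lengths)
        angles = np.degrees(np.arccos(np.clip(cos[np.triu_indices(3, 1)], -1, 1)))
        assert angles == pytest.approx([105.8] * 3, abs=1e-8)

    def test_geometry_errors(self):
        with pytest.raises(ff.GeometryError):
            ff.build_pyramidal_species(
                "x", "S", bond_length=1.5, bond_angle=121.0,
                apex_site=ff.SiteSpec("S", (0, 0, 0), mass=32.06),
                oxygen_site=ff.SiteSpec("O", (0, 0, 0), mass=15.999),
            )
        with pytest.raises(ff.GeometryError):
            ff.build_pyramidal_species(
                "x", "S", bond_length=-1.0, bond_angle=100.0,
                apex_site=ff.SiteSpec("S", (0, 0, 0), mass=32.06),
                oxygen_site=ff.SiteSpec("O", (0, 0, 0), mass=15.999),
            )


class TestTIP4P:
    def test_charge_sum_zero(self, water_sp):
        assert sum(s.charge for s in water_sp.sites) == pytest.approx(0.0, abs=1e-12)

    def test_hoh_angle(self, water_sp):
        b = water_sp.body_positions
        v1, v2 = b[1] - b[0], b[2] - b[0]
        ang = math.degrees(
            math.acos(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2))
        )
        assert ang == pytest.approx(104.52, abs=1e-6)

    def test_lp_on_bisector(self, water_sp):
        b = water_sp.body_positions
        o, h1, h2, lp = b

        def angle(u, v):
            return math.acos(u @ v / np.linalg.norm(u) / np.linalg.norm(v))

        assert angle(h1 - o, lp - o) == pytest.approx(angle(h2 - o, lp - o), abs=1e-10)
        assert np.linalg.norm(lp - o) == pytest.approx(0.15, abs=1e-10)

    def test_lp_is_massless_and_without_lj(self, water_sp):
        lp = water_sp.sites[3]
        assert lp.mass == 0.0 and lp.epsilon == 0.0 and lp.sigma == 0.0

    def test_parameter_sets(self):
        canon = ff.water("canonical").sites[0]
        printed = ff.water("as_printed").sites[0]
        assert (canon.epsilon, canon.sigma) == (0.1550, 3.15365)
        assert (printed.epsilon, printed.sigma) == (0.648, 3.2)


class TestSpeciesInvariants:
    @pytest.mark.parametrize(
        "maker,expected",
        [(ff.water, 0.0), (ff.sulfite, -2.0), (ff.chlorate, -1.0)],
    )
    def test_charge_sums_at_printed_precision(self, maker, expected):
        sp = maker()
        total = sum(s.charge for s in sp.sites)
        # charges are printed to 3 d.p.; sulfite's sum is -1.999 exactly
        assert total == pytest.approx(expected, abs=2e-3)

    def test_com_at_origin(self, water_sp, sulfite_sp, chlorate_sp):
        for sp in (water_sp, sulfite_sp, chlorate_sp):
            assert np.linalg.norm(sp.centre_of_mass()) < 1e-12

    def test_rebuild_is_bitwise_idempotent(self):
        assert ff.sulfite() == ff.sulfite()
        assert ff.water() == ff.water()

    def test_serialization_round_trip(self, sulfite_sp):
        d = ff.species_to_dict(sulfite_sp)
        assert ff.species_from_dict(d) == sulfite_sp

    def test_charge_sum_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ff.SpeciesSpec(
                "bad",
                (ff.SiteSpec("O", (0, 0, 0), charge=-0.5, mass=16.0),),
                net_charge=0.0,
            )


class TestPoses:
    def test_identity_pose_reproduces_body_frame(self, water_sp):
        c = ff.ClusterConfig((water_sp,), np.zeros((1, 3)), np.zeros((1, 3)))
        assert np.allclose(c.site_positions()[0], water_sp.body_positions)

    def test_pure_translation(self, water_sp):
        t = np.array([1.5, -2.0, 0.7])
        c = ff.ClusterConfig((water_sp,), t[None, :], np.zeros((1, 3)))
        assert np.allclose(
            c.site_positions()[0], water_sp.body_positions + t, atol=1e-14
        )

    def test_rigidity_under_random_poses(self, sulfite_sp, rng):
        body = sulfite_sp.body_positions
        ref = np.linalg.norm(body[:, None] - body[None, :], axis=2)
        for _ in range(20):
            c = ff.ClusterConfig(
                (sulfite_sp,), rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
            )
            lab = c.site_positions()[0]
            d = np.linalg.norm(lab[:, None] - lab[None, :], axis=2)
            assert np.abs(d - ref).max() < 1e-10

    def test_ion_count_limit(self, sulfite_sp, water_sp):
        with pytest.raises(ValueError):
            ff.ClusterConfig(
                (sulfite_sp, sulfite_sp), np.zeros((2, 3)), np.zeros((2, 3))
            )

    def test_cluster_queries(self, sulfite_sp, water_sp):
        c = ff.ClusterConfig(
            (sulfite_sp, water_sp, water_sp), np.zeros((3, 3)), np.zeros((3, 3))
        )
        assert c.ion_index == 0 and c.n_waters == 2 and c.n_molecules == 3
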