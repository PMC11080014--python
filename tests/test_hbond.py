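"""Hydrogen-bond detection against planted geometries and a brute-force oracle."""

import numpy as np
import pytest

from sugarshell.hbond import (
    capacity_check,
    detect_hbonds,
    distance_angle_map,
    site_stats,
    water_coordination,
)
from sugarshell.io_formats import Frame

from conftest import BOX, brute_force_hbonds, make_water, random_water_frame, water_frame


def two_water_pair(r_oo=2.8, theta_deg=5.0, box=BOX):
    """Donor water at the center aiming (almost) at an acceptor water."""
    c = box / 2
    o1 = np.array([c, c, c])
    o2 = o1 + np.array([r_oo, 0.0, 0.0])
    th = np.deg2rad(theta_deg)
    d1 = np.array([np.cos(th), np.sin(th), 0.0])  # O->H tilted by theta
    d1b = np.array([-0.3, -0.9, 0.2])
    w1 = make_water(o1, d1, d1b)
    w2 = make_water(o2, [0.3, 0.9, 0.2], [0.3, -0.9, 0.2])
    return water_frame([w1, w2], box)


class TestDetection:
    def test_single_planted_bond(self):
        frame, topo = two_water_pair(r_oo=2.8, theta_deg=5.0)
        bonds = detect_hbonds(frame, topo)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.donor_O == 0 and b.acceptor_O == 3
        assert b.r_HA == pytest.approx(2.8 - 0.9572, abs=0.02)
        assert b.theta == pytest.approx(5.0, abs=0.5)

    def test_beyond_distance_cutoff(self):
        frame, topo = two_water_pair(r_oo=5.0, theta_deg=5.0)
        assert detect_hbonds(frame, topo) == []

    def test_angle_cutoff(self):
        frame, topo = two_water_pair(r_oo=2.8, theta_deg=35.0)
        assert detect_hbonds(frame, topo) == []

    def test_boundary_distance_excluded_strictly(self):
        # H...O exactly 2.5 Å: the strict inequality excludes it
        frame, topo = two_water_pair(r_oo=2.5 + 0.9572, theta_deg=0.0)
        bonds = detect_hbonds(frame, topo)
        assert bonds == []
        # a hair inside is kept
        frame, topo = two_water_pair(r_oo=2.5 + 0.9572 - 1e-3, theta_deg=0.0)
        assert len(detect_hbonds(frame, topo)) == 1

    def test_minimum_image_across_boundary(self):
        w1 = make_water([0.3, 5.0, 5.0], [-1, 0.05, 0], [0.3, 0.9, 0])
        w2 = make_water([BOX - 1.6, 5.0, 5.0], [0.3, 0.9, 0.2], [0.3, -0.9, 0.2])
        frame, topo = water_frame([w1, w2])
        bonds = detect_hbonds(frame, topo)
        assert len(bonds) == 1
        assert bonds[0].r_HA < 1.1

    def test_r_cut_above_half_box_rejected(self):
        frame, topo = two_water_pair()
        with pytest.raises(ValueError, match="minimum image"):
            detect_hbonds(frame, topo, r_cut=BOX / 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        frame, topo = random_water_frame(rng)
        bonds = detect_hbonds(frame, topo)
        assert {(b.donor_O, b.H, b.acceptor_O) for b in bonds} == brute_force_hbonds(
            frame, topo
        )

    def test_oracle_on_planted_sugar_system(self, planted, topo):
        traj, _ = planted
        bonds = detect_hbonds(traj[0], topo)
        assert {(b.donor_O, b.H, b.acceptor_O) for b in bonds} == brute_force_hbonds(
            traj[0], topo
        )

    def test_rigid_motion_invariance(self):
        """Arbitrary translations and lattice-compatible (90 deg) rotations.

        Only rotations from the cubic point group map the periodic
        lattice to itself, so those are the rotations under which the
        bond set is exactly conserved after re-wrapping.
        """
        rng = np.random.default_rng(7)
        frame, topo = random_water_frame(rng, n_waters=30)
        ref = {(b.donor_O, b.H, b.acceptor_O) for b in detect_hbonds(frame, topo)}
        rot = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90 deg z
        shift = rng.uniform(-20, 20, 3)
        center = np.full(3, BOX / 2)
        moved = Frame(
            list(frame.elements),
            np.mod((frame.positions - center) @ rot.T + center + shift, BOX),
            BOX,
        )
        got = {(b.donor_O, b.H, b.acceptor_O) for b in detect_hbonds(moved, topo)}
        assert got == ref

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(3)
        frame, topo = random_water_frame(rng, n_waters=50)
        base = {(b.donor_O, b.H, b.acceptor_O) for b in detect_hbonds(frame, topo)}
        wider_r = {
            (b.donor_O, b.H, b.acceptor_O)
            for b in detect_hbonds(frame, topo, r_cut=3.2)
        }
        wider_t = {
            (b.donor_O, b.H, b.acceptor_O)
            for b in detect_hbonds(frame, topo, theta_cut=50.0)
        }
        assert base <= wider_r and base <= wider_t


class TestSiteStats:
    def test_planted_counts_and_lengths(self, planted, topo):
        traj, truth = planted
        bonds = detect_hbonds(traj[0], topo)
        stats = site_stats(bonds, topo, n_frames=1)
        for site, n in truth.site_donor_counts.items():
            assert stats.donor_count[site] == pytest.approx(float(n))
        for site, n in truth.site_acceptor_counts.items():
            assert stats.acceptor_count[site] == pytest.approx(float(n))
        # planted donor bonds are systematically shorter than acceptor bonds
        d = np.mean([v for v in stats.donor_length.values()])
        a = np.mean([v for v in stats.acceptor_length.values()])
        assert d < a

    def test_replication_invariance(self, planted, topo):
        traj, _ = planted
        bonds1 = detect_hbonds(traj[0], topo, frame_index=0)
        ten = [b for k in range(10) for b in detect_hbonds(traj[0], topo, frame_index=k)]
        s1 = site_stats(bonds1, topo, n_frames=1)
        s10 = site_stats(ten, topo, n_frames=10)
        assert s10.n_frames == 10
        for site in s1.donor_count:
            assert s10.donor_count[site] == pytest.approx(s1.donor_count[site])
            assert s10.donor_length[site] == pytest.approx(s1.donor_length[site])

    def test_single_bond_mean_length(self):
        from sugarshell.hbond import HBond

        b = HBond(0, 1, 10, 1.75, 4.0, "sugar", "water", "O1", None)
        stats = site_stats([b], _dummy_topo(), n_frames=1)
        assert stats.donor_length["O1"] == pytest.approx(1.75)
        assert stats.donor_count["O1"] == pytest.approx(1.0)

    def test_unknown_site_rejected(self):
        from sugarshell.hbond import HBond

        b = HBond(0, 1, 10, 1.75, 4.0, "sugar", "water", "O9", None)
        with pytest.raises(ValueError, match="unknown"):
            site_stats([b], _dummy_topo(), n_frames=1)


def _dummy_topo():
    from sugarshell.io_formats import Topology

    return Topology(np.array([], dtype=int), {}, [])


class TestCapacityAndCoordination:
    def test_at_capacity_no_warnings(self):
        from sugarshell.hbond import SiteHbondStats

        stats = SiteHbondStats(
            donor_count={s: 1.0 for s in ("O1", "O2", "O3", "O4", "O6")},
            acceptor_count={s: 2.0 for s in ("O1", "O2", "O3", "O4", "O5", "O6")},
            donor_length={},
            acceptor_length={},
            n_frames=1,
        )
        assert capacity_check(stats) == []

    def test_over_capacity_flagged(self):
        from sugarshell.hbond import SiteHbondStats

        stats = SiteHbondStats(
            donor_count={"O1": 1.2},
            acceptor_count={"O2": 2.6},
            donor_length={},
            acceptor_length={},
            n_frames=1,
        )
        report = capacity_check(stats)
        assert {(r["site"], r["role"]) for r in report} == {
            ("O1", "donor"),
            ("O2", "acceptor"),
        }

    def test_empty_stats_empty_report(self):
        from sugarshell.hbond import SiteHbondStats

        assert capacity_check(SiteHbondStats({}, {}, {}, {}, 1)) == []

    def test_handshake_identity(self, planted, topo):
        """sum of water coordinations = 2 x (w-w bonds) + (sugar-water bonds)."""
        traj, _ = planted
        bonds = detect_hbonds(traj[0], topo)
        counts = water_coordination(traj[0], topo, bonds)
        n_ww = sum(
            1 for b in bonds if b.donor_role == "water" and b.acceptor_role == "water"
        )
        n_sw = len(bonds) - n_ww
        assert counts.sum() == 2 * n_ww + n_sw

    def test_coordination_matches_planted_truth(self, planted, topo):
        traj, truth = planted
        bonds = detect_hbonds(traj[0], topo)
        np.testing.assert_array_equal(
            water_coordination(traj[0], topo, bonds), truth.coordination
        )

    def test_isolated_water_zero(self):
        frame, topo = two_water_pair(r_oo=6.0)
        counts = water_coordination(frame, topo, [])
        np.testing.assert_array_equal(counts, [0, 0])


class TestDistanceAngleMap:
    def test_single_bond_single_bin(self):
        from sugarshell.hbond import HBond

        b = HBond(0, 1, 10, 1.85, 12.0, "sugar", "water", "O1", None)
        m = distance_angle_map(
            [b], "sugar-donor", np.arange(1.0, 2.6, 0.1), np.arange(0.0, 31.0, 5.0)
        )
        assert m.total == 1
        assert m.counts[8, 2] == 1  # r in [1.8, 1.9), theta in [10, 15)

    def test_empty_class_all_zero(self):
        m = distance_angle_map(
            [], "water-water", np.arange(1.0, 2.6, 0.1), np.arange(0.0, 31.0, 5.0)
        )
        assert m.total == 0

    def test_empty_bin_spec_rejected(self):
        with pytest.raises(ValueError):
            distance_angle_map([], "water-water", np.array([1.0]), np.arange(0, 31, 5))

    def test_planted_donor_shorter_than_acceptor(self, planted, topo):
        traj, _ = planted
        bonds = detect_hbonds(traj[0], topo)
        r_bins = np.arange(1.2, 2.6, 0.05)
        t_bins = np.arange(0.0, 31.0, 2.0)
        donor = distance_angle_map(bonds, "sugar-donor", r_bins, t_bins)
        acceptor = distance_angle_map(bonds, "sugar-acceptor", r_bins, t_bins)
        assert donor.total > 0 and acceptor.total > 0
        assert donor.mean_r() < acceptor.mean_r()
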