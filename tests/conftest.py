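"""Shared fixtures: planted synthetic systems and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from sugarshell.io_formats import Frame, Topology, perceive_topology
from sugarshell.synthetic import PlantSpec, build_system, sugar_template

BOX = 15.2640  # Å, the beta-glucose system


@pytest.fixture(scope="session")
def beta_template():
    return sugar_template("beta-glucose")


@pytest.fixture(scope="session")
def planted(beta_template):
    """Full 99-water planted system, zero jitter (exact truth)."""
    spec = PlantSpec(n_frames=3, jitter_sigma=0.0, seed=11)
    traj, truth = build_system(spec, beta_template)
    return traj, truth


@pytest.fixture(scope="session")
def topo(planted, beta_template) -> Topology:
    traj, _truth = planted
    return perceive_topology(traj[0], beta_template)


def make_water(o, h1_dir, h2_dir, oh=0.9572):
    """A rigid water from O position and two O->H unit directions."""
    o = np.asarray(o, float)
    h1 = o + oh * np.asarray(h1_dir) / np.linalg.norm(h1_dir)
    h2 = o + oh * np.asarray(h2_dir) / np.linalg.norm(h2_dir)
    return np.vstack([o, h1, h2])


def water_frame(water_blocks, box=BOX):
    """Frame + Topology from a list of (3, 3) water coordinate blocks."""
    pos = np.vstack(water_blocks)
    n = len(water_blocks)
    elements = ["O", "H", "H"] * n
    frame = Frame(elements, pos, box)
    topo = Topology(
        solute_atoms=np.array([], dtype=int),
        site_map={},
        waters=[(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n)],
    )
    return frame, topo


def random_water_frame(rng, n_waters=99, box=BOX):
    """Random rigid waters (overlaps allowed; detection fixtures only)."""
    blocks = []
    for _ in range(n_waters):
        o = rng.uniform(0, box, 3)
        d1 = rng.normal(size=3)
        d1 /= np.linalg.norm(d1)
        perp = np.cross(d1, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        ang = np.deg2rad(104.52)
        d2 = np.cos(ang) * d1 + np.sin(ang) * perp
        blocks.append(make_water(o, d1, d2))
    return water_frame(blocks, box)


def brute_force_hbonds(frame, topo, r_cut=2.5, theta_cut=30.0):
    """O(N^2) enumeration over all donor-H/acceptor-O pairs.

    Independent of the package's KD-tree path: plain loops, minimum image
    by explicit rounding, angle at the donor oxygen.
    """
    box = frame.box_edge
    pos = frame.positions

    def mi(v):
        return v - box * np.round(v / box)

    donors = []
    for site, o_idx, h_idx in topo.hydroxyl_pairs():
        donors.append((o_idx, h_idx, "sugar", site))
    for o, h1, h2 in topo.waters:
        donors.append((o, h1, "water", None))
        donors.append((o, h2, "water", None))
    acceptors = [(i, "sugar", s) for i, s in sorted(topo.sugar_oxygen_sites().items())]
    acceptors += [(int(o), "water", None) for o in topo.water_oxygens]

    found = set()
    for d_o, d_h, d_role, _ds in donors:
        for a_o, a_role, _as in acceptors:
            if a_o == d_o or (d_role == "sugar" and a_role == "sugar"):
                continue
            r = np.linalg.norm(mi(pos[a_o] - pos[d_h]))
            if r >= r_cut:
                continue
            v1 = mi(pos[d_h] - pos[d_o])
            v2 = mi(pos[a_o] - pos[d_o])
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if theta < theta_cut:
                found.add((d_o, d_h, a_o))
    return found
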