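"""Geometric hydrogen-bond detection and per-site statistics.

A donor-H...acceptor triple is a hydrogen bond when r(H...O_acceptor) is
below ``r_cut`` (default 2.5 Å) AND the angle at the donor oxygen between
the covalent O->H vector and the O->O_acceptor vector is below
``theta_cut`` (default 30°). Both inequalities are strict; theta = 0 is a
perfectly linear bond. Note carefully that the angle is measured at the
donor *oxygen*, not at the hydrogen — the two conventions differ.

Donors are oxygens bearing covalent hydrogens (the five sugar hydroxyls
and every water); acceptors are all oxygens (including the ring O5).
Intramolecular sugar-sugar pairs are excluded: the populations are
sugar->water, water->sugar and water-water. Bifurcated donors (one H
satisfying the criterion with two acceptors) are kept as two bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import angles_deg, minimum_image, wrap_positions
from .io_formats import Frame, Topology

__all__ = [
    "HBond",
    "SiteHbondStats",
    "DistanceAngleMap",
    "detect_hbonds",
    "site_stats",
    "capacity_check",
    "water_coordination",
    "distance_angle_map",
    "bonds_to_dataframe",
    "write_bond_table",
]

SUGAR_SITES = ("O1", "O2", "O3", "O4", "O5", "O6")
HYDROXYL_SITES = ("O1", "O2", "O3", "O4", "O6")

R_CUT_DEFAULT = 2.5  # Å
THETA_CUT_DEFAULT = 30.0  # degrees


@dataclass(frozen=True)
class HBond:
    donor_O: int
    H: int
    acceptor_O: int
    r_HA: float  # Å, H...acceptor distance
    theta: float  # deg, at donor O between O->H and O->acceptor
    donor_role: str  # 'sugar' | 'water'
    acceptor_role: str
    donor_site: Optional[str] = None
    acceptor_site: Optional[str] = None
    frame_index: int = 0


@dataclass
class SiteHbondStats:
    """Per-site per-frame-average donor/acceptor counts and bond lengths.

    Lengths are averaged over contributing bonds only; a site with no
    bonds of a kind reports NaN for the corresponding mean length.
    """

    donor_count: dict[str, float]
    acceptor_count: dict[str, float]
    donor_length: dict[str, float]  # Å, mean H_i...O_water
    acceptor_length: dict[str, float]  # Å, mean O_i...H_water
    n_frames: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for site in SUGAR_SITES:
            rows.append(
                {
                    "site": site,
                    "donor_count": self.donor_count.get(site, 0.0),
                    "acceptor_count": self.acceptor_count.get(site, 0.0),
                    "donor_length_A": self.donor_length.get(site, np.nan),
                    "acceptor_length_A": self.acceptor_length.get(site, np.nan),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DistanceAngleMap:
    """2D histogram over (r_HA, theta) for one bond population class."""

    counts: np.ndarray  # (n_r_bins, n_theta_bins)
    r_edges: np.ndarray
    theta_edges: np.ndarray
    population: str  # 'sugar-donor' | 'sugar-acceptor' | 'water-water'

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def mean_r(self) -> float:
        if self.total == 0:
            return float("nan")
        centers = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        return float((self.counts.sum(axis=1) * centers).sum() / self.total)


def _donors_acceptors(frame: Frame, topo: Topology):
    """Collect (donor O, H) pairs and acceptor O indices with roles/sites."""
    donor_pairs: list[tuple[int, int, str, Optional[str]]] = []
    for site, o_idx, h_idx in topo.hydroxyl_pairs():
        donor_pairs.append((o_idx, h_idx, "sugar", site))
    for o, h1, h2 in topo.waters:
        donor_pairs.append((o, h1, "water", None))
        donor_pairs.append((o, h2, "water", None))
    o_sites = topo.sugar_oxygen_sites()
    acceptors: list[tuple[int, str, Optional[str]]] = [
        (idx, "sugar", name) for idx, name in sorted(o_sites.items())
    ]
    acceptors += [(int(o), "water", None) for o in topo.water_oxygens]
    return donor_pairs, acceptors


def detect_hbonds(
    frame: Frame,
    topo: Topology,
    r_cut: float = R_CUT_DEFAULT,
    theta_cut: float = THETA_CUT_DEFAULT,
    frame_index: int = 0,
) -> list[HBond]:
    """Detect all hydrogen bonds in one frame under the geometric criterion.

    Exact under the minimum image convention; candidate H/acceptor pairs
    come from a periodic KD-tree query, then the strict distance and angle
    inequalities are applied.
    """
    if r_cut <= 0 or theta_cut <= 0:
        raise ValueError("cutoffs must be positive")
    if r_cut >= frame.box_edge / 2:
        raise ValueError(
            f"r_cut={r_cut} Å invalidates the minimum image convention "
            f"for box edge {frame.box_edge} Å"
        )
    donor_pairs, acceptors = _donors_acceptors(frame, topo)
    if not donor_pairs or not acceptors:
        return []
    box = frame.box_edge
    pos = frame.positions
    h_idx = np.array([p[1] for p in donor_pairs])
    acc_idx = np.array([a[0] for a in acceptors])
    tree = cKDTree(wrap_positions(pos[acc_idx], box), boxsize=box)
    neighbor_lists = tree.query_ball_point(wrap_positions(pos[h_idx], box), r_cut)

    bonds: list[HBond] = []
    for di, nbrs in enumerate(neighbor_lists):
        if not nbrs:
            continue
        d_o, d_h, d_role, d_site = donor_pairs[di]
        for ai in sorted(nbrs):
            a_o, a_role, a_site = acceptors[ai]
            if a_o == d_o:
                continue
            if d_role == "sugar" and a_role == "sugar":
                continue  # intramolecular; out of the analyzed populations
            v_oh = minimum_image(pos[d_h] - pos[d_o], box)
            v_oa = minimum_image(pos[a_o] - pos[d_o], box)
            r_ha = float(np.linalg.norm(minimum_image(pos[a_o] - pos[d_h], box)))
            if not r_ha < r_cut:  # strict; KD-tree query is inclusive
                continue
            theta = float(angles_deg(v_oh[None], v_oa[None])[0])
            if theta < theta_cut:
                bonds.append(
                    HBond(d_o, d_h, a_o, r_ha, theta, d_role, a_role, d_site, a_site, frame_index)
                )
    return bonds


def detect_hbonds_trajectory(
    traj: Sequence[Frame],
    topo: Topology,
    r_cut: float = R_CUT_DEFAULT,
    theta_cut: float = THETA_CUT_DEFAULT,
) -> list[list[HBond]]:
    """Per-frame bond lists for a whole trajectory."""
    return [
        detect_hbonds(fr, topo, r_cut=r_cut, theta_cut=theta_cut, frame_index=k)
        for k, fr in enumerate(traj)
    ]


def site_stats(
    bonds: Iterable[HBond], topo: Topology, n_frames: int
) -> SiteHbondStats:
    """Per-site donor/acceptor counts (per-frame averages) and mean lengths."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    known = set(SUGAR_SITES)
    d_count: dict[str, int] = {}
    a_count: dict[str, int] = {}
    d_len: dict[str, list[float]] = {}
    a_len: dict[str, list[float]] = {}
    for b in bonds:
        if b.donor_role == "sugar":
            if b.donor_site not in known:
                raise ValueError(f"bond references unknown donor site {b.donor_site!r}")
            d_count[b.donor_site] = d_count.get(b.donor_site, 0) + 1
            d_len.setdefault(b.donor_site, []).append(b.r_HA)
        if b.acceptor_role == "sugar":
            if b.acceptor_site not in known:
                raise ValueError(
                    f"bond references unknown acceptor site {b.acceptor_site!r}"
                )
            a_count[b.acceptor_site] = a_count.get(b.acceptor_site, 0) + 1
            a_len.setdefault(b.acceptor_site, []).append(b.r_HA)
    return SiteHbondStats(
        donor_count={s: c / n_frames for s, c in d_count.items()},
        acceptor_count={s: c / n_frames for s, c in a_count.items()},
        donor_length={s: float(np.mean(v)) for s, v in d_len.items()},
        acceptor_length={s: float(np.mean(v)) for s, v in a_len.items()},
        n_frames=n_frames,
    )


# H-bonding capacities: a hydroxyl donates at most one H-bond and accepts
# at most two; the ring oxygen accepts at most two and cannot donate.
DONOR_CAPACITY = 1.0
ACCEPTOR_CAPACITY = 2.0


def capacity_check(stats: SiteHbondStats) -> list[dict]:
    """Flag sites whose mean counts exceed chemical capacity (warnings)."""
    report: list[dict] = []
    for site, c in sorted(stats.donor_count.items()):
        if c > DONOR_CAPACITY:
            report.append(
                {"site": site, "role": "donor", "mean_count": c, "capacity": DONOR_CAPACITY}
            )
    for site, c in sorted(stats.acceptor_count.items()):
        if c > ACCEPTOR_CAPACITY:
            report.append(
                {
                    "site": site,
                    "role": "acceptor",
                    "mean_count": c,
                    "capacity": ACCEPTOR_CAPACITY,
                }
            )
    return report


def water_coordination(
    frame: Frame, topo: Topology, bonds: Iterable[HBond]
) -> np.ndarray:
    """Total H-bond count per water (donated + accepted, to water or sugar)."""
    counts = np.zeros(topo.n_waters, dtype=int)
    w_of = topo.water_of_atom()
    for b in bonds:
        if b.donor_role == "water":
            counts[w_of[b.donor_O]] += 1
        if b.acceptor_role == "water":
            counts[w_of[b.acceptor_O]] += 1
    return counts


def water_roles(topo: Topology, bonds: Iterable[HBond]) -> list[str]:
    """Role of each water toward the solute: donor/acceptor/both/none."""
    donated = np.zeros(topo.n_waters, bool)
    accepted = np.zeros(topo.n_waters, bool)
    w_of = topo.water_of_atom()
    for b in bonds:
        if b.donor_role == "water" and b.acceptor_role == "sugar":
            donated[w_of[b.donor_O]] = True
        if b.donor_role == "sugar" and b.acceptor_role == "water":
            accepted[w_of[b.acceptor_O]] = True
    out = []
    for d, a in zip(donated, accepted):
        out.append("both" if d and a else "donor" if d else "acceptor" if a else "none")
    return out


def _bond_in_class(b: HBond, population: str) -> bool:
    if population == "sugar-donor":
        return b.donor_role == "sugar"
    if population == "sugar-acceptor":
        return b.acceptor_role == "sugar" and b.donor_role == "water"
    if population == "water-water":
        return b.donor_role == "water" and b.acceptor_role == "water"
    raise ValueError(f"unknown population class {population!r}")


def distance_angle_map(
    bonds: Iterable[HBond],
    population: str,
    r_bins: np.ndarray,
    theta_bins: np.ndarray,
) -> DistanceAngleMap:
    """2D (r_HA, theta) histogram for one bond population class."""
    r_bins = np.asarray(r_bins, float)
    theta_bins = np.asarray(theta_bins, float)
    if r_bins.size < 2 or theta_bins.size < 2:
        raise ValueError("bin edge arrays need at least two edges")
    if np.any(np.diff(r_bins) <= 0) or np.any(np.diff(theta_bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    sel = [b for b in bonds if _bond_in_class(b, population)]
    r = np.array([b.r_HA for b in sel])
    t = np.array([b.theta for b in sel])
    counts, _, _ = np.histogram2d(r, t, bins=(r_bins, theta_bins))
    return DistanceAngleMap(counts, r_bins, theta_bins, population)


def bonds_to_dataframe(bonds: Iterable[HBond]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": b.frame_index,
                "donor_O": b.donor_O,
                "H": b.H,
                "acceptor_O": b.acceptor_O,
                "r_HA_A": b.r_HA,
                "theta_deg": b.theta,
                "donor_role": b.donor_role,
                "acceptor_role": b.acceptor_role,
                "donor_site": b.donor_site or "",
                "acceptor_site": b.acceptor_site or "",
            }
            for b in bonds
        ]
    )


def write_bond_table(bonds: Iterable[HBond], path: str | Path) -> None:
    bonds_to_dataframe(bonds).to_csv(path, sep="\t", index=False)
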