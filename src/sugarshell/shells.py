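"""Hydrophilic/hydrophobic first-shell classification and partial RDFs.

A water is *hydrophilic* when it takes part in at least one sugar-water
hydrogen bond (either role); it is *hydrophobic* when the minimum distance
from its oxygen to any of the six sugar carbons is below ``r_phobe``
(default 4.5 Å) and it is not hydrophilic. The two sets are exclusive by
construction, matching the coordination-number bookkeeping in which the
total first shell is their sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from ._geometry import minimum_image
from .hbond import HBond, R_CUT_DEFAULT, THETA_CUT_DEFAULT, detect_hbonds
from .io_formats import Frame, Topology

__all__ = [
    "ShellAssignment",
    "ShellSeries",
    "RDF",
    "R_PHOBE_DEFAULT",
    "classify_shells",
    "shell_counts",
    "partial_rdf",
    "first_minimum",
]

R_PHOBE_DEFAULT = 4.5  # Å, carbon-contact cutoff for the hydrophobic shell

CARBON_SITES = ("C1", "C2", "C3", "C4", "C5", "C6")


@dataclass
class ShellAssignment:
    frame_index: int
    hydrophilic: frozenset[int]  # water molecule indices
    hydrophobic: frozenset[int]

    def __post_init__(self) -> None:
        if self.hydrophilic & self.hydrophobic:
            raise ValueError("hydrophilic and hydrophobic sets overlap")


@dataclass
class ShellSeries:
    """Per-frame shell populations with their trajectory means."""

    nphile_series: np.ndarray
    nphobe_series: np.ndarray
    assignments: list[ShellAssignment]

    @property
    def nphile_mean(self) -> float:
        return float(np.mean(self.nphile_series))

    @property
    def nphobe_mean(self) -> float:
        return float(np.mean(self.nphobe_series))


@dataclass
class RDF:
    r: np.ndarray  # bin centers, Å
    g: np.ndarray  # dimensionless
    pair: str
    n_frames: int


def classify_shells(
    frame: Frame,
    topo: Topology,
    bonds: Iterable[HBond],
    r_phobe: float = R_PHOBE_DEFAULT,
) -> ShellAssignment:
    """Partition first-shell waters into exclusive hydrophilic/hydrophobic sets.

    ``bonds`` must be this frame's bond list (sugar-water bonds are read
    from it; water-water bonds are ignored here).
    """
    if r_phobe >= frame.box_edge / 2:
        raise ValueError(
            f"r_phobe={r_phobe} Å invalidates the minimum image convention "
            f"for box edge {frame.box_edge} Å"
        )
    w_of = topo.water_of_atom()
    philic: set[int] = set()
    frame_index = 0
    for b in bonds:
        frame_index = b.frame_index
        if b.donor_role == "water" and b.acceptor_role == "sugar":
            philic.add(w_of[b.donor_O])
        elif b.donor_role == "sugar" and b.acceptor_role == "water":
            philic.add(w_of[b.acceptor_O])

    carbons = np.array([topo.site_map[c] for c in CARBON_SITES if c in topo.site_map])
    phobic: set[int] = set()
    if carbons.size:
        c_pos = frame.positions[carbons]
        for wi, (o, _h1, _h2) in enumerate(topo.waters):
            if wi in philic:
                continue
            d = np.linalg.norm(
                minimum_image(c_pos - frame.positions[o], frame.box_edge), axis=1
            )
            if float(d.min()) < r_phobe:
                phobic.add(wi)
    return ShellAssignment(frame_index, frozenset(philic), frozenset(phobic))


def shell_counts(
    traj: Sequence[Frame],
    topo: Topology,
    r_cut: float = R_CUT_DEFAULT,
    theta_cut: float = THETA_CUT_DEFAULT,
    r_phobe: float = R_PHOBE_DEFAULT,
    bonds_per_frame: Optional[Sequence[Iterable[HBond]]] = None,
) -> ShellSeries:
    """NHPHILE/NHPHOBE means and per-frame series over a trajectory.

    Bond lists may be supplied to avoid re-detection; otherwise they are
    computed per frame with the given cutoffs.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must contain at least one frame")
    assignments: list[ShellAssignment] = []
    for k, fr in enumerate(traj):
        bonds = (
            bonds_per_frame[k]
            if bonds_per_frame is not None
            else detect_hbonds(fr, topo, r_cut=r_cut, theta_cut=theta_cut, frame_index=k)
        )
        sa = classify_shells(fr, topo, bonds, r_phobe=r_phobe)
        assignments.append(ShellAssignment(k, sa.hydrophilic, sa.hydrophobic))
    return ShellSeries(
        nphile_series=np.array([len(a.hydrophilic) for a in assignments], float),
        nphobe_series=np.array([len(a.hydrophobic) for a in assignments], float),
        assignments=assignments,
    )


def partial_rdf(
    traj: Sequence[Frame],
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    dr: float,
    r_max: float,
    pair: str = "A-B",
) -> RDF:
    """Partial radial distribution function g_AB(r).

    Standard pair-distance histogram under the minimum image convention,
    normalized by the ideal-gas shell count 4*pi*r^2*dr at the B-partner
    number density (instantaneous box volume; self pairs excluded and the
    density corrected to (N_B - 1)/V when the selections coincide).
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    selection_a = np.asarray(selection_a, int)
    selection_b = np.asarray(selection_b, int)
    if selection_a.size == 0 or selection_b.size == 0:
        raise ValueError("empty selection")
    if len(traj) == 0:
        raise ValueError("trajectory must contain at least one frame")
    if r_max >= traj[0].box_edge / 2:
        raise ValueError("r_max must be below half the box edge")
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    hist = np.zeros(len(edges) - 1)
    same = selection_a.size == selection_b.size and np.array_equal(
        np.sort(selection_a), np.sort(selection_b)
    )
    norm = np.zeros_like(hist)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for fr in traj:
        pa = fr.positions[selection_a]
        pb = fr.positions[selection_b]
        d = pb[None, :, :] - pa[:, None, :]
        d = minimum_image(d, fr.box_edge)
        r = np.linalg.norm(d, axis=-1)
        if same:
            np.fill_diagonal(r, np.inf)
        elif np.intersect1d(selection_a, selection_b).size:
            mask = selection_a[:, None] == selection_b[None, :]
            r[mask] = np.inf
        hist += np.histogram(r.ravel(), bins=edges)[0]
        volume = fr.box_edge**3
        n_b = selection_b.size - (1 if same else 0)
        rho_b = n_b / volume
        norm += selection_a.size * rho_b * shell_vol
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDF(r=centers, g=g, pair=pair, n_frames=len(traj))


def first_minimum(rdf: RDF, window: tuple[float, float]) -> float:
    """Abscissa of the first intermolecular minimum of a smoothed g(r).

    The g(r) is smoothed with a 3-bin moving average; within ``window``
    the first local maximum is located and the first interior local
    minimum after it is returned. If the curve has no interior minimum in
    the window (e.g. it is monotone), a ValueError is raised rather than
    guessing.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be an increasing interval")
    if lo < rdf.r[0] or hi > rdf.r[-1]:
        raise ValueError("window outside the RDF support")
    g = np.convolve(rdf.g, np.ones(3) / 3.0, mode="same")
    idx = np.nonzero((rdf.r >= lo) & (rdf.r <= hi))[0]
    if idx.size < 3:
        raise ValueError("window too narrow for the RDF binning")
    gw = g[idx]
    max_pos = None
    for i in range(1, len(gw) - 1):
        if gw[i] > gw[i - 1] and gw[i] >= gw[i + 1]:
            max_pos = i
            break
    if max_pos is None:
        raise ValueError("no interior maximum found in the window")
    for i in range(max_pos + 1, len(gw) - 1):
        if gw[i] < gw[i - 1] and gw[i] <= gw[i + 1]:
            return float(rdf.r[idx[i]])
    raise ValueError("no interior minimum found after the first maximum")
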