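"""Synthetic trajectories, Wannier centers and densities with planted truth.

The generator emulates the studied systems — one hexopyranose (24 atoms)
plus 99 rigid three-site waters in a cubic box of edge ~15.1-15.3 Å —
with fully known ground truth: which waters are hydrogen-bonded to which
sugar site and in which role, which are hydrophobic contacts, and which
are bulk. Every planted classification is built with explicit safety
margins to the 2.5 Å / 30° / 4.5 Å thresholds so that per-frame Gaussian
jitter cannot flip it; incidental water-water hydrogen bonds (unavoidable
at liquid-like packing) are themselves margin-protected and recorded in
the truth record.

No attempt is made at physically realistic liquid structure: these are
geometric fixtures for validating the analysis pipeline, not simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._geometry import ATOMIC_MASSES, minimum_image, rotation_about_axis
from .io_formats import Frame, SugarTemplate, Topology, DensityGrid, WannierFrame

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "PackingError",
    "ANOMERS",
    "sugar_template",
    "build_system",
    "make_wannier",
    "make_density",
]

# Water internal geometry: rigid three-site, 0.9572 Å / 104.52 deg.
WATER_OH = 0.9572
WATER_HOH_DEG = 104.52

# Classification thresholds and the safety margins planted geometries keep
# to them (>= 3 sigma of the jitter amplitudes the fixtures use).
R_CUT = 2.5
THETA_CUT = 30.0
R_PHOBE = 4.5
DELTA_R = 0.30  # Å
DELTA_THETA = 15.0  # deg
DELTA_PHOBE = 0.30  # Å
MIN_OO = 2.4  # Å, non-overlap between oxygens / heavy atoms
# Shell waters keep this margin to the molecular XY plane so that jitter
# (which also tilts the molecule-fixed frame slightly) cannot move them
# across it.
MIN_PLANE_Z = 0.6  # Å

ANOMERS = ("alpha-glucose", "beta-glucose", "alpha-galactose", "alpha-mannose")


class PackingError(RuntimeError):
    """Waters could not be packed under the planted-margin constraints."""


# --------------------------------------------------------------------------
# Sugar templates
# --------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def sugar_template(anomer: str) -> SugarTemplate:
    """Idealized 24-atom chair-conformer hexopyranose template.

    Sites: ring C1..C5 + O5, hydroxyl oxygens O1..O4 and O6 (on the
    exocyclic C6), hydroxyl hydrogens HO1..HO4/HO6 and seven C-H
    hydrogens. Anomers differ in which side of the ring plane O1 (and,
    for galactose/mannose, O4/O2) points: for the beta anomer O1 and O6
    lie on the same side of the molecular plane, for alpha anomers on
    opposite sides.
    """
    if anomer not in ANOMERS:
        raise ValueError(f"unknown anomer {anomer!r}; choose from {ANOMERS}")
    # z-side of the O substituent at C1, C2, C4 (O6 is always +1)
    o_sign = {"O1": -1.0, "O2": -1.0, "O3": 1.0, "O4": -1.0}
    if anomer == "beta-glucose":
        o_sign["O1"] = 1.0
    elif anomer == "alpha-galactose":
        o_sign["O4"] = 1.0
    elif anomer == "alpha-mannose":
        o_sign["O2"] = 1.0

    r_ring, dz = 1.45, 0.25
    cc, co, oh, ch = 1.52, 1.43, 0.96, 1.09
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    ring_pos = {}
    for i, nm in enumerate(names):
        th = np.deg2rad(60.0 * i)
        z = dz if i % 2 == 0 else -dz
        ring_pos[nm] = np.array([r_ring * np.cos(th), r_ring * np.sin(th), z])

    sites: list[str] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []

    def add(site: str, el: str, pos: np.ndarray) -> None:
        sites.append(site)
        elements.append(el)
        coords.append(pos)

    zhat = np.array([0.0, 0.0, 1.0])
    for nm in names:
        add(nm, nm[0], ring_pos[nm])

    # hydroxyls on C1..C4 and the ring hydrogens on the opposite slot
    for i in (1, 2, 3, 4):
        c = ring_pos[f"C{i}"]
        rhat = _unit(np.array([c[0], c[1], 0.0]))
        s = o_sign[f"O{i}"]
        d_o = _unit(rhat + 0.9 * s * zhat)
        d_h = _unit(rhat - 0.9 * s * zhat)
        o = c + co * d_o
        t = _unit(np.cross(zhat, rhat))
        ho = o + oh * _unit(_unit(o - c) + 0.6 * t)
        add(f"O{i}", "O", o)
        add(f"HO{i}", "H", ho)
        add(f"H{i}", "H", c + ch * d_h)

    # exocyclic CH2OH on C5: C6 above the plane, so O6 has z > 0
    c5 = ring_pos["C5"]
    rhat5 = _unit(np.array([c5[0], c5[1], 0.0]))
    d_c6 = _unit(rhat5 + 0.9 * zhat)
    c6 = c5 + cc * d_c6
    add("C6", "C", c6)
    add("H5", "H", c5 + ch * _unit(rhat5 - 0.9 * zhat))
    d_o6 = _unit(zhat + 0.45 * rhat5)
    o6 = c6 + co * d_o6
    add("O6", "O", o6)
    t6 = _unit(np.cross(zhat, rhat5))
    add("HO6", "H", o6 + oh * _unit(_unit(o6 - c6) + 0.6 * t6))
    # two H on C6 completing a tetrahedron around it
    b1 = _unit(c5 - c6)
    b2 = _unit(o6 - c6)
    p = _unit(np.cross(b1, b2))
    base = -_unit(b1 + b2)
    add("H61", "H", c6 + ch * _unit(base + 1.1 * p))
    add("H62", "H", c6 + ch * _unit(base - 1.1 * p))

    pos = np.array(coords)
    masses = np.array([ATOMIC_MASSES[e] for e in elements])
    pos -= (pos * masses[:, None]).sum(axis=0) / masses.sum()  # CM at origin
    return SugarTemplate(name=anomer, elements=elements, positions=pos, site_names=sites)


# --------------------------------------------------------------------------
# Plant specification and ground truth
# --------------------------------------------------------------------------


def _default_donors() -> dict[str, int]:
    # waters donating an H to sugar oxygens (sugar is acceptor)
    return {"O1": 1, "O2": 1, "O3": 1, "O4": 1, "O6": 2}


def _default_acceptors() -> dict[str, int]:
    # waters accepting the hydroxyl H (sugar is donor); one per hydroxyl
    return {"O1": 1, "O2": 1, "O3": 1, "O4": 1, "O6": 1}


@dataclass
class PlantSpec:
    """Planted system layout; defaults emulate the beta-glucose system.

    11 hydrogen-bonded (hydrophilic) waters, 9 exclusive hydrophobic
    contacts and 79 bulk waters (99 total) in a 15.2640 Å box, with donor
    bonds planted shorter than acceptor bonds.
    """

    donor_waters: dict[str, int] = field(default_factory=_default_donors)
    acceptor_waters: dict[str, int] = field(default_factory=_default_acceptors)
    n_hydrophobic: int = 9
    n_bulk: int = 79
    # sugar-donor bonds (hydroxyl H -> water O) are planted shorter than
    # sugar-acceptor bonds (water H -> sugar O), the ordering seen in
    # carbohydrate hydration studies.
    sugar_donor_r_mean: float = 1.80  # Å, H_i...O_water
    sugar_donor_r_spread: float = 0.06
    sugar_acceptor_r_mean: float = 1.95  # Å, O_i...H_water
    sugar_acceptor_r_spread: float = 0.06
    angle_spread_deg: float = 5.0  # planted theta ~ |N(0, spread)|, capped
    phobe_frac_above: float = 0.6667  # steer hydrophobic waters above the plane
    box_edge: float = 15.2640
    n_frames: int = 20
    jitter_sigma: float = 0.03  # Å per coordinate per frame
    seed: int = 0

    @property
    def n_hydrophilic(self) -> int:
        return sum(self.donor_waters.values()) + sum(self.acceptor_waters.values())

    @property
    def n_waters(self) -> int:
        return self.n_hydrophilic + self.n_hydrophobic + self.n_bulk


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a planted system."""

    topology: Topology
    sugar_bonds: list[dict]  # site, water, role ('donor'|'acceptor' of sugar), r_HA, theta
    water_water_bonds: list[tuple[int, int, int]]  # (donor water, H slot, acceptor water)
    hydrophilic: frozenset[int]
    hydrophobic: frozenset[int]
    coordination: np.ndarray  # per water, sugar + water-water bonds
    roles: list[str]  # per water toward the solute
    above_below: dict[str, tuple[int, int]]  # class -> (above, below) in base config
    site_donor_counts: dict[str, int]  # sugar site as donor
    site_acceptor_counts: dict[str, int]  # sugar site as acceptor
    base_positions: np.ndarray
    margins: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Margin classifier shared by placement and self-validation
# --------------------------------------------------------------------------


def _classify_pair(
    o_donor: np.ndarray, h: np.ndarray, o_acc: np.ndarray, box: float
) -> str:
    """'bond' / 'free' / 'ambiguous' for one donor-H...acceptor triple."""
    r = float(np.linalg.norm(minimum_image(o_acc - h, box)))
    if r >= R_CUT + DELTA_R:
        return "free"
    v_oh = minimum_image(h - o_donor, box)
    v_oa = minimum_image(o_acc - o_donor, box)
    cosang = np.dot(v_oh, v_oa) / (np.linalg.norm(v_oh) * np.linalg.norm(v_oa))
    theta = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    if theta >= THETA_CUT + DELTA_THETA:
        return "free"
    if r <= R_CUT - DELTA_R and theta <= THETA_CUT - DELTA_THETA:
        return "bond"
    return "ambiguous"


def _pair_geometry(
    o_donor: np.ndarray, h: np.ndarray, o_acc: np.ndarray, box: float
) -> tuple[float, float]:
    r = float(np.linalg.norm(minimum_image(o_acc - h, box)))
    v_oh = minimum_image(h - o_donor, box)
    v_oa = minimum_image(o_acc - o_donor, box)
    cosang = np.dot(v_oh, v_oa) / (np.linalg.norm(v_oh) * np.linalg.norm(v_oa))
    return r, float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


# vectorized classification codes: 0 = free, 1 = bond, 2 = ambiguous
def _classify_batch(
    o_donor: np.ndarray, h: np.ndarray, o_acc: np.ndarray, box: float
) -> np.ndarray:
    """Classify many donor-H...acceptor triples at once (broadcastable)."""
    o_donor, h, o_acc = np.broadcast_arrays(
        np.atleast_2d(o_donor), np.atleast_2d(h), np.atleast_2d(o_acc)
    )
    r = np.linalg.norm(minimum_image(o_acc - h, box), axis=-1)
    v_oh = minimum_image(h - o_donor, box)
    v_oa = minimum_image(o_acc - o_donor, box)
    with np.errstate(invalid="ignore"):  # self pairs (zero O->O vector)
        cosang = np.einsum("ij,ij->i", v_oh, v_oa) / (
            np.linalg.norm(v_oh, axis=-1) * np.linalg.norm(v_oa, axis=-1)
        )
    theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    free = (r >= R_CUT + DELTA_R) | (theta >= THETA_CUT + DELTA_THETA)
    bond = (r <= R_CUT - DELTA_R) & (theta <= THETA_CUT - DELTA_THETA)
    return np.where(free, 0, np.where(bond, 1, 2))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _water_orientation(
    o_pos: np.ndarray, h1_dir: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """(2, 3) H positions for a rigid water with H1 along ``h1_dir``."""
    h1_dir = _unit(h1_dir)
    perp = np.cross(h1_dir, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-8:
        perp = np.cross(h1_dir, _random_unit(rng))
    perp = _unit(perp)
    rot = rotation_about_axis(perp, np.deg2rad(WATER_HOH_DEG))
    h2_dir = rot @ h1_dir
    return np.vstack([o_pos + WATER_OH * h1_dir, o_pos + WATER_OH * h2_dir])


# --------------------------------------------------------------------------
# System builder
# --------------------------------------------------------------------------


class _Builder:
    def __init__(self, spec: PlantSpec, template: SugarTemplate):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.box = spec.box_edge
        center = np.full(3, self.box / 2.0)
        self.solute_pos = template.positions + center
        self.template = template
        self.site = {nm: i for i, nm in enumerate(template.site_names)}
        self.sugar_o = {
            nm: self.solute_pos[i] for nm, i in self.site.items()
            if nm in ("O1", "O2", "O3", "O4", "O5", "O6")
        }
        self.hydroxyls = {
            f"O{k}": (self.solute_pos[self.site[f"O{k}"]], self.solute_pos[self.site[f"HO{k}"]])
            for k in (1, 2, 3, 4, 6)
        }
        self.carbons = np.array(
            [self.solute_pos[self.site[f"C{k}"]] for k in range(1, 7)]
        )
        self._sugar_o_names = sorted(self.sugar_o)
        self._sugar_o_pos = np.array([self.sugar_o[n] for n in self._sugar_o_names])
        self._hydroxyl_names = sorted(self.hydroxyls)
        self._hydroxyl_o_pos = np.array([self.hydroxyls[n][0] for n in self._hydroxyl_names])
        self._hydroxyl_h_pos = np.array([self.hydroxyls[n][1] for n in self._hydroxyl_names])
        self.heavy = self.solute_pos[
            [i for i, e in enumerate(template.elements) if e != "H"]
        ]
        self.cm = (
            self.solute_pos
            * np.array([ATOMIC_MASSES[e] for e in template.elements])[:, None]
        ).sum(axis=0) / sum(ATOMIC_MASSES[e] for e in template.elements)
        # molecule-fixed axes of the base configuration (for plane steering)
        c1 = self.solute_pos[self.site["C1"]]
        c5 = self.solute_pos[self.site["C5"]]
        self.z_axis = _unit(np.cross(c5 - self.cm, c1 - self.cm))
        self.waters: list[np.ndarray] = []  # (3, 3) blocks: O, H1, H2
        self.kinds: list[str] = []
        self.sugar_bonds: list[dict] = []

    # -- constraint checks -------------------------------------------------

    def _overlap_ok(self, o_pos: np.ndarray) -> bool:
        if self.waters:
            oo = np.array([w[0] for w in self.waters])
            if np.min(np.linalg.norm(minimum_image(oo - o_pos, self.box), axis=1)) < MIN_OO:
                return False
        d = np.linalg.norm(minimum_image(self.heavy - o_pos, self.box), axis=1)
        return bool(np.min(d) >= MIN_OO)

    def _water_env_ok(
        self,
        o_pos: np.ndarray,
        h_pos: np.ndarray,
        planted: Optional[tuple[str, str]] = None,
    ) -> bool:
        """Margin-check one candidate water against sugar and placed waters.

        ``planted`` = (kind, site): ('donor', site) means H slot 0 must be
        a clear bond to that sugar O; ('acceptor', site) means the sugar
        hydroxyl at ``site`` must be a clear donor to this water's O.
        Every other pairing must be clearly non-bonded toward the sugar;
        water-water pairings may be clear bonds (recorded later) but not
        ambiguous.
        """
        box = self.box
        # candidate's H vs sugar oxygens
        for slot in (0, 1):
            codes = _classify_batch(o_pos, h_pos[slot], self._sugar_o_pos, box)
            expected = np.zeros(len(codes), dtype=int)
            if planted and planted[0] == "donor" and slot == 0:
                expected[self._sugar_o_names.index(planted[1])] = 1
            if np.any(codes != expected):
                return False
        # sugar hydroxyl H vs candidate O
        codes = _classify_batch(self._hydroxyl_o_pos, self._hydroxyl_h_pos, o_pos, box)
        expected = np.zeros(len(codes), dtype=int)
        if planted and planted[0] == "acceptor":
            expected[self._hydroxyl_names.index(planted[1])] = 1
        if np.any(codes != expected):
            return False
        # vs placed waters, both directions: anything but 'ambiguous' is fine
        if self.waters:
            oo = np.array([w[0] for w in self.waters])
            for slot in (0, 1):
                if np.any(_classify_batch(o_pos, h_pos[slot], oo, box) == 2):
                    return False
                hh = np.array([w[1 + slot] for w in self.waters])
                if np.any(_classify_batch(oo, hh, o_pos, box) == 2):
                    return False
        return True

    def _try_orientations(
        self,
        o_pos: np.ndarray,
        planted: Optional[tuple[str, str]],
        h1_dir: Optional[np.ndarray],
        tries: int = 80,
    ) -> Optional[np.ndarray]:
        for _ in range(tries):
            d1 = h1_dir if h1_dir is not None else _random_unit(self.rng)
            h_pos = _water_orientation(o_pos, d1, self.rng)
            if self._water_env_ok(o_pos, h_pos, planted):
                return h_pos
        return None

    def _commit(self, o_pos: np.ndarray, h_pos: np.ndarray, kind: str) -> int:
        self.waters.append(np.vstack([o_pos, h_pos]))
        self.kinds.append(kind)
        return len(self.waters) - 1

    # -- placement per category -------------------------------------------

    def place_donor_water(self, site: str) -> None:
        """Water donating one H to sugar oxygen ``site``."""
        o_s = self.sugar_o[site]
        out_axis = _unit(o_s - self.cm)
        rng, spec = self.rng, self.spec
        for _ in range(600):
            d = _unit(out_axis + 0.55 * rng.normal(size=3))
            if np.dot(d, out_axis) < 0.5:
                continue
            r_ha = float(
                np.clip(
                    rng.normal(spec.sugar_acceptor_r_mean, spec.sugar_acceptor_r_spread),
                    1.65,
                    R_CUT - DELTA_R - 0.05,
                )
            )
            h1 = o_s + r_ha * d
            # small angular detuning of the water O about H1
            tilt = np.deg2rad(
                min(abs(rng.normal(0.0, spec.angle_spread_deg)), 2 * spec.angle_spread_deg)
            )
            axis = np.cross(d, _random_unit(rng))
            if np.linalg.norm(axis) < 1e-8:
                continue
            d2 = rotation_about_axis(_unit(axis), tilt) @ d
            o_w = h1 + WATER_OH * d2
            if abs(np.dot(o_w - self.cm, self.z_axis)) < MIN_PLANE_Z:
                continue
            if not self._overlap_ok(o_w):
                continue
            # theta at the water O for the planted bond must stay in-margin
            r_chk, theta_chk = _pair_geometry(o_w, h1, o_s, self.box)
            if r_chk > R_CUT - DELTA_R or theta_chk > THETA_CUT - DELTA_THETA - 3.0:
                continue
            h_pos = self._try_orientations(o_w, ("donor", site), _unit(h1 - o_w))
            if h_pos is None:
                continue
            wi = self._commit(o_w, h_pos, "hydrophilic")
            self.sugar_bonds.append(
                {"site": site, "water": wi, "sugar_role": "acceptor",
                 "r_HA": r_chk, "theta": theta_chk}
            )
            return
        raise PackingError(f"could not place donor water at {site}")

    def place_acceptor_water(self, site: str) -> None:
        """Water accepting the hydroxyl H of sugar ``site``."""
        o_s, h_s = self.hydroxyls[site]
        u = _unit(h_s - o_s)
        rng, spec = self.rng, self.spec
        for _ in range(600):
            r_ha = float(
                np.clip(
                    rng.normal(spec.sugar_donor_r_mean, spec.sugar_donor_r_spread),
                    1.65,
                    R_CUT - DELTA_R - 0.05,
                )
            )
            tilt = np.deg2rad(
                min(abs(rng.normal(0.0, spec.angle_spread_deg)), 2 * spec.angle_spread_deg)
            )
            axis = np.cross(u, _random_unit(rng))
            if np.linalg.norm(axis) < 1e-8:
                continue
            d = rotation_about_axis(_unit(axis), tilt) @ u
            o_w = h_s + r_ha * d
            if abs(np.dot(o_w - self.cm, self.z_axis)) < MIN_PLANE_Z:
                continue
            if not self._overlap_ok(o_w):
                continue
            r_chk, theta_chk = _pair_geometry(o_s, h_s, o_w, self.box)
            if r_chk > R_CUT - DELTA_R or theta_chk > THETA_CUT - DELTA_THETA - 3.0:
                continue
            h_pos = self._try_orientations(o_w, ("acceptor", site), None)
            if h_pos is None:
                continue
            wi = self._commit(o_w, h_pos, "hydrophilic")
            self.sugar_bonds.append(
                {"site": site, "water": wi, "sugar_role": "donor",
                 "r_HA": r_chk, "theta": theta_chk}
            )
            return
        raise PackingError(f"could not place acceptor water at {site}")

    def place_hydrophobic_water(self, want_above: bool) -> None:
        rng = self.rng
        for _ in range(2000):
            c = self.carbons[rng.integers(len(self.carbons))]
            d = _unit(c - self.cm + 0.8 * rng.normal(size=3))
            r = rng.uniform(3.5, R_PHOBE - DELTA_PHOBE)
            o_w = c + r * d
            z = float(np.dot(o_w - self.cm, self.z_axis))
            if (z >= 0.0) != want_above or abs(z) < MIN_PLANE_Z:
                continue  # keep a margin to the plane so jitter cannot flip it
            dmin = float(
                np.min(np.linalg.norm(minimum_image(self.carbons - o_w, self.box), axis=1))
            )
            if dmin >= R_PHOBE - DELTA_PHOBE or dmin < 3.2:
                continue
            if not self._overlap_ok(o_w):
                continue
            h_pos = self._try_orientations(o_w, None, None, tries=60)
            if h_pos is None:
                continue
            self._commit(o_w, h_pos, "hydrophobic")
            return
        raise PackingError("could not place a hydrophobic-contact water")

    def place_bulk_water(self) -> None:
        rng = self.rng
        for _ in range(4000):
            o_w = rng.uniform(0.0, self.box, size=3)
            dmin = float(
                np.min(np.linalg.norm(minimum_image(self.carbons - o_w, self.box), axis=1))
            )
            if dmin <= R_PHOBE + DELTA_PHOBE:
                continue
            if not self._overlap_ok(o_w):
                continue
            h_pos = self._try_orientations(o_w, None, None, tries=60)
            if h_pos is None:
                continue
            self._commit(o_w, h_pos, "bulk")
            return
        raise PackingError(
            f"could not place bulk water #{self.kinds.count('bulk') + 1} "
            f"({len(self.waters)} placed so far)"
        )

    # -- assembly ----------------------------------------------------------

    def build(self) -> tuple[list[Frame], GroundTruth]:
        spec = self.spec
        for site in sorted(spec.acceptor_waters):
            for _ in range(spec.acceptor_waters[site]):
                self.place_acceptor_water(site)
        for site in sorted(spec.donor_waters):
            for _ in range(spec.donor_waters[site]):
                self.place_donor_water(site)
        n_above = int(round(spec.n_hydrophobic * spec.phobe_frac_above))
        for k in range(spec.n_hydrophobic):
            self.place_hydrophobic_water(want_above=k < n_above)
        for _ in range(spec.n_bulk):
            self.place_bulk_water()

        n_sol = self.template.n_atoms
        elements = list(self.template.elements) + ["O", "H", "H"] * len(self.waters)
        base = np.vstack([self.solute_pos] + self.waters)
        topo = Topology(
            solute_atoms=np.arange(n_sol),
            site_map={nm: i for i, nm in enumerate(self.template.site_names)},
            waters=[
                (n_sol + 3 * k, n_sol + 3 * k + 1, n_sol + 3 * k + 2)
                for k in range(len(self.waters))
            ],
        )

        # final sweep: classify every pair, assert margins, collect ww bonds
        ww_bonds: list[tuple[int, int, int]] = []
        oo = np.array([w[0] for w in self.waters])
        for i, wi in enumerate(self.waters):
            for slot in (0, 1):
                codes = _classify_batch(wi[0], wi[1 + slot], oo, self.box)
                codes[i] = 0  # self
                if np.any(codes == 2):
                    raise PackingError(
                        f"water {i} left an ambiguous pairing; margins violated"
                    )
                for j in np.nonzero(codes == 1)[0]:
                    ww_bonds.append((i, slot, int(j)))
        planted_keys = {(b["site"], b["water"], b["sugar_role"]) for b in self.sugar_bonds}
        found_keys = set()
        for nm, o_s in self.sugar_o.items():
            for slot in (0, 1):
                hh = np.array([w[1 + slot] for w in self.waters])
                codes = _classify_batch(oo, hh, o_s, self.box)
                if np.any(codes == 2):
                    raise PackingError("ambiguous sugar-acceptor pairing survived")
                for i in np.nonzero(codes == 1)[0]:
                    found_keys.add((nm, int(i), "acceptor"))
        for nm, (o_s, h_s) in self.hydroxyls.items():
            codes = _classify_batch(o_s, h_s, oo, self.box)
            if np.any(codes == 2):
                raise PackingError("ambiguous sugar-donor pairing survived")
            for i in np.nonzero(codes == 1)[0]:
                found_keys.add((nm, int(i), "donor"))
        if found_keys != planted_keys:
            raise PackingError(
                f"sugar-water bond sweep disagrees with plant: "
                f"extra={found_keys - planted_keys}, missing={planted_keys - found_keys}"
            )

        hydrophilic = frozenset(b["water"] for b in self.sugar_bonds)
        hydrophobic = frozenset(
            i
            for i, w in enumerate(self.waters)
            if i not in hydrophilic
            and float(
                np.min(np.linalg.norm(minimum_image(self.carbons - w[0], self.box), axis=1))
            )
            < R_PHOBE
        )

        coordination = np.zeros(len(self.waters), dtype=int)
        for b in self.sugar_bonds:
            coordination[b["water"]] += 1
        for di, _slot, ai in ww_bonds:
            coordination[di] += 1
            coordination[ai] += 1

        roles = []
        for i in range(len(self.waters)):
            d = any(
                b["water"] == i and b["sugar_role"] == "acceptor" for b in self.sugar_bonds
            )
            a = any(
                b["water"] == i and b["sugar_role"] == "donor" for b in self.sugar_bonds
            )
            roles.append("both" if d and a else "donor" if d else "acceptor" if a else "none")

        above_below = {}
        for cls, members in (("hydrophilic", hydrophilic), ("hydrophobic", hydrophobic)):
            zs = [
                float(np.dot(self.waters[i][0] - self.cm, self.z_axis)) for i in members
            ]
            above_below[cls] = (sum(z >= 0 for z in zs), sum(z < 0 for z in zs))

        site_donor = {}
        site_acceptor = {}
        for b in self.sugar_bonds:
            if b["sugar_role"] == "donor":
                site_donor[b["site"]] = site_donor.get(b["site"], 0) + 1
            else:
                site_acceptor[b["site"]] = site_acceptor.get(b["site"], 0) + 1

        frames = []
        for k in range(spec.n_frames):
            pos = base.copy()
            if spec.jitter_sigma > 0:
                pos = pos + self.rng.normal(0.0, spec.jitter_sigma, size=pos.shape)
            frames.append(Frame(list(elements), pos, self.box, time_fs=0.5 * k))

        truth = GroundTruth(
            topology=topo,
            sugar_bonds=self.sugar_bonds,
            water_water_bonds=ww_bonds,
            hydrophilic=hydrophilic,
            hydrophobic=hydrophobic,
            coordination=coordination,
            roles=roles,
            above_below=above_below,
            site_donor_counts=site_donor,
            site_acceptor_counts=site_acceptor,
            base_positions=base,
            margins={
                "delta_r": DELTA_R,
                "delta_theta": DELTA_THETA,
                "delta_phobe": DELTA_PHOBE,
            },
        )
        return frames, truth


def build_system(
    spec: Optional[PlantSpec] = None, template: Optional[SugarTemplate] = None
) -> tuple[list[Frame], GroundTruth]:
    """Build a planted trajectory and its ground-truth record.

    Same seed, spec and template give a bit-identical trajectory.
    """
    spec = spec or PlantSpec()
    template = template or sugar_template("beta-glucose")
    return _Builder(spec, template).build()


# --------------------------------------------------------------------------
# Wannier-center fixtures
# --------------------------------------------------------------------------

LP_DIST = 0.34  # Å, lone-pair center distance from O
LP_HALF_ANGLE = 45.0  # deg, from the negative bisector


def _o_lone_pairs(o: np.ndarray, b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Two lone-pair center positions for an O bonded along b1, b2."""
    bis = _unit(_unit(b1) + _unit(b2))
    perp = _unit(np.cross(b1, b2))
    c, s = np.cos(np.deg2rad(LP_HALF_ANGLE)), np.sin(np.deg2rad(LP_HALF_ANGLE))
    return np.vstack(
        [o + LP_DIST * (-c * bis + s * perp), o + LP_DIST * (-c * bis - s * perp)]
    )


def _solute_bonds(template: SugarTemplate) -> list[tuple[int, int]]:
    from .io_formats import _bond_graph  # template connectivity

    g = _bond_graph(template.elements, template.positions, None)
    return sorted(tuple(sorted(e)) for e in g.edges)


# bond-center position fraction from the first (more electronegative) atom
_BOND_FRACTION = {("O", "H"): 0.30, ("O", "C"): 0.40, ("C", "C"): 0.50, ("C", "H"): 0.55}


def _bond_center(ea: str, pa: np.ndarray, eb: str, pb: np.ndarray) -> np.ndarray:
    if (ea, eb) in _BOND_FRACTION:
        f = _BOND_FRACTION[(ea, eb)]
        return pa + f * (pb - pa)
    f = _BOND_FRACTION[(eb, ea)]
    return pb + f * (pa - pb)


def make_wannier(
    traj: Sequence[Frame],
    topo: Topology,
    template: Optional[SugarTemplate] = None,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[list[WannierFrame], list[dict[str, np.ndarray]]]:
    """Idealized Wannier centers for every frame plus ground-truth dipoles.

    Each water gets two bond centers at half its O-H vectors and two
    lone-pair centers 0.34 Å from O; the solute gets one center per
    covalent bond plus two lone pairs per oxygen (36 centers for the
    24-atom sugar). Ground-truth dipoles are point-charge sums (cores
    O +6 / H +1 / C +4, centers -2e) about each molecule's center of
    mass, in Debye.
    """
    from .electronic import CORE_CHARGES, EANG_TO_DEBYE

    rng = np.random.default_rng(seed)
    sol_bonds: list[tuple[int, int]] = []
    if len(topo.solute_atoms) and template is not None:
        sol_bonds = _solute_bonds(template)
    wframes: list[WannierFrame] = []
    truths: list[dict[str, np.ndarray]] = []

    def dipole(els, pos, centers):
        q = np.array([CORE_CHARGES[e] for e in els])
        m = np.array([ATOMIC_MASSES[e] for e in els])
        cm = (pos * m[:, None]).sum(axis=0) / m.sum()
        mu = (q[:, None] * (pos - cm)).sum(axis=0) - 2.0 * (centers - cm).sum(axis=0)
        return mu * EANG_TO_DEBYE

    for fr in traj:
        centers_all = []
        truth: dict[str, np.ndarray] = {}
        if sol_bonds:
            tmpl_to_frame = {t: topo.site_map[template.site_names[t]] for t in range(template.n_atoms)}
            spos = {t: fr.positions[tmpl_to_frame[t]] for t in tmpl_to_frame}
            scenters = []
            neighbors: dict[int, list[int]] = {}
            for a, b in sol_bonds:
                neighbors.setdefault(a, []).append(b)
                neighbors.setdefault(b, []).append(a)
                scenters.append(
                    _bond_center(
                        template.elements[a], spos[a], template.elements[b], spos[b]
                    )
                )
            for t in range(template.n_atoms):
                if template.elements[t] != "O":
                    continue
                nb = neighbors[t]
                b1 = spos[nb[0]] - spos[t]
                b2 = (
                    spos[nb[1]] - spos[t]
                    if len(nb) > 1
                    else np.cross(b1, [0.0, 0.0, 1.0])
                )
                scenters.extend(_o_lone_pairs(spos[t], b1, b2))
            scenters = np.array(scenters)
            if jitter_sigma > 0:
                scenters = scenters + rng.normal(0, jitter_sigma, scenters.shape)
            centers_all.append(scenters)
            sol_idx = topo.solute_atoms
            truth["solute"] = dipole(
                [fr.elements[i] for i in sol_idx], fr.positions[sol_idx], scenters
            )
        for wi, (o, h1, h2) in enumerate(topo.waters):
            po, p1, p2 = fr.positions[o], fr.positions[h1], fr.positions[h2]
            v1 = minimum_image(p1 - po, fr.box_edge)
            v2 = minimum_image(p2 - po, fr.box_edge)
            wc = np.vstack(
                [po + 0.5 * v1, po + 0.5 * v2, _o_lone_pairs(po, v1, v2)]
            )
            if jitter_sigma > 0:
                wc = wc + rng.normal(0, jitter_sigma, wc.shape)
            centers_all.append(wc)
            truth[f"water{wi}"] = dipole(
                [fr.elements[i] for i in (o, h1, h2)],
                np.vstack([po, po + v1, po + v2]),
                wc,
            )
        wframes.append(
            WannierFrame(np.vstack(centers_all), frame_index=len(wframes))
        )
        truths.append(truth)
    return wframes, truths


# --------------------------------------------------------------------------
# Gaussian density fixtures
# --------------------------------------------------------------------------


def make_density(
    atom_positions: np.ndarray,
    weights: Sequence[float],
    box_lengths: Sequence[float],
    shape: Sequence[int],
    sigma: float,
    elements: Optional[Sequence[str]] = None,
) -> DensityGrid:
    """Sum of isotropic normalized Gaussians on an axis-aligned grid.

    Each atom contributes ``weight`` electrons; the analytic grid
    integral is sum(weights) up to truncation at the box boundary.
    """
    atom_positions = np.asarray(atom_positions, float).reshape(-1, 3)
    box_lengths = np.asarray(box_lengths, float)
    shape = tuple(int(s) for s in shape)
    steps = box_lengths / np.array(shape)
    if sigma < 2 * steps.max():
        raise ValueError(
            f"Gaussian width {sigma} Å too narrow for voxel edges {steps} Å"
        )
    axes = [
        (np.arange(n) + 0.5) * st for n, st in zip(shape, steps)
    ]
    values = np.zeros(shape)
    norm1d = 1.0 / (np.sqrt(2 * np.pi) * sigma)
    for w, p in zip(weights, atom_positions):
        gx = norm1d * np.exp(-0.5 * ((axes[0] - p[0]) / sigma) ** 2)
        gy = norm1d * np.exp(-0.5 * ((axes[1] - p[1]) / sigma) ** 2)
        gz = norm1d * np.exp(-0.5 * ((axes[2] - p[2]) / sigma) ** 2)
        values += w * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
    if elements is None:
        elements = ["O"] * len(atom_positions)
    return DensityGrid(
        origin=steps / 2.0,
        cell_vectors=np.diag(steps),
        values=values,
        atom_positions=atom_positions,
        atom_elements=list(elements),
    )
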