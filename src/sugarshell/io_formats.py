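"""Trajectory and volumetric-grid I/O plus topology perception.

Formats handled
---------------
* multi-frame XYZ in the CP2K dialect (count line; comment line in which
  ``i = <step>, time = <fs>`` is tolerated and parsed when present),
* GRO fixed-column single frames (read through MDAnalysis; nm -> Å),
* PDB ATOM/HETATM subset (read-only, through MDAnalysis),
* Gaussian cube volumetric grids (positive voxel counts, i.e. Bohr axes),
* Wannier-center XYZ frames whose element label is ``X``.

The internal length unit is Å everywhere; nm (GRO) and Bohr (cube) are
converted at the boundary. Only cubic boxes are supported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from ._geometry import (
    ATOMIC_NUMBERS,
    BOHR_TO_ANGSTROM,
    COVALENT_RADII,
    mi_distance,
)

__all__ = [
    "Frame",
    "Topology",
    "DensityGrid",
    "WannierFrame",
    "SugarTemplate",
    "FormatError",
    "ParseError",
    "PerceptionError",
    "UnsupportedGeometryError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_gro",
    "write_gro",
    "read_pdb",
    "read_cube",
    "write_cube",
    "read_wannier_trajectory",
    "write_wannier_trajectory",
    "perceive_topology",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(ValueError):
    """A file parsed but violates the format's structural rules."""


class UnsupportedGeometryError(ValueError):
    """Non-cubic or otherwise unsupported simulation cell."""


class PerceptionError(ValueError):
    """Topology perception failed; the message names the offending atoms."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class Frame:
    """One configuration: element labels, Å coordinates, cubic box edge."""

    elements: list[str]
    positions: np.ndarray  # (N, 3) Å
    box_edge: float
    time_fs: Optional[float] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.elements) != len(self.positions):
            raise ValueError(
                f"{len(self.elements)} labels but {len(self.positions)} positions"
            )
        if not self.box_edge > 0:
            raise ValueError(f"box_edge must be positive, got {self.box_edge}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates in frame")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Topology:
    """Which atoms form the solute's named sites and which form waters.

    ``site_map`` maps names like ``C1``..``C6``, ``O1``..``O6``,
    ``HO1``..``HO4``, ``HO6`` and ring hydrogens to atom indices.
    ``waters`` lists (O, H, H) index triples, one per water molecule.
    """

    solute_atoms: np.ndarray  # sorted int indices
    site_map: dict[str, int]
    waters: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        self.solute_atoms = np.asarray(sorted(self.solute_atoms), dtype=int)
        solute = set(self.solute_atoms.tolist())
        water_atoms = [i for w in self.waters for i in w]
        if len(set(water_atoms)) != len(water_atoms):
            raise ValueError("an atom appears in two waters")
        if solute & set(water_atoms):
            raise ValueError("solute and water atom sets overlap")
        if len(set(self.site_map.values())) != len(self.site_map):
            raise ValueError("two sites map to the same atom")

    @property
    def n_waters(self) -> int:
        return len(self.waters)

    @property
    def water_oxygens(self) -> np.ndarray:
        return np.array([w[0] for w in self.waters], dtype=int)

    def water_of_atom(self) -> dict[int, int]:
        """Map atom index -> water molecule index."""
        out: dict[int, int] = {}
        for wi, (o, h1, h2) in enumerate(self.waters):
            out[o] = wi
            out[h1] = wi
            out[h2] = wi
        return out

    def hydroxyl_pairs(self) -> list[tuple[str, int, int]]:
        """(site name, O index, hydroxyl-H index) for every O-H site."""
        pairs = []
        for name, idx in self.site_map.items():
            if name.startswith("HO"):
                o_name = "O" + name[2:]
                if o_name in self.site_map:
                    pairs.append((o_name, self.site_map[o_name], idx))
        return sorted(pairs)

    def sugar_oxygen_sites(self) -> dict[int, str]:
        """Atom index -> site name for solute oxygens O1..O6."""
        return {
            idx: name
            for name, idx in self.site_map.items()
            if re.fullmatch(r"O\d", name)
        }


@dataclass
class DensityGrid:
    """Volumetric scalar field on an axis-aligned (or general) cell.

    ``values`` are in e/Å^3 for charge densities so that
    ``values.sum() * voxel_volume`` is an electron count.
    """

    origin: np.ndarray  # (3,) Å
    cell_vectors: np.ndarray  # (3, 3) Å, rows are voxel step vectors
    values: np.ndarray  # (nx, ny, nz)
    atom_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    atom_elements: list[str] = field(default_factory=list)
    atom_charges: Optional[np.ndarray] = None  # cube per-atom charge column

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.cell_vectors = np.asarray(self.cell_vectors, float).reshape(3, 3)
        self.values = np.asarray(self.values, float)
        self.atom_positions = np.asarray(self.atom_positions, float).reshape(-1, 3)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.cell_vectors)))

    def integral(self) -> float:
        """Integral of the field over the grid (e.g. total electron count)."""
        return float(self.values.sum() * self.voxel_volume)


@dataclass
class WannierFrame:
    """Maximally-localized orbital centers for one frame (Å)."""

    centers: np.ndarray  # (M, 3)
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float).reshape(-1, 3)


@dataclass
class SugarTemplate:
    """Named idealized solute geometry used for topology perception."""

    name: str
    elements: list[str]
    positions: np.ndarray  # (N, 3) Å
    site_names: list[str]  # per-atom site label

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        if not (len(self.elements) == len(self.positions) == len(self.site_names)):
            raise ValueError("template fields have inconsistent lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


# --------------------------------------------------------------------------
# XYZ (CP2K dialect)
# --------------------------------------------------------------------------

_TIME_RE = re.compile(r"time\s*=\s*([-+0-9.eEdD]+)")


def _parse_xyz_blocks(path: Path) -> Iterable[tuple[list[str], np.ndarray, Optional[float]]]:
    lines = path.read_text().splitlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if natoms < 0:
            raise ParseError(f"{path}: line {i + 1}: negative atom count")
        if i + 1 + natoms >= n_lines + 1 and natoms > 0:
            raise ParseError(f"{path}: truncated block starting at line {i + 1}")
        comment = lines[i + 1] if i + 1 < n_lines else ""
        m = _TIME_RE.search(comment)
        time_fs = float(m.group(1).replace("D", "E").replace("d", "e")) if m else None
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            ln = i + 2 + k
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {ln + 1}: malformed atom record")
            elements.append(parts[0])
            coords[k] = [float(p) for p in parts[1:4]]
        yield elements, coords, time_fs
        i += 2 + natoms


def read_xyz_trajectory(path: str | Path, box_edge: float) -> list[Frame]:
    """Read a multi-frame XYZ file into a list of :class:`Frame`.

    An empty file yields an empty list. Atom counts must be constant
    across frames.
    """
    path = Path(path)
    frames: list[Frame] = []
    n_ref: Optional[int] = None
    for elements, coords, time_fs in _parse_xyz_blocks(path):
        if n_ref is None:
            n_ref = len(elements)
        elif len(elements) != n_ref:
            raise FormatError(
                f"{path}: frame {len(frames)} has {len(elements)} atoms, expected {n_ref}"
            )
        frames.append(Frame(elements, coords, box_edge, time_fs))
    return frames


def write_xyz_trajectory(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames as multi-frame XYZ (coordinates to 6 decimals)."""
    path = Path(path)
    with path.open("w") as fh:
        for k, fr in enumerate(frames):
            fh.write(f"{fr.n_atoms}\n")
            t = fr.time_fs if fr.time_fs is not None else float(k)
            fh.write(f" i = {k}, time = {t:.3f}\n")
            for el, (x, y, z) in zip(fr.elements, fr.positions):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_wannier_trajectory(path: str | Path) -> list[WannierFrame]:
    """Read Wannier centers stored as XYZ frames with element label 'X'."""
    path = Path(path)
    out: list[WannierFrame] = []
    for k, (elements, coords, _t) in enumerate(_parse_xyz_blocks(path)):
        mask = [e.upper().startswith("X") for e in elements]
        if not any(mask):
            raise FormatError(f"{path}: frame {k} contains no 'X' center records")
        out.append(WannierFrame(coords[np.array(mask)], frame_index=k))
    return out


def write_wannier_trajectory(wframes: Sequence[WannierFrame], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for wf in wframes:
            fh.write(f"{len(wf.centers)}\n")
            fh.write(f" i = {wf.frame_index}, Wannier centers\n")
            for x, y, z in wf.centers:
                fh.write(f"X  {x:14.6f} {y:14.6f} {z:14.6f}\n")


# --------------------------------------------------------------------------
# GRO / PDB via MDAnalysis
# --------------------------------------------------------------------------


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise FormatError(f"cannot infer element from atom name {name!r}")


def _frame_from_universe(u, source: str) -> Frame:
    if u.atoms.n_atoms == 0:
        raise FormatError(f"{source}: empty system (0 atoms)")
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise UnsupportedGeometryError(f"{source}: no box information")
    lx, ly, lz, alpha, beta, gamma = [float(v) for v in dims]
    if not (
        np.isclose(lx, ly, rtol=1e-5)
        and np.isclose(ly, lz, rtol=1e-5)
        and np.allclose([alpha, beta, gamma], 90.0, atol=1e-3)
    ):
        raise UnsupportedGeometryError(
            f"{source}: only cubic boxes are supported, got {dims[:6]}"
        )
    try:
        elements = [e.capitalize() for e in u.atoms.elements]
    except Exception:
        elements = [_element_from_name(n) for n in u.atoms.names]
    return Frame(elements, u.atoms.positions.astype(float), box_edge=lx)


def read_gro(path: str | Path) -> Frame:
    """Read a GRO configuration (nm converted to Å by MDAnalysis)."""
    import MDAnalysis as mda

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except UnsupportedGeometryError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: {exc}") from exc
    return _frame_from_universe(u, str(path))


def write_gro(frame: Frame, path: str | Path, names: Optional[Sequence[str]] = None) -> None:
    """Write a single-frame GRO file (Å converted back to nm)."""
    path = Path(path)
    names = list(names) if names is not None else frame.elements
    with path.open("w") as fh:
        fh.write("generated by sugarshell\n")
        fh.write(f"{frame.n_atoms:5d}\n")
        for i, (el, (x, y, z)) in enumerate(zip(names, frame.positions)):
            resid = i + 1
            fh.write(
                f"{resid % 100000:5d}{'MOL':<5s}{el[:5]:>5s}{(i + 1) % 100000:5d}"
                f"{x / 10:8.3f}{y / 10:8.3f}{z / 10:8.3f}\n"
            )
        b = frame.box_edge / 10.0
        fh.write(f"{b:10.5f}{b:10.5f}{b:10.5f}\n")


def read_pdb(path: str | Path) -> Frame:
    """Read a PDB configuration (ATOM/HETATM subset, read-only)."""
    import MDAnalysis as mda

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except UnsupportedGeometryError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: {exc}") from exc
    return _frame_from_universe(u, str(path))


# --------------------------------------------------------------------------
# Gaussian cube
# --------------------------------------------------------------------------


def read_cube(path: str | Path) -> DensityGrid:
    """Read a Gaussian cube file.

    Positive voxel counts mean Bohr axes (the convention used here);
    lengths are converted to Å and values rescaled from Bohr^-3 to Å^-3
    so the grid integral is unit-invariant. Negative voxel counts raise
    :class:`FormatError`.
    """
    path = Path(path)
    with path.open() as fh:
        fh.readline()
        fh.readline()
        natoms_line = fh.readline().split()
        natoms = int(natoms_line[0])
        origin = np.array([float(v) for v in natoms_line[1:4]])
        counts = np.empty(3, dtype=int)
        axes = np.empty((3, 3))
        for i in range(3):
            parts = fh.readline().split()
            counts[i] = int(parts[0])
            axes[i] = [float(v) for v in parts[1:4]]
        if np.any(counts < 0):
            raise FormatError(f"{path}: negative voxel counts are not supported")
        elements: list[str] = []
        apos = np.empty((abs(natoms), 3))
        charges = np.empty(abs(natoms))
        z_to_el = {v: k for k, v in ATOMIC_NUMBERS.items()}
        for i in range(abs(natoms)):
            parts = fh.readline().split()
            z = int(parts[0])
            elements.append(z_to_el.get(z, f"Z{z}"))
            charges[i] = float(parts[1])
            apos[i] = [float(v) for v in parts[2:5]]
        data = np.fromstring(fh.read(), sep=" ")
    nvox = int(np.prod(counts))
    if data.size != nvox:
        raise FormatError(f"{path}: expected {nvox} voxel values, found {data.size}")
    values = data.reshape(tuple(counts))
    a = BOHR_TO_ANGSTROM
    return DensityGrid(
        origin=origin * a,
        cell_vectors=axes * a,
        values=values / a**3,
        atom_positions=apos * a,
        atom_elements=elements,
        atom_charges=charges,
    )


def write_cube(grid: DensityGrid, path: str | Path, comment: str = "sugarshell grid") -> None:
    """Write a :class:`DensityGrid` as a Gaussian cube file (Bohr axes)."""
    path = Path(path)
    a = BOHR_TO_ANGSTROM
    counts = grid.shape
    with path.open("w") as fh:
        fh.write(f"{comment}\n")
        fh.write("values on a regular grid\n")
        o = grid.origin / a
        fh.write(f"{len(grid.atom_elements):5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        for n, vec in zip(counts, grid.cell_vectors):
            v = vec / a
            fh.write(f"{n:5d} {v[0]:12.6f} {v[1]:12.6f} {v[2]:12.6f}\n")
        q = grid.atom_charges
        for i, el in enumerate(grid.atom_elements):
            z = ATOMIC_NUMBERS.get(el, 0)
            charge = float(q[i]) if q is not None else float(z)
            p = grid.atom_positions[i] / a
            fh.write(f"{z:5d} {charge:12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")
        vals = (grid.values * a**3).reshape(counts[0] * counts[1], counts[2])
        for row in vals:
            for j in range(0, len(row), 6):
                fh.write("".join(f"{v:13.5E}" for v in row[j : j + 6]) + "\n")


# --------------------------------------------------------------------------
# Topology perception
# --------------------------------------------------------------------------

WATER_OH_CUTOFF = 1.2  # Å; separates covalent O-H (~1.0 Å) from H-bonds (>1.5 Å)
BOND_TOLERANCE = 1.2  # bonds: pairs within covalent-radius sum x 1.2


def _bond_graph(elements: Sequence[str], positions: np.ndarray, box_edge: Optional[float]) -> nx.Graph:
    """Covalent bond graph: pairs within covalent-radius sum x 1.2.

    H-H pairs never bond, and each H keeps only its nearest heavy-atom
    bond (a hydrogen has exactly one covalent partner).
    """
    g = nx.Graph()
    n = len(elements)
    for i, el in enumerate(elements):
        g.add_node(i, element=el)
    radii = np.array([COVALENT_RADII[e] for e in elements])
    dist = {}
    for i in range(n):
        if box_edge is not None:
            d = mi_distance(positions[i], positions[i + 1 :], box_edge)
        else:
            d = np.linalg.norm(positions[i + 1 :] - positions[i], axis=1)
        cut = (radii[i] + radii[i + 1 :]) * BOND_TOLERANCE
        for off in np.nonzero(d < cut)[0]:
            j = int(i + 1 + off)
            if elements[i] == "H" and elements[j] == "H":
                continue
            g.add_edge(i, j)
            dist[(i, j)] = float(d[off])
    for i in range(n):
        if elements[i] != "H":
            continue
        nbrs = list(g.neighbors(i))
        if len(nbrs) > 1:
            best = min(nbrs, key=lambda j: dist.get((min(i, j), max(i, j)), np.inf))
            for j in nbrs:
                if j != best:
                    g.remove_edge(i, j)
    return g


def perceive_topology(frame: Frame, solute_template: SugarTemplate) -> Topology:
    """Identify the solute's named sites and group remaining atoms into waters.

    The frame's bond graph (pairs within covalent-radius sum x 1.2, minimum
    image) is split into connected components; the unique component whose
    element multiset matches the template is the solute, and every other
    component must be a water (one O with exactly two H within 1.2 Å).
    Solute sites are labeled by graph isomorphism against the template's
    own bond graph.
    """
    g = _bond_graph(frame.elements, frame.positions, frame.box_edge)
    components = [sorted(c) for c in nx.connected_components(g)]

    def multiset(idx: Iterable[int]) -> tuple:
        return tuple(sorted(frame.elements[i] for i in idx))

    target = tuple(sorted(solute_template.elements))
    solute_comp: Optional[list[int]] = None
    if solute_template.n_atoms > 0:
        matches = [c for c in components if multiset(c) == target]
        if len(matches) == 0:
            raise PerceptionError("no connected component matches the solute template")
        if len(matches) > 1:
            raise PerceptionError(
                f"{len(matches)} components match the solute template (ambiguous)"
            )
        solute_comp = matches[0]

    waters: list[tuple[int, int, int]] = []
    solute_set = set(solute_comp or [])
    for comp in components:
        if solute_comp is not None and comp == solute_comp:
            continue
        elems = [frame.elements[i] for i in comp]
        o_atoms = [i for i in comp if frame.elements[i] == "O"]
        if len(o_atoms) != 1 or sorted(elems) != ["H", "H", "O"]:
            bad = o_atoms[0] if o_atoms else comp[0]
            raise PerceptionError(
                f"component {comp} is neither the solute nor a water "
                f"(offending atom index {bad})"
            )
        o = o_atoms[0]
        hs = sorted(i for i in comp if frame.elements[i] == "H")
        d = mi_distance(frame.positions[o], frame.positions[hs], frame.box_edge)
        if np.any(d >= WATER_OH_CUTOFF):
            raise PerceptionError(
                f"water O atom {o} does not have exactly 2 H within "
                f"{WATER_OH_CUTOFF} Å (distances {d})"
            )
        waters.append((o, hs[0], hs[1]))
    waters.sort()

    site_map: dict[str, int] = {}
    if solute_comp is not None:
        sub = g.subgraph(solute_comp)
        tg = _bond_graph(solute_template.elements, solute_template.positions, None)
        gm = nx.algorithms.isomorphism.GraphMatcher(
            tg,
            sub,
            node_match=lambda a, b: a["element"] == b["element"],
        )
        mapping = next(gm.isomorphisms_iter(), None)
        if mapping is None:
            raise PerceptionError(
                "solute matches the template composition but not its connectivity"
            )
        for t_idx in sorted(mapping):
            site_map[solute_template.site_names[t_idx]] = int(mapping[t_idx])
        # Canonicalize graph-equivalent hydrogens (e.g. the two C6 hydrogens):
        # assign their sorted site names to sorted frame indices so the map is
        # invariant under atom-order permutation of the input frame.
        for t_heavy in tg.nodes:
            h_children = [
                t
                for t in tg.neighbors(t_heavy)
                if solute_template.elements[t] == "H" and tg.degree[t] == 1
            ]
            if len(h_children) > 1:
                names = sorted(solute_template.site_names[t] for t in h_children)
                idxs = sorted(site_map[solute_template.site_names[t]] for t in h_children)
                for nm, ix in zip(names, idxs):
                    site_map[nm] = ix

    return Topology(
        solute_atoms=np.array(sorted(solute_set), dtype=int),
        site_map=site_map,
        waters=waters,
    )
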