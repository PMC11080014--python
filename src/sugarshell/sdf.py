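"""Spatial distribution functions in the molecule-fixed frame.

The molecule-fixed coordinate system follows the convention used for
sugar hydration maps: the origin is the solute center of mass (CM), the
XY plane contains C5, CM and C1, and +x is the bisector of the
C5-CM-C1 angle. z is along (CM->C5) x (CM->C1). Water oxygens are imaged
relative to the CM (minimum image), transformed into this frame, and
histogrammed on a cubic voxel grid; shell-resolved variants restrict the
binning to hydrophilic or hydrophobic waters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._geometry import ATOMIC_MASSES, minimum_image
from .io_formats import DensityGrid, Frame, Topology, write_cube
from .shells import ShellAssignment

__all__ = [
    "MolecularFrame",
    "SDFGrid",
    "PlanePartition",
    "BULK_WATER_DENSITY",
    "bulk_water_number_density",
    "molecular_frame",
    "accumulate_sdf",
    "plane_partition",
    "export_sdf_cube",
]

AVOGADRO = 6.02214076e23
WATER_MOLAR_MASS = 18.01528  # g/mol


def bulk_water_number_density(mass_density_g_cm3: float = 1.00) -> float:
    """Number density of bulk water in molecules/Å^3.

    At 1.00 g/cm^3 this evaluates to 0.0334, the standard reference used
    to express solvation densities relative to bulk.
    """
    return mass_density_g_cm3 / WATER_MOLAR_MASS * AVOGADRO * 1e-24


BULK_WATER_DENSITY = bulk_water_number_density()  # 0.03343 molecules/Å^3


@dataclass
class MolecularFrame:
    """Rigid map from lab coordinates to the molecule-fixed frame."""

    origin: np.ndarray  # (3,) Å, solute center of mass
    rotation: np.ndarray  # (3, 3), rows x/y/z-hat; r_mol = R @ (r_lab - origin)
    box_edge: float

    def transform(self, points: np.ndarray) -> np.ndarray:
        """Molecule-frame coordinates of lab points (minimum image to CM)."""
        rel = minimum_image(np.atleast_2d(points) - self.origin, self.box_edge)
        return rel @ self.rotation.T


@dataclass
class SDFGrid:
    """3D histogram of water-oxygen positions in the molecule-fixed frame."""

    counts: np.ndarray  # (n, n, n) raw counts
    voxel_edge: float  # Å
    extent: float  # Å; grid spans [-extent, extent] per axis
    n_frames: int
    shell_class: str  # 'hydrophilic' | 'hydrophobic' | 'all'

    @property
    def voxel_volume(self) -> float:
        return self.voxel_edge**3

    def density(self) -> np.ndarray:
        """Mean number density per voxel, molecules/Å^3."""
        return self.counts / (self.voxel_volume * self.n_frames)

    def relative_density(self) -> np.ndarray:
        """Density relative to bulk water (0.0334 molecules/Å^3)."""
        return self.density() / BULK_WATER_DENSITY

    def integral(self) -> float:
        """Integral of the mean density over the grid = mean population."""
        return float(self.density().sum() * self.voxel_volume)


@dataclass
class PlanePartition:
    """Mean counts of shell waters above/below the molecular XY plane."""

    above: dict[str, float]
    below: dict[str, float]
    n_frames: int
    above_series: dict[str, np.ndarray]
    below_series: dict[str, np.ndarray]


def _unwrap_solute(frame: Frame, topo: Topology) -> np.ndarray:
    """Solute coordinates made whole across the periodic boundary.

    The solute is compact (< half the box), so imaging every atom
    relative to the first solute atom reconnects it.
    """
    idx = topo.solute_atoms
    ref = frame.positions[idx[0]]
    return ref + minimum_image(frame.positions[idx] - ref, frame.box_edge)


def molecular_frame(
    frame: Frame,
    topo: Topology,
    masses: Optional[dict[str, float]] = None,
) -> MolecularFrame:
    """Molecule-fixed frame from the solute's C1, C5 and center of mass."""
    if "C1" not in topo.site_map or "C5" not in topo.site_map:
        raise ValueError("topology must name C1 and C5 solute sites")
    masses = masses or ATOMIC_MASSES
    idx = topo.solute_atoms
    pos = _unwrap_solute(frame, topo)
    m = np.array([masses[frame.elements[i]] for i in idx])
    cm = (pos * m[:, None]).sum(axis=0) / m.sum()
    local = {int(a): p for a, p in zip(idx, pos)}
    c1 = local[topo.site_map["C1"]]
    c5 = local[topo.site_map["C5"]]
    u5 = c5 - cm
    u1 = c1 - cm
    z = np.cross(u5, u1)
    nz = np.linalg.norm(z)
    if nz < 1e-8 * np.linalg.norm(u5) * np.linalg.norm(u1):
        raise ValueError("C1, C5 and the center of mass are collinear")
    z /= nz
    x = u5 / np.linalg.norm(u5) + u1 / np.linalg.norm(u1)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    rotation = np.vstack([x, y, z])
    return MolecularFrame(origin=cm, rotation=rotation, box_edge=frame.box_edge)


def _frame_water_mol_coords(
    frame: Frame, topo: Topology, mf: MolecularFrame
) -> np.ndarray:
    return mf.transform(frame.positions[topo.water_oxygens])


def _select_waters(
    n_waters: int, shell: Optional[ShellAssignment], shell_class: str
) -> np.ndarray:
    if shell_class == "all" or shell is None:
        if shell_class != "all" and shell is None:
            raise ValueError("shell assignments required for shell-resolved SDF")
        if shell_class == "all":
            return np.arange(n_waters)
    if shell_class == "hydrophilic":
        return np.array(sorted(shell.hydrophilic), dtype=int)
    if shell_class == "hydrophobic":
        return np.array(sorted(shell.hydrophobic), dtype=int)
    raise ValueError(f"unknown shell class {shell_class!r}")


def accumulate_sdf(
    traj: Sequence[Frame],
    topo: Topology,
    shell_class: str = "all",
    shells: Optional[Sequence[ShellAssignment]] = None,
    voxel_edge: float = 0.2,
    extent: float = 10.0,
) -> SDFGrid:
    """Accumulate the water-oxygen SDF over a trajectory.

    Waters outside ``[-extent, extent]`` on any molecule-frame axis fall
    outside the grid and are not counted.
    """
    if len(traj) == 0:
        raise ValueError("trajectory must contain at least one frame")
    if extent >= traj[0].box_edge / 2:
        raise ValueError("extent must be below half the box edge")
    n_bins = int(round(2 * extent / voxel_edge))
    edges = np.linspace(-extent, extent, n_bins + 1)
    counts = np.zeros((n_bins, n_bins, n_bins))
    for k, fr in enumerate(traj):
        mf = molecular_frame(fr, topo)
        coords = _frame_water_mol_coords(fr, topo, mf)
        sel = _select_waters(topo.n_waters, shells[k] if shells else None, shell_class)
        if sel.size == 0:
            continue
        h, _ = np.histogramdd(coords[sel], bins=(edges, edges, edges))
        counts += h
    return SDFGrid(
        counts=counts,
        voxel_edge=2 * extent / n_bins,
        extent=extent,
        n_frames=len(traj),
        shell_class=shell_class,
    )


def plane_partition(
    traj: Sequence[Frame],
    topo: Topology,
    shells: Sequence[ShellAssignment],
) -> PlanePartition:
    """Mean number of shell waters above (z >= 0) and below the XY plane."""
    classes = ("hydrophilic", "hydrophobic")
    above = {c: np.zeros(len(traj)) for c in classes}
    below = {c: np.zeros(len(traj)) for c in classes}
    for k, fr in enumerate(traj):
        mf = molecular_frame(fr, topo)
        coords = _frame_water_mol_coords(fr, topo, mf)
        for c in classes:
            sel = _select_waters(topo.n_waters, shells[k], c)
            if sel.size == 0:
                continue
            z = coords[sel, 2]
            above[c][k] = int(np.sum(z >= 0.0))  # z = 0 counts as above
            below[c][k] = int(np.sum(z < 0.0))
    return PlanePartition(
        above={c: float(v.mean()) for c, v in above.items()},
        below={c: float(v.mean()) for c, v in below.items()},
        n_frames=len(traj),
        above_series=above,
        below_series=below,
    )


def export_sdf_cube(
    grid: SDFGrid,
    topo: Topology,
    reference_frame: Frame,
    path: str | Path,
    normalization: str = "density",
) -> None:
    """Write the SDF as a Gaussian cube with the solute as atom records.

    The solute atoms are written in molecule-frame coordinates of
    ``reference_frame`` so a viewer shows the density around the sugar.
    """
    mf = molecular_frame(reference_frame, topo)
    solute_pos = mf.transform(reference_frame.positions[topo.solute_atoms])
    elements = [reference_frame.elements[i] for i in topo.solute_atoms]
    if normalization == "raw":
        values = grid.counts
    elif normalization == "density":
        values = grid.density()
    elif normalization == "relative":
        values = grid.relative_density()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    dg = DensityGrid(
        origin=np.array([-grid.extent] * 3),
        cell_vectors=np.eye(3) * grid.voxel_edge,
        values=values,
        atom_positions=solute_pos,
        atom_elements=elements,
    )
    write_cube(dg, path, comment=f"sugarshell SDF ({grid.shell_class}, {normalization})")
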