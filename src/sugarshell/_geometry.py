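"""Periodic-boundary helpers shared across the package.

All lengths are in Å; boxes are cubic. The minimum image convention is
applied with ``round``, so it is valid for arbitrary (unwrapped) input
coordinates, not only for coordinates already inside the primary cell.
"""

from __future__ import annotations

import numpy as np

# Standard atomic masses (amu) for the elements this pipeline encounters.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}

# Covalent radii (Å, Cordero-style) used for bond perception.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
}

ATOMIC_NUMBERS: dict[str, int] = {"H": 1, "C": 6, "N": 7, "O": 8}

BOHR_TO_ANGSTROM = 0.529177


def minimum_image(vec: np.ndarray, box_edge: float) -> np.ndarray:
    """Return the minimum-image representation of displacement vector(s)."""
    vec = np.asarray(vec, dtype=float)
    return vec - box_edge * np.round(vec / box_edge)


def mi_distance(a: np.ndarray, b: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image distance(s) between points ``a`` and ``b``."""
    d = minimum_image(np.asarray(b) - np.asarray(a), box_edge)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(positions: np.ndarray, box_edge: float) -> np.ndarray:
    """Wrap coordinates into [0, box_edge) on every axis."""
    return np.mod(positions, box_edge)


def angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two vectors in degrees, robust at 0 and 180."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Vectorized pairwise angle (deg) between matching rows of v1 and v2."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    num = np.einsum("ij,ij->i", v1, v2)
    den = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    return np.degrees(np.arccos(np.clip(num / den, -1.0, 1.0)))


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random proper rotation (QR-based, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_rad``."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle_rad) * k + (1.0 - np.cos(angle_rad)) * (k @ k)
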