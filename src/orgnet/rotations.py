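"""Rotation sampling for augmentation and the orientation-bias scan.

Two rotation families are used:

* augmentation — (axis, angle) pairs drawn from a deterministic equal-area
  axis grid on the sphere (Fibonacci lattice) crossed with the 72-angle set
  {0, π/36, …, 2π − π/36}; ten random draws per structure by default;
* bias scan — the 10 non-polar vertices of a canonical icosahedron (the two
  pentagonal rings; the 12 vertices form 6 antipodal pairs, so 10 distinct
  non-polar axes) crossed with the 12 angles {0, π/6, …, 11π/6}, giving 120
  fixed orientations used to probe a model for orientation bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Structure

__all__ = [
    "RotationSet",
    "rotation_matrix",
    "uniform_axes",
    "icosahedron_axes",
    "bias_scan_rotations",
    "augmentation_orientations",
    "bias_scan_orientations",
    "rotate_structure",
]

AUGMENTATION_ANGLE_STEP = np.pi / 36  # 72 angles in [0, 2π)
BIAS_SCAN_ANGLE_STEP = np.pi / 6  # 12 angles in [0, 2π)
DEFAULT_AXIS_GRID = 100  # axis-grid size for augmentation sampling
DEFAULT_N_AUGMENT = 10


@dataclass(frozen=True)
class RotationSet:
    """Axes, angles and the corresponding rotation matrices."""

    axes: np.ndarray  # (M, 3) unit vectors
    angles: np.ndarray  # (M,) radians
    matrices: np.ndarray  # (M, 3, 3)

    def __len__(self) -> int:
        return len(self.matrices)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError(f"rotation axis must be unit length, |axis| = {norm:.3e}")
    return Rotation.from_rotvec(axis * angle).as_matrix()


def uniform_axes(n: int) -> np.ndarray:
    """`n` near-uniformly distributed unit axes (Fibonacci sphere lattice)."""
    if n < 1:
        raise ValueError("need at least one axis")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    axes = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return axes / np.linalg.norm(axes, axis=1, keepdims=True)


def icosahedron_axes() -> np.ndarray:
    """The 10 non-polar vertices of a canonical icosahedron as unit axes.

    The icosahedron is oriented with one vertex at each pole; the poles are
    dropped and the two 5-vertex rings at z = ±1/√5 are kept.
    """
    axes = []
    for k in range(5):
        phi = 2.0 * np.pi * k / 5.0
        axes.append([np.cos(phi) * 2 / np.sqrt(5), np.sin(phi) * 2 / np.sqrt(5), 1 / np.sqrt(5)])
    for k in range(5):
        phi = 2.0 * np.pi * k / 5.0 + np.pi / 5.0
        axes.append([np.cos(phi) * 2 / np.sqrt(5), np.sin(phi) * 2 / np.sqrt(5), -1 / np.sqrt(5)])
    axes = np.array(axes)
    return axes / np.linalg.norm(axes, axis=1, keepdims=True)


def bias_scan_rotations() -> RotationSet:
    """The fixed 10 axes × 12 angles = 120 bias-scan rotations."""
    axes = icosahedron_axes()
    angles = np.arange(12) * BIAS_SCAN_ANGLE_STEP
    all_axes = np.repeat(axes, len(angles), axis=0)
    all_angles = np.tile(angles, len(axes))
    mats = np.stack(
        [rotation_matrix(a, t) for a, t in zip(all_axes, all_angles)]
    )
    return RotationSet(axes=all_axes, angles=all_angles, matrices=mats)


def rotate_structure(
    structure: Structure, matrix: np.ndarray, center: np.ndarray | None = None
) -> Structure:
    """Rotate a structure about `center` (default: its centroid)."""
    coords = structure.coords()
    if center is None:
        center = coords.mean(axis=0)
    rotated = (coords - center) @ np.asarray(matrix).T
    return structure.with_coords(rotated)


def augmentation_orientations(
    structure: Structure,
    n: int = DEFAULT_N_AUGMENT,
    seed: int = 0,
    axis_grid: int = DEFAULT_AXIS_GRID,
) -> list[Structure]:
    """`n` random orientations for dataset augmentation.

    Coordinates are centered at the all-atom centroid, then rotated by
    matrices built from (axis, angle) pairs sampled uniformly (seeded) from
    the Fibonacci axis grid and the 72-angle set {0, π/36, …, 2π − π/36}.
    """
    if n < 1:
        raise ValueError("need at least one orientation")
    rng = np.random.default_rng(seed)
    axes = uniform_axes(axis_grid)
    angles = np.arange(72) * AUGMENTATION_ANGLE_STEP
    out = []
    for i in range(n):
        axis = axes[rng.integers(len(axes))]
        angle = angles[rng.integers(len(angles))]
        mat = rotation_matrix(axis, float(angle))
        rotated = rotate_structure(structure, mat)
        out.append(
            structure.with_coords(rotated.coords(), id=f"{structure.id}_rot{i}")
        )
    return out


def bias_scan_orientations(structure: Structure) -> list[Structure]:
    """The 120 centered bias-scan orientations of a structure."""
    if not structure.atoms:
        raise ValueError("empty structure")
    rotset = bias_scan_rotations()
    out = []
    for i, mat in enumerate(rotset.matrices):
        rotated = rotate_structure(structure, mat)
        out.append(
            structure.with_coords(rotated.coords(), id=f"{structure.id}_scan{i:03d}")
        )
    return out
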