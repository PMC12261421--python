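"""Standardized residue coordinate frames.

A 3D CNN on voxelized structures is not SE(3)-invariant: rotating the input
protein changes the prediction.  The fix implemented here transforms every
structure into a canonical frame built from the mutated residue's backbone
before voxelization, so any rigid motion of the input yields identical grids.

Frame definition for residue k with preceding residue k−1 in the same chain:

* x — unit vector from C(k−1) to N(k),
* y — the component of N(k)→Cα(k) orthogonal to x (so Cα(k) lies in the
  half-plane y > 0, z ≈ 0),
* z — x × y (right-handed),
* origin — N(k); it is the one point shared by all three defining elements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import DegenerateGeometryError, Structure

__all__ = ["Frame", "FrameUndefinedError", "compute_frame", "standardize"]

_DEGENERACY_ANGLE = 1e-6  # rad; below this, y is numerically undefined


class FrameUndefinedError(ValueError):
    """Raised when the residue frame cannot be constructed (e.g. chain start)."""


@dataclass(frozen=True)
class Frame:
    """Origin plus a right-handed orthonormal basis (rows are x, y, z)."""

    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        basis = np.asarray(self.basis, dtype=float)
        if origin.shape != (3,) or basis.shape != (3, 3):
            raise ValueError("Frame needs a 3-vector origin and a 3x3 basis")
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-9):
            raise ValueError("Frame basis is not orthonormal")
        if np.linalg.det(basis) < 0:
            raise ValueError("Frame basis is left-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "basis", basis)

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        """Map world coordinates into this frame."""
        return (np.asarray(coords, dtype=float) - self.origin) @ self.basis.T

    @staticmethod
    def identity() -> "Frame":
        return Frame(origin=np.zeros(3), basis=np.eye(3))


def compute_frame(structure: Structure, chain: str, position: int) -> Frame:
    """Canonical frame of residue `position` in `chain`.

    Requires N and CA on the residue and C on the sequentially preceding
    residue of the same chain; a chain-start site therefore has no frame.
    """
    residue = structure.residue(chain, position)
    prev = structure.preceding_residue(chain, position)
    if prev is None or not prev.has("C"):
        raise FrameUndefinedError(
            f"{structure.id}: residue {chain}/{position} has no preceding residue "
            "with a C atom; the frame is undefined at chain starts"
        )
    for name in ("N", "CA"):
        if not residue.has(name):
            raise FrameUndefinedError(
                f"{structure.id}: residue {chain}/{position} lacks backbone atom {name}"
            )
    c_prev = prev.atom("C").coords
    n_k = residue.atom("N").coords
    ca_k = residue.atom("CA").coords

    x = n_k - c_prev
    norm_x = np.linalg.norm(x)
    if norm_x < 1e-8:
        raise DegenerateGeometryError("C(k-1) and N(k) coincide")
    x = x / norm_x

    v = ca_k - n_k
    norm_v = np.linalg.norm(v)
    if norm_v < 1e-8:
        raise DegenerateGeometryError("N(k) and CA(k) coincide")
    # angle between N→CA and x; parallel vectors leave y undefined
    sin_angle = np.linalg.norm(np.cross(x, v / norm_v))
    if sin_angle < _DEGENERACY_ANGLE:
        raise DegenerateGeometryError(
            "N->CA vector is parallel to the x axis; y is undefined"
        )
    y = v - (v @ x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    return Frame(origin=n_k, basis=np.vstack([x, y, z]))


def standardize(structure: Structure, frame: Frame) -> Structure:
    """Rigidly transform `structure` into `frame` (coords ↦ B·(coords − o)).

    Recomputing the frame on the result yields the identity frame at the
    origin, so the operation is idempotent and removes any input rigid motion.
    """
    return structure.with_coords(frame.to_local(structure.coords()))
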