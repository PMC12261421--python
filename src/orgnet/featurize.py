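"""Voxel-grid featurization of a point-mutation site.

A mutation is represented by two 16×16×16×7 voxel grids — one for the
wild-type structure, one for the pre-modeled mutant — centered at the
wild-type Cβ of the mutated residue and computed in the standardized
orientation, then stacked channel-wise as [WT, MT], [WT, WT−MT] or [WT−MT].

Each channel holds, at every voxel center v, the maximum over the channel's
atoms of a smooth van-der-Waals occupancy 1 − exp(−(r/d)^12), where d is the
atom–voxel distance and r the atom's vdW radius.  Values therefore live in
[0, 1] and decay steeply outside the vdW sphere.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .chemdata import CHANNEL_NAMES, atom_flags, vdw_radius
from .orientation import Frame, compute_frame, standardize
from .structures import Atom, MutationRecord, Structure, virtual_cbeta

__all__ = [
    "GRID_SIZE",
    "DEFAULT_SPACING",
    "AtomProperties",
    "VoxelGrid",
    "Representation",
    "assign_properties",
    "occupancy_value",
    "voxelize",
    "build_representation",
    "reverse_representation",
    "featurize_mutation",
    "FeaturizationError",
    "save_representations",
    "load_representations",
]

GRID_SIZE = 16
DEFAULT_SPACING = 1.0  # Å per voxel → a 16 Å cube around the mutation site

MODES = ("wt_mt", "wt_diff", "diff")


class FeaturizationError(ValueError):
    """Raised when a mutation cannot be featurized (e.g. chain-start site)."""


@dataclass(frozen=True)
class AtomProperties:
    """Seven channel flags plus the vdW radius of one heavy atom."""

    flags: tuple[bool, ...]
    vdw_radius: float

    def flag(self, channel: str) -> bool:
        return self.flags[CHANNEL_NAMES.index(channel)]


def assign_properties(atom: Atom, residue_name: str | None = None) -> AtomProperties:
    """Look up the channel flags and vdW radius for one atom.

    The lookup is a frozen rule table; unknown residue/atom names raise with
    the offending name rather than guessing.
    """
    res = residue_name if residue_name is not None else atom.residue_name
    flags = atom_flags(res, atom.name)
    return AtomProperties(
        flags=tuple(name in flags for name in CHANNEL_NAMES),
        vdw_radius=vdw_radius(atom.element),
    )


def occupancy_value(distance, vdw_radius):
    """Smooth vdW occupancy 1 − exp(−(r/d)^12); the d→0 limit is 1.

    Accepts scalars or arrays; strictly decreasing in distance for d > 0.
    """
    distance = np.asarray(distance, dtype=float)
    out = np.empty_like(distance)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(distance > 0, vdw_radius / np.maximum(distance, 1e-300), np.inf)
        out = -np.expm1(-(ratio**12))
    out = np.where(distance <= 0, 1.0, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class VoxelGrid:
    """A 16×16×16×C channel grid with its geometry."""

    values: np.ndarray
    spacing: float
    center: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 4 or values.shape[:3] != (GRID_SIZE,) * 3:
            raise ValueError(f"grid must be {GRID_SIZE}^3 x C, got {values.shape}")
        if values.shape[3] != len(self.channel_names):
            raise ValueError("channel count does not match channel_names")
        if np.any(values < 0) or np.any(values > 1):
            raise ValueError("grid values must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.spacing == other.spacing
            and np.allclose(self.center, other.center, atol=1e-9)
            and self.channel_names == other.channel_names
        )


def _voxel_centers(center: np.ndarray, spacing: float) -> np.ndarray:
    offsets = (np.arange(GRID_SIZE) - (GRID_SIZE - 1) / 2.0) * spacing
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    return pts + np.asarray(center, dtype=float)


def voxelize(
    structure: Structure,
    center: np.ndarray,
    spacing: float = DEFAULT_SPACING,
) -> VoxelGrid:
    """Compute the 7-channel voxel grid of `structure` around `center`.

    Heavy atoms only; hydrogens (donor information is already encoded in the
    rule table) are skipped.  Grid axes are the coordinate axes of the input,
    i.e. the standardized basis when the caller standardized first.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise ValueError("grid center must be a finite 3-vector")
    heavy = [a for a in structure.atoms if a.element.upper() != "H"]
    n_channels = len(CHANNEL_NAMES)
    values = np.zeros((GRID_SIZE,) * 3 + (n_channels,))
    if not heavy:
        return VoxelGrid(values, spacing, center, CHANNEL_NAMES)
    props = [assign_properties(a) for a in heavy]
    flags = np.array([p.flags for p in props], dtype=bool)  # (N, 7)
    radii = np.array([p.vdw_radius for p in props])
    coords = np.array([a.coords for a in heavy])
    pts = _voxel_centers(center, spacing)  # (V, 3)
    dists = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)  # (V, N)
    occ = occupancy_value(dists, radii[None, :])
    flat = np.zeros((pts.shape[0], n_channels))
    for c in range(n_channels):
        mask = flags[:, c]
        if mask.any():
            flat[:, c] = occ[:, mask].max(axis=1)
    values = flat.reshape((GRID_SIZE,) * 3 + (n_channels,))
    return VoxelGrid(values, spacing, center, CHANNEL_NAMES)


@dataclass(frozen=True)
class Representation:
    """Stacked WT/MT tensor fed to the network: (16, 16, 16, C) channel-last."""

    tensor: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        tensor = np.asarray(self.tensor, dtype=float)
        expected = 7 if self.mode == "diff" else 14
        if tensor.shape != (GRID_SIZE,) * 3 + (expected,):
            raise ValueError(
                f"mode {self.mode!r} expects shape {(GRID_SIZE,)*3 + (expected,)}, "
                f"got {tensor.shape}"
            )
        object.__setattr__(self, "tensor", tensor)

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[3]


def build_representation(wt: VoxelGrid, mt: VoxelGrid, mode: str) -> Representation:
    """Stack WT and MT grids channel-wise: [WT, MT], [WT, WT−MT] or [WT−MT].

    Difference blocks are raw subtractions (values in [−1, 1], no rescaling).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not wt.same_geometry(mt):
        raise ValueError("WT and MT grids have different geometry")
    if mode == "wt_mt":
        tensor = np.concatenate([wt.values, mt.values], axis=3)
    elif mode == "wt_diff":
        tensor = np.concatenate([wt.values, wt.values - mt.values], axis=3)
    else:
        tensor = wt.values - mt.values
    return Representation(tensor=tensor, mode=mode)


def reverse_representation(
    wt: VoxelGrid, mt: VoxelGrid, ddg: float, mode: str
) -> tuple[Representation, float]:
    """The formally inverted mutation: grid roles swapped, label negated."""
    return build_representation(mt, wt, mode), -ddg


def featurize_mutation(
    wt_structure: Structure,
    mt_structure: Structure,
    record: MutationRecord,
    mode: str = "wt_diff",
    spacing: float = DEFAULT_SPACING,
    orient: bool = True,
) -> Representation:
    """Full featurization of one mutation: standardize, voxelize, stack.

    The frame is computed on the wild-type structure and applied to BOTH
    structures, and both grids are centered at the wild-type Cβ (virtual Cβ
    for glycine), so the two grids are spatially aligned.  With ``orient=False``
    (diagnostic ablation) structures are voxelized in their input orientation
    and the result is NOT invariant to input rotations.
    """
    from .orientation import FrameUndefinedError
    from .structures import DegenerateGeometryError

    if orient:
        try:
            frame = compute_frame(wt_structure, record.chain_id, record.position)
        except (FrameUndefinedError, DegenerateGeometryError, KeyError) as exc:
            raise FeaturizationError(
                f"cannot featurize {record.structure_id} "
                f"{record.wt_aa}{record.position}{record.mt_aa}: {exc}"
            ) from exc
        wt_oriented = standardize(wt_structure, frame)
        mt_oriented = standardize(mt_structure, frame)
    else:
        wt_oriented = wt_structure
        mt_oriented = mt_structure

    residue = wt_oriented.residue(record.chain_id, record.position)
    if residue.has("CB"):
        center = residue.atom("CB").coords
    else:
        try:
            center = virtual_cbeta(
                residue.atom("N").coords,
                residue.atom("CA").coords,
                residue.atom("C").coords,
            )
        except (KeyError, DegenerateGeometryError) as exc:
            raise FeaturizationError(
                f"cannot place grid center for {record.structure_id} "
                f"{record.chain_id}/{record.position}: {exc}"
            ) from exc
    wt_grid = voxelize(wt_oriented, center, spacing)
    mt_grid = voxelize(mt_oriented, center, spacing)
    return build_representation(wt_grid, mt_grid, mode)


def save_representations(
    path: str | Path,
    representations: list[Representation],
    labels: np.ndarray,
    records: list[MutationRecord] | None = None,
) -> None:
    """Write representations to an HDF5 container (grids, labels, meta)."""
    if not representations:
        raise ValueError("nothing to save")
    mode = representations[0].mode
    if any(r.mode != mode for r in representations):
        raise ValueError("mixed representation modes")
    grids = np.stack([r.tensor for r in representations]).astype(np.float32)
    labels = np.asarray(labels, dtype=np.float32)
    if labels.shape != (len(representations),):
        raise ValueError("one label per representation required")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("grids", data=grids, compression="gzip")
        fh.create_dataset("labels", data=labels)
        fh.attrs["mode"] = mode
        if records is not None:
            meta = pd.DataFrame(
                {
                    "structure_id": [r.structure_id for r in records],
                    "chain": [r.chain_id for r in records],
                    "position": [r.position for r in records],
                    "wt": [r.wt_aa for r in records],
                    "mt": [r.mt_aa for r in records],
                    "ddg": [r.ddg for r in records],
                    "is_reverse": [r.is_reverse for r in records],
                }
            )
            for col in ("structure_id", "chain", "wt", "mt"):
                meta[col] = meta[col].astype("S32")
            rec = meta.to_records(index=False)
            fh.create_dataset("meta", data=np.array(rec, dtype=rec.dtype))


def load_representations(
    path: str | Path,
) -> tuple[list[Representation], np.ndarray, pd.DataFrame | None]:
    with h5py.File(path, "r") as fh:
        mode = fh.attrs["mode"]
        grids = fh["grids"][...]
        labels = fh["labels"][...]
        meta = None
        if "meta" in fh:
            meta = pd.DataFrame.from_records(fh["meta"][...])
            for col in ("structure_id", "chain", "wt", "mt"):
                meta[col] = meta[col].str.decode("utf-8")
    reps = [Representation(tensor=g.astype(float), mode=str(mode)) for g in grids]
    return reps, labels.astype(float), meta
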