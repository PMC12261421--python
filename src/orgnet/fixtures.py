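"""Ideal-geometry peptides and synthetic labeled mutation datasets.

Everything downstream (frames, voxel grids, training) is testable offline on
peptides built from standard internal coordinates: N–Cα 1.458 Å, Cα–C
1.525 Å, C–N 1.329 Å, planar trans peptide bonds (ω = 180°), and the given
per-residue φ/ψ.  Side chains are stubs — Cβ placed with L-chirality plus at
most one representative property-bearing atom per residue type — enough to
exercise every physicochemical channel without a rotamer library.

The synthetic dataset couples labels to structure by construction: each label
is w·s + ε, where s is the signed sum of the WT−MT voxel difference grid of
the (standardized) mutation representation, w a fixed scale putting labels on
a realistic ΔΔG range of a few kcal/mol, and ε seeded Gaussian noise with
σ = 0.1 kcal/mol.  Labels are therefore learnable from the representations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chemdata import CHANNEL_NAMES
from .featurize import DEFAULT_SPACING, VoxelGrid, featurize_mutation, voxelize
from .orientation import compute_frame, standardize
from .structures import (
    AA1_TO_AA3,
    Atom,
    MutationRecord,
    Structure,
    virtual_cbeta,
    write_mutation_table,
    write_pdb,
)

__all__ = [
    "PeptideSpec",
    "SyntheticDataset",
    "build_peptide",
    "make_synthetic_dataset",
    "featurize_dataset",
    "write_fixture_dir",
]

# backbone internal coordinates (Å, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5
_OMEGA = 180.0
# Cβ: 1.521 Å, equal N-Cα-Cβ / C-Cα-Cβ angles of 110.5°; the improper torsion
# N-C-Cα-Cβ = +123.096° reproduces those angles with L-chirality.
_BOND_CA_CB = 1.521
_ANGLE_C_CA_CB = 110.5
_TORSION_N_C_CA_CB = 123.096

# one property-bearing stub atom per residue type (name → placed beyond Cβ)
_STUB_ATOMS: dict[str, str | None] = {
    "ALA": None, "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "GLY": None, "HIS": "ND1", "ILE": "CD1",
    "LEU": "CD1", "LYS": "NZ", "MET": "SD", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "NE1", "TYR": "OH", "VAL": "CG1",
}


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """NeRF placement: point d with |cd| = bond, ∠(b,c,d) = angle, dihedral
    (a,b,c,d) = torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


@dataclass(frozen=True)
class PeptideSpec:
    """Sequence plus per-residue backbone dihedrals."""

    sequence: str
    phi: tuple[float, ...]  # degrees, one per residue (phi of residue 1 unused)
    psi: tuple[float, ...]
    chain_id: str = "A"
    start_index: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("need at least two residues (frames need a predecessor)")
        bad = [c for c in self.sequence if c not in AA1_TO_AA3]
        if bad:
            raise ValueError(f"unknown residue code(s) {bad}")
        if len(self.phi) != len(self.sequence) or len(self.psi) != len(self.sequence):
            raise ValueError("phi/psi must have one entry per residue")

    @staticmethod
    def regular(sequence: str, phi: float = -57.0, psi: float = -47.0, **kw) -> "PeptideSpec":
        n = len(sequence)
        return PeptideSpec(sequence, (phi,) * n, (psi,) * n, **kw)


def build_peptide(spec: PeptideSpec, structure_id: str = "peptide") -> Structure:
    """Build an all-heavy-atom peptide from ideal internal coordinates."""
    seq3 = [AA1_TO_AA3[c] for c in spec.sequence]
    backbone: list[dict[str, np.ndarray]] = []
    for i in range(len(seq3)):
        if i == 0:
            n = np.zeros(3)
            ca = n + np.array([_BOND_N_CA, 0.0, 0.0])
            ang = math.radians(_ANGLE_N_CA_C)
            c = ca + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
        else:
            prev = backbone[i - 1]
            n = _place_atom(
                prev["N"], prev["CA"], prev["C"],
                _BOND_C_N, _ANGLE_CA_C_N, spec.psi[i - 1],
            )
            ca = _place_atom(
                prev["CA"], prev["C"], n, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA
            )
            c = _place_atom(prev["C"], n, ca, _BOND_CA_C, _ANGLE_N_CA_C, spec.phi[i])
        backbone.append({"N": n, "CA": ca, "C": c})

    atoms: list[Atom] = []
    for i, resname in enumerate(seq3):
        idx = spec.start_index + i
        bb = backbone[i]
        if i + 1 < len(seq3):
            psi_for_o = spec.psi[i]
        else:
            psi_for_o = spec.psi[i]  # last residue: use its nominal ψ
        o = _place_atom(
            bb["N"], bb["CA"], bb["C"], _BOND_C_O, _ANGLE_CA_C_O, psi_for_o + 180.0
        )

        def add(name: str, element: str, coords: np.ndarray) -> None:
            atoms.append(
                Atom(
                    name=name, element=element, coords=coords,
                    residue_index=idx, residue_name=resname,
                    chain_id=spec.chain_id,
                )
            )

        add("N", "N", bb["N"])
        add("CA", "C", bb["CA"])
        add("C", "C", bb["C"])
        add("O", "O", o)
        if resname != "GLY":
            cb = _place_atom(
                bb["N"], bb["C"], bb["CA"],
                _BOND_CA_CB, _ANGLE_C_CA_CB, _TORSION_N_C_CA_CB,
            )
            add("CB", "C", cb)
            stub = _STUB_ATOMS[resname]
            if stub is not None:
                pos = _place_atom(bb["N"], bb["CA"], cb, 1.52, 114.0, -60.0)
                add(stub, stub[0], pos)
    return Structure(id=structure_id, atoms=atoms)


# label = _LABEL_SCALE · (signed sum of the WT−MT difference grid) + ε;
# the scale puts labels on a realistic ΔΔG spread (sd ≈ 1.6 kcal/mol)
_LABEL_SCALE = 0.04
_LABEL_NOISE_SD = 0.1  # kcal/mol

_PHI_PSI_BASKETS = ((-57.0, -47.0), (-120.0, 120.0), (-75.0, 145.0))
_AA_CODES = "ARNDCQEGHILKMFPSTWYV"


@dataclass
class SyntheticDataset:
    """Labeled WT/MT structure pairs with a synthetic identity matrix."""

    records: list[MutationRecord]
    wt_structures: dict[str, Structure]
    mt_structures: dict[str, Structure]
    identity: pd.DataFrame
    seed: int
    summary: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.records)


def _difference_summary(wt_grid: VoxelGrid, mt_grid: VoxelGrid) -> float:
    return float(np.sum(wt_grid.values - mt_grid.values))


def make_synthetic_dataset(
    n: int, seed: int = 0, length: int = 7, spacing: float = DEFAULT_SPACING
) -> SyntheticDataset:
    """`n` featurizable WT/MT peptide pairs with learnable ΔΔG labels.

    Mutation sites sit mid-chain (never at a chain start), so every record
    has a defined residue frame.  The identity matrix groups proteins into
    synthetic homology clusters of about three members with within-cluster
    identities of 30–60% and background identities of 5–15%.
    """
    if n < 2:
        raise ValueError("need at least two records")
    rng = np.random.default_rng(seed)
    records: list[MutationRecord] = []
    wt_structures: dict[str, Structure] = {}
    mt_structures: dict[str, Structure] = {}
    summaries: list[float] = []
    site = 1 + length // 2  # start_index 1 → mid-chain position
    for i in range(n):
        sid = f"synth{i:03d}"
        seq = "".join(rng.choice(list(_AA_CODES), size=length))
        base_phi, base_psi = _PHI_PSI_BASKETS[int(rng.integers(len(_PHI_PSI_BASKETS)))]
        phi = tuple(base_phi + rng.uniform(-8, 8) for _ in range(length))
        psi = tuple(base_psi + rng.uniform(-8, 8) for _ in range(length))
        wt_aa = seq[site - 1]
        mt_aa = str(rng.choice([c for c in _AA_CODES if c != wt_aa]))
        mt_seq = seq[: site - 1] + mt_aa + seq[site:]
        wt = build_peptide(PeptideSpec(seq, phi, psi), structure_id=sid)
        mt = build_peptide(PeptideSpec(mt_seq, phi, psi), structure_id=f"{sid}_mt")
        record = MutationRecord(
            structure_id=sid, chain_id="A", position=site,
            wt_aa=wt_aa, mt_aa=mt_aa, ddg=0.0,
        )
        wt_grid, mt_grid = _grid_pair(wt, mt, record, spacing)
        s = _difference_summary(wt_grid, mt_grid)
        label = _LABEL_SCALE * s + rng.normal(0.0, _LABEL_NOISE_SD)
        records.append(
            MutationRecord(
                structure_id=sid, chain_id="A", position=site,
                wt_aa=wt_aa, mt_aa=mt_aa, ddg=float(label),
            )
        )
        wt_structures[sid] = wt
        mt_structures[sid] = mt
        summaries.append(s)

    ids = [r.structure_id for r in records]
    cluster_of = {sid: i // 3 for i, sid in enumerate(ids)}
    mat = rng.uniform(5.0, 15.0, size=(n, n))
    mat = (mat + mat.T) / 2.0
    for i in range(n):
        for j in range(i + 1, n):
            if cluster_of[ids[i]] == cluster_of[ids[j]]:
                v = rng.uniform(30.0, 60.0)
                mat[i, j] = mat[j, i] = v
    np.fill_diagonal(mat, 100.0)
    identity = pd.DataFrame(mat, index=ids, columns=ids)
    return SyntheticDataset(
        records=records,
        wt_structures=wt_structures,
        mt_structures=mt_structures,
        identity=identity,
        seed=seed,
        summary=np.array(summaries),
    )


def _grid_pair(
    wt: Structure, mt: Structure, record: MutationRecord, spacing: float
) -> tuple[VoxelGrid, VoxelGrid]:
    frame = compute_frame(wt, record.chain_id, record.position)
    wt_std = standardize(wt, frame)
    mt_std = standardize(mt, frame)
    residue = wt_std.residue(record.chain_id, record.position)
    if residue.has("CB"):
        center = residue.atom("CB").coords
    else:
        center = virtual_cbeta(
            residue.atom("N").coords,
            residue.atom("CA").coords,
            residue.atom("C").coords,
        )
    return voxelize(wt_std, center, spacing), voxelize(mt_std, center, spacing)


def featurize_dataset(
    dataset: SyntheticDataset, spacing: float = DEFAULT_SPACING
) -> list[tuple[VoxelGrid, VoxelGrid]]:
    """Standardized WT/MT grid pairs for every record (for assemble_dataset)."""
    out = []
    for record in dataset.records:
        wt = dataset.wt_structures[record.structure_id]
        mt = dataset.mt_structures[record.structure_id]
        out.append(_grid_pair(wt, mt, record, spacing))
    return out


def write_fixture_dir(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write PDBs, mutations.csv and identity.csv for CLI/offline use."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, st in dataset.wt_structures.items():
        write_pdb(st, out_dir / f"{sid}_wt.pdb")
    for sid, st in dataset.mt_structures.items():
        write_pdb(st, out_dir / f"{sid}_mt.pdb")
    write_mutation_table(dataset.records, out_dir / "mutations.csv")
    dataset.identity.to_csv(out_dir / "identity.csv")
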