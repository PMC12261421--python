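"""Protein structure I/O and mutation bookkeeping.

Structures are read from and written to PDB files through gemmi, then held in a
flat, ordered atom list that the orientation/featurization pipeline can
transform with plain numpy.  Only the information the pipeline needs is kept:
atom name, element, Cartesian coordinates (Å), and residue/chain identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "MutationRecord",
    "PDBParseError",
    "PDBFormatError",
    "DegenerateGeometryError",
    "read_pdb",
    "write_pdb",
    "virtual_cbeta",
    "read_mutation_table",
    "write_mutation_table",
]

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA1_TO_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed (message cites the line)."""


class PDBFormatError(ValueError):
    """Raised when a structure cannot be expressed in fixed-column PDB."""


class DegenerateGeometryError(ValueError):
    """Raised when points are collinear/coincident where a frame is needed."""


@dataclass(frozen=True)
class Atom:
    """One atom: PDB-convention name, element symbol, coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    residue_index: int
    residue_name: str
    chain_id: str

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass(frozen=True)
class Residue:
    """Ordered view of one residue's atoms."""

    name: str
    index: int
    chain_id: str
    atoms: tuple[Atom, ...]

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(
            f"residue {self.chain_id}/{self.name}{self.index} has no atom {name!r}"
        )

    def has(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """An ordered collection of atoms with a stable residue ordering."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array (copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """A new Structure with the same atoms at replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coords of shape ({len(self.atoms)}, 3)")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(id=id if id is not None else self.id, atoms=atoms)

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        """Residues in file order, optionally restricted to one chain."""
        current: list[Atom] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            if current and (
                a.chain_id != current[0].chain_id
                or a.residue_index != current[0].residue_index
            ):
                yield self._pack(current)
                current = []
            current.append(a)
        if current:
            yield self._pack(current)

    @staticmethod
    def _pack(atoms: list[Atom]) -> Residue:
        first = atoms[0]
        return Residue(
            name=first.residue_name,
            index=first.residue_index,
            chain_id=first.chain_id,
            atoms=tuple(atoms),
        )

    def residue(self, chain_id: str, position: int) -> Residue:
        for res in self.residues(chain_id):
            if res.index == position:
                return res
        raise KeyError(f"no residue {position} in chain {chain_id!r} of {self.id}")

    def preceding_residue(self, chain_id: str, position: int) -> Residue | None:
        """The residue immediately before `position` in chain order, or None."""
        prev: Residue | None = None
        for res in self.residues(chain_id):
            if res.index == position:
                return prev
            prev = res
        raise KeyError(f"no residue {position} in chain {chain_id!r} of {self.id}")


@dataclass(frozen=True)
class MutationRecord:
    """A single point mutation with its experimental ΔΔG label.

    Sign convention: ΔΔG = ΔG(mutant) − ΔG(wild type); destabilizing mutations
    are positive.  ``is_reverse`` marks formally inverted records (B→A carries
    −ΔΔG of A→B).
    """

    structure_id: str
    chain_id: str
    position: int
    wt_aa: str
    mt_aa: str
    ddg: float
    is_reverse: bool = False

    def __post_init__(self) -> None:
        if self.wt_aa == self.mt_aa:
            raise ValueError("wild-type and mutant residues must differ")
        if not math.isfinite(self.ddg):
            raise ValueError("ddg must be finite")

    def reversed(self) -> "MutationRecord":
        return MutationRecord(
            structure_id=self.structure_id,
            chain_id=self.chain_id,
            position=self.position,
            wt_aa=self.mt_aa,
            mt_aa=self.wt_aa,
            ddg=-self.ddg,
            is_reverse=not self.is_reverse,
        )


def _validate_pdb_columns(path: Path) -> None:
    # gemmi zero-fills unparsable numeric fields instead of failing, so check
    # the fixed coordinate columns up front to give a line-accurate error.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}: line {lineno}: truncated ATOM record")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: line {lineno}: non-numeric {what} field {fieldtxt!r}"
                    ) from None
            if line[26] not in (" ", ""):
                raise PDBParseError(
                    f"{path}: line {lineno}: insertion codes are unsupported "
                    f"(found {line[26]!r})"
                )


def read_pdb(path: str | Path, keep_hetero: bool = False) -> Structure:
    """Read ATOM records from a PDB file.

    HETATM records and waters are skipped unless ``keep_hetero``.  For
    alternate locations only the highest-occupancy conformer is kept.
    Missing backbone atoms are not an error here; they surface later when a
    residue frame is requested.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_columns(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            het = res.het_flag == "H"
            if het and not keep_hetero:
                continue
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for a in res:
                if a.name not in best:
                    order.append(a.name)
                    best[a.name] = a
                elif a.occ > best[a.name].occ:
                    best[a.name] = a
            for name in order:
                a = best[name]
                atoms.append(
                    Atom(
                        name=name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                    )
                )
    return Structure(id=path.stem, atoms=atoms)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column PDB ATOM records (3-decimal Å)."""
    if not structure.atoms:
        raise PDBFormatError("cannot write an empty structure")
    coords = structure.coords()
    if np.any(np.abs(coords) > 9999.999):
        raise PDBFormatError("coordinates exceed the PDB fixed-column range")
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for res_view in structure.residues():
        try:
            chain = next(c for c in model if c.name == res_view.chain_id)
        except StopIteration:
            chain = gemmi.Chain(res_view.chain_id)
            model.add_chain(chain)
            chain = model[len(model) - 1]
        res = gemmi.Residue()
        res.name = res_view.name
        res.seqid = gemmi.SeqId(res_view.index, " ")
        for a in res_view.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.coords)
            ga.occ = 1.0
            res.add_atom(ga)
        chain.add_residue(res)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
    Path(path).write_text(doc)


# Cβ is placed 1.521 Å from Cα with equal N-Cα-Cβ and C-Cα-Cβ angles of 110.5°,
# on the L-amino-acid side of the backbone plane.
_CB_BOND = 1.521
_CB_ANGLE = math.radians(110.5)


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, Cα, C (e.g. for glycine sites).

    Tetrahedral construction about Cα: the Cβ direction makes equal angles
    with Cα→N and Cα→C and points out of the backbone plane on the side that
    gives L-chirality.  SE(3)-equivariant and deterministic.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    vn = n - ca
    vc = c - ca
    norm_n = np.linalg.norm(vn)
    norm_c = np.linalg.norm(vc)
    if norm_n < 1e-8 or norm_c < 1e-8:
        raise DegenerateGeometryError("coincident backbone atoms")
    vn /= norm_n
    vc /= norm_c
    perp = np.cross(vn, vc)
    norm_p = np.linalg.norm(perp)
    if norm_p < 1e-8:
        raise DegenerateGeometryError("collinear N/CA/C backbone atoms")
    perp /= norm_p
    bisector = vn + vc
    bisector /= np.linalg.norm(bisector)
    half = math.acos(float(np.clip(vn @ vc, -1.0, 1.0))) / 2.0
    cos_mu = -math.cos(_CB_ANGLE) / math.cos(half)
    cos_mu = float(np.clip(cos_mu, -1.0, 1.0))
    sin_mu = math.sqrt(1.0 - cos_mu * cos_mu)
    direction = cos_mu * (-bisector) + sin_mu * perp
    return ca + _CB_BOND * direction


MUTATION_TABLE_COLUMNS = ["structure_id", "chain", "position", "wt", "mt", "ddg"]


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a mutation CSV with header structure_id,chain,position,wt,mt,ddg."""
    df = pd.read_csv(path, dtype={"chain": str, "wt": str, "mt": str})
    missing = set(MUTATION_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        MutationRecord(
            structure_id=str(row.structure_id),
            chain_id=str(row.chain),
            position=int(row.position),
            wt_aa=str(row.wt),
            mt_aa=str(row.mt),
            ddg=float(row.ddg),
        )
        for row in df.itertuples()
    ]


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "structure_id": [r.structure_id for r in records],
            "chain": [r.chain_id for r in records],
            "position": [r.position for r in records],
            "wt": [r.wt_aa for r in records],
            "mt": [r.mt_aa for r in records],
            "ddg": [r.ddg for r in records],
        }
    )
    df.to_csv(path, index=False)
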