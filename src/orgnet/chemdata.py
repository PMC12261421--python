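"""Frozen atom-typing rule table for the seven voxel channels.

Flags follow standard pharmacophore-style typing of the 20 amino acids at
physiological protonation:

* hydrophobic — carbon atoms not covalently bonded to N or O,
* hbond_acceptor — backbone O and side-chain acceptor N/O,
* hbond_donor — backbone N (except proline) and side-chain N/O bearing an H,
* aromatic — ring atoms of PHE, TYR, TRP, HIS,
* pos_ionizable — LYS NZ; ARG NE/NH1/NH2/CZ; HIS ring nitrogens,
* neg_ionizable — ASP OD1/OD2; GLU OE1/OE2,
* occupancy — every heavy atom.

The table is deliberately explicit (no bond perception at run time) so that
featurization is reproducible bit-for-bit.
"""

from __future__ import annotations

__all__ = [
    "CHANNEL_NAMES",
    "VDW_RADII",
    "atom_flags",
    "vdw_radius",
    "UnknownAtomError",
]

CHANNEL_NAMES = (
    "hydrophobic",
    "hbond_acceptor",
    "hbond_donor",
    "aromatic",
    "pos_ionizable",
    "neg_ionizable",
    "occupancy",
)

# van der Waals radii in Å, per element
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

_H = "hydrophobic"
_ACC = "hbond_acceptor"
_DON = "hbond_donor"
_ARO = "aromatic"
_POS = "pos_ionizable"
_NEG = "neg_ionizable"

# Side-chain atoms (beyond CA/C/N/O) with their flags.  Carbons bonded to N or
# O lose the hydrophobic flag; aromatic ring membership is explicit.
_SIDE_CHAINS: dict[str, dict[str, frozenset[str]]] = {
    "ALA": {"CB": {_H}},
    "ARG": {
        "CB": {_H}, "CG": {_H}, "CD": set(),
        "NE": {_DON, _POS}, "CZ": {_POS},
        "NH1": {_DON, _POS}, "NH2": {_DON, _POS},
    },
    "ASN": {"CB": {_H}, "CG": set(), "OD1": {_ACC}, "ND2": {_DON}},
    "ASP": {"CB": {_H}, "CG": set(), "OD1": {_ACC, _NEG}, "OD2": {_ACC, _NEG}},
    "CYS": {"CB": {_H}, "SG": set()},
    "GLN": {"CB": {_H}, "CG": {_H}, "CD": set(), "OE1": {_ACC}, "NE2": {_DON}},
    "GLU": {
        "CB": {_H}, "CG": {_H}, "CD": set(),
        "OE1": {_ACC, _NEG}, "OE2": {_ACC, _NEG},
    },
    "GLY": {},
    "HIS": {
        "CB": {_H},
        "CG": {_ARO}, "CD2": {_ARO}, "CE1": {_ARO},
        "ND1": {_ARO, _DON, _ACC, _POS},
        "NE2": {_ARO, _DON, _ACC, _POS},
    },
    "ILE": {"CB": {_H}, "CG1": {_H}, "CG2": {_H}, "CD1": {_H}},
    "LEU": {"CB": {_H}, "CG": {_H}, "CD1": {_H}, "CD2": {_H}},
    "LYS": {"CB": {_H}, "CG": {_H}, "CD": {_H}, "CE": set(), "NZ": {_DON, _POS}},
    "MET": {"CB": {_H}, "CG": {_H}, "SD": set(), "CE": {_H}},
    "PHE": {
        "CB": {_H},
        "CG": {_H, _ARO}, "CD1": {_H, _ARO}, "CD2": {_H, _ARO},
        "CE1": {_H, _ARO}, "CE2": {_H, _ARO}, "CZ": {_H, _ARO},
    },
    "PRO": {"CB": {_H}, "CG": {_H}, "CD": set()},
    "SER": {"CB": set(), "OG": {_DON, _ACC}},
    "THR": {"CB": set(), "OG1": {_DON, _ACC}, "CG2": {_H}},
    "TRP": {
        "CB": {_H},
        "CG": {_H, _ARO}, "CD1": {_ARO}, "CD2": {_H, _ARO},
        "NE1": {_ARO, _DON}, "CE2": {_ARO}, "CE3": {_H, _ARO},
        "CZ2": {_H, _ARO}, "CZ3": {_H, _ARO}, "CH2": {_H, _ARO},
    },
    "TYR": {
        "CB": {_H},
        "CG": {_H, _ARO}, "CD1": {_H, _ARO}, "CD2": {_H, _ARO},
        "CE1": {_H, _ARO}, "CE2": {_H, _ARO}, "CZ": {_ARO},
        "OH": {_DON, _ACC},
    },
    "VAL": {"CB": {_H}, "CG1": {_H}, "CG2": {_H}},
}


class UnknownAtomError(KeyError):
    """Raised for an atom/residue combination missing from the rule table."""


def atom_flags(residue_name: str, atom_name: str) -> frozenset[str]:
    """Property flags for one heavy atom (occupancy always included)."""
    residue_name = residue_name.upper()
    atom_name = atom_name.upper()
    if residue_name not in _SIDE_CHAINS:
        raise UnknownAtomError(f"unknown residue {residue_name!r}")
    if atom_name in ("N",):
        flags = set() if residue_name == "PRO" else {_DON}
    elif atom_name in ("O", "OXT"):
        flags = {_ACC}
    elif atom_name in ("CA", "C"):
        flags = set()
    else:
        table = _SIDE_CHAINS[residue_name]
        if atom_name not in table:
            raise UnknownAtomError(
                f"unknown atom {atom_name!r} for residue {residue_name!r}"
            )
        flags = set(table[atom_name])
    return frozenset(flags | {"occupancy"})


def vdw_radius(element: str) -> float:
    """van der Waals radius (Å) from the fixed per-element table."""
    element = element.upper()
    if element not in VDW_RADII:
        raise UnknownAtomError(f"no van der Waals radius for element {element!r}")
    return VDW_RADII[element]
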