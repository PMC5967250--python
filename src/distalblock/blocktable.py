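"""Distal-block definitions for the 18 side-chain-bearing residue types.

A side chain is partitioned into rigid groups; the group farthest from the
backbone is the *distal block*.  The block table records, per residue type,
the ordered heavy-atom names of that group, their atomic masses, and the χ1
atom quadruple.  GLY and ALA are deliberately absent: their side chains are
too small to carry a block.

The default table ships the chemically terminal rigid group of each side
chain (ARG guanidinium, LYS CE+NZ, PHE/TYR-style ring or hydroxyl tips, ...),
calibrated so that ideal-geometry conformers built by
:mod:`distalblock.builder` reproduce the modal block lengths observed in
high-resolution structure sets (LYS 5.7 Å, ILE 3.88 Å, PHE 3.78 Å,
TYR 6.43 Å).  The table is plain data and can be serialized/edited as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

__all__ = [
    "ATOMIC_MASSES",
    "STANDARD_RESIDUES",
    "BLOCKLESS_RESIDUES",
    "BlockDef",
    "BlockTable",
    "default_block_table",
]

#: Standard atomic masses (u) of the heavy elements occurring in side chains.
ATOMIC_MASSES: Dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Residue types without a distal block (and without χ1).
BLOCKLESS_RESIDUES = frozenset({"GLY", "ALA"})

# Terminal rigid group of each side chain.  ARG, LYS, ILE, PHE, TYR follow the
# calibrated defaults; the remaining types use the chemically terminal group.
_DEFAULT_BLOCKS: Dict[str, Tuple[str, ...]] = {
    "ARG": ("NE", "CZ", "NH1", "NH2"),
    "ASN": ("CG", "OD1", "ND2"),
    "ASP": ("CG", "OD1", "OD2"),
    "CYS": ("SG",),
    "GLN": ("CD", "OE1", "NE2"),
    "GLU": ("CD", "OE1", "OE2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CD1",),
    "LEU": ("CD1", "CD2"),
    "LYS": ("CE", "NZ"),
    "MET": ("SD", "CE"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CG", "CD"),
    "SER": ("OG",),
    "THR": ("OG1", "CG2"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("OH",),
    "VAL": ("CG1", "CG2"),
}

# γ atom completing the χ1 quadruple N-CA-CB-Xγ (standard convention:
# lowest-numbered branch for ILE/VAL/THR).
_CHI1_GAMMA: Dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}


def element_of(atom_name: str) -> str:
    """Element symbol of a standard protein heavy-atom name (first letter)."""
    return atom_name[0]


@dataclass(frozen=True)
class BlockDef:
    """Distal block of one residue type: ordered atom names and masses (u)."""

    atoms: Tuple[str, ...]
    masses: Tuple[float, ...]

    def __post_init__(self):
        if len(self.atoms) != len(self.masses) or not self.atoms:
            raise ValueError("block needs one mass per atom and at least one atom")
        if any(m <= 0 for m in self.masses):
            raise ValueError("atomic masses must be positive")


class BlockTable:
    """Per-residue-type distal-block definitions plus χ1 quadruples.

    The table must cover exactly the 18 non-GLY/ALA standard residue types.
    """

    def __init__(self, blocks: Dict[str, BlockDef], chi1_gamma: Optional[Dict[str, str]] = None):
        expected = STANDARD_RESIDUES - BLOCKLESS_RESIDUES
        if set(blocks) != expected:
            missing = expected - set(blocks)
            extra = set(blocks) - expected
            raise ValueError(
                f"block table must cover the 18 side-chain types exactly "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )
        self._blocks = dict(blocks)
        self._chi1_gamma = dict(chi1_gamma or _CHI1_GAMMA)

    def block(self, res_type: str) -> Optional[BlockDef]:
        """Block definition for a residue type, or None for GLY/ALA."""
        return self._blocks.get(res_type)

    def chi1_quadruple(self, res_type: str) -> Optional[Tuple[str, str, str, str]]:
        """(N, CA, CB, Xγ) atom names, or None for GLY/ALA/unknown types."""
        gamma = self._chi1_gamma.get(res_type)
        if gamma is None:
            return None
        return ("N", "CA", "CB", gamma)

    @property
    def residue_types(self) -> Tuple[str, ...]:
        return tuple(sorted(self._blocks))

    # -- plain-text (JSON) serialization ------------------------------------

    def to_json(self, path) -> None:
        payload = {
            res: {"atoms": list(b.atoms), "masses": list(b.masses),
                  "chi1_gamma": self._chi1_gamma[res]}
            for res, b in sorted(self._blocks.items())
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "BlockTable":
        payload = json.loads(Path(path).read_text())
        blocks = {
            res: BlockDef(tuple(v["atoms"]), tuple(float(m) for m in v["masses"]))
            for res, v in payload.items()
        }
        gamma = {res: v["chi1_gamma"] for res, v in payload.items()}
        return cls(blocks, gamma)


def default_block_table() -> BlockTable:
    """The calibrated default block table (see module docstring)."""
    blocks = {
        res: BlockDef(atoms, tuple(ATOMIC_MASSES[element_of(a)] for a in atoms))
        for res, atoms in _DEFAULT_BLOCKS.items()
    }
    return BlockTable(blocks)
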