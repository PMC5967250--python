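"""Torsion angles and the distal-block length statistic.

All dihedral angles follow the IUPAC sign convention (cis = 0°, trans = 180°)
and are reported on [0°, 360°).  This is the convention used throughout the
package: an α-helical residue with Ramachandran φR = −57° has φ = 303°.

The distal-block length ``dBlock`` of a residue is the Euclidean distance from
its Cα atom to the mass center of the terminal rigid group ("distal block") of
its side chain, as defined by a :class:`~distalblock.blocktable.BlockTable`.
It is a one-number summary separating folded from extended side-chain
conformations; GLY and ALA carry no distal block.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .exceptions import DegenerateGeometryError

__all__ = [
    "dihedral",
    "to_full_range",
    "backbone_phi",
    "backbone_psi",
    "chi1",
    "block_center",
    "block_length",
]


def dihedral(a, b, c, d) -> float:
    """Dihedral angle of the quadruple a-b-c-d, in degrees on [0, 360).

    Parameters are 3-vectors in Å.  Raises
    :class:`~distalblock.exceptions.DegenerateGeometryError` when the b-c axis
    has (near-)zero length or either flanking atom is collinear with it, in
    which case the angle is undefined.
    """
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b0 = b - a
    b1 = c - b
    b2 = d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    nb1 = float(np.linalg.norm(b1))
    scale0 = float(np.linalg.norm(b0)) * nb1
    scale2 = nb1 * float(np.linalg.norm(b2))
    if nb1 < 1e-9:
        raise DegenerateGeometryError("central axis b-c has zero length")
    if np.linalg.norm(n1) < 1e-9 * max(scale0, 1e-30):
        raise DegenerateGeometryError("atom a is collinear with the b-c axis")
    if np.linalg.norm(n2) < 1e-9 * max(scale2, 1e-30):
        raise DegenerateGeometryError("atom d is collinear with the b-c axis")
    x = float(n1 @ n2)
    y = nb1 * float(b0 @ n2)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def to_full_range(phi_r: float) -> float:
    """Map an angle from the Ramachandran convention (−180, 180] to the
    full [0, 360) range used throughout the package.

    Identity on [0, 180]; +360° on (−180, 0).  The boundary value −180 is
    accepted and mapped to 180 (the two labels denote the same angle).
    """
    if not -180.0 <= phi_r <= 180.0:
        raise ValueError(f"angle {phi_r!r} outside (-180, 180]")
    return float(phi_r % 360.0)


def backbone_phi(prev_c, n, ca, c) -> float:
    """Backbone φ = dihedral C(i−1)–N–Cα–C, on [0, 360)."""
    return dihedral(prev_c, n, ca, c)


def backbone_psi(n, ca, c, next_n) -> float:
    """Backbone ψ = dihedral N–Cα–C–N(i+1), on [0, 360)."""
    return dihedral(n, ca, c, next_n)


def chi1(residue, block_table) -> Optional[float]:
    """First side-chain dihedral χ1 = N–Cα–Cβ–Xγ, or None when undefined.

    The γ atom follows the standard convention recorded in the block table
    (CG; CG1 for ILE/VAL; OG for SER; OG1 for THR; SG for CYS).  GLY/ALA have
    no χ1; a missing quadruple atom yields None (missing feature, never
    imputed).
    """
    quad = block_table.chi1_quadruple(residue.res_type)
    if quad is None:
        return None
    coords = []
    for name in quad:
        atom = residue.atom(name)
        if atom is None:
            return None
        coords.append(atom.coords)
    return dihedral(*coords)


def block_center(residue, block_table) -> Optional[np.ndarray]:
    """Mass center of the residue's distal block (heavy atoms only).

    Returns None when the residue type carries no distal block (GLY/ALA) or
    any block atom is absent from the model.
    """
    block = block_table.block(residue.res_type)
    if block is None:
        return None
    coords = []
    for name in block.atoms:
        atom = residue.atom(name)
        if atom is None:
            return None
        coords.append(atom.coords)
    masses = np.asarray(block.masses, dtype=float)
    coords = np.asarray(coords, dtype=float)
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def block_length(residue, block_table) -> Optional[float]:
    """dBlock: distance from Cα to the distal-block mass center, in Å."""
    ca = residue.atom("CA")
    if ca is None:
        return None
    center = block_center(residue, block_table)
    if center is None:
        return None
    return float(np.linalg.norm(center - np.asarray(ca.coords, dtype=float)))
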