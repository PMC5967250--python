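"""Ideal covalent geometry used by the conformer builder.

Bond lengths (Å) and bond angles (°) follow a standard stereochemistry
parameter set of the Engh–Huber type; aromatic and other sp2 groups are
expressed as rigid planar templates (successive in-plane placements), so no
ring-closure solving is needed.  Side chains are described in internal
coordinates: each atom is placed from three reference atoms by bond length,
bond angle and a torsion that is either a free χ angle, a fixed offset from a
χ (branches, carboxylate/amide second atoms), or a constant (planar groups).

The chirality-defining Cβ improper and the branched-atom offsets (ILE, VAL,
THR, LEU) match ideal L-amino-acid coordinates from the chemical component
dictionary.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

__all__ = [
    "BACKBONE",
    "SIDE_CHAINS",
    "N_CHI",
    "CLOSURE_BONDS",
    "Placement",
]

#: Backbone bonds (Å) and angles (°).
BACKBONE = {
    "N_CA": 1.458,
    "CA_C": 1.525,
    "C_N": 1.329,
    "C_O": 1.231,
    "CA_CB": 1.530,
    "ang_C_N_CA": 121.7,
    "ang_N_CA_C": 111.2,
    "ang_CA_C_N": 116.2,
    "ang_CA_C_O": 120.8,
    "ang_O_C_N": 123.0,
    "ang_N_CA_CB": 110.4,
    "omega": 180.0,
    # improper dihedral(C, N, CA, CB) fixing the L configuration
    "tor_C_N_CA_CB": 240.0,
}

# torsion spec: ("chi", k, offset_deg) -> chis[k-1] + offset; ("fix", value)
TorsionSpec = Tuple
#: (atom_name, (ref_a, ref_b, ref_c), bond, angle, torsion_spec)
Placement = Tuple[str, Tuple[str, str, str], float, float, TorsionSpec]

SIDE_CHAINS: Dict[str, List[Placement]] = {
    "ALA": [],
    "GLY": [],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("NE", ("CB", "CG", "CD"), 1.461, 112.0, ("chi", 3, 0.0)),
        ("CZ", ("CG", "CD", "NE"), 1.329, 124.2, ("chi", 4, 0.0)),
        ("NH1", ("CD", "NE", "CZ"), 1.326, 120.0, ("fix", 0.0)),
        ("NH2", ("CD", "NE", "CZ"), 1.326, 120.0, ("fix", 180.0)),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, ("chi", 2, 0.0)),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, ("chi", 2, 180.0)),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, ("chi", 1, 0.0)),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 0.0)),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, ("chi", 2, 180.0)),
    ],
    "CYS": [
        ("SG", ("N", "CA", "CB"), 1.808, 114.4, ("chi", 1, 0.0)),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.231, 120.8, ("chi", 3, 0.0)),
        ("NE2", ("CB", "CG", "CD"), 1.328, 116.4, ("chi", 3, 180.0)),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.516, 112.6, ("chi", 2, 0.0)),
        ("OE1", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 0.0)),
        ("OE2", ("CB", "CG", "CD"), 1.249, 118.4, ("chi", 3, 180.0)),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.497, 113.8, ("chi", 1, 0.0)),
        ("ND1", ("CA", "CB", "CG"), 1.378, 122.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.354, 131.2, ("chi", 2, 180.0)),
        ("CE1", ("CB", "CG", "ND1"), 1.321, 107.5, ("fix", 180.0)),
        ("NE2", ("CB", "CG", "CD2"), 1.374, 109.0, ("fix", 180.0)),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), 1.530, 110.4, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
        ("CD1", ("CA", "CB", "CG1"), 1.513, 113.8, ("chi", 2, 0.0)),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, ("chi", 2, 120.0)),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.520, 111.3, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "CD"), 1.520, 111.3, ("chi", 3, 0.0)),
        ("NZ", ("CG", "CD", "CE"), 1.489, 111.9, ("chi", 4, 0.0)),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), 1.520, 114.1, ("chi", 1, 0.0)),
        ("SD", ("CA", "CB", "CG"), 1.803, 112.7, ("chi", 2, 0.0)),
        ("CE", ("CB", "CG", "SD"), 1.791, 100.9, ("chi", 3, 0.0)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.502, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.384, 120.7, ("chi", 2, 0.0)),
        ("CD2", ("CD1", "CB", "CG"), 1.384, 120.7, ("fix", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 120.7, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 120.7, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.382, 120.0, ("fix", 0.0)),
    ],
    "PRO": [
        # fixed Cγ-endo-like ring template (no free χ)
        ("CG", ("N", "CA", "CB"), 1.492, 104.5, ("fix", 341.0)),
        ("CD", ("CA", "CB", "CG"), 1.503, 106.1, ("fix", 9.0)),
    ],
    "SER": [
        ("OG", ("N", "CA", "CB"), 1.417, 111.1, ("chi", 1, 0.0)),
    ],
    "THR": [
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, ("chi", 1, -120.0)),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, ("chi", 2, 0.0)),
        ("CD2", ("CD1", "CB", "CG"), 1.433, 126.7, ("fix", 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, ("fix", 180.0)),
        ("CE2", ("CG", "CD1", "NE1"), 1.370, 109.0, ("fix", 0.0)),
        ("CE3", ("CD1", "CG", "CD2"), 1.398, 133.9, ("fix", 180.0)),
        ("CZ2", ("CD1", "NE1", "CE2"), 1.394, 130.1, ("fix", 180.0)),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, ("fix", 180.0)),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.400, 121.1, ("fix", 0.0)),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.512, 113.8, ("chi", 1, 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.387, 120.9, ("chi", 2, 0.0)),
        ("CD2", ("CD1", "CB", "CG"), 1.387, 120.9, ("fix", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.389, 121.2, ("fix", 180.0)),
        ("CE2", ("CB", "CG", "CD2"), 1.389, 121.2, ("fix", 180.0)),
        ("CZ", ("CG", "CD1", "CE1"), 1.381, 119.6, ("fix", 0.0)),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, ("fix", 180.0)),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 0.0)),
        ("CG2", ("N", "CA", "CB"), 1.527, 110.5, ("chi", 1, 120.0)),
    ],
}

#: Number of free χ angles per residue type (PRO uses a fixed ring template).
N_CHI: Dict[str, int] = {
    "ALA": 0, "GLY": 0, "ARG": 4, "ASN": 2, "ASP": 2, "CYS": 1, "GLN": 3,
    "GLU": 3, "HIS": 2, "ILE": 2, "LEU": 2, "LYS": 4, "MET": 3, "PHE": 2,
    "PRO": 0, "SER": 1, "THR": 1, "TRP": 2, "TYR": 2, "VAL": 1,
}

#: Ring-closing bonds not expressed by the placement parents.
CLOSURE_BONDS: Dict[str, List[Tuple[str, str]]] = {
    "PHE": [("CE2", "CZ")],
    "TYR": [("CE2", "CZ")],
    "HIS": [("CE1", "NE2")],
    "TRP": [("CD2", "CE2"), ("CZ2", "CH2")],
    "PRO": [("CD", "N")],
}
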