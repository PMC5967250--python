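"""Shared fixtures and the rotation-construction dihedral oracle."""

from __future__ import annotations

import numpy as np
import pytest

from distalblock import default_block_table


@pytest.fixture(scope="session")
def block_table():
    return default_block_table()


def rotation_quadruple(rng, torsion):
    """Construct a random quadruple with a known dihedral by explicit axis
    rotation — an oracle independent of both the dihedral formula (cross
    products + atan2) and NeRF placement (local frames).

    b sits at a random origin, c along a random axis.  The cis (torsion 0)
    direction for d is the component of b→a perpendicular to the axis;
    rotating it about the axis by ``torsion`` (Rodrigues) and tilting by the
    bond angle gives d.  Returns (a, b, c, d).
    """
    b = rng.uniform(-5, 5, 3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    lbc = rng.uniform(1.0, 2.0)
    c = b + lbc * axis
    # a: random position with a non-degenerate perpendicular component
    while True:
        a = b + rng.uniform(1.0, 2.0) * _random_unit(rng)
        perp = (a - b) - ((a - b) @ axis) * axis
        if np.linalg.norm(perp) > 0.1:
            break
    e_cis = perp / np.linalg.norm(perp)
    t = np.radians(torsion)
    w = e_cis * np.cos(t) + np.cross(axis, e_cis) * np.sin(t)
    ang = np.radians(rng.uniform(60.0, 150.0))  # bond angle b-c-d
    lcd = rng.uniform(1.0, 2.0)
    d = c + lcd * (-axis * np.cos(ang) + w * np.sin(ang))
    return a, b, c, d


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def random_rigid_motion(rng):
    """A uniformly random proper rotation matrix and a random translation."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-20, 20, 3)


def pdb_atom_line(serial, name, resname, chain, resseq, x, y, z,
                  altloc="", icode="", occ=1.0, element=None, hetatm=False):
    """One fixed-column ATOM/HETATM record."""
    record = "HETATM" if hetatm else "ATOM  "
    element = element or name[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {name_field}{altloc or ' '}{resname:>3s} "
            f"{chain}{resseq:4d}{icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
            f"{element:>2s}")
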