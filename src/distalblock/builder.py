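"""Synthetic conformer generation at exact, user-specified torsions.

Side chains and short peptides are built from standard covalent geometry
(:mod:`distalblock.templates`) by sequential internal-coordinate placement
(NeRF-style), so every requested backbone or side-chain torsion is realized
exactly (up to the 3-decimal coordinate quantization of PDB output).  Each
residue is embedded in a GLY–X–GLY tripeptide so that φ and ψ are defined.

Ensembles are drawn from mixtures of torsion components with per-angle
Gaussian noise, filtered for steric clashes, and emitted together with a
ground-truth table — this is the stand-in for experimental structure sets
used throughout the test suite.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from .blocktable import BlockTable, default_block_table
from .exceptions import BuildError, DegenerateGeometryError, GenerationError
from .structure_io import AtomRecord, ResidueUnit
from .templates import BACKBONE, CLOSURE_BONDS, N_CHI, SIDE_CHAINS
from . import geometry

logger = logging.getLogger(__name__)

__all__ = [
    "place_atom",
    "build_residue",
    "build_tripeptide",
    "clash_filter",
    "Component",
    "SyntheticSpec",
    "sample_ensemble",
    "write_pdb",
    "CHAIN_IDS",
]

CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
             "abcdefghijklmnopqrstuvwxyz0123456789")

#: Default minimal non-bonded heavy-atom separation (Å).
DEFAULT_CLASH_THRESHOLD = 2.0
RETRY_CAP = 100


def _place(a, b, c, bond: float, angle: float, torsion: float):
    """Scalar NeRF placement; returns a coordinate tuple."""
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    if nbc < 1e-9:
        raise DegenerateGeometryError("reference atoms b and c coincide")
    ux, uy, uz = bcx / nbc, bcy / nbc, bcz / nbc
    # plane normal of (a, b, c)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-9:
        raise DegenerateGeometryError("reference atoms a, b, c are collinear")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    # m completes the right-handed frame (u, m, n)
    mx = ny * uz - nz * uy
    my = nz * ux - nx * uz
    mz = nx * uy - ny * ux
    ang = math.radians(angle)
    tor = math.radians(torsion)
    d1 = -bond * math.cos(ang)
    d2 = bond * math.sin(ang) * math.cos(tor)
    d3 = bond * math.sin(ang) * math.sin(tor)
    return (
        c[0] + d1 * ux + d2 * mx + d3 * nx,
        c[1] + d1 * uy + d2 * my + d3 * ny,
        c[2] + d1 * uz + d2 * mz + d3 * nz,
    )


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that \\|d−c\\| = bond, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees, IUPAC convention).

    Raises :class:`DegenerateGeometryError` for a collinear reference frame.
    """
    a = tuple(float(v) for v in np.asarray(a, dtype=float))
    b = tuple(float(v) for v in np.asarray(b, dtype=float))
    c = tuple(float(v) for v in np.asarray(c, dtype=float))
    return np.asarray(_place(a, b, c, bond, angle, torsion), dtype=float)


def _build_coords(res_type: str, phi_r: float, psi_r: float,
                  chis: Sequence[float]) -> Dict[str, Tuple[float, float, float]]:
    """All heavy-atom coordinates of the GLY-X-GLY tripeptide, name-spaced
    with 'p:' (preceding GLY), 'x:' (central residue) and 'n:' (following GLY).
    """
    if res_type not in SIDE_CHAINS:
        raise BuildError(f"unknown residue type {res_type!r}")
    if len(chis) != N_CHI[res_type]:
        raise BuildError(
            f"{res_type} takes {N_CHI[res_type]} chi angle(s), got {len(chis)}")
    bb = BACKBONE
    at: Dict[str, Tuple[float, float, float]] = {}
    ang = math.radians(bb["ang_N_CA_C"])
    at["x:N"] = (0.0, 0.0, 0.0)
    at["x:CA"] = (bb["N_CA"], 0.0, 0.0)
    at["x:C"] = (bb["N_CA"] - bb["CA_C"] * math.cos(ang),
                 bb["CA_C"] * math.sin(ang), 0.0)
    # preceding glycine, grown backwards from the central N via phi
    at["p:C"] = _place(at["x:C"], at["x:CA"], at["x:N"],
                       bb["C_N"], bb["ang_C_N_CA"], phi_r)
    at["p:O"] = _place(at["x:CA"], at["x:N"], at["p:C"],
                       bb["C_O"], bb["ang_O_C_N"], 0.0)
    at["p:CA"] = _place(at["x:CA"], at["x:N"], at["p:C"],
                        bb["CA_C"], bb["ang_CA_C_N"], bb["omega"])
    at["p:N"] = _place(at["x:N"], at["p:C"], at["p:CA"],
                       bb["N_CA"], bb["ang_N_CA_C"], 150.0)
    # following glycine, grown forwards via psi
    at["x:O"] = _place(at["x:N"], at["x:CA"], at["x:C"],
                       bb["C_O"], bb["ang_CA_C_O"], psi_r + 180.0)
    at["n:N"] = _place(at["x:N"], at["x:CA"], at["x:C"],
                       bb["C_N"], bb["ang_CA_C_N"], psi_r)
    at["n:CA"] = _place(at["x:CA"], at["x:C"], at["n:N"],
                        bb["N_CA"], bb["ang_C_N_CA"], bb["omega"])
    at["n:C"] = _place(at["x:C"], at["n:N"], at["n:CA"],
                       bb["CA_C"], bb["ang_N_CA_C"], 240.0)
    at["n:O"] = _place(at["n:N"], at["n:CA"], at["n:C"],
                       bb["C_O"], bb["ang_CA_C_O"], 330.0)
    # side chain of the central residue
    if res_type != "GLY":
        at["x:CB"] = _place(at["x:C"], at["x:N"], at["x:CA"],
                            bb["CA_CB"], bb["ang_N_CA_CB"], bb["tor_C_N_CA_CB"])
    for name, (ra, rb, rc), bond, angle, tor in SIDE_CHAINS[res_type]:
        kind = tor[0]
        if kind == "chi":
            value = float(chis[tor[1] - 1]) + tor[2]
        else:
            value = tor[1]
        at[f"x:{name}"] = _place(at[f"x:{ra}"], at[f"x:{rb}"], at[f"x:{rc}"],
                                 bond, angle, value)
    return at


_BACKBONE_ORDER = ("N", "CA", "C", "O")


def _as_residues(res_type: str, at: Dict[str, Tuple[float, float, float]]
                 ) -> Tuple[ResidueUnit, ResidueUnit, ResidueUnit]:
    from .blocktable import element_of

    def mk(prefix: str, rtype: str, seq: int) -> ResidueUnit:
        names = list(_BACKBONE_ORDER)
        if rtype != "GLY":
            names.append("CB")
            names.extend(p[0] for p in SIDE_CHAINS[rtype])
        atoms = [AtomRecord(n, element_of(n), at[f"{prefix}:{n}"]) for n in names]
        return ResidueUnit(rtype, "A", seq, "", atoms)

    prev = mk("p", "GLY", 1)
    mid = mk("x", res_type, 2)
    nxt = mk("n", "GLY", 3)
    prev.next, mid.prev = mid, prev
    mid.next, nxt.prev = nxt, mid
    return prev, mid, nxt


def build_tripeptide(res_type: str, phi_r: float, psi_r: float,
                     chis: Sequence[float] = ()) -> Tuple[ResidueUnit, ResidueUnit, ResidueUnit]:
    """Build a GLY-X-GLY tripeptide; returns (gly, X, gly), peptide-linked."""
    return _as_residues(res_type, _build_coords(res_type, phi_r, psi_r, chis))


def build_residue(res_type: str, phi_r: float, psi_r: float,
                  chis: Sequence[float] = ()) -> ResidueUnit:
    """Build the central residue of a GLY-X-GLY tripeptide.

    The requested torsions (any degree convention; φR/ψR accepted directly)
    are realized exactly.  The flanking glycines are reachable through
    ``prev``/``next`` and provide the atoms needed to measure φ and ψ.
    """
    return build_tripeptide(res_type, phi_r, psi_r, chis)[1]


# ---------------------------------------------------------------------------
# clash filtering
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _clash_pairs(res_type: str) -> Tuple[Tuple[Tuple[str, str], Tuple[str, str]], ...]:
    """Heavy-atom pairs of the tripeptide ≥3 bonds apart (BFS on the bond graph)."""
    nodes: List[Tuple[str, str]] = []
    for prefix, rtype in (("p", "GLY"), ("x", res_type), ("n", "GLY")):
        names = list(_BACKBONE_ORDER)
        if rtype != "GLY":
            names.append("CB")
            names.extend(p[0] for p in SIDE_CHAINS[rtype])
        nodes.extend((prefix, n) for n in names)
    edges: List[Tuple[Tuple[str, str], Tuple[str, str]]] = []
    for prefix in ("p", "x", "n"):
        edges += [((prefix, "N"), (prefix, "CA")),
                  ((prefix, "CA"), (prefix, "C")),
                  ((prefix, "C"), (prefix, "O"))]
    edges += [(("p", "C"), ("x", "N")), (("x", "C"), ("n", "N"))]
    if res_type != "GLY":
        edges.append((("x", "CA"), ("x", "CB")))
        for name, (_, _, parent), *_rest in SIDE_CHAINS[res_type]:
            edges.append((("x", parent), ("x", name)))
        for u, v in CLOSURE_BONDS.get(res_type, ()):
            edges.append((("x", u), ("x", v)))
    adj: Dict[Tuple[str, str], List[Tuple[str, str]]] = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    pairs = []
    index = {n: i for i, n in enumerate(nodes)}
    for src in nodes:
        dist = {src: 0}
        queue = [src]
        while queue:
            cur = queue.pop(0)
            for nb in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    queue.append(nb)
        for other in nodes:
            if index[other] > index[src] and dist.get(other, 99) >= 3:
                pairs.append((src, other))
    return tuple(pairs)


def clash_filter(residue: ResidueUnit, threshold: float = DEFAULT_CLASH_THRESHOLD) -> bool:
    """True iff no heavy-atom pair separated by ≥3 bonds is closer than ``threshold``.

    Operates on a built tripeptide (the central residue with its glycine
    neighbors); 1-2 and 1-3 pairs are bonded geometry, not clashes.
    """
    if threshold <= 0:
        return True
    coords = {}
    for prefix, res in (("p", residue.prev), ("x", residue), ("n", residue.next)):
        if res is None:
            continue
        for a in res.atoms:
            coords[(prefix, a.name)] = a.coords
    thr2 = threshold * threshold
    for u, v in _clash_pairs(residue.res_type):
        cu = coords.get(u)
        cv = coords.get(v)
        if cu is None or cv is None:
            continue
        dx = cu[0] - cv[0]
        dy = cu[1] - cv[1]
        dz = cu[2] - cv[2]
        if dx * dx + dy * dy + dz * dz < thr2:
            return False
    return True


# ---------------------------------------------------------------------------
# ensemble sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One torsion mixture component: mean angles, weight and noise σ (°)."""

    phi_r: float
    psi_r: float
    chis: Tuple[float, ...] = ()
    weight: float = 1.0
    sigma: float = 0.0

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("component weight must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class SyntheticSpec:
    """Recipe for a ground-truth ensemble of one residue type."""

    res_type: str
    components: List[Component]
    n_samples: int
    seed: int
    clash_threshold: float = DEFAULT_CLASH_THRESHOLD

    def __post_init__(self):
        if self.res_type not in N_CHI:
            raise BuildError(f"unknown residue type {self.res_type!r}")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not self.components:
            raise ValueError("at least one component required")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component weights must sum to 1 (got {total})")
        for c in self.components:
            if len(c.chis) != N_CHI[self.res_type]:
                raise BuildError(
                    f"{self.res_type} takes {N_CHI[self.res_type]} chi angle(s)")

    def to_json(self, path) -> None:
        payload = {
            "res_type": self.res_type,
            "n_samples": self.n_samples,
            "seed": self.seed,
            "clash_threshold": self.clash_threshold,
            "components": [
                {"phi_r": c.phi_r, "psi_r": c.psi_r, "chis": list(c.chis),
                 "weight": c.weight, "sigma": c.sigma}
                for c in self.components
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        p = json.loads(Path(path).read_text())
        comps = [Component(c["phi_r"], c["psi_r"], tuple(c.get("chis", ())),
                           c.get("weight", 1.0), c.get("sigma", 0.0))
                 for c in p["components"]]
        return cls(p["res_type"], comps, int(p["n_samples"]), int(p["seed"]),
                   float(p.get("clash_threshold", DEFAULT_CLASH_THRESHOLD)))


def sample_ensemble(spec: SyntheticSpec,
                    block_table: Optional[BlockTable] = None
                    ) -> Tuple[List[ResidueUnit], pd.DataFrame]:
    """Draw an ensemble per the spec; fully reproducible from its seed.

    Components are chosen by weight; each angle gets independent Gaussian
    noise with the component's σ.  Clashing conformers are redrawn (same
    component) up to {cap} times, then :class:`GenerationError` is raised.
    Returns the built central residues and a ground-truth table with one row
    per emitted structure: component index, the exact torsions drawn, the
    resulting dBlock, and the number of redraws.
    """
    table = block_table or default_block_table()
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components], dtype=float)
    weights = weights / weights.sum()
    structures: List[ResidueUnit] = []
    rows = []
    n_chi = N_CHI[spec.res_type]
    chi_cols = [f"chi{k+1}" for k in range(n_chi)]
    for i in range(spec.n_samples):
        ci = int(rng.choice(len(spec.components), p=weights))
        comp = spec.components[ci]
        means = np.array([comp.phi_r, comp.psi_r, *comp.chis], dtype=float)
        for attempt in range(RETRY_CAP):
            tors = means + rng.normal(0.0, comp.sigma, size=means.size) \
                if comp.sigma > 0 else means.copy()
            residue = build_residue(spec.res_type, tors[0], tors[1], tors[2:])
            if clash_filter(residue, spec.clash_threshold):
                break
        else:
            raise GenerationError(
                f"sample {i}: component {ci} produced clashes in "
                f"{RETRY_CAP} consecutive draws")
        if attempt:
            logger.debug("sample %d: %d clash redraw(s)", i, attempt)
        dbl = geometry.block_length(residue, table)
        row = {"sample": i, "component": ci, "phi_r": tors[0], "psi_r": tors[1]}
        row.update({col: tors[2 + k] for k, col in enumerate(chi_cols)})
        row["dblock"] = np.nan if dbl is None else dbl
        row["redraws"] = attempt
        rows.append(row)
        structures.append(residue)
    truth = pd.DataFrame(rows)
    return structures, truth


sample_ensemble.__doc__ = sample_ensemble.__doc__.format(cap=RETRY_CAP)


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _tripeptide_of(residue: ResidueUnit) -> List[ResidueUnit]:
    out = []
    if residue.prev is not None:
        out.append(residue.prev)
    out.append(residue)
    if residue.next is not None:
        out.append(residue.next)
    return out


def _gemmi_chain(name: str, residues: Sequence[ResidueUnit]) -> gemmi.Chain:
    chain = gemmi.Chain(name)
    for res in residues:
        r = gemmi.Residue()
        r.name = res.res_type
        r.seqid = gemmi.SeqId(res.seq_num, res.icode or " ")
        for a in res.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            atom.occ = a.occupancy
            atom.b_iso = 0.0
            r.add_atom(atom)
        chain.add_residue(r)
    return chain


def write_pdb(structures: Sequence[ResidueUnit], path, mode: str = "models") -> None:
    """Write built structures as a PDB file re-readable by ``structure_io``.

    ``mode="models"``: one MODEL per structure (any count); ``mode="chains"``:
    one chain per structure in a single model (at most 62, the PDB chain-id
    alphabet).  Coordinates are quantized to 3 decimals by the format, which
    perturbs re-measured torsions by well under 0.05°.
    """
    if mode not in ("models", "chains"):
        raise ValueError("mode must be 'models' or 'chains'")
    st = gemmi.Structure()
    st.name = "distalblock synthetic ensemble"
    if mode == "models":
        for i, residue in enumerate(structures):
            model = gemmi.Model(i + 1)
            model.add_chain(_gemmi_chain("A", _tripeptide_of(residue)))
            st.add_model(model)
    else:
        if len(structures) > len(CHAIN_IDS):
            raise ValueError(
                f"chains mode supports at most {len(CHAIN_IDS)} structures")
        model = gemmi.Model(1)
        for i, residue in enumerate(structures):
            model.add_chain(_gemmi_chain(CHAIN_IDS[i], _tripeptide_of(residue)))
        st.add_model(model)
    st.write_pdb(str(path))
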