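"""Reading coordinate files and turning residues into feature records.

This module owns the in-memory model (:class:`AtomRecord`,
:class:`ResidueUnit`), the dataset selection policies (first chain vs all
chains, first alternate conformation), and the extraction of the four
per-residue features φ, ψ, χ1 and dBlock into tabular records.

PDB is the supported input dialect (read through gemmi; only the first MODEL
of a file is used).  HETATM records and waters are excluded on read;
non-standard residues are dropped (and counted) during selection unless
explicitly retained.  Missing features are flagged as missing, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from . import geometry
from .blocktable import BLOCKLESS_RESIDUES, STANDARD_RESIDUES, BlockTable
from .exceptions import DegenerateGeometryError, EmptyStructureError, RecordsParseError

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueUnit",
    "SelectionPolicy",
    "DatasetManifest",
    "ManifestEntry",
    "ConformationRecord",
    "read_structure",
    "apply_selection",
    "extract_records",
    "records_to_frame",
    "frame_to_records",
    "write_records",
    "read_records",
]

#: Maximum C(i)–N(i+1) distance (Å) for two residues to count as peptide-bonded.
PEPTIDE_BOND_CUTOFF = 2.0

RECORD_COLUMNS = (
    "source", "chain", "seq", "icode", "res_type", "phi", "psi", "chi1", "dblock",
)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy-atom coordinate record (a carrier for PDB ATOM fields)."""

    name: str
    element: str
    coords: Tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ResidueUnit:
    """One residue: typed, addressed, holding its atoms and neighbor links.

    Before altloc resolution ``atoms`` may hold several records per atom name;
    :meth:`atom` always returns the first in file order, which is exactly what
    the first-conformation policy keeps.
    """

    res_type: str
    chain_id: str
    seq_num: int
    icode: str = ""
    atoms: List[AtomRecord] = field(default_factory=list)
    prev: Optional["ResidueUnit"] = None
    next: Optional["ResidueUnit"] = None

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> List[str]:
        return [a.name for a in self.atoms]

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_type}{self.seq_num}{self.icode}"


@dataclass(frozen=True)
class SelectionPolicy:
    """Chain/altloc selection applied to a parsed structure.

    ``chains="first"`` mirrors the treatment of crystallographic sets (one
    chain per file); ``chains="all"`` keeps every chain, the choice made for
    small EM sets to retain NCS copies.  Altloc policy is always "first in
    file order".  The policy is configuration, never inferred from the file.
    """

    chains: str = "first"
    altloc: str = "first"
    include_nonstandard: bool = False

    def __post_init__(self):
        if self.chains not in ("first", "all"):
            raise ValueError("chains policy must be 'first' or 'all'")
        if self.altloc != "first":
            raise ValueError("only the 'first' altloc policy is supported")


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    structure_id: str
    method: str = "synthetic"  # xray | em | synthetic
    resolution: Optional[float] = None

    def __post_init__(self):
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive where given")


@dataclass
class DatasetManifest:
    """List of structure files with method/resolution metadata plus a policy."""

    entries: List[ManifestEntry]
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)

    @classmethod
    def from_csv(cls, path, policy: Optional[SelectionPolicy] = None) -> "DatasetManifest":
        frame = pd.read_csv(path, dtype={"id": str})
        entries = []
        base = Path(path).parent
        for row in frame.itertuples(index=False):
            p = Path(str(row.path))
            if not p.is_absolute():
                p = base / p
            res = getattr(row, "resolution", None)
            res = None if res is None or pd.isna(res) else float(res)
            entries.append(ManifestEntry(str(p), str(row.id),
                                         str(getattr(row, "method", "synthetic")), res))
        return cls(entries, policy or SelectionPolicy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"path": e.path, "id": e.structure_id, "method": e.method,
              "resolution": e.resolution} for e in self.entries]
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConformationRecord:
    """The four features of one residue; NaN marks a missing feature."""

    source: str
    chain: str
    seq: int
    icode: str
    res_type: str
    phi: float = float("nan")
    psi: float = float("nan")
    chi1: float = float("nan")
    dblock: float = float("nan")

    @property
    def has_phi(self) -> bool:
        return not np.isnan(self.phi)

    @property
    def has_psi(self) -> bool:
        return not np.isnan(self.psi)

    @property
    def has_chi1(self) -> bool:
        return not np.isnan(self.chi1)

    @property
    def has_dblock(self) -> bool:
        return not np.isnan(self.dblock)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _link_chain(residues: List[ResidueUnit]) -> None:
    """Set prev/next between consecutive residues joined by a peptide bond."""
    for r1, r2 in zip(residues, residues[1:]):
        c = r1.atom("C")
        n = r2.atom("N")
        if c is None or n is None:
            continue
        dist = float(np.linalg.norm(np.subtract(c.coords, n.coords)))
        if dist < PEPTIDE_BOND_CUTOFF:
            r1.next = r2
            r2.prev = r1


def read_structure(path) -> List[List[ResidueUnit]]:
    """Parse a PDB file into chains of :class:`ResidueUnit`.

    Only the first MODEL is used.  HETATM records (ligands, waters, modified
    residues deposited as heteroatoms) are excluded.  All altlocs are retained
    at this stage; chain and atom order follow the file.  Raises
    :class:`EmptyStructureError` when no protein ATOM records remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: List[List[ResidueUnit]] = []
    for chain in model:
        residues: List[ResidueUnit] = []
        for res in chain:
            if res.het_flag != "A":  # HETATM (incl. waters) excluded
                continue
            unit = ResidueUnit(
                res_type=res.name,
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=res.seqid.icode.strip(),
            )
            for atom in res:
                unit.atoms.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    altloc=atom.altloc if atom.altloc != "\0" else "",
                    occupancy=atom.occ,
                ))
            if unit.atoms:
                residues.append(unit)
        if residues:
            _link_chain(residues)
            chains.append(residues)
    if not chains:
        raise EmptyStructureError(f"{path}: no protein residues in ATOM records")
    return chains


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _dedupe_altlocs(residue: ResidueUnit) -> ResidueUnit:
    seen: Dict[str, AtomRecord] = {}
    for a in residue.atoms:
        if a.name not in seen:
            seen[a.name] = a
    return replace_atoms(residue, list(seen.values()))


def replace_atoms(residue: ResidueUnit, atoms: List[AtomRecord]) -> ResidueUnit:
    out = ResidueUnit(residue.res_type, residue.chain_id, residue.seq_num,
                      residue.icode, atoms)
    return out


def apply_selection(chains: Sequence[List[ResidueUnit]],
                    policy: SelectionPolicy) -> List[ResidueUnit]:
    """Apply chain and altloc policies; drop (and count) non-standard residues.

    Returns a flat residue list.  For every atom with alternate conformations
    only the first in file order is kept.  GLY/ALA are retained (they are only
    excluded later, from dBlock statistics).  Idempotent.
    """
    if not chains:
        raise EmptyStructureError("no chains to select from")
    picked = [chains[0]] if policy.chains == "first" else list(chains)
    out: List[ResidueUnit] = []
    n_nonstandard = 0
    for chain in picked:
        kept: List[Tuple[ResidueUnit, ResidueUnit]] = []  # (original, deduped)
        for res in chain:
            if res.res_type not in STANDARD_RESIDUES and not policy.include_nonstandard:
                n_nonstandard += 1
                continue
            kept.append((res, _dedupe_altlocs(res)))
        # re-establish neighbor links only between residues that were linked
        # in the source chain and both survived selection; dropping a residue
        # severs the link, so no torsion is computed across the gap
        for (orig1, new1), (orig2, new2) in zip(kept, kept[1:]):
            if orig1.next is orig2:
                new1.next = new2
                new2.prev = new1
        out.extend(new for _, new in kept)
    if n_nonstandard:
        logger.info("selection dropped %d non-standard residue(s)", n_nonstandard)
    return out


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_records(residues: Sequence[ResidueUnit], block_table: BlockTable,
                    source: str = "") -> List[ConformationRecord]:
    """One :class:`ConformationRecord` per residue (conservation guaranteed).

    φ is missing for chain-start residues, ψ for chain-end residues, χ1 and
    dBlock for GLY/ALA or when a required atom is absent.  Degenerate
    geometry is treated as a missing feature and logged, never an error.
    """
    records: List[ConformationRecord] = []
    n_incomplete = 0
    for res in residues:
        phi = psi = chi = dbl = float("nan")
        n_at, ca_at, c_at = res.atom("N"), res.atom("CA"), res.atom("C")
        try:
            if res.prev is not None and res.prev.atom("C") and n_at and ca_at and c_at:
                phi = geometry.backbone_phi(res.prev.atom("C").coords, n_at.coords,
                                            ca_at.coords, c_at.coords)
            if res.next is not None and res.next.atom("N") and n_at and ca_at and c_at:
                psi = geometry.backbone_psi(n_at.coords, ca_at.coords, c_at.coords,
                                            res.next.atom("N").coords)
            v = geometry.chi1(res, block_table)
            chi = float("nan") if v is None else v
            v = geometry.block_length(res, block_table)
            dbl = float("nan") if v is None else v
        except DegenerateGeometryError as exc:
            logger.warning("degenerate geometry at %s: %s", res.label, exc)
        if res.res_type not in BLOCKLESS_RESIDUES and (np.isnan(chi) or np.isnan(dbl)):
            n_incomplete += 1
        records.append(ConformationRecord(
            source=source, chain=res.chain_id, seq=res.seq_num, icode=res.icode,
            res_type=res.res_type, phi=phi, psi=psi, chi1=chi, dblock=dbl,
        ))
    if n_incomplete:
        logger.info("%s: %d residue(s) with incomplete side-chain features",
                    source or "<memory>", n_incomplete)
    return records


# ---------------------------------------------------------------------------
# record table round trip
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[ConformationRecord]) -> pd.DataFrame:
    rows = [{
        "source": r.source, "chain": r.chain, "seq": r.seq, "icode": r.icode,
        "res_type": r.res_type, "phi": r.phi, "psi": r.psi, "chi1": r.chi1,
        "dblock": r.dblock,
    } for r in records]
    frame = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
    return frame.astype({"seq": "int64"}) if len(frame) else frame


def frame_to_records(frame: pd.DataFrame) -> List[ConformationRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(ConformationRecord(
            source="" if pd.isna(row.source) else str(row.source),
            chain="" if pd.isna(row.chain) else str(row.chain),
            seq=int(row.seq),
            icode="" if pd.isna(row.icode) else str(row.icode),
            res_type=str(row.res_type),
            phi=float(row.phi) if not pd.isna(row.phi) else float("nan"),
            psi=float(row.psi) if not pd.isna(row.psi) else float("nan"),
            chi1=float(row.chi1) if not pd.isna(row.chi1) else float("nan"),
            dblock=float(row.dblock) if not pd.isna(row.dblock) else float("nan"),
        ))
    return records


def write_records(records: Sequence[ConformationRecord], path) -> None:
    """Write records to a delimited text table (CSV, NaN as empty field)."""
    records_to_frame(records).to_csv(path, index=False, float_format="%.6f")


def read_records(path) -> List[ConformationRecord]:
    """Read a record table written by :func:`write_records` (lossless)."""
    try:
        frame = pd.read_csv(path, dtype={"source": str, "chain": str, "icode": str})
    except pd.errors.ParserError as exc:
        raise RecordsParseError(f"{path}: {exc}") from exc
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise RecordsParseError(f"{path}: missing columns {sorted(missing)} (line 1)")
    return frame_to_records(frame)
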