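"""PDB reading, selection policies, feature extraction, record round trips."""

import math

import numpy as np
import pytest

from conftest import pdb_atom_line
from distalblock import (
    SelectionPolicy,
    apply_selection,
    build_residue,
    extract_records,
    read_records,
    read_structure,
    write_pdb,
    write_records,
)
from distalblock.exceptions import EmptyStructureError, RecordsParseError
from distalblock.structure_io import frame_to_records, records_to_frame


def _two_chain_pdb(tmp_path):
    """Two ALA-GLY chains (B a copy of A), with an altloc pair on chain A's CB
    and a HETATM ligand + water appended."""
    lines = []
    serial = 1

    def emit(*args, **kw):
        nonlocal serial
        lines.append(pdb_atom_line(serial, *args, **kw))
        serial += 1

    for chain in "AB":
        # ALA 1 (with CB in two altlocs) — ideal-ish coordinates, bonded C-N
        emit("N", "ALA", chain, 1, 0.0, 0.0, 0.0)
        emit("CA", "ALA", chain, 1, 1.458, 0.0, 0.0)
        emit("C", "ALA", chain, 1, 2.009, 1.42, 0.0)
        emit("O", "ALA", chain, 1, 1.40, 2.44, 0.0)
        emit("CB", "ALA", chain, 1, 1.95, -0.77, 1.20, altloc="A", occ=0.6)
        emit("CB", "ALA", chain, 1, 1.95, -0.77, -1.20, altloc="B", occ=0.4)
        # GLY 2, N placed 1.33 A from C of residue 1
        emit("N", "GLY", chain, 2, 3.33, 1.48, 0.0)
        emit("CA", "GLY", chain, 2, 4.0, 2.7, 0.0)
        emit("C", "GLY", chain, 2, 5.5, 2.6, 0.0)
        emit("O", "GLY", chain, 2, 6.1, 1.55, 0.0)
        lines.append("TER")
    emit("C1", "LIG", "A", 90, 8.0, 8.0, 8.0, hetatm=True)
    emit("O", "HOH", "A", 91, 9.0, 9.0, 9.0, hetatm=True)
    path = tmp_path / "two_chain.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_read_structure_builder_round_trip(tmp_path):
    res = build_residue("LYS", -62, -41, [180, 180, 180, 180])
    path = tmp_path / "tri.pdb"
    write_pdb([res], path)
    chains = read_structure(path)
    assert len(chains) == 1
    assert [r.res_type for r in chains[0]] == ["GLY", "LYS", "GLY"]
    assert chains[0][0].next is chains[0][1]
    assert chains[0][2].prev is chains[0][1]


def test_read_structure_keeps_altlocs_and_drops_hetatm(tmp_path):
    chains = read_structure(_two_chain_pdb(tmp_path))
    assert len(chains) == 2  # HETATM residues gone entirely
    ala = chains[0][0]
    assert len([a for a in ala.atoms if a.name == "CB"]) == 2
    assert {a.altloc for a in ala.atoms if a.name == "CB"} == {"A", "B"}


def test_read_structure_hetatm_only_is_empty(tmp_path):
    path = tmp_path / "ligand.pdb"
    path.write_text(pdb_atom_line(1, "C1", "LIG", "A", 1, 0, 0, 0, hetatm=True)
                    + "\nEND\n")
    with pytest.raises(EmptyStructureError):
        read_structure(path)


def test_read_structure_missing_file():
    with pytest.raises(FileNotFoundError):
        read_structure("/nonexistent/file.pdb")


def test_apply_selection_first_chain_and_first_altloc(tmp_path):
    chains = read_structure(_two_chain_pdb(tmp_path))
    sel = apply_selection(chains, SelectionPolicy(chains="first"))
    assert {r.chain_id for r in sel} == {"A"}
    ala = sel[0]
    cbs = [a for a in ala.atoms if a.name == "CB"]
    assert len(cbs) == 1 and cbs[0].altloc == "A"  # first in file order


def test_apply_selection_all_chains_duplicates_conformations(tmp_path):
    chains = read_structure(_two_chain_pdb(tmp_path))
    sel = apply_selection(chains, SelectionPolicy(chains="all"))
    assert sorted({r.chain_id for r in sel}) == ["A", "B"]
    assert len(sel) == 4


def test_apply_selection_is_idempotent(tmp_path):
    chains = read_structure(_two_chain_pdb(tmp_path))
    once = apply_selection(chains, SelectionPolicy(chains="all"))
    twice = apply_selection([once], SelectionPolicy(chains="all"))
    assert len(once) == len(twice)
    for r1, r2 in zip(once, twice):
        assert r1.res_type == r2.res_type
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
        assert (r1.next is None) == (r2.next is None)


def test_apply_selection_drops_nonstandard(tmp_path):
    lines = [
        pdb_atom_line(1, "N", "MSE", "A", 1, 0, 0, 0),
        pdb_atom_line(2, "CA", "MSE", "A", 1, 1.458, 0, 0),
        pdb_atom_line(3, "N", "GLY", "A", 2, 5, 5, 5),
        pdb_atom_line(4, "CA", "GLY", "A", 2, 6.458, 5, 5),
    ]
    path = tmp_path / "mse.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    sel = apply_selection(read_structure(path), SelectionPolicy())
    assert [r.res_type for r in sel] == ["GLY"]
    kept = apply_selection(read_structure(path),
                           SelectionPolicy(include_nonstandard=True))
    assert [r.res_type for r in kept] == ["MSE", "GLY"]


def test_extract_records_full_feature_set(block_table):
    res = build_residue("LYS", -62, -41, [180, 180, 180, 180])
    residues = [res.prev, res, res.next]
    records = extract_records(residues, block_table, source="synthetic")
    assert len(records) == 3  # conservation
    first, mid, last = records
    assert not first.has_phi and first.has_psi  # chain start
    assert last.has_phi and not last.has_psi    # chain end
    assert mid.has_phi and mid.has_psi and mid.has_chi1 and mid.has_dblock
    assert mid.phi == pytest.approx(298.0, abs=1e-6)
    assert mid.chi1 == pytest.approx(180.0, abs=1e-6)
    # GLY carries neither chi1 nor dBlock
    assert not first.has_chi1 and not first.has_dblock


def test_extract_records_missing_block_atom(block_table):
    res = build_residue("LYS", -62, -41, [180, 180, 180, 180])
    res.atoms = [a for a in res.atoms if a.name != "NZ"]
    rec = extract_records([res.prev, res, res.next], block_table)[1]
    assert rec.has_phi and rec.has_psi and rec.has_chi1
    assert not rec.has_dblock


def test_torsion_round_trip_through_pdb_within_quantization(tmp_path, block_table):
    """Builder -> PDB (3-decimal coords) -> parser -> geometry: 0.05 deg."""
    targets = {"phi": 298.0, "psi": 319.0, "chi1": 287.0}
    res = build_residue("LYS", -62, -41, [287.0, 175.0, 64.0, 180.0])
    path = tmp_path / "round.pdb"
    write_pdb([res], path)
    sel = apply_selection(read_structure(path), SelectionPolicy())
    rec = extract_records(sel, block_table)[1]
    assert rec.phi == pytest.approx(targets["phi"], abs=0.05)
    assert rec.psi == pytest.approx(targets["psi"], abs=0.05)
    assert rec.chi1 == pytest.approx(targets["chi1"], abs=0.05)


def test_records_file_round_trip(tmp_path, block_table):
    res_a = build_residue("LYS", -62, -41, [180, 180, 180, 180])
    res_b = build_residue("GLY", -120, 130, [])
    records = extract_records([res_a.prev, res_a, res_a.next], block_table, "x")
    records += extract_records([res_b], block_table, "y")
    path = tmp_path / "records.csv"
    write_records(records, path)
    back = read_records(path)
    assert len(back) == len(records)
    for r1, r2 in zip(records, back):
        assert (r1.source, r1.chain, r1.seq, r1.res_type) == \
               (r2.source, r2.chain, r2.seq, r2.res_type)
        for feat in ("phi", "psi", "chi1", "dblock"):
            v1, v2 = getattr(r1, feat), getattr(r2, feat)
            assert math.isnan(v1) == math.isnan(v2)
            if not math.isnan(v1):
                assert v2 == pytest.approx(v1, abs=1e-5)


def test_records_empty_round_trip(tmp_path):
    path = tmp_path / "empty.csv"
    write_records([], path)
    assert read_records(path) == []


def test_records_malformed_table(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("just,two,columns\n1,2,3\n")
    with pytest.raises(RecordsParseError):
        read_records(path)


def test_records_frame_conversion_is_lossless(block_table):
    res = build_residue("TYR", -62, -41, [300, 90])
    records = extract_records([res.prev, res, res.next], block_table, "s")
    frame = records_to_frame(records)
    back = frame_to_records(frame)
    assert [r.res_type for r in back] == [r.res_type for r in records]
    assert np.isnan(back[0].chi1) and back[1].chi1 == pytest.approx(300.0, abs=1e-6)
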