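"""Molecular model, PDB I/O, energy tables, and synthetic fixtures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from molsock import (
    Atom,
    EnergyMap,
    MolecularModel,
    Residue,
    make_synthetic_model,
    parse_energies,
    parse_pdb,
    perturb_model,
    serialize_energies,
    toy_score,
    write_pdb,
)
from molsock import wire
from molsock.structures import EmptyModelError, EnergyParseError, PDBParseError


# -- PDB round trip --------------------------------------------------------

def test_pdb_round_trip_preserves_everything(helix10):
    m2 = parse_pdb(write_pdb(helix10), name=helix10.name)
    assert len(m2.residues) == len(helix10.residues)
    assert m2.n_atoms == helix10.n_atoms
    for r1, r2 in zip(helix10.residues, m2.residues):
        assert r1.key == r2.key and r1.name == r2.name
        assert [a.name for a in r1.atoms] == [a.name for a in r2.atoms]
    assert np.abs(m2.coordinates() - helix10.coordinates()).max() <= 0.001


def test_single_atom_at_origin_writes_one_80_column_record():
    m = MolecularModel("pt", (Residue("A", 1, "GLY", (Atom("CA", "C", 0, 0, 0),)),))
    lines = write_pdb(m).splitlines()
    atom_lines = [l for l in lines if l.startswith("ATOM")]
    assert len(atom_lines) == 1
    line = atom_lines[0]
    assert len(line) == 80
    assert line[30:38].strip() == "0.000"
    assert line[38:46].strip() == "0.000"
    assert line[46:54].strip() == "0.000"
    assert line[54:60] == "  1.00" and line[60:66] == "  0.00"
    assert line[76:78] == " C"


def test_two_chain_model_preserves_chain_order():
    res = lambda c, i: Residue(c, i, "ALA", (Atom("CA", "C", float(i), 0.0, 0.0),))
    m = MolecularModel("two", (res("B", 1), res("B", 2), res("A", 1)))
    m2 = parse_pdb(write_pdb(m))
    assert [r.key for r in m2.residues] == [("B", 1), ("B", 2), ("A", 1)]
    text = write_pdb(m)
    assert text.count("\nTER") + text.startswith("TER") == 2  # one TER per chain


def test_against_independent_pdb_reader(helix10):
    biotite_pdb = pytest.importorskip("biotite.structure.io.pdb")
    import io

    f = biotite_pdb.PDBFile.read(io.StringIO(write_pdb(helix10)))
    arr = f.get_structure(model=1)
    assert arr.array_length() == helix10.n_atoms
    assert np.abs(arr.coord - helix10.coordinates()).max() <= 0.001
    assert list(arr.res_id[arr.atom_name == "CA"]) == [r.number for r in helix10.residues]


def test_unknown_records_ignored_and_errors_named_by_line(helix10):
    text = "HEADER    junk\nREMARK  1 more junk\n" + write_pdb(helix10)
    assert parse_pdb(text).n_atoms == helix10.n_atoms
    with pytest.raises(EmptyModelError):
        parse_pdb("REMARK nothing here\n")
    bad = write_pdb(helix10).splitlines()
    bad[2] = bad[2][:30] + "  xx.yyy" + bad[2][38:]
    with pytest.raises(PDBParseError, match="line 3"):
        parse_pdb("\n".join(bad))


# -- energy tables ---------------------------------------------------------

def test_energy_round_trip_exact():
    e = EnergyMap("total", {("A", 1): -2.5, ("A", 2): 0.0})
    payload = serialize_energies(e)
    assert payload.count(b"\n") == 2
    assert parse_energies(payload, "total") == e


def test_empty_energy_map_round_trips():
    e = EnergyMap("total", {})
    assert serialize_energies(e) == b""
    assert parse_energies(b"", "total") == e


def test_large_energy_map_survives_compression_layer():
    rng = np.random.default_rng(0)
    e = EnergyMap("toy_clash", {("A", i + 1): float(v) for i, v in
                                enumerate(rng.normal(size=500))})
    wire_bytes = wire.compress_payload(serialize_energies(e), "bz2")
    back = parse_energies(wire.decompress_payload(wire_bytes, "Ener.bz2"), "toy_clash")
    assert back == e  # bit-exact: repr-faithful float text


def test_non_numeric_energy_field_is_a_parse_error():
    with pytest.raises(EnergyParseError, match="line 1"):
        parse_energies(b"A 1 not-a-number\n")


@given(st.dictionaries(
    st.tuples(st.sampled_from("ABC"), st.integers(1, 999)),
    st.floats(allow_nan=False, allow_infinity=False, width=64),
    max_size=30,
))
def test_energy_serialization_is_exact_for_arbitrary_floats(values):
    e = EnergyMap("t", values)
    assert parse_energies(serialize_energies(e), "t") == e


# -- synthetic fixtures ----------------------------------------------------

def test_synthetic_model_is_deterministic_per_seed():
    a = make_synthetic_model(20, seed=5)
    b = make_synthetic_model(20, seed=5)
    c = make_synthetic_model(20, seed=6)
    assert np.array_equal(a.coordinates(), b.coordinates())
    assert not np.array_equal(a.coordinates(), c.coordinates())


def test_synthetic_model_has_four_backbone_atoms_per_residue():
    m = make_synthetic_model(10, seed=0)
    assert m.n_atoms == 40
    assert [a.name for a in m.residues[0].atoms] == ["N", "CA", "C", "O"]


def test_helix_geometry_gives_peptide_like_ca_spacing():
    m = make_synthetic_model(30, seed=2)
    ca = np.array([a.xyz for r in m.residues for a in r.atoms if a.name == "CA"])
    d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
    assert np.all(np.abs(d - 3.8) <= 0.5)


def test_invalid_residue_count_rejected():
    with pytest.raises(ValueError):
        make_synthetic_model(0)


def test_perturbation_is_bounded_seeded_and_nondestructive(helix10):
    before = helix10.coordinates().copy()
    p1 = perturb_model(helix10, 0.4, seed=9)
    p2 = perturb_model(helix10, 0.4, seed=9)
    assert np.array_equal(helix10.coordinates(), before)  # original untouched
    assert np.array_equal(p1.coordinates(), p2.coordinates())
    # rounding to PDB precision adds at most 0.0005 on top of the bound
    assert np.abs(p1.coordinates() - before).max() <= 0.4 + 0.001
    assert perturb_model(helix10, 0.0, seed=1) is helix10


# -- toy clash score -------------------------------------------------------

def brute_force_clash(m, cutoff=3.0):
    counts = {r.key: 0.0 for r in m.residues}
    for ri in m.residues:
        for rj in m.residues:
            if ri.key == rj.key:
                continue
            for a in ri.atoms:
                for b in rj.atoms:
                    if np.linalg.norm(np.subtract(a.xyz, b.xyz)) <= cutoff:
                        counts[ri.key] += 1
    return counts


def test_two_close_single_atom_residues_each_count_one():
    res = lambda i, x: Residue("A", i, "GLY", (Atom("CA", "C", x, 0.0, 0.0),))
    m = MolecularModel("pair", (res(1, 0.0), res(2, 2.0)))
    assert toy_score(m).values == {("A", 1): 1.0, ("A", 2): 1.0}
    far = MolecularModel("far", (res(1, 0.0), res(2, 10.0)))
    assert toy_score(far).values == {("A", 1): 0.0, ("A", 2): 0.0}


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_toy_score_matches_brute_force_oracle(seed):
    m = perturb_model(make_synthetic_model(20, seed=seed), 0.5, seed=seed)
    assert toy_score(m).values == brute_force_clash(m)


def test_toy_score_invariant_under_translation_and_reordering():
    m = make_synthetic_model(15, seed=4)
    shifted = MolecularModel(m.name, tuple(
        Residue(r.chain_id, r.number, r.name, tuple(
            Atom(a.name, a.element, a.x + 100, a.y - 50, a.z + 7) for a in r.atoms
        )) for r in m.residues
    ))
    assert toy_score(shifted).values == toy_score(m).values
    reordered = MolecularModel(m.name, tuple(reversed(m.residues)))
    assert toy_score(reordered).values == toy_score(m).values
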