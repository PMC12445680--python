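"""Structure I/O, titratable-site definition, slab tallies and distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

from pbem.structure import (AtomRecord, ParseError, ChargeAssignmentError,
                            Structure, TitratableSite, define_sites,
                            edge_to_edge_distance, read_pdb, read_pqr,
                            region_charge_tally, write_pqr)

TOY_PQR = """\
ATOM 1 O PSA A 1 0.000 0.000 0.000 -0.500 1.520
ATOM 2 C PSA A 1 1.200 0.000 0.000 0.250 1.700
HETATM 3 NA ION B 2 5.000 5.000 5.000 1.000 1.200
"""


def make_atoms(coords, charges=None, radii=None, resnums=None, names=None,
               resnames=None, chain="A"):
    coords = np.atleast_2d(coords)
    n = len(coords)
    charges = charges if charges is not None else np.zeros(n)
    radii = radii if radii is not None else np.full(n, 1.7)
    resnums = resnums if resnums is not None else np.arange(1, n + 1)
    names = names or [f"C{i}" for i in range(n)]
    resnames = resnames or ["RES"] * n
    return [AtomRecord(i + 1, names[i], resnames[i], chain, int(resnums[i]),
                       coords[i], float(charges[i]), float(radii[i]))
            for i in range(n)]


class TestPqr:
    def test_toy_file_parses_as_written(self, tmp_path):
        p = tmp_path / "toy.pqr"
        p.write_text(TOY_PQR)
        st = read_pqr(p)
        assert st.n_atoms == 3
        assert st.charges.tolist() == [-0.5, 0.25, 1.0]
        assert st.radii.tolist() == [1.52, 1.7, 1.2]
        assert st.chain_id == ["A", "A", "B"]
        assert st.residue_number.tolist() == [1, 1, 2]

    def test_round_trip_preserves_everything(self, tmp_path):
        p1, p2 = tmp_path / "a.pqr", tmp_path / "b.pqr"
        p1.write_text(TOY_PQR)
        st = read_pqr(p1)
        write_pqr(st, p2)
        st2 = read_pqr(p2)
        assert np.allclose(st.positions, st2.positions)
        assert np.allclose(st.charges, st2.charges)
        assert np.allclose(st.radii, st2.radii)
        assert st.atom_name == st2.atom_name
        # normalized re-write is byte-stable
        p3 = tmp_path / "c.pqr"
        write_pqr(st2, p3)
        assert p2.read_text() == p3.read_text()

    def test_non_numeric_radius_reports_line(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 O PSA A 1 0.0 0.0 0.0 -0.5 oops\n")
        with pytest.raises(ParseError, match="line 1"):
            read_pqr(p)

    def test_wrong_field_count_rejected(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 O PSA A 1 0.0 0.0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_pqr(p)


PDB_ASP = """\
CRYST1  1.000    1.000    1.000  90.00  90.00  90.00 P 1
ATOM      1  N   ASP A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ASP A   1      12.759   7.095  -4.916  1.00  0.00           C
ATOM      4  O   ASP A   1      13.163   7.861  -5.791  1.00  0.00           O
ATOM      5  CB  ASP A   1      10.521   6.284  -4.115  1.00  0.00           C
ATOM      6  CG  ASP A   1       9.915   7.674  -4.210  1.00  0.00           C
ATOM      7  OD1 ASP A   1      10.485   8.552  -4.901  1.00  0.00           O
ATOM      8  OD2 ASP A   1       8.851   7.892  -3.594  1.00  0.00           O
HETATM    9  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O
HETATM   10  O   HOH A 102       4.000   4.000   4.000  1.00  0.00           O
END
"""

PDB_LIGAND = PDB_ASP.replace(
    "HETATM    9  O   HOH A 101       2.000   2.000   2.000  1.00  0.00           O",
    "HETATM    9  C1  LIG A 201       2.000   2.000   2.000  1.00  0.00           C")


class TestPdb:
    def test_asp_charged_from_library_waters_dropped(self, tmp_path):
        p = tmp_path / "asp.pdb"
        p.write_text(PDB_ASP)
        st = read_pdb(p)
        assert "HOH" not in st.residue_name
        i_od1 = st.atom_name.index("OD1")
        assert st.charges[i_od1] == -0.5
        i_n = st.atom_name.index("N")
        assert st.charges[i_n] == -0.47
        assert st.radii[i_od1] == 1.52

    def test_retained_water_kept(self, tmp_path):
        p = tmp_path / "asp.pdb"
        p.write_text(PDB_ASP)
        st = read_pdb(p, retain_waters=["A:101"])
        assert st.residue_name.count("HOH") == 1
        assert 101 in st.residue_number

    def test_unknown_ligand_without_fallback_errors(self, tmp_path):
        p = tmp_path / "lig.pdb"
        p.write_text(PDB_LIGAND)
        with pytest.raises(ChargeAssignmentError, match="LIG"):
            read_pdb(p)
        st = read_pdb(p, zero_charge_fallback=True)
        assert "LIG" in st.residue_name
        assert st.charges[st.residue_name.index("LIG")] == 0.0


class TestSites:
    def _residue(self, resname, names, resnum=1):
        coords = np.arange(len(names) * 3, dtype=float).reshape(-1, 3)
        return make_atoms(coords, names=names,
                          resnames=[resname] * len(names),
                          resnums=[resnum] * len(names))

    def test_asp_site_carries_reference_4(self):
        st = Structure(self._residue("ASP", ["CG", "OD1", "OD2"]))
        sites = define_sites(st)
        assert len(sites) == 1
        assert sites[0].kind == "acid"
        assert sites[0].reference["protonated"] == 4.0

    def test_his_is_three_state_with_both_tautomer_pkas(self):
        st = Structure(self._residue("HIS",
                                     ["CG", "ND1", "CD2", "CE1", "NE2"]))
        sites = define_sites(st)
        assert sites[0].n_states == 3
        assert sites[0].reference["delta_protonated"] == 7.0
        assert sites[0].reference["epsilon_protonated"] == 6.6
        # each deprotonation removes exactly one charge
        assert sites[0].state_charges[1].sum() == pytest.approx(0.0)
        assert sites[0].state_charges[0].sum() == pytest.approx(1.0)

    def test_trp_redox_only_when_flagged(self):
        names = ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3",
                 "CH2"]
        st = Structure(self._residue("TRP", names))
        assert define_sites(st) == []
        sites = define_sites(st, redox_residues=["A:1"])
        assert sites[0].kind == "redox"
        assert sites[0].reference["oxidized"] == 1070.0
        assert sites[0].diff_charges(1).sum() == pytest.approx(1.0)

    def test_missing_state_atoms_error(self):
        st = Structure(self._residue("ASP", ["CG", "OD1"]))  # no OD2
        with pytest.raises(ValueError, match="OD2"):
            define_sites(st)

    def test_fixed_state_honored(self):
        st = Structure(self._residue("HIS",
                                     ["CG", "ND1", "CD2", "CE1", "NE2"]))
        sites = define_sites(st, fixed_states={
            "HIS-A:1": "epsilon_protonated"})
        assert sites[0].fixed_state == "epsilon_protonated"

    def test_state_charge_invariant_enforced(self):
        with pytest.raises(ValueError, match="expected"):
            TitratableSite("x", "acid", [0], ["a", "b"],
                           np.array([[-0.5], [0.0]]), {"b": 4.0})


def _tally_structure(groups):
    """groups: list of (z, charge); builds single-atom ionized groups."""
    atoms = []
    coords, charges = [], []
    for i, (z, q) in enumerate(groups):
        coords.append([0.0, 0.0, z])
        charges.append(0.0)
    atoms = make_atoms(coords, charges=charges,
                       resnames=["GRP"] * len(groups))
    st = Structure(atoms, interfaces=(-20.0, 20.0))
    sites = []
    for i, (z, q) in enumerate(groups):
        kind = "base" if q > 0 else "acid"
        charges_states = np.array([[0.0], [1.0]]) if q > 0 \
            else np.array([[-1.0], [0.0]])
        sites.append(TitratableSite(f"G{i}", kind, [i],
                                    ["deprotonated", "protonated"],
                                    charges_states, {"protonated": 7.0}))
    states = {f"G{i}": ("protonated" if q > 0 else "deprotonated")
              for i, (z, q) in enumerate(groups)}
    return st, sites, states


class TestRegionTally:
    def test_constructed_layer_counts(self):
        groups = [(-18.0, 1), (-17.0, 1), (-16.0, 1),
                  (-18.5, -1), (-17.5, -1), (-16.5, -1), (-15.5, -1)]
        st, sites, states = _tally_structure(groups)
        tally = region_charge_tally(st, sites, states)
        assert tally.n_positive[0] == 3
        assert tally.n_negative[0] == 4
        assert tally.net[0] == -1

    def test_no_ionized_groups_all_zero(self):
        groups = [(-18.0, 1), (5.0, -1)]
        st, sites, states = _tally_structure(groups)
        # force every site into its neutral state
        states = {"G0": "deprotonated", "G1": "protonated"}
        tally = region_charge_tally(st, sites, states)
        assert tally.n_positive.sum() == 0
        assert tally.n_negative.sum() == 0

    def test_interfaces_outside_range_error(self):
        st, sites, states = _tally_structure([(0.0, 1)])
        with pytest.raises(ValueError, match="outside"):
            region_charge_tally(st, sites, states,
                                interfaces=(-100.0, 100.0))

    @given(st_.lists(st_.tuples(
        st_.integers(-199, 199).map(lambda v: v / 10.0),
        st_.sampled_from([-1, 1])),
        min_size=1, max_size=25))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_binning(self, groups):
        st, sites, states = _tally_structure(groups)
        tally = region_charge_tally(st, sites, states)
        # independent oracle: direct loop over 5 Å bins
        edges = np.arange(-20.0, 20.1, 5.0)
        for r in range(len(edges) - 1):
            pos = sum(1 for z, q in groups if q > 0
                      and edges[r] <= z and
                      (z < edges[r + 1] or r == len(edges) - 2
                       and z <= edges[-1]))
            neg = sum(1 for z, q in groups if q < 0
                      and edges[r] <= z and
                      (z < edges[r + 1] or r == len(edges) - 2
                       and z <= edges[-1]))
            assert tally.n_positive[r] == pos
            assert tally.n_negative[r] == neg


class TestEdgeDistance:
    def test_two_single_atom_sidechains(self):
        atoms = make_atoms([[0, 0, 0], [5.0, 0, 0]], names=["CB", "CB"],
                           resnums=[1, 2])
        st = Structure(atoms)
        assert edge_to_edge_distance(st, ("A", 1), ("A", 2)) == \
            pytest.approx(5.0)

    def test_backbone_and_hydrogens_excluded(self):
        atoms = make_atoms([[0, 0, 0], [1, 0, 0], [9, 0, 0], [4, 0, 0]],
                           names=["CB", "CA", "CB", "HB1"],
                           resnums=[1, 1, 2, 2])
        st = Structure(atoms)
        # CA of res1 and HB1 of res2 must be ignored
        assert edge_to_edge_distance(st, ("A", 1), ("A", 2)) == \
            pytest.approx(9.0)

    def test_missing_sidechain_error(self):
        atoms = make_atoms([[0, 0, 0], [5, 0, 0]], names=["CA", "CB"],
                           resnums=[1, 2])
        st = Structure(atoms)
        with pytest.raises(ValueError, match="side-chain"):
            edge_to_edge_distance(st, ("A", 1), ("A", 2))

    def test_symmetric_and_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            na, nb = rng.integers(1, 6, size=2)
            ca = rng.uniform(-10, 10, (na, 3))
            cb = rng.uniform(-10, 10, (nb, 3)) + 15.0
            atoms = make_atoms(np.vstack([ca, cb]),
                               names=[f"CB{i}" for i in range(na + nb)],
                               resnums=[1] * na + [2] * nb)
            st = Structure(atoms)
            d = edge_to_edge_distance(st, ("A", 1), ("A", 2))
            assert d == pytest.approx(
                edge_to_edge_distance(st, ("A", 2), ("A", 1)))
            brute = min(np.linalg.norm(a - b)
                        for a in ca for b in cb)
            assert d == pytest.approx(brute)


class TestConformers:
    def test_conformers_keep_atom_order(self):
        atoms = make_atoms(np.arange(9, dtype=float).reshape(3, 3))
        st = Structure(atoms, conformers=[np.ones((3, 3))])
        st2 = st.with_positions(st.conformers[0])
        assert st2.atom_name == st.atom_name
        assert st2.residue_number.tolist() == st.residue_number.tolist()

    def test_conformer_shape_mismatch_rejected(self):
        atoms = make_atoms(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            Structure(atoms, conformers=[np.zeros((2, 3))])
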