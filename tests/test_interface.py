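"""Footprints, polar contacts, buried areas and superposition."""

import math

import numpy as np
import pytest

from dcxmt.errors import FormatError, SelectionError
from dcxmt.fixtures import (TOY_FOOTPRINT, TOY_N_IONIC, TOY_N_POLAR,
                            toy_complex_model, write_model_pdb)
from dcxmt.interface import (buried_interface_area, contact_footprint,
                             deviation_map, interface_report, ionic_count,
                             polar_contacts, rmsd, superpose)
from dcxmt.sasa import radii_for, shrake_rupley, sphere_points
from dcxmt.structure import ContactParams, StructureModel, read_structure

TUBULIN = {"chains": ["A", "B", "C", "E"]}


def _two_atom_model(distance, res_a=("LYS", "NZ", "N"),
                    res_b=("GLU", "OE1", "O")):
    return StructureModel(
        chain=np.array(["A", "B"]), resnum=np.array([1, 2]),
        icode=np.array(["", ""]), resname=np.array([res_a[0], res_b[0]]),
        atname=np.array([res_a[1], res_b[1]]),
        element=np.array([res_a[2], res_b[2]]),
        xyz=np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]),
        occ=np.ones(2))



class TestReadStructure:
    def test_minimal_pdb_fixture(self, tmp_path):
        (tmp_path / "two.pdb").write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       1.500   0.000   0.000"
            "  1.00  0.00           C\nEND\n")
        m = read_structure(tmp_path / "two.pdb")
        assert m.n_atoms == 2

    def test_highest_occupancy_altloc_kept(self, tmp_path):
        (tmp_path / "alt.pdb").write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.60  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000"
            "  0.40  0.00           C\nEND\n")
        m = read_structure(tmp_path / "alt.pdb")
        assert m.n_atoms == 1
        assert m.xyz[0, 0] == 0.0

    def test_absent_declared_chain_rejected(self, tmp_path):
        write_model_pdb(toy_complex_model(), tmp_path / "toy.pdb")
        with pytest.raises(FormatError, match="absent"):
            read_structure(tmp_path / "toy.pdb", chain_roles={"Z": "DC"})

    def test_pdb_roundtrip_preserves_atoms(self, tmp_path):
        m = toy_complex_model()
        write_model_pdb(m, tmp_path / "toy.pdb")
        back = read_structure(tmp_path / "toy.pdb")
        keyed = {(c, int(r), a): tuple(x) for c, r, a, x in
                 zip(back.chain, back.resnum, back.atname, back.xyz)}
        for c, r, a, x in zip(m.chain, m.resnum, m.atname, m.xyz):
            assert keyed[(c, int(r), a)] == pytest.approx(tuple(x), abs=1e-3)


class TestFootprint:
    @pytest.mark.parametrize("d,inside", [(3.9, True), (4.1, False)])
    def test_cutoff_is_sharp(self, d, inside):
        m = _two_atom_model(d)
        fp = contact_footprint(m, "A", "B")
        assert (len(fp.residues) == 1) is inside

    def test_toy_complex_matches_designed_footprint(self):
        m = toy_complex_model()
        fp = contact_footprint(m, "DC", TUBULIN)
        got = {k: [(c, n, rn) for c, n, rn in v]
               for k, v in fp.by_partner.items()}
        assert got == TOY_FOOTPRINT
        assert [r[1] for r in fp.residues] == [1, 2, 3]

    def test_swap_transposes_pairs(self):
        m = toy_complex_model()
        ab = contact_footprint(m, "DC", TUBULIN)
        ba = contact_footprint(m, TUBULIN, "DC")
        assert {(b, a) for a, b in ab.pair_set} == ba.pair_set

    def test_monotone_in_cutoff(self, random_protein_model):
        m = random_protein_model
        small = contact_footprint(m, "A", "B", ContactParams(d_contact=3.5))
        large = contact_footprint(m, "A", "B", ContactParams(d_contact=4.5))
        assert set(small.residues) <= set(large.residues)
        assert small.pair_set <= large.pair_set

    def test_overlapping_groups_rejected(self):
        m = toy_complex_model()
        with pytest.raises(SelectionError, match="disjoint"):
            contact_footprint(m, "DC", {"chains": ["D", "A"]})

    def test_empty_group_rejected(self):
        m = toy_complex_model()
        with pytest.raises(SelectionError, match="no atoms"):
            contact_footprint(m, {"chains": ["Z"]}, TUBULIN)

    def test_equals_all_pairs_brute_force(self, random_protein_model):
        m = random_protein_model
        cp = ContactParams()
        fp = contact_footprint(m, "A", "B", cp)
        ia = np.flatnonzero(m.chain == "A")
        ib = np.flatnonzero(m.chain == "B")
        brute_pairs = set()
        brute_res = set()
        for a in ia:
            for b in ib:
                if np.linalg.norm(m.xyz[a] - m.xyz[b]) <= cp.d_contact:
                    brute_pairs.add((f"A:{m.resnum[a]}", f"B:{m.resnum[b]}"))
                    brute_res.add(int(m.resnum[a]))
        assert fp.pair_set == brute_pairs
        assert set(fp.residue_numbers) == brute_res


class TestPolarContacts:
    def test_toy_complex_contacts(self):
        m = toy_complex_model()
        pc = polar_contacts(m, "DC", TUBULIN)
        assert len(pc) == TOY_N_POLAR
        assert ionic_count(pc) == TOY_N_IONIC
        types = dict(zip(pc.a_atom, pc.type))
        assert types == {"NZ": "salt-bridge", "OG": "H-bond"}

    @pytest.mark.parametrize("d,n", [(3.0, 1), (5.0, 0)])
    def test_lysine_glutamate_pair(self, d, n):
        m = _two_atom_model(d)
        pc = polar_contacts(m, "A", "B")
        assert len(pc) == n
        if n:
            assert pc.type.iloc[0] == "salt-bridge"

    def test_salt_bridge_beyond_polar_cutoff_still_counts(self):
        # charged pair at 3.8 A: beyond d_polar (3.5) but within d_salt (4.0)
        pc = polar_contacts(_two_atom_model(3.8), "A", "B")
        assert list(pc.type) == ["salt-bridge"]

    def test_uncharged_pair_beyond_polar_cutoff_is_not_a_contact(self):
        pc = polar_contacts(_two_atom_model(3.8, res_a=("SER", "OG", "O")),
                            "A", "B")
        assert pc.empty

    def test_histidine_charge_is_configurable(self):
        m = _two_atom_model(3.8, res_a=("HIS", "NE2", "N"))
        assert list(polar_contacts(m, "A", "B").type) == ["salt-bridge"]
        off = polar_contacts(m, "A", "B", ContactParams(his_charged=False))
        assert off.empty

    def test_within_footprint_when_cutoffs_nested(self, random_protein_model):
        m = random_protein_model
        cp = ContactParams()     # d_polar, d_salt <= d_contact
        fp = contact_footprint(m, "A", "B", cp)
        pc = polar_contacts(m, "A", "B", cp)
        for row in pc.itertuples():
            assert (f"{row.a_chain}:{row.a_resnum}",
                    f"{row.b_chain}:{row.b_resnum}") in fp.pair_set

    def test_equals_all_pairs_brute_force(self, random_protein_model):
        m = random_protein_model
        cp = ContactParams()
        pc = polar_contacts(m, "A", "B", cp)
        got = {(int(r.a_resnum), r.a_atom, int(r.b_resnum), r.b_atom): r.type
               for r in pc.itertuples()}
        pos = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"},
               "HIS": {"ND1", "NE2"}}
        neg = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}
        expect = {}
        for a in np.flatnonzero(m.chain == "A"):
            for b in np.flatnonzero(m.chain == "B"):
                d = np.linalg.norm(m.xyz[a] - m.xyz[b])
                charged = (
                    (m.atname[a] in pos.get(m.resname[a], ()) and
                     m.atname[b] in neg.get(m.resname[b], ())) or
                    (m.atname[a] in neg.get(m.resname[a], ()) and
                     m.atname[b] in pos.get(m.resname[b], ())))
                salty = charged and d <= cp.d_salt
                hbond = (m.element[a] in "NO" and m.element[b] in "NO"
                         and d <= cp.d_polar)
                if salty or hbond:
                    expect[(int(m.resnum[a]), m.atname[a],
                            int(m.resnum[b]), m.atname[b])] = \
                        "salt-bridge" if salty else "H-bond"
        assert got == expect


class TestSASA:
    def test_single_sphere_matches_closed_form(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert area[0] == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)

    def test_distant_spheres_are_independent(self):
        xyz = np.array([[0.0, 0, 0], [50.0, 0, 0]])
        areas = shrake_rupley(xyz, np.array([1.7, 1.52]))
        assert areas[0] == pytest.approx(4 * math.pi * 3.1 ** 2, rel=0.01)
        assert areas[1] == pytest.approx(4 * math.pi * 2.92 ** 2, rel=0.01)

    def test_enclosed_atom_has_zero_area(self):
        shell = 2.5 * sphere_points(48)
        xyz = np.vstack([[0.0, 0, 0], shell])
        areas = shrake_rupley(xyz, np.full(len(xyz), 1.7))
        assert areas[0] == 0.0

    def test_agrees_with_independent_implementation(self):
        import biotite.structure as struc

        m = toy_complex_model()
        radii = radii_for(m.element)
        arr = struc.AtomArray(m.n_atoms)
        arr.coord = m.xyz.astype(np.float32)
        arr.chain_id = m.chain
        arr.res_id = m.resnum
        arr.res_name = m.resname
        arr.atom_name = m.atname
        arr.element = m.element
        ref = struc.sasa(arr, probe_radius=1.4, vdw_radii=radii,
                         point_number=960)
        ours = shrake_rupley(m.xyz, radii, 1.4, 960)
        assert ours.sum() == pytest.approx(float(ref.sum()), rel=0.01)


class TestBuriedArea:
    def test_separated_bodies_bury_nothing(self):
        m = toy_complex_model()
        assert buried_interface_area(m, "DC", {"chains": ["E"]}) == 0.0

    def test_positive_for_contacting_groups(self):
        m = toy_complex_model()
        assert buried_interface_area(m, "DC", TUBULIN) > 10.0

    def test_both_sides_convention_halves(self):
        m = toy_complex_model()
        half = buried_interface_area(m, "DC", TUBULIN, both_sides=True)
        full = buried_interface_area(m, "DC", TUBULIN, both_sides=False)
        assert full == pytest.approx(2 * half)

    def test_invariant_under_rigid_motion(self):
        from scipy.spatial.transform import Rotation

        m = toy_complex_model()
        a0 = buried_interface_area(m, "DC", TUBULIN)
        rot = Rotation.from_euler("zyx", [33, -20, 75], degrees=True)
        moved = m.transformed(rot.as_matrix(), np.array([11.0, -4.0, 8.0]))
        a1 = buried_interface_area(moved, "DC", TUBULIN)
        assert a1 == pytest.approx(a0, rel=0.005)


class TestSuperposition:
    def test_identical_models_have_zero_residuals(self):
        m = toy_complex_model()
        res = superpose(m, m, {"chains": ["D"]})
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_known_rigid_transform_recovered(self):
        from scipy.spatial.transform import Rotation

        m = toy_complex_model()
        rot = Rotation.from_euler("xyz", [10, 25, -40], degrees=True)
        moved = m.transformed(rot.as_matrix(), np.array([5.0, -3.0, 2.0]))
        res = superpose(m, moved, {"chains": ["D", "A", "B"]})
        assert res.residuals.max() < 1e-6
        # recovered rotation undoes the applied one
        assert res.rotation @ rot.as_matrix() == pytest.approx(np.eye(3),
                                                               abs=1e-9)

    def test_two_atom_rmsd_without_fit(self):
        a = _two_atom_model(5.0)
        b = a.take([0, 1])
        b.xyz = a.xyz + np.array([[1.0, 0, 0], [0.0, 0, 0]])
        assert rmsd(a, b, {"chains": ["A", "B"]}, fit=False) == \
            pytest.approx(math.sqrt(0.5))

    def test_resnum_offset_pairing(self):
        m = toy_complex_model()
        shifted = m.take(np.arange(m.n_atoms))
        shifted.resnum = m.resnum + 5
        val = rmsd(m, shifted, {"chains": ["D"]}, fit=False, resnum_offset=5)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_unpairable_selection_rejected(self):
        m = toy_complex_model()
        other = m.take(m.chain == "A")
        with pytest.raises(SelectionError):
            superpose(m, other, {"chains": ["D"]})

    def test_deviation_map_identical_models(self):
        m = toy_complex_model()
        dev = deviation_map(m, m, {"chains": ["D"]}, {"chains": ["D"]})
        assert dev.attrs["max_A"] == pytest.approx(0.0, abs=1e-12)

    def test_deviation_map_localises_perturbation(self):
        m = toy_complex_model()
        bumped = m.take(np.arange(m.n_atoms))
        bumped.xyz = m.xyz.copy()
        target = np.flatnonzero((m.chain == "D") & (m.atname == "NZ"))[0]
        bumped.xyz[target] += [0.0, 0.0, 0.7]
        dev = deviation_map(m, bumped, {"chains": ["A", "B", "C", "E"]},
                            {"chains": ["D"]})
        assert dev.attrs["max_A"] == pytest.approx(0.7, abs=1e-6)
        assert dev.attrs["argmax"][2] == "NZ"


class TestInterfaceReport:
    def test_bundles_all_measurements(self):
        m = toy_complex_model()
        rep = interface_report(m, "DC", TUBULIN)
        assert rep.n_polar == TOY_N_POLAR
        assert rep.n_ionic == TOY_N_IONIC
        assert rep.buried_area_A2 > 0
        d = rep.to_dict()
        assert d["params"]["d_contact"] == 4.0
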