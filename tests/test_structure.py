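"""PDB handling, virtual mutagenesis, site geometry and clash detection."""

import io

import numpy as np
import pytest

import degradock as dd
from degradock.structure import (AA_3TO1, BACKBONE_ATOMS, MutationSpec,
                                 PDBFormatError, StructureError, get_residue,
                                 pdb_string, residue_coords, site_atom_coords,
                                 structure_coords, vdw_radius)

PAPER_MUTATIONS = [MutationSpec("A", 71, "V", "A"),
                   MutationSpec("A", 72, "A", "V"),
                   MutationSpec("A", 74, "L", "F"),
                   MutationSpec("A", 81, "R", "K")]


class TestPdbIO:
    def test_parse_counts(self, surrogate_structure):
        chains = {c.name: len(c) for c in surrogate_structure[0]}
        assert chains == {"A": 6, "B": 3}

    def test_roundtrip_preserves_coordinates(self, surrogate_structure):
        text = pdb_string(surrogate_structure)
        again = dd.read_pdb(text)
        c0, e0 = structure_coords(surrogate_structure)
        c1, e1 = structure_coords(again)
        assert e0 == e1
        assert np.allclose(c0, c1, atol=1e-3)

    def test_non_numeric_coordinate_names_line(self):
        bad = ("ATOM      1  CA  GLY A   1      xx.xxx   0.000   0.000"
               "  1.00  0.00           C\nEND\n")
        with pytest.raises(PDBFormatError, match="line 1"):
            dd.read_pdb(io.StringIO(bad))


class TestDeleteComponents:
    def test_delete_whole_chain(self, surrogate_structure):
        out = dd.delete_components(surrogate_structure, "B")
        assert [c.name for c in out[0]] == ["A"]
        # chain A untouched, atom for atom
        a0, _ = structure_coords(dd.delete_components(surrogate_structure, "B"))
        assert len(a0) == sum(len(r) for r in surrogate_structure[0]["A"])

    def test_delete_residue_range(self, surrogate_structure):
        out = dd.delete_components(surrogate_structure, "A:71-73")
        assert [r.seqid.num for r in out[0]["A"]] == [74, 75, 81]

    def test_delete_missing_chain_raises(self, surrogate_structure):
        with pytest.raises(StructureError):
            dd.delete_components(surrogate_structure, "Z")

    def test_delete_empty_range_raises(self, surrogate_structure):
        with pytest.raises(StructureError):
            dd.delete_components(surrogate_structure, "A:500-510")


class TestMutagenesis:
    def test_truncation_v_to_a(self, surrogate_structure):
        out = dd.apply_mutations(surrogate_structure, MutationSpec("A", 71, "V", "A"))
        res = get_residue(out, "A", 71)
        assert res.name == "ALA"
        assert sorted(a.name for a in res) == ["C", "CA", "CB", "N", "O"]
        before = residue_coords(get_residue(surrogate_structure, "A", 71))[:5]
        after = residue_coords(res)
        assert np.allclose(before, after)

    def test_surrogate_mutation_set(self, surrogate_structure):
        out = dd.apply_mutations(surrogate_structure, PAPER_MUTATIONS)
        names = {r.seqid.num: r.name for r in out[0]["A"]}
        assert names[71] == "ALA" and names[72] == "VAL"
        assert names[74] == "PHE" and names[81] == "LYS"
        assert names[73] == "GLY" and names[75] == "SER"  # untouched
        # zero backbone movement at every mutated position
        for spec in PAPER_MUTATIONS:
            r_old = get_residue(surrogate_structure, "A", spec.position)
            r_new = get_residue(out, "A", spec.position)
            for atom_name in BACKBONE_ATOMS + ("CB",):
                old = [a for a in r_old if a.name == atom_name]
                new = [a for a in r_new if a.name == atom_name]
                if old and new:
                    assert old[0].pos.dist(new[0].pos) < 1e-9

    def test_lysine_rebuild_ideal_bond_lengths(self, surrogate_structure):
        out = dd.apply_mutations(surrogate_structure, MutationSpec("A", 81, "R", "K"))
        res = get_residue(out, "A", 81)
        pos = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
        for a, b, ideal in [("CB", "CG", 1.52), ("CG", "CD", 1.52),
                            ("CD", "CE", 1.52), ("CE", "NZ", 1.47)]:
            assert np.linalg.norm(pos[a] - pos[b]) == pytest.approx(ideal, abs=0.02)

    def test_wrong_from_residue_raises(self, surrogate_structure):
        with pytest.raises(StructureError, match="71"):
            dd.apply_mutations(surrogate_structure, MutationSpec("A", 71, "L", "A"))

    def test_self_mutation_idempotent(self, surrogate_structure):
        once = dd.apply_mutations(surrogate_structure, MutationSpec("A", 75, "S", "S"))
        twice = dd.apply_mutations(once, MutationSpec("A", 75, "S", "S"))
        c1, _ = structure_coords(once)
        c2, _ = structure_coords(twice)
        assert np.allclose(c1, c2)

    def test_mutation_then_reverse_restores_name_and_backbone(self, surrogate_structure):
        fwd = dd.apply_mutations(surrogate_structure, MutationSpec("A", 71, "V", "F"))
        back = dd.apply_mutations(fwd, MutationSpec("A", 71, "F", "V"))
        r0 = get_residue(surrogate_structure, "A", 71)
        r1 = get_residue(back, "A", 71)
        assert r1.name == r0.name
        for atom_name in ("N", "CA", "C", "O", "CB"):
            a0 = next(a for a in r0 if a.name == atom_name)
            a1 = next(a for a in r1 if a.name == atom_name)
            assert a0.pos.dist(a1.pos) < 1e-9

    def test_parse_compact_notation(self):
        spec = MutationSpec.parse("V71A")
        assert spec == MutationSpec("A", 71, "V", "A")


class TestClashes:
    def test_two_carbons_just_inside_threshold(self):
        # C-C threshold 1.70 + 1.70 - 0.4 = 3.0
        pairs = dd.find_clashes([[0, 0, 0]], [[2.9, 0, 0]])
        assert pairs == [(0, 0)]

    def test_two_carbons_just_outside_threshold(self):
        assert dd.find_clashes([[0, 0, 0]], [[3.1, 0, 0]]) == []

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        elements = ["C", "N", "O", "S"]
        for _ in range(30):
            A = rng.uniform(-5, 5, (20, 3))
            B = rng.uniform(-5, 5, (20, 3))
            ea = rng.choice(elements, 20).tolist()
            eb = rng.choice(elements, 20).tolist()
            got = dd.find_clashes(A, B, 0.4, ea, eb)
            expected = sorted(
                (i, j)
                for i in range(20) for j in range(20)
                if np.linalg.norm(A[i] - B[j]) < vdw_radius(ea[i]) + vdw_radius(eb[j]) - 0.4)
            assert got == expected

    def test_symmetric_pair_sets(self):
        rng = np.random.default_rng(7)
        A = rng.uniform(-3, 3, (10, 3))
        B = rng.uniform(-3, 3, (10, 3))
        ab = set(dd.find_clashes(A, B))
        ba = {(j, i) for i, j in dd.find_clashes(B, A)}
        assert ab == ba


class TestSite:
    def test_centroid_is_pooled_atom_mean(self, surrogate_structure):
        site = dd.define_site(surrogate_structure, [("A", 71), ("A", 81)])
        coords = np.vstack([residue_coords(get_residue(surrogate_structure, "A", 71)),
                            residue_coords(get_residue(surrogate_structure, "A", 81))])
        assert np.allclose(site.centroid, coords.mean(axis=0))
        assert site.radius == 8.0

    def test_duplicate_residue_same_centroid(self, surrogate_structure):
        one = dd.define_site(surrogate_structure, [("A", 71)])
        two = dd.define_site(surrogate_structure, [("A", 71), ("A", 71)])
        assert np.allclose(one.centroid, two.centroid)

    def test_missing_residue_raises(self, surrogate_structure):
        with pytest.raises(StructureError):
            dd.define_site(surrogate_structure, [("A", 999)])

    def test_min_site_distance_exact_cases(self, surrogate_structure):
        site = dd.define_site(surrogate_structure, [("A", 81)])
        atoms = site_atom_coords(surrogate_structure, site)
        anchor = atoms[np.argmax(atoms[:, 0])]  # extreme atom: nearest by construction
        assert dd.min_site_distance([anchor + [4.9, 0, 0]], surrogate_structure,
                                    site) == pytest.approx(4.9, abs=1e-9)
        assert dd.min_site_distance([anchor], surrogate_structure, site) == 0.0

    def test_min_site_distance_matches_brute_force(self, surrogate_structure):
        rng = np.random.default_rng(3)
        site = dd.define_site(surrogate_structure, [("A", 71), ("A", 81)])
        S = site_atom_coords(surrogate_structure, site)
        for _ in range(20):
            lig = rng.uniform(-10, 40, (30, 3))
            expected = min(np.linalg.norm(l - s) for l in lig for s in S)
            assert dd.min_site_distance(lig, surrogate_structure, site) == \
                pytest.approx(expected, rel=1e-12)

    def test_translation_rotation_invariance(self, surrogate_pdb_text):
        st = dd.read_pdb(surrogate_pdb_text)
        site = dd.define_site(st, [("A", 81)])
        rng = np.random.default_rng(9)
        lig = rng.uniform(0, 10, (5, 3))
        d0 = dd.min_site_distance(lig, st, site)
        # rotate + translate everything together
        from degradock.geometry import rotvec_to_matrix
        R = rotvec_to_matrix(np.array([0.3, -1.2, 0.7]))
        shift = np.array([5.0, -3.0, 11.0])
        st2 = dd.read_pdb(surrogate_pdb_text)
        for chain in st2[0]:
            for res in chain:
                for atom in res:
                    p = R @ np.array([atom.pos.x, atom.pos.y, atom.pos.z]) + shift
                    atom.pos.x, atom.pos.y, atom.pos.z = p
        site2 = dd.define_site(st2, [("A", 81)])
        d1 = dd.min_site_distance(lig @ R.T + shift, st2, site2)
        assert d1 == pytest.approx(d0, abs=1e-9)
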