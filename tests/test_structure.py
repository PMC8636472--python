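"""Structure editing, Hoogsteen tetrad detection, ion placement, building."""

import numpy as np
import pandas as pd
import pytest

from quadstruct.sequences import OligoSequence, apply_methylation, c9_22mer, find_cpg_sites
from quadstruct.structure import (
    ATOM_COLUMNS,
    ConnectivityError,
    GQStructure,
    SelectionError,
    TopologyError,
    add_methyl_cpg,
    append_residue_3prime,
    build_ideal_gq,
    count_clashes,
    delete_residues,
    detect_tetrads,
    join_strands,
    mutate_base,
    place_interplane_ions,
    read_pdb,
    write_pdb,
)
from quadstruct.templates import base_atom_names
from support import four_strand_fixture as _multi_chain_fixture


class TestPDBRoundtrip:
    def test_roundtrip_atoms(self, tmp_path, ideal_ap):
        path = tmp_path / "gq.pdb"
        write_pdb(ideal_ap, path)
        back = read_pdb(path)
        assert len(back) == len(ideal_ap)
        assert list(back.atoms["name"]) == list(ideal_ap.atoms["name"])
        assert np.allclose(back.coords(), ideal_ap.coords(), atol=1.5e-3)

    def test_four_chains(self, tmp_path):
        s = _multi_chain_fixture()
        path = tmp_path / "four.pdb"
        write_pdb(s, path)
        assert read_pdb(path).chains == ["A", "B", "C", "D"]

    def test_multi_model(self, tmp_path, ideal_ap):
        dfs = []
        for m in (1, 2, 3):
            df = ideal_ap.atoms.copy()
            df["model"] = m
            df[["x", "y", "z"]] += (m - 1) * 0.5
            dfs.append(df)
        multi = GQStructure(pd.concat(dfs, ignore_index=True))
        path = tmp_path / "multi.pdb"
        write_pdb(multi, path)
        assert read_pdb(path).models == [1, 2, 3]


class TestDelete:
    def test_delete_t1_t2_all_chains(self):
        s = _multi_chain_fixture()
        out = delete_residues(s, [(c, r) for c in "ABCD" for r in (1, 2)])
        res = out.residues()
        assert all((res[res["chain"] == c]["resseq"].tolist() == [3, 4, 5, 6, 7])
                   for c in "ABCD")

    def test_delete_nothing_identity(self):
        s = _multi_chain_fixture()
        out = delete_residues(s, [])
        pd.testing.assert_frame_equal(out.atoms, s.atoms)

    def test_unresolvable_selection(self):
        with pytest.raises(SelectionError):
            delete_residues(_multi_chain_fixture(), [("Z", 99)])


class TestMutate:
    def test_t_to_g_atom_names(self):
        s = _multi_chain_fixture()
        out = mutate_base(s, ("A", 7), "DG")
        sub = out.residue_atoms("A", 7)
        assert sub["resname"].iloc[0] == "DG"
        assert set(base_atom_names("DG")) <= set(sub["name"])
        assert "O2" not in set(sub["name"])  # thymine carbonyl gone

    def test_identity_mutation_preserves_shared_atoms(self):
        s = _multi_chain_fixture()
        before = s.residue_atoms("B", 3).set_index("name")[["x", "y", "z"]]
        out = mutate_base(s, ("B", 3), "DG")
        after = out.residue_atoms("B", 3).set_index("name")[["x", "y", "z"]]
        shared = before.index.intersection(after.index)
        assert np.allclose(before.loc[shared], after.loc[shared], atol=1e-6)

    def test_mutation_conserves_other_atoms(self):
        s = _multi_chain_fixture()
        out = mutate_base(s, ("A", 7), "DG")
        others_before = s.atoms[~((s.atoms["chain"] == "A") & (s.atoms["resseq"] == 7))]
        others_after = out.atoms[~((out.atoms["chain"] == "A") & (out.atoms["resseq"] == 7))]
        assert np.array_equal(others_before[["x", "y", "z"]].to_numpy(),
                              others_after[["x", "y", "z"]].to_numpy())

    def test_debromination(self):
        s = _multi_chain_fixture(brominate={("A", 3)})
        assert (s.residue_atoms("A", 3)["name"] == "BR").any()
        out = mutate_base(s, ("A", 3), "DG")
        sub = out.residue_atoms("A", 3)
        assert sub["resname"].iloc[0] == "DG"
        assert not (sub["name"] == "BR").any()
        assert len(sub) == len(s.residue_atoms("A", 3)) - 1


class TestAppend:
    def test_append_dc_all_chains(self):
        s = _multi_chain_fixture()
        for c in "ABCD":
            s = append_residue_3prime(s, c, "DC")
        res = s.residues()
        for c in "ABCD":
            sub = res[res["chain"] == c]
            assert len(sub) == 8
            assert sub.iloc[-1]["resname"] == "DC"

    def test_appended_dc_has_19_heavy_atoms(self):
        s = append_residue_3prime(_multi_chain_fixture(), "A", "DC")
        sub = s.residue_atoms("A", 8)
        assert len(sub) == 19
        assert np.isfinite(sub[["x", "y", "z"]].to_numpy()).all()

    def test_missing_chain(self):
        with pytest.raises(SelectionError):
            append_residue_3prime(_multi_chain_fixture(), "Z", "DC")


class TestJoin:
    def _edited(self):
        """The published four-strand edit recipe: delete T1-T2, mutate T7->G,
        append 3' dC, then fuse the strands."""
        s = _multi_chain_fixture()
        s = delete_residues(s, [(c, r) for c in "ABCD" for r in (1, 2)])
        for c in "ABCD":
            s = mutate_base(s, (c, 7), "DG")
        for c in "ABCD":
            s = append_residue_3prime(s, c, "DC")
        return s

    def test_four_strands_to_24mer(self):
        joined = join_strands(self._edited(), list("ABCD"))
        assert joined.chains == ["A"]
        res = joined.residues()
        assert len(res) == 24
        assert res["resseq"].tolist() == list(range(1, 25))

    def test_three_junction_records_with_gaps(self):
        joined = join_strands(self._edited(), list("ABCD"))
        junctions = joined.metadata["junctions"]
        assert len(junctions) == 3
        assert all(j["gap_A"] > 0 for j in junctions)

    def test_single_chain_identity_renumber(self, ideal_ap):
        out = join_strands(ideal_ap, ["A"])
        assert out.metadata["junctions"] == []
        assert len(out.residues()) == len(ideal_ap.residues())

    def test_missing_junction_atoms(self):
        s = _multi_chain_fixture()
        # strip the 5' phosphate of chain B -> junction A->B unbondable
        df = s.atoms[~((s.atoms["chain"] == "B") & (s.atoms["resseq"] == 1)
                       & (s.atoms["name"] == "P"))]
        with pytest.raises(ConnectivityError):
            join_strands(GQStructure(df), list("ABCD"))


class TestMethylation:
    def test_22mer_three_sites(self, ideal_ap):
        out = add_methyl_cpg(ideal_ap, c9_22mer(methylated=True))
        res = out.residues()
        assert (res["resname"] == "5CM").sum() == 3
        assert len(out) == len(ideal_ap) + 3

    def test_no_flags_identity(self, ideal_ap):
        out = add_methyl_cpg(ideal_ap, c9_22mer(methylated=False))
        assert len(out) == len(ideal_ap)

    def test_methyl_geometry(self, ideal_ap):
        """New C-C5 bond 1.50 +/- 0.01 A, methyl in the base plane."""
        from quadstruct.geometry import fit_plane
        out = add_methyl_cpg(ideal_ap, c9_22mer(methylated=True))
        res = out.residues()
        for _, r in res[res["resname"] == "5CM"].iterrows():
            c5 = out.atom_xyz(r["chain"], r["resseq"], "C5")
            c7 = out.atom_xyz(r["chain"], r["resseq"], "C7")
            assert np.linalg.norm(c7 - c5) == pytest.approx(1.50, abs=0.01)
            ring = np.array([out.atom_xyz(r["chain"], r["resseq"], n)
                             for n in ("N1", "C2", "N3", "C4", "C5", "C6")])
            centroid, normal = fit_plane(ring)
            assert abs(np.dot(c7 - centroid, normal)) < 0.05
            # directed away from the ring centroid
            assert np.linalg.norm(c7 - centroid) > np.linalg.norm(c5 - centroid)

    def test_non_cpg_site_rejected(self, ideal_ap):
        with pytest.raises(SelectionError):
            add_methyl_cpg(ideal_ap, [("A", 1)])  # a guanine


class TestTetradDetection:
    def test_ideal_22mer_four_tetrads(self, ap_tetrads):
        assert len(ap_tetrads) == 4
        assert [t.stack_index for t in ap_tetrads] == [0, 1, 2, 3]
        for t in ap_tetrads:
            assert np.linalg.norm(t.normal) == pytest.approx(1.0)

    def test_duplex_fixture_no_tetrads(self):
        assert detect_tetrads(_multi_chain_fixture("ACGTACG", "AB")) == []

    def test_displaced_guanine_breaks_its_tetrad(self, ideal_ap, ap_tetrads):
        # a rigid shift of all four guanines would preserve the quartet, so
        # pull a single guanine 5 A out to violate the Hoogsteen cutoff
        df = ideal_ap.atoms.copy()
        chain, resseq = ap_tetrads[0].residues[0]
        mask = (df["chain"] == chain) & (df["resseq"] == resseq)
        df.loc[mask, ["x", "y", "z"]] += 5.0
        assert len(detect_tetrads(GQStructure(df))) == 3

    def test_rotation_translation_invariance(self, ideal_ap, ap_tetrads):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("zyx", [31.0, -47.0, 112.0], degrees=True).as_matrix()
        df = ideal_ap.atoms.copy()
        df[["x", "y", "z"]] = df[["x", "y", "z"]].to_numpy() @ R.T + [10.0, -3.0, 7.5]
        tets = detect_tetrads(GQStructure(df))
        assert len(tets) == 4
        assert [frozenset(t.residues) for t in tets] == \
            [frozenset(t.residues) for t in ap_tetrads]


class TestIons:
    def test_four_tetrads_three_ions(self, ideal_ap, ap_tetrads):
        out = place_interplane_ions(ideal_ap, ap_tetrads)
        assert (out.atoms["resname"] == "K").sum() == 3

    def test_two_tetrads_midpoint(self, ideal_ap, ap_tetrads):
        out = place_interplane_ions(ideal_ap, ap_tetrads[:2])
        k = out.atoms[out.atoms["resname"] == "K"]
        assert len(k) == 1
        kxyz = k[["x", "y", "z"]].to_numpy()[0]
        cents = []
        for t in ap_tetrads[:2]:
            pts = [ideal_ap.atom_xyz(c, r, "O6") for c, r in t.residues]
            cents.append(np.mean(pts, axis=0))
        d0, d1 = (np.linalg.norm(kxyz - c) for c in cents)
        assert abs(d0 - d1) < 0.1

    def test_single_tetrad_warns(self, ideal_ap, ap_tetrads):
        with pytest.warns(UserWarning):
            out = place_interplane_ions(ideal_ap, ap_tetrads[:1])
        assert (out.atoms["resname"] == "K").sum() == 0


class TestBuilder:
    def test_22mer_antiparallel(self, ideal_ap):
        assert len(ideal_ap.residues()) == 22
        assert len(detect_tetrads(ideal_ap)) == 4
        assert count_clashes(ideal_ap) == 0

    def test_parallel(self, ideal_p):
        assert len(detect_tetrads(ideal_p)) == 4
        assert count_clashes(ideal_p) == 0

    @pytest.mark.parametrize("tract_len", [2, 3, 4, 5])
    def test_tetrad_count_equals_tract_length(self, tract_len):
        seq = OligoSequence(bases=("G" * tract_len + "CC") * 3 + "G" * tract_len)
        gq = build_ideal_gq(seq, topology="antiparallel")
        assert len(detect_tetrads(gq)) == tract_len
        assert count_clashes(gq) == 0

    def test_planar_tetrads_zero_buckle(self, ideal_ap, ap_tetrads):
        from quadstruct.geometry import angle_between_normals, fit_plane
        from quadstruct.templates import ring_atom_names
        for t in ap_tetrads:
            for chain, resseq in t.residues:
                sub = ideal_ap.residue_atoms(chain, resseq)
                ring = sub[sub["name"].isin(ring_atom_names("DG"))]
                _, n = fit_plane(ring[["x", "y", "z"]].to_numpy())
                assert angle_between_normals(n, t.normal) < 0.5

    def test_no_tracts_rejected(self):
        with pytest.raises(TopologyError):
            build_ideal_gq(OligoSequence(bases="ACGTACGTACGT"))

    def test_determinism(self, ideal_ap):
        again = build_ideal_gq(c9_22mer(), topology="antiparallel")
        assert np.array_equal(again.coords(), ideal_ap.coords())


class TestClashes:
    def test_two_close_atoms(self):
        df = pd.DataFrame([
            (1, "A", 1, "DG", "O6", "O", 0.0, 0.0, 0.0, 1.0),
            (1, "A", 5, "DG", "O6", "O", 1.0, 0.0, 0.0, 1.0),
        ], columns=ATOM_COLUMNS)
        assert count_clashes(GQStructure(df)) == 1

    def test_single_atom(self):
        df = pd.DataFrame([(1, "A", 1, "DG", "O6", "O", 0.0, 0.0, 0.0, 1.0)],
                          columns=ATOM_COLUMNS)
        assert count_clashes(GQStructure(df)) == 0

    def test_bonded_neighbors_excluded(self):
        df = pd.DataFrame([
            (1, "A", 1, "DG", "O3'", "O", 0.0, 0.0, 0.0, 1.0),
            (1, "A", 2, "DG", "P", "P", 1.6, 0.0, 0.0, 1.0),
        ], columns=ATOM_COLUMNS)
        assert count_clashes(GQStructure(df)) == 0
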