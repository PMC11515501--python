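"""Structure parsing, cleaning, pocket completion and labelling."""

import json

import numpy as np
import pytest

from allopocket import structure_io as sio


def pdb_line(record, serial, name, resname, chain, resnum, x=1.0, y=2.0, z=3.0,
             altloc=" ", icode=" ", element=None):
    element = element or name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


class TestParsePdb:
    def test_two_residue_fixture(self, tmp_path):
        p = write_pdb(tmp_path / "two.pdb", [
            pdb_line("ATOM", 1, "N", "GLY", "A", 1),
            pdb_line("ATOM", 2, "CA", "GLY", "A", 1),
            pdb_line("ATOM", 3, "N", "ALA", "A", 2),
            pdb_line("ATOM", 4, "CA", "ALA", "A", 2),
            pdb_line("ATOM", 5, "CB", "ALA", "A", 2),
        ])
        s = sio.parse_pdb(p)
        assert len(s.residues) == 2
        assert [r.residue_name for r in s.residues] == ["GLY", "ALA"]
        assert len(s.residues[1].atoms) == 3
        assert s.residues[0].kind == "standard-aa"

    def test_altloc_keeps_first_listed(self, tmp_path):
        p = write_pdb(tmp_path / "alt.pdb", [
            pdb_line("ATOM", 1, "N", "SER", "A", 1),
            pdb_line("ATOM", 2, "CA", "SER", "A", 1, x=9.0, altloc="B"),
            pdb_line("ATOM", 3, "CA", "SER", "A", 1, x=4.0, altloc="A"),
        ])
        s = sio.parse_pdb(p)
        (res,) = s.residues
        ca = [a for a in res.atoms if a.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0].x == pytest.approx(9.0)  # first-listed wins

    def test_first_model_only(self, tmp_path):
        p = write_pdb(tmp_path / "models.pdb", [
            "MODEL        1",
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1, x=1.0),
            "ENDMDL",
            "MODEL        2",
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1, x=5.0),
            "ENDMDL",
        ])
        s = sio.parse_pdb(p)
        assert s.residues[0].atoms[0].x == pytest.approx(1.0)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("")
        with pytest.raises(sio.StructureFormatError):
            sio.parse_pdb(p)


class TestCleanStructure:
    def test_removes_waters_ions_ligands(self, tmp_path):
        p = write_pdb(tmp_path / "dirty.pdb", [
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1),
            pdb_line("ATOM", 2, "CA", "ALA", "A", 2),
            pdb_line("ATOM", 3, "CA", "SER", "A", 3),
            pdb_line("HETATM", 4, "O", "HOH", "A", 101),
            pdb_line("HETATM", 5, "O", "HOH", "A", 102),
            pdb_line("HETATM", 6, "NA", "NA", "A", 103, element="NA"),
            pdb_line("HETATM", 7, "C1", "LIG", "A", 104, element="C"),
            pdb_line("HETATM", 8, "C2", "LIG", "A", 104, element="C"),
        ])
        s = sio.parse_pdb(p)
        clean = sio.clean_structure(s)
        assert [r.residue_name for r in clean.residues] == ["GLY", "ALA", "SER"]
        # input untouched
        assert len(s.residues) == 7

    def test_pure_protein_unchanged(self, tmp_path):
        p = write_pdb(tmp_path / "pure.pdb", [
            pdb_line("ATOM", 1, "CA", "GLY", "A", 1),
            pdb_line("ATOM", 2, "CA", "ALA", "A", 2),
        ])
        s = sio.parse_pdb(p)
        assert sio.clean_structure(s) == s

    def test_water_only_becomes_empty(self, tmp_path, caplog):
        p = write_pdb(tmp_path / "wet.pdb", [
            pdb_line("HETATM", 1, "O", "HOH", "A", 1),
        ])
        s = sio.parse_pdb(p)
        with caplog.at_level("WARNING"):
            clean = sio.clean_structure(s)
        assert clean.residues == ()
        assert any("removed every residue" in m for m in caplog.messages)


class TestFpocketRun:
    def test_descriptors_match_manifest(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        assert len(pockets) == len(manifest["pockets"])
        for p in pockets:
            expected = manifest["descriptors"][str(p.pocket_id)]
            assert p.descriptors.as_dict() == expected
            keys = [[r.chain_id, r.residue_number] for r in p.residues]
            assert keys == manifest["pockets"][str(p.pocket_id)]

    def test_empty_run_dir(self, tmp_path):
        parent_lines = [pdb_line("ATOM", 1, "CA", "GLY", "A", 1)]
        p = write_pdb(tmp_path / "x.pdb", parent_lines)
        parent = sio.parse_pdb(p)
        run = tmp_path / "run"
        run.mkdir()
        assert sio.parse_fpocket_run(run, parent) == []

    def test_missing_descriptor_key_raises(self, fixture_dir, tmp_path):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        run = tmp_path / "broken_run"
        run.mkdir()
        for f in (d / manifest["run_dir"]).iterdir():
            (run / f.name).write_text(f.read_text())
        info = run / "toyprot_info.txt"
        text = info.read_text().replace("\tVolume :", "\tIgnored :", 1)
        info.write_text(text)
        with pytest.raises(sio.FpocketFormatError, match="volume"):
            sio.parse_fpocket_run(run, parent)


class TestCompleteResidues:
    def test_restores_parent_atoms_and_preserves_descriptors(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        pocket = pockets[0]
        done = sio.complete_residues(pocket, parent)
        assert done.completed
        assert done.descriptors == pocket.descriptors
        parent_map = parent.residue_map()
        for r in done.residues:
            assert len(r.atoms) == len(parent_map[r.key].atoms)
        # idempotent
        again = sio.complete_residues(done, parent)
        assert [r.atoms for r in again.residues] == [r.atoms for r in done.residues]

    def test_missing_residue_raises(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        truncated = sio.ProteinStructure(
            structure_id="trunc", residues=parent.residues[8:]
        )
        with pytest.raises(LookupError):
            sio.complete_residues(pockets[0], truncated)


class TestNucleotideFilter:
    def test_manifest_nucleotide_pocket_removed(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        kept = sio.filter_nucleotide_pockets(pockets)
        kept_ids = [p.pocket_id for p in kept]
        for pid in manifest["nucleotide_only_pockets"]:
            assert pid not in kept_ids
        assert kept_ids == [
            p.pocket_id for p in pockets
            if p.pocket_id not in manifest["nucleotide_only_pockets"]
        ]

    def test_matches_bruteforce_predicate(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        rng = np.random.default_rng(5)
        for _ in range(20):
            sample = [pockets[i] for i in rng.integers(0, len(pockets), 4)]
            # de-duplicate ids to satisfy the uniqueness invariant downstream
            kept = sio.filter_nucleotide_pockets(sample)
            expected = [
                p for p in sample
                if not all(r.kind == "nucleotide" for r in p.residues)
            ]
            assert kept == expected

    def test_mixed_pocket_retained(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        aa = next(r for r in parent.residues if r.kind == "standard-aa")
        nuc_pocket = next(
            p for p in pockets
            if p.pocket_id in manifest["nucleotide_only_pockets"]
        )
        mixed = sio.Pocket(
            pocket_id=99,
            residues=tuple(sorted([aa, *nuc_pocket.residues], key=lambda r: r.key)),
            descriptors=nuc_pocket.descriptors,
        )
        assert sio.filter_nucleotide_pockets([mixed]) == [mixed]

    def test_empty_input(self):
        assert sio.filter_nucleotide_pockets([]) == []


class TestLabelPockets:
    def test_intersection_rule(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        pockets = sio.filter_nucleotide_pockets(pockets)
        ann = sio.read_annotations(d / "annotations.tsv")["toyprot"]
        labelled, has_positive = sio.label_pockets(pockets, ann)
        assert has_positive
        by_id = {p.pocket_id: p.label for p in labelled}
        assert by_id[manifest["allosteric_pocket"]] == 1
        assert all(v == 0 for pid, v in by_id.items()
                   if pid != manifest["allosteric_pocket"])

    def test_empty_annotation_all_negative(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        empty = sio.AllostericAnnotation("toyprot", frozenset())
        labelled, has_positive = sio.label_pockets(pockets, empty)
        assert not has_positive
        assert all(p.label == 0 for p in labelled)

    def test_permutation_equivariance(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        pockets = sio.parse_fpocket_run(d / manifest["run_dir"], parent)
        ann = sio.read_annotations(d / "annotations.tsv")["toyprot"]
        forward, _ = sio.label_pockets(pockets, ann)
        backward, _ = sio.label_pockets(pockets[::-1], ann)
        assert {p.pocket_id: p.label for p in forward} == {
            p.pocket_id: p.label for p in backward
        }


class TestSelectChains:
    def test_modes(self, fixture_dir):
        d, manifest = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        ann = sio.read_annotations(d / "annotations.tsv")["toyprot"]
        assert parent.chain_ids == {"A", "B"}
        only = sio.select_chains(parent, ann, "allosteric-chains-only")
        assert only.chain_ids == {"A"}
        both = sio.select_chains(parent, ann, "all-chains")
        assert both.chain_ids == {"A", "B"}

    def test_empty_annotation_raises(self, fixture_dir):
        d, _ = fixture_dir
        parent = sio.clean_structure(sio.parse_pdb(d / "toyprot.pdb", "toyprot"))
        empty = sio.AllostericAnnotation("toyprot", frozenset())
        with pytest.raises(ValueError):
            sio.select_chains(parent, empty, "allosteric-chains-only")


def test_residue_kind_tables():
    assert sio.residue_kind("MSE") == "standard-aa"
    assert sio.residue_kind("DA") == "nucleotide"
    assert sio.residue_kind("HOH") == "water"
    assert sio.residue_kind("ZN") == "ion"
    assert sio.residue_kind("LIG") == "other-hetero"
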