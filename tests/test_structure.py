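"""Structure model: PDB I/O, superposition, threading, disulfides."""

import numpy as np
import pytest

from conftest import horn_rotation
from mc4rkit.geometry import kabsch, random_rotation
from mc4rkit.sequences import SequenceRecord, align_pair
from mc4rkit.structure import (Atom, Chain, Residue, StructureModel,
                               annotate_disulfides, paired_coords,
                               read_structure, superpose, thread_sequence,
                               write_structure)

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.152  -4.936  1.00  0.00           C
ATOM      4  O   ALA A   1      13.560   7.362  -5.792  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   2       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   2       1.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA BSER A   2       2.000   0.000   0.000  0.60  0.00           C
ATOM      4  C   SER A   2       3.000   0.000   0.000  1.00  0.00           C
ATOM      5  O   SER A   2       4.000   0.000   0.000  1.00  0.00           O
END
"""


class TestPdbIO:
    def test_minimal_single_residue_file(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(MINIMAL_PDB)
        model = read_structure(path)
        assert len(model.chains) == 1
        assert len(model.chains[0].residues) == 1
        assert model.chains[0].residues[0].name == "ALA"
        assert model.atom_count == 4

    def test_altloc_resolved_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = read_structure(path)
        ca = model.chains[0].residues[0].atom("CA")
        assert ca.pos[0] == pytest.approx(2.0)  # the 0.60-occupancy B conf

    def test_round_trip_preserves_atoms_and_coordinates(self, tmp_path,
                                                        bundle):
        model, _, _ = bundle
        path = tmp_path / "bundle.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.atom_count == model.atom_count
        orig = np.array([a.pos for _, _, a in model.atoms()])
        read = np.array([a.pos for _, _, a in back.atoms()])
        assert np.abs(orig - read).max() < 1e-3
        orig_names = [(c.id, r.number, a.name) for c, r, a in model.atoms()]
        read_names = [(c.id, r.number, a.name) for c, r, a in back.atoms()]
        assert orig_names == read_names

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(path)


def _point_model(points, chain="A"):
    residues = [Residue(number=i + 1, name="GLY",
                        atoms=[Atom("CA", p, "C")])
                for i, p in enumerate(points)]
    return StructureModel([Chain(chain, residues)])


class TestSuperpose:
    def test_self_superposition_is_identity(self, bundle):
        model, _, _ = bundle
        sup = superpose(model, model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_pure_translation_recovered(self, bundle):
        model, _, _ = bundle
        moved = model.transformed(np.eye(3), np.array([10.0, 0.0, 0.0]))
        sup = superpose(moved, model)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sup.translation, [-10.0, 0.0, 0.0], atol=1e-9)

    def test_agreement_with_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            P = rng.normal(size=(10, 3)) * 5.0
            R_true = random_rotation(rng)
            Q = P @ R_true.T + rng.normal(size=3) * 10.0
            Q += rng.normal(size=P.shape) * 0.1
            R, t, rmsd = kabsch(P, Q)
            R_horn = horn_rotation(P, Q)
            assert np.allclose(R, R_horn, atol=1e-8)
            assert np.linalg.det(R) == pytest.approx(1.0)
            # rmsd cannot beat the optimum of the oracle's rotation
            Pc = P - P.mean(axis=0)
            Qc = Q - Q.mean(axis=0)
            horn_rmsd = np.sqrt(np.mean(np.sum(
                (Pc @ R_horn.T - Qc) ** 2, axis=1)))
            assert rmsd == pytest.approx(horn_rmsd, abs=1e-9)

    def test_noise_level_reflected_in_rmsd(self):
        rng = np.random.default_rng(9)
        sigma = 0.1
        n = 10
        rmsds = []
        for _ in range(60):
            P = rng.normal(size=(n, 3)) * 5.0
            Q = P @ random_rotation(rng).T + rng.normal(size=P.shape) * sigma
            rmsds.append(kabsch(P, Q)[2])
        # the rigid fit absorbs 6 degrees of freedom, so the noise floor
        # is sigma * sqrt((3n - 6) / n)
        assert np.mean(rmsds) == pytest.approx(
            sigma * np.sqrt((3 * n - 6) / n), rel=0.1)

    def test_idempotent_after_applying_transform(self, bundle):
        model, _, _ = bundle
        rng = np.random.default_rng(4)
        moved = model.transformed(random_rotation(rng),
                                  np.array([5.0, -3.0, 8.0]))
        sup = superpose(moved, model)
        aligned = sup.apply(moved)
        again = superpose(aligned, model)
        assert again.rmsd == pytest.approx(sup.rmsd, abs=1e-6)
        assert np.allclose(again.rotation, np.eye(3), atol=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        a = _point_model([np.zeros(3), np.ones(3)])
        with pytest.raises(ValueError):
            superpose(a, a)
        line = [np.array([float(i), 0.0, 0.0]) for i in range(5)]
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch(np.array(line), np.array(line))


class TestThreading:
    def _template_alignment(self, bundle_model, target):
        tmpl_seq = SequenceRecord(
            id="tmpl", residues=bundle_model.chains[0].sequence())
        return align_pair(target, tmpl_seq)

    def test_identity_threading_reproduces_template_backbone(self, bundle,
                                                             hmc4r):
        model, _, _ = bundle
        aln = self._template_alignment(model, hmc4r)
        threaded = thread_sequence(model, aln, hmc4r)
        P, Q = paired_coords(threaded, model, ("N", "CA", "C", "O"),
                            chain_pair=("A", "R"))
        assert len(P) > 1000
        assert np.abs(P - Q).max() == 0.0

    def test_substituted_residue_renamed_and_truncated_to_cb(self, bundle,
                                                             hmc4r):
        model, _, _ = bundle
        mutated = hmc4r.residues[:89] + "N" + hmc4r.residues[90:]  # D90N
        target = SequenceRecord(id="mut", residues=mutated)
        aln = self._template_alignment(model, target)
        threaded = thread_sequence(model, aln, target)
        res = threaded.chains[0].residue(90)
        assert res.name == "ASN"
        assert sorted(a.name for a in res.atoms) == ["C", "CA", "CB",
                                                     "N", "O"]
        # backbone untouched
        tmpl = model.chains[0].residue(90)
        assert np.allclose(res.atom("CA").pos, tmpl.atom("CA").pos)

    def test_target_insertion_left_unmodeled_and_reported(self, bundle,
                                                          hmc4r):
        model, _, _ = bundle
        inserted = hmc4r.residues[:150] + "GGG" + hmc4r.residues[150:]
        target = SequenceRecord(id="ins", residues=inserted)
        aln = self._template_alignment(model, target)
        threaded = thread_sequence(model, aln, target)
        n_aligned = sum(1 for na, nb in aln.columns
                        if na is not None and nb is not None)
        assert len(threaded.chains[0].residues) == n_aligned
        assert len(threaded.metadata["unmodeled_target_residues"]) == 3


class TestDisulfides:
    def _cys_pair(self, distance):
        def cys(number, x):
            atoms = [Atom("N", [x, 0, 2]), Atom("CA", [x, 0, 1]),
                     Atom("C", [x, 1, 1]), Atom("O", [x, 2, 1]),
                     Atom("CB", [x, 0, 0]), Atom("SG", [x, 0, -1])]
            return Residue(number=number, name="CYS", atoms=atoms)
        return StructureModel([Chain("A", [cys(1, 0.0),
                                           cys(2, distance)])])

    def test_close_sg_pair_reported_once(self):
        bonds = annotate_disulfides(self._cys_pair(2.05))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.05)

    def test_distant_pair_not_reported(self):
        assert annotate_disulfides(self._cys_pair(6.0),
                                   max_ss_distance=2.5) == []

    def test_hmc4r_bundle_reports_planted_ecl3_bridge(self, bundle):
        model, _, _ = bundle
        bonds = annotate_disulfides(model)
        pairs = {(b.residue_a, b.residue_b) for b in bonds}
        assert (271, 277) in pairs
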