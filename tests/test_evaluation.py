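"""Pose and screening metrics against independent statistical oracles."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from lid.evaluation import (PoseEvaluation, TitrationComplex,
                            enrichment_factor, ligand_rmsd,
                            reference_titration, roc_auc, top1_success_rate,
                            tp_at_decoy_rate)
from lid.interactions import IPA, InteractionType, Mode
from lid.structures import AtomRecord


def benzene(rotation_deg=0.0, shift=(0.0, 0.0, 0.0)):
    atoms = []
    for k in range(6):
        ang = np.radians(60.0 * k + rotation_deg)
        atoms.append(AtomRecord("C", f"C{k + 1}",
                                np.array([1.39 * np.cos(ang),
                                          1.39 * np.sin(ang), 0.0]) + shift,
                                ("A", "LIG", "1")))
    bonds = [(k, (k + 1) % 6, "ar") for k in range(6)]
    return atoms, bonds


class TestLigandRmsd:
    def test_identical_zero(self):
        atoms, bonds = benzene()
        assert ligand_rmsd(atoms, atoms, bonds) == pytest.approx(0.0)

    def test_uniform_displacement_closed_form(self):
        atoms, bonds = benzene()
        moved, _ = benzene(shift=(1.0, 0.0, 0.0))
        assert ligand_rmsd(moved, atoms, bonds) == pytest.approx(1.0)
        assert ligand_rmsd(moved, atoms, bonds, symmetry=False) == \
            pytest.approx(1.0)

    def test_benzene_sixfold_symmetry(self):
        atoms, bonds = benzene()
        rotated, _ = benzene(rotation_deg=60.0)
        assert ligand_rmsd(rotated, atoms, bonds, symmetry=True) == \
            pytest.approx(0.0, abs=1e-9)
        assert ligand_rmsd(rotated, atoms, bonds, symmetry=False) > 1.0

    def test_atom_count_mismatch_raises(self):
        atoms, bonds = benzene()
        with pytest.raises(ValueError):
            ligand_rmsd(atoms[:5], atoms, bonds)

    def test_matches_rdkit_symmetry_rmsd(self):
        """Cross-check the automorphism minimum against RDKit CalcRMS."""
        from rdkit import Chem
        from rdkit.Chem import rdMolAlign
        from rdkit.Geometry import Point3D

        # para-dichlorobenzene: twofold symmetric
        atoms, bonds = benzene()
        for k, name in ((0, "CL1"), (3, "CL2")):
            direction = atoms[k].coords / np.linalg.norm(atoms[k].coords)
            atoms.append(AtomRecord("Cl", name, atoms[k].coords + 1.7 * direction,
                                    ("A", "LIG", "1")))
        bonds = bonds + [(0, 6, "1"), (3, 7, "1")]
        rng = np.random.default_rng(6)
        t = np.radians(180.0)
        rot = np.array([[np.cos(t), -np.sin(t), 0],
                        [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])
        moved = [AtomRecord(a.element, a.name,
                            rot @ a.coords + rng.normal(0, 0.05, 3),
                            a.residue_id) for a in atoms]

        def to_mol(atom_list):
            em = Chem.RWMol()
            for a in atom_list:
                em.AddAtom(Chem.Atom(a.element))
            for i, j, _ in bonds:
                em.AddBond(i, j, Chem.BondType.SINGLE)
            conf = Chem.Conformer(len(atom_list))
            for i, a in enumerate(atom_list):
                conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
            mol = em.GetMol()
            mol.AddConformer(conf)
            return mol

        expect = rdMolAlign.CalcRMS(to_mol(moved), to_mol(atoms))
        got = ligand_rmsd(moved, atoms, bonds, symmetry=True)
        assert got == pytest.approx(expect, abs=1e-6)


class TestTop1Success:
    def test_strict_threshold_boundary(self):
        per_complex = [[PoseEvaluation.from_rmsd("p", r)]
                       for r in (1.2, 3.0, 0.4, 2.0)]
        assert top1_success_rate(per_complex, 2.0) == pytest.approx(0.5)

    def test_all_correct(self):
        per_complex = [[PoseEvaluation.from_rmsd("p", 0.5)]] * 7
        assert top1_success_rate(per_complex) == 1.0

    def test_planted_ranks_bookkeeping(self):
        rng = np.random.default_rng(0)
        correct = rng.random(100) < 0.37
        per_complex = []
        for good in correct:
            top = 1.0 if good else 4.0
            per_complex.append([PoseEvaluation.from_rmsd("a", top),
                                PoseEvaluation.from_rmsd("b", 9.0)])
        assert top1_success_rate(per_complex) == pytest.approx(correct.mean())

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            top1_success_rate([])


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _, _ = roc_auc([1, 1, 0, 0], [9.0, 8.0, 2.0, 1.0])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = roc_auc([1, 0, 1, 0], [5.0, 5.0, 5.0, 5.0])
        assert auc == pytest.approx(0.5)

    def test_matches_mannwhitney_oracle(self):
        rng = np.random.default_rng(42)
        labels = rng.random(200) < 0.3
        scores = rng.normal(labels.astype(float), 1.0)
        auc, _, _ = roc_auc(labels, scores)
        u, _ = mannwhitneyu(scores[labels], scores[~labels])
        expect = u / (labels.sum() * (~labels).sum())
        assert auc == pytest.approx(expect, abs=1e-12)

    def test_negation_complement_for_tie_free_scores(self):
        rng = np.random.default_rng(1)
        labels = np.array([1] * 30 + [0] * 70)
        scores = rng.permutation(100).astype(float)
        a, _, _ = roc_auc(labels, scores)
        b, _, _ = roc_auc(labels, -scores)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.5, 0.2])


class TestTpAtDecoyRate:
    def test_perfect_separation_is_100(self):
        labels = [1] * 10 + [0] * 100
        scores = list(range(110, 0, -1))
        for rate in (0.01, 0.05, 0.5, 1.0):
            assert tp_at_decoy_rate(labels, scores, rate) == 100.0

    def test_hand_counted_fixture(self):
        # 100 decoys scored 0..99; 5% decoys -> threshold = 5th decoy = 95
        # actives >= 95: three of ten -> 30%
        decoys = np.arange(100.0)
        actives = np.array([99.5, 96.0, 95.0, 94.0, 50.0,
                            40.0, 30.0, 20.0, 10.0, 5.0])
        labels = np.r_[np.ones(10), np.zeros(100)]
        scores = np.r_[actives, decoys]
        assert tp_at_decoy_rate(labels, scores, 0.05) == pytest.approx(30.0)

    def test_random_scores_near_rate(self):
        rng = np.random.default_rng(3)
        labels = np.r_[np.ones(10), np.zeros(100)]
        vals = []
        for _ in range(1000):
            scores = rng.permutation(110).astype(float)
            vals.append(tp_at_decoy_rate(labels, scores, 0.05))
        assert np.mean(vals) == pytest.approx(5.0, abs=2.0)

    def test_monotone_in_rate_and_limit(self):
        rng = np.random.default_rng(9)
        labels = rng.random(150) < 0.2
        labels[:2] = [True, False]
        scores = rng.normal(labels.astype(float), 1.5)
        rates = np.linspace(0.01, 1.0, 25)
        vals = [tp_at_decoy_rate(labels, scores, r) for r in rates]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))
        expect = 100.0 * np.mean(scores[labels] >= scores[~labels].min())
        assert vals[-1] == pytest.approx(expect)


def test_enrichment_factor_hand_value():
    labels = np.r_[np.ones(10), np.zeros(90)]
    scores = np.r_[np.arange(100, 90, -1), np.arange(90, 0, -1)].astype(float)
    # top 5% = 5 compounds, all active: (5/10)/0.05 = 10
    assert enrichment_factor(labels, scores, 0.05) == pytest.approx(10.0)


class TestTitration:
    CH = (Mode.LIGAND, InteractionType.HB_LIGAND_DONOR)

    def refs(self, n, rng):
        return {f"r{i:02d}": [IPA(rng.uniform(0, 5, 3), *self.CH)]
                for i in range(n)}

    def cx(self, rng):
        poses = [[IPA(rng.uniform(0, 5, 3), *self.CH)] for _ in range(4)]
        return TitrationComplex(pose_ipas=poses,
                                pose_rmsds=[0.5, 3.0, 5.0, 7.0])

    def test_single_reference_single_combination(self):
        rng = np.random.default_rng(0)
        out = reference_titration(self.refs(1, rng), [self.cx(rng)],
                                  n_range=[1])
        assert len(out[1]) == 1

    def test_all_combinations_enumerated_below_cap(self):
        rng = np.random.default_rng(1)
        out = reference_titration(self.refs(6, rng), [self.cx(rng)],
                                  n_range=[2])
        assert len(out[2]) == 15

    def test_cap_and_seed_determinism(self):
        rng = np.random.default_rng(2)
        refs = self.refs(25, rng)
        # each pose coincides with one reference IPA, so the winning pose
        # (hence the median) depends on which references the subset contains
        ids = sorted(refs)
        poses = [[IPA(refs[ids[k]][0].coords.copy(), *self.CH)]
                 for k in range(4)]
        cx = TitrationComplex(pose_ipas=poses,
                              pose_rmsds=[0.5, 3.0, 5.0, 7.0])
        a = reference_titration(refs, [cx], n_range=[10], seed=7)
        b = reference_titration(refs, [cx], n_range=[10], seed=7)
        c = reference_titration(refs, [cx], n_range=[10], seed=8)
        assert len(a[10]) == 1000
        assert np.array_equal(a[10], b[10])
        assert not np.array_equal(a[10], c[10])

    def test_range_truncated_with_warning(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning):
            out = reference_titration(self.refs(3, rng), [self.cx(rng)],
                                      n_range=[1, 2, 3, 4, 5])
        assert sorted(out) == [1, 2, 3]
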