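"""Structure reading, binding-site consensus and superposition."""

import numpy as np
import pytest

from lid.structures import (AtomRecord, RigidTransform, SelectionError,
                            StructureModel, define_binding_site,
                            read_structure, select_representative, site_rmsd,
                            superpose)
from lid.synthetic import (SyntheticSiteSpec, make_reference_ensemble,
                           write_reference_pdb)


def ca_structure(sid, coords, chain="A"):
    atoms = [AtomRecord("C", "CA", c, (chain, "GLY", str(i + 1)))
             for i, c in enumerate(coords)]
    lig = [AtomRecord("C", "C1", np.mean(coords, axis=0), (chain, "LIG", "1"))]
    return StructureModel(sid, atoms, lig, [], [])


def full_site(structures):
    return define_binding_site(structures, contact_cutoff=1e6,
                               presence_threshold=0.0)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class TestReadStructure:
    def test_waters_and_atom_counts_recovered(self, tmp_path,
                                              zero_jitter_study):
        _, models, _ = zero_jitter_study
        path = tmp_path / "ref.pdb"
        write_reference_pdb(models[0], path, n_waters=5)
        st = read_structure(path, "LIG")
        assert not any(a.residue_id[1] in ("HOH", "WAT")
                       for a in st.protein_atoms + st.metals)
        assert len([a for a in st.ligand_atoms if not a.is_hydrogen]) == \
            len(models[0].ligand_heavy_indices())
        assert len(st.protein_atoms) == len(models[0].protein_atoms)
        assert len(st.metals) == len(models[0].metals)
        # formal charges survive the PDB round trip
        charges = sorted(a.formal_charge for a in st.ligand_atoms
                         if a.formal_charge)
        assert charges == [-1, 1]

    def test_bonds_recovered_from_conect(self, tmp_path, zero_jitter_study):
        _, models, _ = zero_jitter_study
        path = tmp_path / "ref.pdb"
        write_reference_pdb(models[0], path)
        st = read_structure(path, "LIG")
        assert len(st.ligand_bonds) == len(models[0].ligand_bonds)

    def test_duplicate_copies_need_index(self, tmp_path):
        lines = []
        serial = 0
        for copy, x in ((1, 0.0), (2, 8.0)):
            for k, dy in enumerate((0.0, 1.4)):
                serial += 1
                lines.append(
                    f"HETATM{serial:>5d}  O{k + 1}  SO4 A{copy:>4d}    "
                    f"{x:>8.3f}{dy:>8.3f}{0.0:>8.3f}  1.00  0.00           O")
        lines.append("END")
        path = tmp_path / "two.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SelectionError):
            read_structure(path, "SO4")
        st = read_structure(path, "SO4:2")
        assert len(st.ligand_atoms) == 2
        assert st.ligand_atoms[0].coords[0] == pytest.approx(8.0)

    def test_missing_selector_raises(self, tmp_path, zero_jitter_study):
        _, models, _ = zero_jitter_study
        path = tmp_path / "ref.pdb"
        write_reference_pdb(models[0], path)
        with pytest.raises(SelectionError):
            read_structure(path, "XYZ")


# ---------------------------------------------------------------------------
# binding site
# ---------------------------------------------------------------------------

class TestBindingSite:
    def make(self, dist):
        prot = [AtomRecord("C", "CB", [dist, 0, 0], ("A", "ALA", "1"))]
        lig = [AtomRecord("O", "O1", [0, 0, 0], ("A", "LIG", "1"))]
        return StructureModel("s", prot, lig, [], [])

    def test_strict_distance_boundary(self):
        inside = define_binding_site([self.make(6.4)])
        outside = define_binding_site([self.make(6.5)])
        assert ("A", "ALA", "1") in inside.residues
        assert ("A", "ALA", "1") not in outside.residues

    def test_strict_presence_boundary(self):
        # contact in exactly 1 of 10: fraction 0.10 is not > 0.10
        structures = [self.make(3.0)] + [self.make(30.0) for _ in range(9)]
        site = define_binding_site(structures)
        assert ("A", "ALA", "1") not in site.residues
        # 3 of 5 contacts: 0.6 > 0.1
        structures = [self.make(3.0)] * 3 + [self.make(30.0)] * 2
        site = define_binding_site(structures)
        assert ("A", "ALA", "1") in site.residues
        assert site.per_structure_presence[("A", "ALA", "1")] == pytest.approx(0.6)

    def test_order_invariance(self, rigid_study):
        models = rigid_study["models"]
        a = define_binding_site(models)
        b = define_binding_site(models[::-1])
        assert a.residues == b.residues
        assert a.per_structure_presence == b.per_structure_presence

    def test_hydrogens_ignored(self):
        # only a hydrogen is within reach: residue must not qualify
        prot = [AtomRecord("H", "H1", [3.0, 0, 0], ("A", "ALA", "1"),
                           is_hydrogen=True),
                AtomRecord("C", "CB", [30.0, 0, 0], ("A", "ALA", "1"))]
        lig = [AtomRecord("O", "O1", [0, 0, 0], ("A", "LIG", "1"))]
        site = define_binding_site([StructureModel("s", prot, lig, [], [])])
        assert not site.residues

    def test_synthetic_site_excludes_far_scaffold(self, zero_jitter_study):
        _, models, _ = zero_jitter_study
        site = define_binding_site(models)
        assert all(int("".join(c for c in rid[2] if c.isdigit())) < 100
                   for rid in site.residues)
        assert len(site.residues) >= 5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            define_binding_site([])


# ---------------------------------------------------------------------------
# representative selection
# ---------------------------------------------------------------------------

class TestRepresentative:
    def test_single_structure_is_itself(self):
        s = ca_structure("only", np.eye(4, 3) * 5)
        site = full_site([s])
        assert select_representative([s], site) == "only"

    def test_average_geometry_selected(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 10, (8, 3))
        eta = rng.normal(0, 0.6, (8, 3))
        a = ca_structure("A", base)
        b = ca_structure("B", base + eta)
        c = ca_structure("C", base - eta)
        site = full_site([a, b, c])
        # explicit check of the decision matrix: A is the Calpha average
        mat = np.array([[site_rmsd(x, y, site) for y in (a, b, c)]
                        for x in (a, b, c)])
        means = mat.sum(axis=1) / 2
        assert means[0] == min(means)
        assert select_representative([b, c, a], site) == "A"

    def test_tie_broken_lexicographically(self):
        coords = np.random.default_rng(1).uniform(0, 10, (5, 3))
        x = ca_structure("zeta", coords)
        y = ca_structure("alpha", coords)
        site = full_site([x, y])
        assert select_representative([x, y], site) == "alpha"

    def test_invariant_to_global_rigid_motion(self):
        rng = np.random.default_rng(7)
        structures = [ca_structure(f"s{i}", rng.uniform(0, 10, (6, 3)))
                      for i in range(4)]
        site = full_site(structures)
        chosen = select_representative(structures, site)
        t = RigidTransform(_rotz(40.0), np.array([3.0, -2.0, 7.0]))
        moved = [s.transformed(t) for s in structures]
        site2 = full_site(moved)
        assert select_representative(moved, site2) == chosen


def _rotz(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0],
                     [np.sin(t), np.cos(t), 0],
                     [0, 0, 1.0]])


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def quaternion_superpose(mobile, target):
    """Independent closed-form (Horn quaternion) rigid superposition oracle."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    x, y = mobile - mc, target - tc
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    vals, vecs = np.linalg.eigh(n)
    q = vecs[:, np.argmax(vals)]
    w, qx, qy, qz = q
    rot = np.array([
        [1 - 2 * (qy**2 + qz**2), 2 * (qx * qy - w * qz), 2 * (qx * qz + w * qy)],
        [2 * (qx * qy + w * qz), 1 - 2 * (qx**2 + qz**2), 2 * (qy * qz - w * qx)],
        [2 * (qx * qz - w * qy), 2 * (qy * qz + w * qx), 1 - 2 * (qx**2 + qy**2)],
    ])
    tran = tc - rot @ mc
    fitted = mobile @ rot.T + tran
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return rot, tran, rmsd


class TestSuperpose:
    def test_self_superposition_is_identity(self, rigid_study):
        for model in rigid_study["models"]:
            site = define_binding_site([model])
            t = superpose(model, model, site)
            assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(t.translation, 0.0, atol=1e-9)
            assert t.rmsd_after_fit < 1e-9

    def test_exact_rigid_motion_recovered(self):
        coords = np.random.default_rng(3).uniform(0, 15, (10, 3))
        target = ca_structure("t", coords)
        motion = RigidTransform(_rotz(90.0), np.array([5.0, 0.0, 0.0]))
        mobile = target.transformed(motion)
        mobile.id = "m"
        site = full_site([target, mobile])
        t = superpose(mobile, target, site)
        assert t.rmsd_after_fit < 1e-6
        assert np.allclose(t.rotation, motion.inverse().rotation, atol=1e-6)
        back = t.apply(np.array([a.coords for a in mobile.protein_atoms]))
        assert np.allclose(back, coords, atol=1e-6)

    def test_inverse_consistency(self):
        rng = np.random.default_rng(9)
        a = ca_structure("a", rng.uniform(0, 10, (20, 3)))
        b = ca_structure("b", rng.uniform(0, 10, (20, 3)))
        site = full_site([a, b])
        fwd = superpose(a, b, site)
        rev = superpose(b, a, site)
        comp = fwd.compose(rev)
        assert np.allclose(comp.rotation, np.eye(3), atol=1e-6)
        assert np.allclose(comp.translation, 0.0, atol=1e-6)

    def test_matches_quaternion_oracle_under_noise(self):
        rng = np.random.default_rng(21)
        target_coords = rng.uniform(0, 20, (20, 3))
        noise = rng.normal(0, 0.3, (20, 3))
        motion = RigidTransform(_rotz(35.0), np.array([1.0, -4.0, 2.0]))
        mobile_coords = (target_coords + noise) @ motion.rotation.T \
            + motion.translation
        mobile = ca_structure("m", mobile_coords)
        target = ca_structure("t", target_coords)
        site = full_site([mobile, target])
        t = superpose(mobile, target, site)
        rot, tran, rmsd = quaternion_superpose(mobile_coords, target_coords)
        assert np.allclose(t.rotation, rot, atol=1e-6)
        assert np.allclose(t.translation, tran, atol=1e-6)
        assert t.rmsd_after_fit == pytest.approx(rmsd, abs=1e-9)
        noise_rms = float(np.sqrt(np.mean(np.sum(noise**2, axis=1))))
        assert t.rmsd_after_fit < 2 * noise_rms

    def test_too_few_matches_raises(self):
        a = ca_structure("a", np.eye(2, 3))
        b = ca_structure("b", np.eye(2, 3))
        site = full_site([a, b])
        from lid.structures import AlignmentError
        with pytest.raises(AlignmentError):
            superpose(a, b, site)


class TestSiteRmsd:
    def test_identical_structures_zero(self, rigid_study):
        m = rigid_study["models"][0]
        site = define_binding_site([m])
        assert site_rmsd(m, m, site, "CA") == pytest.approx(0.0, abs=1e-9)
        assert site_rmsd(m, m, site, "all-heavy") == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, (12, 3))
        a = ca_structure("a", coords)
        moved = coords.copy()
        moved[0] += [1.0, 0.0, 0.0]
        b = ca_structure("b", moved)
        site = full_site([a, b])
        val = site_rmsd(a, b, site, "CA")
        assert 0.0 < val < 1.0  # fit shares the error over all atoms

    def test_flexible_loop_inflates_all_heavy(self, zero_jitter_study):
        _, models, _ = zero_jitter_study
        a = models[0]
        moved = a.transformed(RigidTransform.identity())
        moved.id = "moved"
        # displace one side chain (non-CA atoms of residue 4, the Lys arm)
        for atom in moved.protein_atoms:
            if atom.residue_id[2] == "4" and atom.name not in ("CA", "N", "C", "O"):
                atom.coords = atom.coords + np.array([0.0, 0.0, 3.0])
        site = define_binding_site([a])
        ca = site_rmsd(a, moved, site, "CA")
        heavy = site_rmsd(a, moved, site, "all-heavy")
        assert heavy > ca
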