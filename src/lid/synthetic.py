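"""Synthetic binding-site generator with fully known interaction ground truth.

A toy binding site is built from real residue templates placed on a circle
around the site center ("stations"), one station per planted interaction
type.  The ligand is a pseudomolecule with one functional group per station,
positioned so that each group satisfies exactly one default-RuleSet
interaction with its station and nothing else: stations are far enough apart
that no cross-station contact falls inside any rule window.  This makes the
generator/detector closure exact at zero jitter.

Reference ensembles emulate crystallographic variability with two knobs:

* ``ligand_jitter`` — per-reference Gaussian rigid displacement of each
  ligand group (binding-mode variability; the protein scaffold stays rigid).
* ``site_jitter`` — per-reference rigid displacement of a whole station,
  residue and ligand group together (side-chain flexibility; this is the
  knob that emulates a flexible site).

Pose sets contain near-native poses (small rigid perturbation, heavy-atom
RMSD < 0.5 A) and displaced poses (rigid shift of several Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import mol2 as m2
from .interactions import (IPA, InteractionRecord, InteractionType, Mode,
                           RuleSet)
from .structures import AtomRecord, StructureModel, write_pdb


class GenerationError(ValueError):
    """Planted geometry violates the interaction RuleSet (a spec bug)."""


DIRECTIONAL_TYPES = (
    InteractionType.HB_LIGAND_DONOR,
    InteractionType.HB_PROTEIN_DONOR,
    InteractionType.IONIC_LIGAND_CATION,
    InteractionType.IONIC_PROTEIN_CATION,
    InteractionType.METAL_CHELATION,
)

ALL_TYPES = tuple(InteractionType)


@dataclass
class SyntheticSiteSpec:
    """Study conditions of the synthetic site.

    ``planted_types`` determines which stations exist; distances are the
    canonical planted geometries (center of the corresponding rule window).
    """

    planted_types: tuple[InteractionType, ...] = ALL_TYPES
    n_references: int = 5
    ligand_jitter: float = 0.25   # A, sigma of per-group displacement
    site_jitter: float = 0.0      # A, sigma of per-station displacement
    radius: float = 10.0          # A, station circle radius
    n_extra_residues: int = 1     # distant residues outside the site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ligand_jitter < 0 or self.site_jitter < 0:
            raise ValueError("jitter sigmas must be >= 0")


# planted interaction distance (A) per type, chosen mid-window of the
# default RuleSet (ionic sits above the HB window so only one rule fires)
_PLANT_DISTANCE = {
    InteractionType.HB_LIGAND_DONOR: 2.9,
    InteractionType.HB_PROTEIN_DONOR: 2.9,
    InteractionType.IONIC_LIGAND_CATION: 4.0,
    InteractionType.IONIC_PROTEIN_CATION: 4.0,
    InteractionType.METAL_CHELATION: 2.0,
    InteractionType.PI_STACKING: 3.8,
    InteractionType.HYDROPHOBIC: 4.0,
}

# residue templates in the station frame: +x points toward the site center,
# the functional anchor sits at the origin, the backbone extends outward
_RING = [(1.39 * np.cos(np.radians(60 * k)), 1.39 * np.sin(np.radians(60 * k)))
         for k in range(6)]

_TEMPLATES: dict[InteractionType, tuple[str, list[tuple[str, str, tuple[float, float, float]]]]] = {
    # backbone O acceptor for the ligand donor
    InteractionType.HB_LIGAND_DONOR: ("GLY", [
        ("O", "O", (0.0, 0.0, 0.0)),
        ("C", "C", (-1.23, 0.0, 0.0)),
        ("CA", "C", (-1.9, 1.3, 0.0)),
        ("N", "N", (-1.3, 2.5, 0.2)),
    ]),
    # backbone N donor for the ligand acceptor
    InteractionType.HB_PROTEIN_DONOR: ("GLY", [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("CA", "C", (-1.45, 0.0, 0.0)),
        ("C", "C", (-2.2, 1.2, 0.3)),
        ("O", "O", (-3.4, 1.1, 0.2)),
    ]),
    # carboxylate, group center at origin
    InteractionType.IONIC_LIGAND_CATION: ("ASP", [
        ("OD1", "O", (0.0, 1.05, 0.0)),
        ("OD2", "O", (0.0, -1.05, 0.0)),
        ("CG", "C", (-0.6, 0.0, 0.0)),
        ("CB", "C", (-2.1, 0.0, 0.0)),
        ("CA", "C", (-2.8, 1.2, 0.2)),
        ("N", "N", (-4.2, 1.3, 0.0)),
        ("C", "C", (-2.4, 2.5, 0.6)),
        ("O", "O", (-3.0, 3.5, 0.5)),
    ]),
    # ammonium NZ at origin
    InteractionType.IONIC_PROTEIN_CATION: ("LYS", [
        ("NZ", "N", (0.0, 0.0, 0.0)),
        ("CE", "C", (-1.5, 0.0, 0.0)),
        ("CD", "C", (-2.1, 1.3, 0.0)),
        ("CG", "C", (-3.6, 1.4, 0.0)),
        ("CB", "C", (-4.2, 2.7, 0.0)),
        ("CA", "C", (-5.7, 2.8, 0.0)),
        ("N", "N", (-6.3, 4.1, 0.0)),
        ("C", "C", (-6.4, 1.7, 0.4)),
        ("O", "O", (-7.6, 1.8, 0.6)),
    ]),
    # a lone zinc; handled as a metal, no residue atoms
    InteractionType.METAL_CHELATION: ("ZN", [
        ("ZN", "Zn", (0.0, 0.0, 0.0)),
    ]),
    # phenyl ring in the y-z plane, centroid at origin
    InteractionType.PI_STACKING: ("PHE", [
        ("CG", "C", (0.0, _RING[0][0], _RING[0][1])),
        ("CD1", "C", (0.0, _RING[1][0], _RING[1][1])),
        ("CE1", "C", (0.0, _RING[2][0], _RING[2][1])),
        ("CZ", "C", (0.0, _RING[3][0], _RING[3][1])),
        ("CE2", "C", (0.0, _RING[4][0], _RING[4][1])),
        ("CD2", "C", (0.0, _RING[5][0], _RING[5][1])),
        ("CB", "C", (0.0, 2.9, 0.0)),
        ("CA", "C", (-0.8, 4.2, 0.0)),
        ("N", "N", (-0.8, 5.6, 0.2)),
        ("C", "C", (-2.2, 3.7, 0.0)),
        ("O", "O", (-3.2, 4.3, 0.2)),
    ]),
    # leucine tip carbon at origin
    InteractionType.HYDROPHOBIC: ("LEU", [
        ("CD1", "C", (0.0, 0.0, 0.0)),
        ("CG", "C", (-1.5, 0.0, 0.0)),
        ("CD2", "C", (-2.1, 1.2, -0.5)),
        ("CB", "C", (-2.2, -1.3, 0.3)),
        ("CA", "C", (-3.7, -1.3, 0.3)),
        ("N", "N", (-4.3, -2.6, 0.2)),
        ("C", "C", (-4.3, -0.1, 1.0)),
        ("O", "O", (-5.5, -0.1, 1.2)),
    ]),
}

# ligand group atoms in the station frame (x measured from the protein
# anchor toward the site center): (name suffix, element, coords, charge)
def _ligand_group(itype: InteractionType) -> list[tuple[str, str, tuple[float, float, float], int]]:
    d = _PLANT_DISTANCE[itype]
    if itype is InteractionType.HB_LIGAND_DONOR:
        return [("O", "O", (d, 0.0, 0.0), 0),
                ("H", "H", (d - 1.0, 0.0, 0.0), 0)]
    if itype is InteractionType.HB_PROTEIN_DONOR:
        return [("O", "O", (d, 0.0, 0.0), 0)]
    if itype is InteractionType.IONIC_LIGAND_CATION:
        return [("N", "N", (d, 0.0, 0.0), +1)]
    if itype is InteractionType.IONIC_PROTEIN_CATION:
        return [("O", "O", (d, 0.0, 0.0), -1)]
    if itype is InteractionType.METAL_CHELATION:
        return [("N", "N", (d, 0.0, 0.0), 0)]
    if itype is InteractionType.PI_STACKING:
        out = []
        for k, (a, b) in enumerate(_RING):
            # rotate 30 deg relative to the protein ring
            ang = np.radians(60 * k + 30)
            out.append((f"C{k}", "C", (d, 1.39 * np.cos(ang), 1.39 * np.sin(ang)), 0))
        return out
    if itype is InteractionType.HYDROPHOBIC:
        return [("C", "C", (d, 0.0, 0.0), 0)]
    raise ValueError(itype)


def _station_frame(angle_deg: float, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """(anchor position, rotation matrix local->global)."""
    t = np.radians(angle_deg)
    anchor = radius * np.array([np.cos(t), np.sin(t), 0.0])
    u = -np.array([np.cos(t), np.sin(t), 0.0])   # local +x: inward
    v = np.array([-np.sin(t), np.cos(t), 0.0])
    w = np.array([0.0, 0.0, 1.0])
    return anchor, np.column_stack([u, v, w])


@dataclass
class _Station:
    itype: InteractionType
    resname: str
    residue_atoms: list[AtomRecord]
    ligand_atoms: list[AtomRecord]          # base (unjittered) positions
    ligand_bonds_local: list[tuple[int, int, str]]
    ligand_anchor: np.ndarray               # planted ligand-side IPA position
    protein_anchor: np.ndarray              # planted protein-side IPA position
    is_metal: bool = False


def _build_stations(spec: SyntheticSiteSpec) -> list[_Station]:
    stations = []
    n = len(spec.planted_types)
    for s, itype in enumerate(spec.planted_types):
        angle = 360.0 * s / max(n, 1)
        anchor, rot = _station_frame(angle, spec.radius)
        resname, atoms = _TEMPLATES[itype]
        rid = ("A", resname, str(s + 1))
        res_atoms = [AtomRecord(el, name, anchor + rot @ np.array(xyz), rid)
                     for name, el, xyz in atoms]
        lig_defs = _ligand_group(itype)
        lig_atoms = []
        for name, el, xyz, q in lig_defs:
            lig_atoms.append(AtomRecord(
                el, f"{name}{s + 1}", anchor + rot @ np.array(xyz),
                ("A", "LIG", "1"), is_hydrogen=(el == "H"), formal_charge=q))
        bonds: list[tuple[int, int, str]] = []
        if itype is InteractionType.HB_LIGAND_DONOR:
            bonds = [(0, 1, "1")]
        elif itype is InteractionType.PI_STACKING:
            bonds = [(k, (k + 1) % 6, "ar") for k in range(6)]
        d = _PLANT_DISTANCE[itype]
        lig_anchor = anchor + rot @ np.array([d, 0.0, 0.0])
        stations.append(_Station(
            itype=itype, resname=resname, residue_atoms=res_atoms,
            ligand_atoms=lig_atoms, ligand_bonds_local=bonds,
            ligand_anchor=lig_anchor, protein_anchor=anchor,
            is_metal=(itype is InteractionType.METAL_CHELATION)))
    return stations


def _far_residues(spec: SyntheticSiteSpec) -> list[AtomRecord]:
    """Scaffold residues well outside the 6.5 A contact shell."""
    out = []
    for k in range(spec.n_extra_residues):
        angle = 360.0 * (k + 0.5) / max(spec.n_extra_residues, 1)
        anchor, rot = _station_frame(angle, spec.radius + 12.0)
        rid = ("A", "GLY", str(100 + k))
        for name, el, xyz in _TEMPLATES[InteractionType.HB_PROTEIN_DONOR][1]:
            out.append(AtomRecord(el, name, anchor + rot @ np.array(xyz), rid))
    return out


def _validate_plants(stations: Sequence[_Station], rules: RuleSet) -> None:
    for st in stations:
        d = float(np.linalg.norm(st.ligand_anchor - st.protein_anchor))
        t = st.itype
        ok = {
            InteractionType.HB_LIGAND_DONOR: d <= rules.hb_distance_max,
            InteractionType.HB_PROTEIN_DONOR: d <= rules.hb_distance_max,
            InteractionType.IONIC_LIGAND_CATION:
                rules.hb_distance_max < d <= rules.ionic_distance_max,
            InteractionType.IONIC_PROTEIN_CATION:
                rules.hb_distance_max < d <= rules.ionic_distance_max,
            InteractionType.METAL_CHELATION: d <= rules.metal_distance_max,
            InteractionType.PI_STACKING: d <= rules.pi_distance_max,
            InteractionType.HYDROPHOBIC: d <= rules.hydrophobic_distance_max,
        }[t]
        if not ok:
            raise GenerationError(
                f"planted {t.name} at {d:.2f} A violates the RuleSet")


def _assemble(stations: Sequence[_Station], extra: Sequence[AtomRecord],
              model_id: str,
              group_shifts: Sequence[np.ndarray] | None = None,
              station_shifts: Sequence[np.ndarray] | None = None,
              keep_ligand: Sequence[bool] | None = None) -> StructureModel:
    protein: list[AtomRecord] = []
    metals: list[AtomRecord] = []
    ligand: list[AtomRecord] = []
    bonds: list[tuple[int, int, str]] = []
    for s, st in enumerate(stations):
        sshift = station_shifts[s] if station_shifts is not None else np.zeros(3)
        gshift = group_shifts[s] if group_shifts is not None else np.zeros(3)
        for a in st.residue_atoms:
            rec = AtomRecord(a.element, a.name, a.coords + sshift, a.residue_id)
            (metals if st.is_metal else protein).append(rec)
        if keep_ligand is not None and not keep_ligand[s]:
            continue
        offset = len(ligand)
        for a in st.ligand_atoms:
            ligand.append(AtomRecord(a.element, a.name,
                                     a.coords + sshift + gshift,
                                     a.residue_id, a.is_hydrogen,
                                     a.sybyl_type, a.formal_charge))
        bonds.extend((i + offset, j + offset, o)
                     for i, j, o in st.ligand_bonds_local)
    protein.extend(extra)
    return StructureModel(model_id, protein, ligand, bonds, metals)


def _truth_records(stations: Sequence[_Station],
                   group_shifts: Sequence[np.ndarray] | None = None,
                   station_shifts: Sequence[np.ndarray] | None = None,
                   keep_ligand: Sequence[bool] | None = None
                   ) -> list[InteractionRecord]:
    out = []
    for s, st in enumerate(stations):
        if keep_ligand is not None and not keep_ligand[s]:
            continue
        sshift = station_shifts[s] if station_shifts is not None else np.zeros(3)
        gshift = group_shifts[s] if group_shifts is not None else np.zeros(3)
        lp = st.ligand_anchor + sshift + gshift
        pp = st.protein_anchor + sshift
        center = (lp + pp) / 2.0
        out.append(InteractionRecord(
            ipa_ligand=IPA(lp, Mode.LIGAND, st.itype),
            ipa_center=IPA(center, Mode.CENTER, st.itype),
            ipa_protein=IPA(pp, Mode.PROTEIN, st.itype),
            ligand_atom_index=-1, protein_atom_index=-1,
            distance=float(np.linalg.norm(lp - pp))))
    return out


def make_representative(spec: SyntheticSiteSpec,
                        rules: RuleSet | None = None) -> StructureModel:
    """The unjittered scaffold with the crystal (planted) ligand."""
    stations = _build_stations(spec)
    _validate_plants(stations, rules or RuleSet())
    return _assemble(stations, _far_residues(spec), "representative")


def make_reference_ensemble(
    spec: SyntheticSiteSpec,
    rules: RuleSet | None = None,
) -> tuple[list[StructureModel], list[list[InteractionRecord]]]:
    """Reference complexes sharing the scaffold, plus planted ground truth.

    Each reference's ligand groups carry Gaussian jitter ``ligand_jitter``;
    with ``site_jitter > 0`` whole stations (residue + ligand group) are
    displaced as well, emulating a flexible site.  Jittered instances whose
    geometry leaves a rule window are still listed in the truth (the
    detector legitimately misses them); at zero jitter truth and detection
    coincide exactly.
    """
    rules = rules or RuleSet()
    stations = _build_stations(spec)
    _validate_plants(stations, rules)
    extra = _far_residues(spec)
    rng = np.random.default_rng(spec.seed)
    models, truths = [], []
    for r in range(spec.n_references):
        gs = [rng.normal(0.0, spec.ligand_jitter, 3)
              if spec.ligand_jitter > 0 else np.zeros(3)
              for _ in stations]
        ss = [rng.normal(0.0, spec.site_jitter, 3)
              if spec.site_jitter > 0 else np.zeros(3)
              for _ in stations]
        models.append(_assemble(stations, extra, f"ref{r + 1:02d}",
                                group_shifts=gs, station_shifts=ss))
        truths.append(_truth_records(stations, group_shifts=gs,
                                     station_shifts=ss))
    return models, truths


_ADDITIVE_KINDS: list[tuple[str, tuple[InteractionType, ...]]] = [
    ("sulfamate", (InteractionType.METAL_CHELATION,
                   InteractionType.HB_LIGAND_DONOR)),
    ("acetate", (InteractionType.IONIC_PROTEIN_CATION,
                 InteractionType.HB_PROTEIN_DONOR)),
    ("amine", (InteractionType.IONIC_LIGAND_CATION,)),
]


def make_additive_references(
    spec: SyntheticSiteSpec,
    rules: RuleSet | None = None,
) -> tuple[list[StructureModel], list[list[InteractionRecord]]]:
    """References whose bound molecule is a small crystallization additive.

    Each additive realizes a subset of the planted *directional* interactions
    (hydrogen bonds, ionic bonds, metal chelation), cycling through
    sulfamate-, acetate- and amine-like fragments.
    """
    rules = rules or RuleSet()
    stations = _build_stations(spec)
    _validate_plants(stations, rules)
    extra = _far_residues(spec)
    rng = np.random.default_rng(spec.seed + 1)
    available = {st.itype for st in stations}
    models, truths = [], []
    for r in range(spec.n_references):
        _, kinds = _ADDITIVE_KINDS[r % len(_ADDITIVE_KINDS)]
        keep = [st.itype in kinds and st.itype in available for st in stations]
        if not any(keep):
            keep = [st.itype in DIRECTIONAL_TYPES for st in stations]
        gs = [rng.normal(0.0, spec.ligand_jitter, 3)
              if spec.ligand_jitter > 0 else np.zeros(3)
              for _ in stations]
        ss = [rng.normal(0.0, spec.site_jitter, 3)
              if spec.site_jitter > 0 else np.zeros(3)
              for _ in stations]
        models.append(_assemble(stations, extra, f"add{r + 1:02d}",
                                group_shifts=gs, station_shifts=ss,
                                keep_ligand=keep))
        truths.append(_truth_records(stations, group_shifts=gs,
                                     station_shifts=ss, keep_ligand=keep))
    return models, truths


# ---------------------------------------------------------------------------
# pose sets
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@dataclass
class PoseSet:
    pose_ids: list[str]
    atoms: list[list[AtomRecord]]
    bonds: list[tuple[int, int, str]]
    rmsds: list[float]            # heavy-atom RMSD to the crystal ligand
    labels: list[str]             # "near" / "far"
    crystal_atoms: list[AtomRecord] = field(default_factory=list)


def make_pose_set(spec: SyntheticSiteSpec, n_near: int = 5, n_far: int = 5,
                  displacement: float = 5.0, seed: int | None = None,
                  fragment_types: Sequence[InteractionType] | None = None
                  ) -> PoseSet:
    """Near-native and rigidly displaced poses of the planted ligand.

    Near poses: small rigid perturbation, heavy-atom RMSD < 0.5 A.  Far
    poses: rigid displacement >= *displacement* (must exceed the 2 A
    correctness threshold).  ``fragment_types`` restricts the ligand to the
    groups of those stations (fragment docking scenario).
    """
    if displacement <= 2.0:
        raise ValueError("far-pose displacement must exceed 2 A")
    stations = _build_stations(spec)
    keep = None
    if fragment_types is not None:
        keep = [st.itype in set(fragment_types) for st in stations]
    crystal = _assemble(stations, [], "crystal", keep_ligand=keep)
    heavy_idx = crystal.ligand_heavy_indices()
    base = np.array([a.coords for a in crystal.ligand_atoms])
    center = base[heavy_idx].mean(axis=0)
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    pose_ids, atoms_list, rmsds, labels = [], [], [], []

    def add_pose(tag: str, rot: np.ndarray, shift: np.ndarray) -> None:
        coords = (base - center) @ rot.T + center + shift
        rmsd = float(np.sqrt(np.mean(
            np.sum((coords[heavy_idx] - base[heavy_idx]) ** 2, axis=1))))
        recs = [AtomRecord(a.element, a.name, coords[i], a.residue_id,
                           a.is_hydrogen, a.sybyl_type, a.formal_charge)
                for i, a in enumerate(crystal.ligand_atoms)]
        pose_ids.append(tag)
        atoms_list.append(recs)
        rmsds.append(rmsd)
        labels.append("near" if tag.startswith("near") else "far")

    for k in range(n_near):
        rot = _random_rotation(rng, 1.5)
        shift = rng.normal(0.0, 0.08, 3)
        add_pose(f"near{k + 1}", rot, shift)
    for k in range(n_far):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * (displacement + rng.uniform(0.0, 3.0))
        rot = _random_rotation(rng, 30.0)
        add_pose(f"far{k + 1}", rot, shift)
    return PoseSet(pose_ids, atoms_list, list(crystal.ligand_bonds),
                   rmsds, labels, crystal_atoms=list(crystal.ligand_atoms))


# ---------------------------------------------------------------------------
# file output (fixtures exercise the same readers as real data)
# ---------------------------------------------------------------------------

def write_reference_pdb(model: StructureModel, path: str | Path,
                        n_waters: int = 0, seed: int = 0) -> None:
    """Write a reference complex as PDB, optionally with decoy waters."""
    if n_waters:
        rng = np.random.default_rng(seed)
        model = StructureModel(model.id, list(model.protein_atoms),
                               list(model.ligand_atoms),
                               list(model.ligand_bonds), list(model.metals))
        for w in range(n_waters):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            # emitted as HETATM HOH; readers must strip them
            model.metals.append(AtomRecord(
                "O", "O", direction * 25.0, ("W", "HOH", str(w + 1))))
    write_pdb(model, path)


def write_pose_mol2(poses: PoseSet, path: str | Path) -> None:
    mols = []
    for pid, atoms in zip(poses.pose_ids, poses.atoms):
        mol = m2.Mol2Molecule(name=pid)
        for a in atoms:
            st = a.sybyl_type or (f"{a.element}.3" if a.element != "H" else "H")
            mol.atoms.append(m2.Mol2Atom(
                name=a.name, coords=tuple(float(c) for c in a.coords),
                sybyl_type=st, subst_id=1, subst_name="LIG1",
                charge=float(a.formal_charge)))
        mol.bonds = list(poses.bonds)
        mols.append(mol)
    m2.write_mol2(mols, path)


def write_labels_tsv(poses: PoseSet, path: str | Path) -> None:
    rows = ["pose_id\tlabel\trmsd"]
    for pid, lab, rmsd in zip(poses.pose_ids, poses.labels, poses.rmsds):
        rows.append(f"{pid}\t{lab}\t{rmsd:.4f}")
    Path(path).write_text("\n".join(rows) + "\n")
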