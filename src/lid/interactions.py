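"""Geometric detection of protein-ligand non-covalent interactions.

Five interaction classes are detected — hydrogen bonds, ionic bonds, metal
chelation, pi-stacking and hydrophobic contacts — with the directional
classes split by which side carries the donor or the cation, giving seven
interaction types in total.  Each detected interaction is encoded as a
triplet of interaction pseudo-atoms (IPAs): one on the ligand side, one on
the protein side (a protein atom, charged-group center, ring centroid or
metal), and one at mid-distance between the two.  With three position tags
and seven types there are 21 possible IPA channels.

All geometric thresholds live in :class:`RuleSet` and are user-overridable;
the defaults are standard crystallographic contact criteria.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from . import chemdata, mol2 as m2
from .structures import AtomRecord, StructureModel

logger = logging.getLogger(__name__)


class InteractionType(Enum):
    HB_LIGAND_DONOR = "HBLD"
    HB_PROTEIN_DONOR = "HBPD"
    IONIC_LIGAND_CATION = "IONL"
    IONIC_PROTEIN_CATION = "IONP"
    METAL_CHELATION = "METC"
    PI_STACKING = "PIST"
    HYDROPHOBIC = "HPHO"


class Mode(Enum):
    LIGAND = "L"
    CENTER = "C"
    PROTEIN = "P"


Channel = tuple[Mode, InteractionType]


def all_channels() -> list[Channel]:
    """The 21 possible (position tag, interaction type) channels."""
    return [(m, t) for t in InteractionType for m in Mode]


@dataclass
class IPA:
    coords: np.ndarray
    mode: Mode
    itype: InteractionType

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def channel(self) -> Channel:
        return (self.mode, self.itype)


@dataclass
class InteractionRecord:
    """One detected interaction and its IPA triplet.

    ``protein_atom_index`` is an index into ``model.protein_atoms``, or -1
    when the protein-side anchor is not a single protein atom (ring centroid,
    charged-group center of several atoms, or a metal).  The same convention
    applies to ``ligand_atom_index`` for ligand ring centroids.
    """

    ipa_ligand: IPA
    ipa_center: IPA
    ipa_protein: IPA
    ligand_atom_index: int
    protein_atom_index: int
    distance: float
    angle: float | None = None


@dataclass
class RuleSet:
    """Geometric interaction criteria (distances in Angstrom, angles in deg).

    * Hydrogen bond: donor-acceptor heavy-atom distance <= ``hb_distance_max``
      and, when the donor carries an explicit hydrogen, D-H...A angle >=
      ``hb_angle_min`` (distance-only otherwise).
    * Ionic bond: opposite-sign charged-group centers <= ``ionic_distance_max``.
    * Metal chelation: metal to ligand N/O/S <= ``metal_distance_max``.
    * Hydrophobic: apolar C/S pair <= ``hydrophobic_distance_max``; aromatic
      carbons are excluded (their contacts are captured as pi-stacking).
    * Pi-stacking: ring-centroid distance <= ``pi_distance_max`` with an
      interplane angle <= ``pi_face_angle_max`` (face-to-face) or within
      [``pi_edge_angle_min``, ``pi_edge_angle_max``] (edge-to-face); both
      emit the single PI_STACKING type.
    """

    hb_distance_max: float = 3.5
    hb_angle_min: float = 120.0
    ionic_distance_max: float = 4.5
    metal_distance_max: float = 2.8
    hydrophobic_distance_max: float = 4.5
    pi_distance_max: float = 5.0
    pi_face_angle_max: float = 30.0
    pi_edge_angle_min: float = 60.0
    pi_edge_angle_max: float = 90.0
    cluster_hydrophobic: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RuleSet":
        return cls(**d)


def _make_record(lp: np.ndarray, pp: np.ndarray, itype: InteractionType,
                 li: int, pi: int, distance: float,
                 angle: float | None = None) -> InteractionRecord:
    center = (np.asarray(lp, float) + np.asarray(pp, float)) / 2.0
    return InteractionRecord(
        ipa_ligand=IPA(lp, Mode.LIGAND, itype),
        ipa_center=IPA(center, Mode.CENTER, itype),
        ipa_protein=IPA(pp, Mode.PROTEIN, itype),
        ligand_atom_index=li, protein_atom_index=pi,
        distance=float(distance), angle=angle,
    )


# ---------------------------------------------------------------------------
# perception
# ---------------------------------------------------------------------------

@dataclass
class _LigandPerception:
    donors: list[int]                     # heavy-atom indices
    donor_hydrogens: dict[int, list[int]]  # donor index -> H indices
    acceptors: list[int]
    cations: list[int]
    anions: list[int]
    apolar: list[int]
    chelators: list[int]                  # N/O/S heteroatoms
    rings: list[list[int]]                # aromatic rings (heavy-atom indices)


def perceive_ligand(atoms: Sequence[AtomRecord],
                    bonds: Sequence[tuple[int, int, str]]) -> _LigandPerception:
    """Assign donor/acceptor/charge/apolar/aromatic roles to ligand atoms.

    With explicit hydrogens, donors are N/O/S atoms bonded to H; without any
    hydrogen in the molecule, a SYBYL-type/element lookup is used instead.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j, _ in bonds:
        adj[i].append(j)
        adj[j].append(i)

    has_h = any(a.is_hydrogen for a in atoms)
    donors: list[int] = []
    donor_h: dict[int, list[int]] = {}
    acceptors: list[int] = []
    cations: list[int] = []
    anions: list[int] = []
    apolar: list[int] = []
    chelators: list[int] = []

    ring_atoms = _aromatic_ring_atoms(atoms, bonds)

    for i, a in enumerate(atoms):
        if a.is_hydrogen:
            continue
        el = a.element.upper()
        if a.formal_charge > 0:
            cations.append(i)
        elif a.formal_charge < 0:
            anions.append(i)
        if el in {"N", "O", "S"}:
            chelators.append(i)
            hs = [j for j in adj[i] if atoms[j].is_hydrogen]
            if hs:
                donors.append(i)
                donor_h[i] = hs
            elif not has_h and _table_donor(a):
                donors.append(i)
                donor_h[i] = []
        if el == "O" and a.formal_charge <= 0:
            acceptors.append(i)
        elif el == "N" and a.formal_charge <= 0:
            acceptors.append(i)
        if el == "C" and a.formal_charge == 0 and i not in ring_atoms:
            neighbors = {atoms[j].element.upper() for j in adj[i]
                         if not atoms[j].is_hydrogen}
            if not neighbors & {"N", "O", "F"}:
                apolar.append(i)
        elif el == "S" and a.formal_charge == 0:
            neighbors = {atoms[j].element.upper() for j in adj[i]
                         if not atoms[j].is_hydrogen}
            if neighbors <= {"C"}:
                apolar.append(i)

    rings = _aromatic_rings(atoms, bonds)
    return _LigandPerception(donors, donor_h, acceptors, cations, anions,
                             apolar, chelators, rings)


def _table_donor(a: AtomRecord) -> bool:
    st = a.sybyl_type.lower()
    if st:
        return st in {"n.3", "n.4", "n.am", "n.pl3", "o.3"}
    return a.element.upper() == "N"


def _aromatic_rings(atoms: Sequence[AtomRecord],
                    bonds: Sequence[tuple[int, int, str]]) -> list[list[int]]:
    """Aromatic rings: cycles of 'ar' bonds, or planar 5/6-membered C/N
    cycles when the bond block carries no aromatic orders (PDB CONECT)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    ar_edges = [(i, j) for i, j, order in bonds if order == "ar"]
    if ar_edges:
        g.add_edges_from(ar_edges)
        return [sorted(c) for c in nx.cycle_basis(g) if len(c) in (5, 6)]
    g.add_edges_from((i, j) for i, j, _ in bonds)
    rings = []
    for cyc in nx.cycle_basis(g):
        if len(cyc) not in (5, 6):
            continue
        if not all(atoms[i].element.upper() in {"C", "N"} for i in cyc):
            continue
        coords = np.array([atoms[i].coords for i in cyc])
        if _planarity_rms(coords) < 0.15:
            rings.append(sorted(cyc))
    return rings


def _aromatic_ring_atoms(atoms, bonds) -> set[int]:
    return {i for ring in _aromatic_rings(atoms, bonds) for i in ring}


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def _planarity_rms(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    normal = _plane_normal(coords)
    return float(np.sqrt(np.mean((centered @ normal) ** 2)))


def _protein_rings(model: StructureModel) -> list[tuple[np.ndarray, np.ndarray]]:
    """(centroid, normal) for every template aromatic ring in the protein."""
    by_res: dict = {}
    for idx, a in enumerate(model.protein_atoms):
        by_res.setdefault(a.residue_id, {})[a.name] = idx
    rings = []
    for rid, name_map in by_res.items():
        resname = rid[1]
        for ring_names in chemdata.AROMATIC_RINGS.get(resname, []):
            if all(n in name_map for n in ring_names):
                coords = np.array([model.protein_atoms[name_map[n]].coords
                                   for n in ring_names])
                rings.append((coords.mean(axis=0), _plane_normal(coords)))
    return rings


def _protein_charged_groups(model: StructureModel) -> list[tuple[np.ndarray, int, int]]:
    """(group center, sign, representative protein atom index)."""
    by_res: dict = {}
    for idx, a in enumerate(model.protein_atoms):
        by_res.setdefault(a.residue_id, {})[a.name] = idx
    groups = []
    for rid, name_map in by_res.items():
        tpl = chemdata.CHARGED_GROUPS.get(rid[1])
        if tpl is None:
            continue
        names, sign = tpl
        present = [n for n in names if n in name_map]
        if not present:
            continue
        coords = np.array([model.protein_atoms[name_map[n]].coords
                           for n in present])
        center = coords.mean(axis=0)
        rep = min(present,
                  key=lambda n: np.linalg.norm(model.protein_atoms[name_map[n]].coords - center))
        groups.append((center, sign, name_map[rep]))
    return groups


def _attached_protein_hydrogens(model: StructureModel, donor_idx: int) -> list[np.ndarray]:
    donor = model.protein_atoms[donor_idx]
    out = []
    for a in model.protein_atoms:
        if a.is_hydrogen and a.residue_id == donor.residue_id:
            if np.linalg.norm(a.coords - donor.coords) < 1.25:
                out.append(a.coords)
    return out


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_interactions(model: StructureModel,
                        rules: RuleSet | None = None) -> list[InteractionRecord]:
    """Detect all five interaction classes (including metal chelation)."""
    rules = rules or RuleSet()
    heavy = [i for i, a in enumerate(model.ligand_atoms) if not a.is_hydrogen]
    if not heavy:
        warnings.warn(f"{model.id}: ligand has no heavy atoms", stacklevel=2)
        return []

    lig = model.ligand_atoms
    per = perceive_ligand(lig, model.ligand_bonds)
    records: list[InteractionRecord] = []

    # --- hydrogen bonds ----------------------------------------------------
    prot_acceptors = [i for i, a in enumerate(model.protein_atoms)
                      if not a.is_hydrogen
                      and chemdata.protein_acceptors(a.residue_id[1], a.name)]
    prot_donors = [i for i, a in enumerate(model.protein_atoms)
                   if not a.is_hydrogen
                   and chemdata.protein_donors(a.residue_id[1], a.name)]

    for d in per.donors:  # ligand donor -> protein acceptor
        for p in prot_acceptors:
            dp = model.protein_atoms[p].coords
            dist = float(np.linalg.norm(lig[d].coords - dp))
            if dist > rules.hb_distance_max:
                continue
            angle = None
            hs = per.donor_hydrogens.get(d, [])
            if hs:
                angle = max(_angle_deg(lig[d].coords, lig[h].coords, dp)
                            for h in hs)
                if angle < rules.hb_angle_min:
                    continue
            records.append(_make_record(lig[d].coords, dp,
                                        InteractionType.HB_LIGAND_DONOR,
                                        d, p, dist, angle))

    for a_idx in per.acceptors:  # protein donor -> ligand acceptor
        for p in prot_donors:
            dp = model.protein_atoms[p].coords
            dist = float(np.linalg.norm(lig[a_idx].coords - dp))
            if dist > rules.hb_distance_max:
                continue
            angle = None
            hs = _attached_protein_hydrogens(model, p)
            if hs:
                angle = max(_angle_deg(dp, h, lig[a_idx].coords) for h in hs)
                if angle < rules.hb_angle_min:
                    continue
            records.append(_make_record(lig[a_idx].coords, dp,
                                        InteractionType.HB_PROTEIN_DONOR,
                                        a_idx, p, dist, angle))

    # --- ionic bonds -------------------------------------------------------
    groups = _protein_charged_groups(model)
    for li_list, want_sign, itype in (
        (per.cations, -1, InteractionType.IONIC_LIGAND_CATION),
        (per.anions, +1, InteractionType.IONIC_PROTEIN_CATION),
    ):
        for li in li_list:
            for center, sign, rep in groups:
                if sign != want_sign:
                    continue
                dist = float(np.linalg.norm(lig[li].coords - center))
                if dist <= rules.ionic_distance_max:
                    records.append(_make_record(lig[li].coords, center,
                                                itype, li,
                                                rep if sign else -1, dist))

    # --- metal chelation ---------------------------------------------------
    records.extend(detect_metal_chelation(model, rules))

    # --- pi stacking -------------------------------------------------------
    prot_rings = _protein_rings(model)
    for ring in per.rings:
        coords = np.array([lig[i].coords for i in ring])
        lcen, lnorm = coords.mean(axis=0), _plane_normal(coords)
        for pcen, pnorm in prot_rings:
            dist = float(np.linalg.norm(lcen - pcen))
            if dist > rules.pi_distance_max:
                continue
            cosang = abs(float(np.dot(lnorm, pnorm)))
            ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
            face = ang <= rules.pi_face_angle_max
            edge = rules.pi_edge_angle_min <= ang <= rules.pi_edge_angle_max
            if face or edge:
                records.append(_make_record(lcen, pcen,
                                            InteractionType.PI_STACKING,
                                            -1, -1, dist, ang))

    # --- hydrophobic contacts ----------------------------------------------
    prot_apolar = [i for i, a in enumerate(model.protein_atoms)
                   if not a.is_hydrogen
                   and chemdata.protein_apolar(a.residue_id[1], a.name)]
    hydro: list[InteractionRecord] = []
    for li in per.apolar:
        for p in prot_apolar:
            dp = model.protein_atoms[p].coords
            dist = float(np.linalg.norm(lig[li].coords - dp))
            if dist <= rules.hydrophobic_distance_max:
                hydro.append(_make_record(lig[li].coords, dp,
                                          InteractionType.HYDROPHOBIC,
                                          li, p, dist))
    if rules.cluster_hydrophobic:
        best: dict[int, InteractionRecord] = {}
        for rec in hydro:
            cur = best.get(rec.ligand_atom_index)
            if cur is None or rec.distance < cur.distance:
                best[rec.ligand_atom_index] = rec
        hydro = [best[k] for k in sorted(best)]
    records.extend(hydro)
    return records


def detect_metal_chelation(model: StructureModel,
                           rules: RuleSet | None = None) -> list[InteractionRecord]:
    """One record per ligand N/O/S heteroatom within chelation distance of a
    site metal; the protein-side IPA sits on the metal."""
    rules = rules or RuleSet()
    if not model.metals:
        return []
    per = perceive_ligand(model.ligand_atoms, model.ligand_bonds)
    records = []
    for metal in model.metals:
        for li in per.chelators:
            dist = float(np.linalg.norm(model.ligand_atoms[li].coords - metal.coords))
            if dist <= rules.metal_distance_max:
                records.append(_make_record(model.ligand_atoms[li].coords,
                                            metal.coords,
                                            InteractionType.METAL_CHELATION,
                                            li, -1, dist))
    return records


def to_ipa_list(records: Iterable[InteractionRecord]) -> list[IPA]:
    """Flatten records to IPAs, per record in ligand/center/protein order."""
    out: list[IPA] = []
    for rec in records:
        out.extend((rec.ipa_ligand, rec.ipa_center, rec.ipa_protein))
    return out


# ---------------------------------------------------------------------------
# IPA Mol2 dialect
# ---------------------------------------------------------------------------
# One pseudo-atom per IPA; the channel is encoded redundantly in the atom
# name and the SYBYL type field as "<TYPE>_<MODE>", e.g. HBLD_L for a
# hydrogen bond (ligand donor) ligand-side pseudo-atom.

_CODE_TO_TYPE = {t.value: t for t in InteractionType}
_CODE_TO_MODE = {m.value: m for m in Mode}


def channel_code(channel: Channel) -> str:
    mode, itype = channel
    return f"{itype.value}_{mode.value}"


def parse_channel_code(code: str) -> Channel:
    try:
        tcode, mcode = code.rsplit("_", 1)
        return (_CODE_TO_MODE[mcode], _CODE_TO_TYPE[tcode])
    except (ValueError, KeyError) as exc:
        raise m2.Mol2ParseError(f"unknown IPA channel code {code!r}") from exc


def write_ipa_mol2(ipas: Sequence[IPA], path: str | Path,
                   name: str = "LID_IPAS") -> None:
    """Write IPAs as a single Mol2 pseudomolecule."""
    mol = m2.Mol2Molecule(name=name)
    for ipa in ipas:
        code = channel_code(ipa.channel)
        mol.atoms.append(m2.Mol2Atom(
            name=code, coords=tuple(float(c) for c in ipa.coords),
            sybyl_type=code, subst_id=1, subst_name="IPA1", charge=0.0))
    m2.write_mol2([mol], path)


def read_ipa_mol2(path: str | Path) -> list[IPA]:
    mols = m2.read_mol2(path)
    ipas: list[IPA] = []
    for mol in mols:
        for k, atom in enumerate(mol.atoms, start=1):
            try:
                mode, itype = parse_channel_code(atom.name)
            except m2.Mol2ParseError as exc:
                raise m2.Mol2ParseError(
                    f"{path}: atom {k} ({atom.name!r}): {exc}") from exc
            ipas.append(IPA(np.array(atom.coords), mode, itype))
    return ipas
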