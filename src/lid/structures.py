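"""Structure I/O, binding-site definition and binding-site superposition.

A :class:`StructureModel` is one reference complex: protein atoms, exactly one
bound molecule (a drug-like ligand or a crystallization additive) and any site
metals.  Waters and non-selected HET groups (cofactors, cryoprotectants,
counter-ions) never enter ``protein_atoms``.

The consensus binding site is the set of residues with at least one
non-hydrogen atom closer than 6.5 A to any ligand non-hydrogen atom in more
than 10% of the structures.  All references are expressed in the frame of a
representative structure — the one whose site-Calpha RMSD to all others is
minimal on average — via least-squares rigid superposition on matched site
Calpha atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import chemdata, mol2 as m2

logger = logging.getLogger(__name__)

ResidueId = tuple[str, str, str]  # (chain, residue name, residue number string)


class FormatError(ValueError):
    """Unparseable structure file."""


class SelectionError(ValueError):
    """Ligand selector matched zero or several molecules."""


class AlignmentError(ValueError):
    """Not enough matched atoms to superpose."""


@dataclass
class AtomRecord:
    element: str
    name: str
    coords: np.ndarray  # (3,) Angstrom
    residue_id: ResidueId
    is_hydrogen: bool = False
    sybyl_type: str = ""
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError("atom element must be non-empty")


@dataclass
class StructureModel:
    id: str
    protein_atoms: list[AtomRecord] = field(default_factory=list)
    ligand_atoms: list[AtomRecord] = field(default_factory=list)
    # (i, j, order string) over ligand_atoms indices
    ligand_bonds: list[tuple[int, int, str]] = field(default_factory=list)
    metals: list[AtomRecord] = field(default_factory=list)

    def ligand_heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.ligand_atoms) if not a.is_hydrogen]

    def transformed(self, transform: "RigidTransform") -> "StructureModel":
        """Return a copy with every coordinate mapped through *transform*."""
        def conv(atoms: list[AtomRecord]) -> list[AtomRecord]:
            return [
                AtomRecord(a.element, a.name, transform.apply(a.coords),
                           a.residue_id, a.is_hydrogen, a.sybyl_type,
                           a.formal_charge)
                for a in atoms
            ]
        return StructureModel(self.id, conv(self.protein_atoms),
                              conv(self.ligand_atoms), list(self.ligand_bonds),
                              conv(self.metals))


@dataclass
class BindingSite:
    residues: set[ResidueId]
    per_structure_presence: dict[ResidueId, float]
    representative_id: str | None = None


@dataclass
class RigidTransform:
    """y = rotation @ x + translation (proper rotation, det = +1)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd_after_fit: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying *other* first, then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_selector(selector: str) -> tuple[str, int | None]:
    if ":" in selector:
        name, _, idx = selector.partition(":")
        return name.strip(), int(idx)
    return selector.strip(), None


def _element_from_sybyl(sybyl_type: str, name: str) -> str:
    if sybyl_type:
        el = sybyl_type.split(".")[0]
        if el and el[0].isalpha():
            return el.capitalize()
    return "".join(c for c in name if c.isalpha())[:2].capitalize() or "X"


def read_structure(
    path: str | Path,
    ligand_selector: str,
    cofactor_exclude: Iterable[str] | None = None,
) -> StructureModel:
    """Read a PDB or Mol2 complex and split it into protein / ligand / metals.

    *ligand_selector* is a HET code, optionally with a 1-based copy index
    (``"SO4:2"``) when the crystal contains several copies.  Waters and HET
    groups on the exclusion list are dropped; metals go to ``metals``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        return _read_pdb(path, ligand_selector, cofactor_exclude)
    if suffix == ".mol2":
        return _read_mol2_complex(path, ligand_selector, cofactor_exclude)
    raise FormatError(f"unsupported structure format: {path}")


def _read_pdb(path: Path, ligand_selector: str,
              cofactor_exclude: Iterable[str] | None) -> StructureModel:
    import gemmi

    exclude = set(cofactor_exclude) if cofactor_exclude is not None \
        else set(chemdata.DEFAULT_COFACTOR_EXCLUDE)
    sel_name, sel_copy = _parse_selector(ligand_selector)
    exclude.discard(sel_name)

    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # noqa: BLE001 - gemmi raises RuntimeError
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no model in {path}")
    model = st[0]

    protein: list[AtomRecord] = []
    metals: list[AtomRecord] = []
    # ligand copies: list of (residue_id, [(serial, AtomRecord)])
    copies: list[tuple[ResidueId, list[tuple[int, AtomRecord]]]] = []

    for chain in model:
        for res in chain:
            rid: ResidueId = (chain.name, res.name.strip(),
                              str(res.seqid.num) + res.seqid.icode.strip())
            atoms = _dedupe_altloc(res)
            is_het = res.het_flag == "H"
            recs = []
            for at in atoms:
                el = at.element.name.upper()
                recs.append((at.serial, AtomRecord(
                    element=at.element.name.capitalize() or at.name[:1],
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_id=rid,
                    is_hydrogen=el in {"H", "D"},
                    formal_charge=at.charge,
                )))
            if res.name.strip() in chemdata.WATER_NAMES:
                continue
            if res.name.strip() == sel_name:
                copies.append((rid, recs))
                continue
            if is_het:
                if (len(recs) == 1
                        and recs[0][1].element.upper() in chemdata.METAL_ELEMENTS):
                    metals.append(recs[0][1])
                elif res.name.strip() in exclude:
                    continue
                else:
                    # unselected HET group: treated as a cofactor, dropped
                    logger.info("dropping unselected HET group %s in %s",
                                res.name, path.name)
                continue
            protein.extend(r for _, r in recs)

    if not copies:
        raise SelectionError(f"selector {ligand_selector!r} matched nothing in {path}")
    if len(copies) > 1 and sel_copy is None:
        raise SelectionError(
            f"selector {ligand_selector!r} matched {len(copies)} copies in "
            f"{path}; disambiguate with '{sel_name}:<index>'")
    idx = (sel_copy - 1) if sel_copy is not None else 0
    if not 0 <= idx < len(copies):
        raise SelectionError(f"copy index {sel_copy} out of range for {sel_name}")
    _, lig_pairs = copies[idx]
    ligand = [r for _, r in lig_pairs]
    serial_to_index = {serial: i for i, (serial, _) in enumerate(lig_pairs)}
    bonds = _read_conect(path, serial_to_index)
    return StructureModel(path.stem, protein, ligand, bonds, metals)


def _dedupe_altloc(res) -> list:
    """Keep a single location per atom name, preferring highest occupancy."""
    best: dict[str, object] = {}
    for at in res:
        prev = best.get(at.name)
        if prev is None or at.occ > prev.occ:  # type: ignore[attr-defined]
            best[at.name] = at
    return list(best.values())


def _read_conect(path: Path, serial_to_index: dict[int, int]) -> list[tuple[int, int, str]]:
    bonds: set[tuple[int, int]] = set()
    for line in path.read_text().splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[6:11]] + [line[11 + 5 * k: 16 + 5 * k] for k in range(4)]
        serials = [int(f) for f in fields if f.strip()]
        if not serials:
            continue
        a = serials[0]
        for b in serials[1:]:
            if a in serial_to_index and b in serial_to_index:
                i, j = sorted((serial_to_index[a], serial_to_index[b]))
                bonds.add((i, j))
    return [(i, j, "1") for i, j in sorted(bonds)]


def read_protein(path: str | Path,
                 cofactor_exclude: Iterable[str] | None = None) -> StructureModel:
    """Read a PDB file as protein + metals only (no bound ligand expected)."""
    import gemmi

    path = Path(path)
    exclude = set(cofactor_exclude) if cofactor_exclude is not None \
        else set(chemdata.DEFAULT_COFACTOR_EXCLUDE)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no model in {path}")
    protein: list[AtomRecord] = []
    metals: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            if res.name.strip() in chemdata.WATER_NAMES:
                continue
            rid: ResidueId = (chain.name, res.name.strip(),
                              str(res.seqid.num) + res.seqid.icode.strip())
            atoms = _dedupe_altloc(res)
            recs = [AtomRecord(
                element=at.element.name.capitalize() or at.name[:1],
                name=at.name,
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                residue_id=rid,
                is_hydrogen=at.element.name.upper() in {"H", "D"},
                formal_charge=at.charge) for at in atoms]
            if res.het_flag == "H":
                if len(recs) == 1 and recs[0].element.upper() in chemdata.METAL_ELEMENTS:
                    metals.append(recs[0])
                elif res.name.strip() not in exclude:
                    logger.info("dropping HET group %s in %s", res.name, path.name)
                continue
            protein.extend(recs)
    return StructureModel(path.stem, protein, [], [], metals)


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _split_subst(subst_name: str) -> tuple[str, str]:
    """'SER12' -> ('SER', '12')."""
    base = subst_name.rstrip("0123456789")
    num = subst_name[len(base):] or "1"
    return base.upper(), num


def _read_mol2_complex(path: Path, ligand_selector: str,
                       cofactor_exclude: Iterable[str] | None) -> StructureModel:
    exclude = set(cofactor_exclude) if cofactor_exclude is not None \
        else set(chemdata.DEFAULT_COFACTOR_EXCLUDE)
    sel_name, sel_copy = _parse_selector(ligand_selector)
    exclude.discard(sel_name)
    try:
        mol = m2.read_mol2(path)[0]
    except m2.Mol2ParseError as exc:
        raise FormatError(str(exc)) from exc

    protein: list[AtomRecord] = []
    metals: list[AtomRecord] = []
    copies: dict[int, list[tuple[int, AtomRecord]]] = {}
    for i, a in enumerate(mol.atoms):
        resname, resnum = _split_subst(a.subst_name)
        el = _element_from_sybyl(a.sybyl_type, a.name)
        rec = AtomRecord(
            element=el, name=a.name, coords=np.array(a.coords),
            residue_id=("A", resname, resnum),
            is_hydrogen=el.upper() in {"H", "D"},
            sybyl_type=a.sybyl_type,
            formal_charge=int(round(a.charge)) if abs(a.charge) >= 0.5 else 0,
        )
        if resname in chemdata.WATER_NAMES:
            continue
        if resname == sel_name:
            copies.setdefault(a.subst_id, []).append((i, rec))
        elif resname in _AA3:
            protein.append(rec)
        elif len([x for x in mol.atoms if x.subst_id == a.subst_id]) == 1 \
                and el.upper() in chemdata.METAL_ELEMENTS:
            metals.append(rec)
        elif resname in exclude:
            continue
        else:
            logger.info("dropping unselected group %s in %s", resname, path.name)

    if not copies:
        raise SelectionError(f"selector {ligand_selector!r} matched nothing in {path}")
    keys = sorted(copies)
    if len(keys) > 1 and sel_copy is None:
        raise SelectionError(
            f"selector {ligand_selector!r} matched {len(keys)} copies in {path}")
    key = keys[(sel_copy - 1) if sel_copy is not None else 0]
    pairs = copies[key]
    orig_to_new = {orig: i for i, (orig, _) in enumerate(pairs)}
    bonds = [(orig_to_new[i], orig_to_new[j], order)
             for i, j, order in mol.bonds
             if i in orig_to_new and j in orig_to_new]
    return StructureModel(path.stem, protein, [r for _, r in pairs], bonds, metals)


def read_ligand_records(path: str | Path) -> list[tuple[str, list[AtomRecord], list[tuple[int, int, str]]]]:
    """Read every ligand record of a multi-molecule Mol2 or SDF pose file.

    Returns ``(pose_id, atoms, bonds)`` triples in file order.
    """
    path = Path(path)
    out = []
    if path.suffix.lower() == ".mol2":
        for k, mol in enumerate(m2.read_mol2(path)):
            atoms = []
            for a in mol.atoms:
                el = _element_from_sybyl(a.sybyl_type, a.name)
                atoms.append(AtomRecord(
                    element=el, name=a.name, coords=np.array(a.coords),
                    residue_id=("A", "LIG", "1"),
                    is_hydrogen=el.upper() in {"H", "D"},
                    sybyl_type=a.sybyl_type,
                    formal_charge=int(round(a.charge)) if abs(a.charge) >= 0.5 else 0,
                ))
            name = mol.name if mol.name != "UNNAMED" else f"pose{k + 1}"
            out.append((name, atoms, list(mol.bonds)))
        return out
    if path.suffix.lower() == ".sdf":
        from rdkit import Chem

        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for k, mol in enumerate(supplier):
            if mol is None:
                logger.warning("skipping unreadable SDF record %d in %s", k, path)
                continue
            conf = mol.GetConformer()
            atoms = []
            for atom in mol.GetAtoms():
                pos = conf.GetAtomPosition(atom.GetIdx())
                el = atom.GetSymbol()
                atoms.append(AtomRecord(
                    element=el, name=f"{el}{atom.GetIdx() + 1}",
                    coords=np.array([pos.x, pos.y, pos.z]),
                    residue_id=("A", "LIG", "1"),
                    is_hydrogen=el.upper() in {"H", "D"},
                    formal_charge=atom.GetFormalCharge(),
                ))
            bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                      "ar" if b.GetIsAromatic() else str(int(b.GetBondTypeAsDouble())))
                     for b in mol.GetBonds()]
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            out.append((name or f"pose{k + 1}", atoms, bonds))
        return out
    raise FormatError(f"unsupported pose format: {path}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_pdb(model: StructureModel, path: str | Path) -> None:
    lines: list[str] = []
    serial = 0
    ligand_serials: list[int] = []

    def emit(record: str, a: AtomRecord) -> int:
        nonlocal serial
        serial += 1
        chain, resname, resnum = a.residue_id
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        q = a.formal_charge
        charge_str = f"{abs(q)}{'+' if q > 0 else '-'}" if q else "  "
        lines.append(
            f"{record:<6s}{serial:>5d} {name:<4s}{'':1s}{resname:<3s} "
            f"{chain[:1]:1s}{int(''.join(ch for ch in resnum if ch.isdigit()) or 0):>4d}"
            f"{'':1s}   {a.coords[0]:>8.3f}{a.coords[1]:>8.3f}{a.coords[2]:>8.3f}"
            f"{1.0:>6.2f}{0.0:>6.2f}          {a.element.upper():>2s}{charge_str}"
        )
        return serial

    for a in model.protein_atoms:
        emit("ATOM", a)
    for a in model.ligand_atoms:
        ligand_serials.append(emit("HETATM", a))
    for a in model.metals:
        emit("HETATM", a)
    for i, j, _ in model.ligand_bonds:
        lines.append(f"CONECT{ligand_serials[i]:>5d}{ligand_serials[j]:>5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_site_tsv(site: BindingSite, path: str | Path) -> None:
    rows = ["chain\tresnum\tresname\tpresence"]
    for rid in sorted(site.residues):
        chain, resname, resnum = rid
        rows.append(f"{chain}\t{resnum}\t{resname}\t{site.per_structure_presence[rid]:.4f}")
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# binding site
# ---------------------------------------------------------------------------

def define_binding_site(
    structures: Sequence[StructureModel],
    contact_cutoff: float = 6.5,
    presence_threshold: float = 0.10,
) -> BindingSite:
    """Consensus residues: heavy-atom contact < *contact_cutoff* to the ligand
    in strictly more than *presence_threshold* of the structures."""
    if not structures:
        raise ValueError("define_binding_site needs at least one structure")
    counts: dict[ResidueId, int] = {}
    for st in structures:
        lig = np.array([a.coords for a in st.ligand_atoms if not a.is_hydrogen])
        if lig.size == 0:
            continue
        tree = cKDTree(lig)
        seen: set[ResidueId] = set()
        for a in st.protein_atoms:
            if a.is_hydrogen or a.residue_id in seen:
                continue
            d, _ = tree.query(a.coords)
            if d < contact_cutoff:
                seen.add(a.residue_id)
        for rid in seen:
            counts[rid] = counts.get(rid, 0) + 1
    n = len(structures)
    presence = {rid: c / n for rid, c in counts.items()}
    residues = {rid for rid, frac in presence.items() if frac > presence_threshold}
    return BindingSite(residues=residues, per_structure_presence=presence)


def _site_ca_map(model: StructureModel, site: BindingSite) -> dict[ResidueId, np.ndarray]:
    return {a.residue_id: a.coords for a in model.protein_atoms
            if a.name == "CA" and a.residue_id in site.residues}


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    from Bio.SVDSuperimposer import SVDSuperimposer

    sup = SVDSuperimposer()
    sup.set(np.asarray(target, float), np.asarray(mobile, float))
    sup.run()
    rot, tran = sup.get_rotran()  # y = x @ rot + tran
    return RigidTransform(rot.T, tran, float(sup.get_rms()))


def superpose(mobile: StructureModel, target: StructureModel,
              site: BindingSite) -> RigidTransform:
    """Least-squares rigid fit of *mobile* onto *target* on matched site Calpha."""
    ma, ta = _site_ca_map(mobile, site), _site_ca_map(target, site)
    common = sorted(set(ma) & set(ta))
    if len(common) < 3:
        raise AlignmentError(
            f"only {len(common)} matched site Calpha between "
            f"{mobile.id} and {target.id} (need >= 3)")
    x = np.array([ma[r] for r in common])
    y = np.array([ta[r] for r in common])
    return _kabsch(x, y)


def _pair_rmsd(a: StructureModel, b: StructureModel, site: BindingSite) -> float:
    try:
        return superpose(a, b, site).rmsd_after_fit
    except AlignmentError:
        warnings.warn(f"<3 common site Calpha between {a.id} and {b.id}; "
                      "RMSD set to +inf", stacklevel=2)
        return float("inf")


def select_representative(structures: Sequence[StructureModel],
                          site: BindingSite) -> str:
    """Structure with minimal mean site-Calpha RMSD to all others.

    Ties are broken by lexicographically smaller id.
    """
    if not structures:
        raise ValueError("select_representative needs at least one structure")
    if len(structures) == 1:
        site.representative_id = structures[0].id
        return structures[0].id
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _pair_rmsd(structures[i], structures[j], site)
    means = mat.sum(axis=1) / (n - 1)
    order = sorted(range(n), key=lambda i: (means[i], structures[i].id))
    rep = structures[order[0]].id
    site.representative_id = rep
    return rep


def site_rmsd(a: StructureModel, b: StructureModel, site: BindingSite,
              atoms: Literal["CA", "all-heavy"] = "CA",
              fit: bool = True) -> float:
    """RMSD over matched site atoms, after an internal rigid fit by default."""
    def atom_map(model: StructureModel) -> dict[tuple[ResidueId, str], np.ndarray]:
        out = {}
        for at in model.protein_atoms:
            if at.is_hydrogen or at.residue_id not in site.residues:
                continue
            if atoms == "CA" and at.name != "CA":
                continue
            out[(at.residue_id, at.name)] = at.coords
        return out

    am, bm = atom_map(a), atom_map(b)
    common = sorted(set(am) & set(bm))
    if not common:
        raise ValueError(f"no matched site atoms between {a.id} and {b.id}")
    x = np.array([am[k] for k in common])
    y = np.array([bm[k] for k in common])
    if fit and len(common) >= 3:
        x = _kabsch(x, y).apply(x)
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))
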