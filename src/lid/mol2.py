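"""Minimal SYBYL Mol2 reader/writer.

Supports the subset of the format the pipeline needs: ``@<TRIPOS>MOLECULE``,
``ATOM`` and ``BOND`` record types, multi-molecule files, substructure ids,
per-atom charges and free-form SYBYL atom-type strings.  The atom-type field
is preserved verbatim, which is what lets interaction pseudo-atom channels be
encoded in ordinary Mol2 files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence


@dataclass
class Mol2Atom:
    name: str
    coords: tuple[float, float, float]
    sybyl_type: str
    subst_id: int = 1
    subst_name: str = "MOL1"
    charge: float = 0.0


@dataclass
class Mol2Molecule:
    name: str
    atoms: list[Mol2Atom] = field(default_factory=list)
    # (i, j, order) with 0-based atom indices; order is the Mol2 string
    # ("1", "2", "3", "ar", "am", ...)
    bonds: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


class Mol2ParseError(ValueError):
    pass


def _iter_blocks(text: str) -> Iterator[list[str]]:
    """Yield the lines of each @<TRIPOS>MOLECULE block."""
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if line.strip().startswith("#"):
            continue
        if line.strip() == "@<TRIPOS>MOLECULE":
            if current is not None:
                yield current
            current = [line.strip()]
        elif current is not None:
            current.append(line)
    if current is not None:
        yield current


def _parse_block(lines: list[str]) -> Mol2Molecule:
    # section name -> list of lines
    sections: dict[str, list[str]] = {}
    name = None
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            name = stripped[len("@<TRIPOS>"):]
            sections.setdefault(name, [])
        elif name is not None and stripped:
            sections[name].append(stripped)

    mol_lines = sections.get("MOLECULE", [])
    if not mol_lines:
        raise Mol2ParseError("MOLECULE section is empty")
    mol = Mol2Molecule(name=mol_lines[0].strip() or "UNNAMED")

    for ln in sections.get("ATOM", []):
        parts = ln.split()
        if len(parts) < 6:
            raise Mol2ParseError(f"bad ATOM line: {ln!r}")
        try:
            x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
        except ValueError as exc:
            raise Mol2ParseError(f"bad coordinates in ATOM line: {ln!r}") from exc
        atom = Mol2Atom(
            name=parts[1],
            coords=(x, y, z),
            sybyl_type=parts[5],
            subst_id=int(parts[6]) if len(parts) > 6 else 1,
            subst_name=parts[7] if len(parts) > 7 else "MOL1",
            charge=float(parts[8]) if len(parts) > 8 else 0.0,
        )
        mol.atoms.append(atom)

    for ln in sections.get("BOND", []):
        parts = ln.split()
        if len(parts) < 4:
            raise Mol2ParseError(f"bad BOND line: {ln!r}")
        i, j = int(parts[1]) - 1, int(parts[2]) - 1
        if not (0 <= i < mol.n_atoms and 0 <= j < mol.n_atoms):
            raise Mol2ParseError(f"bond references missing atom: {ln!r}")
        mol.bonds.append((i, j, parts[3]))
    return mol


def read_mol2(path: str | Path) -> list[Mol2Molecule]:
    """Read every molecule record in a Mol2 file."""
    text = Path(path).read_text()
    mols = [_parse_block(block) for block in _iter_blocks(text)]
    if not mols:
        raise Mol2ParseError(f"no @<TRIPOS>MOLECULE record in {path}")
    return mols


def format_mol2(mols: Sequence[Mol2Molecule]) -> str:
    out: list[str] = []
    for mol in mols:
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.name)
        n_subst = len({a.subst_id for a in mol.atoms}) or 1
        out.append(f"{mol.n_atoms:>5d} {len(mol.bonds):>5d} {n_subst:>5d} 0 0")
        out.append("SMALL")
        out.append("USER_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for i, a in enumerate(mol.atoms, start=1):
            x, y, z = a.coords
            out.append(
                f"{i:>7d} {a.name:<8s} {x:>10.4f} {y:>10.4f} {z:>10.4f} "
                f"{a.sybyl_type:<10s} {a.subst_id:>3d} {a.subst_name:<8s} {a.charge:>9.4f}"
            )
        out.append("@<TRIPOS>BOND")
        for b, (i, j, order) in enumerate(mol.bonds, start=1):
            out.append(f"{b:>6d} {i + 1:>5d} {j + 1:>5d} {order:>4s}")
    return "\n".join(out) + "\n"


def write_mol2(mols: Sequence[Mol2Molecule], path: str | Path) -> None:
    Path(path).write_text(format_mol2(mols))
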