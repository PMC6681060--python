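"""Chemical perception lookup tables.

Protein-side hydrogen-bond donors/acceptors, charged groups, aromatic rings
and apolar atoms are assigned from per-residue atom-name templates (the usual
approach when protein structures carry no explicit hydrogens or bond orders).
Ligand-side perception is element/SYBYL-type based and lives in
:mod:`lid.interactions`.
"""

from __future__ import annotations

# Residues for which no template exists contribute only backbone donors and
# acceptors.  Atom names follow PDB v3 conventions.

BACKBONE_DONORS = {"N"}       # amide NH; Pro handled below
BACKBONE_ACCEPTORS = {"O", "OXT"}

SIDECHAIN_DONORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "TRP": {"NE1"},
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}

SIDECHAIN_ACCEPTORS: dict[str, set[str]] = {
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}

# residue -> (atom names forming the charged group, sign)
CHARGED_GROUPS: dict[str, tuple[set[str], int]] = {
    "ASP": ({"OD1", "OD2"}, -1),
    "GLU": ({"OE1", "OE2"}, -1),
    "LYS": ({"NZ"}, +1),
    "ARG": ({"NE", "NH1", "NH2"}, +1),
    "HIS": ({"ND1", "NE2"}, +1),
}

# residue -> list of rings, each a tuple of member atom names
AROMATIC_RINGS: dict[str, list[tuple[str, ...]]] = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "TRP": [
        ("CG", "CD1", "CD2", "NE1", "CE2"),
        ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    ],
}

# Aliphatic side-chain carbons (and thioether sulfurs) treated as apolar.
# Aromatic ring carbons are deliberately absent: stacked rings are captured by
# the pi-stacking rule, not by per-atom hydrophobic pairs.
APOLAR_ATOMS: dict[str, set[str]] = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PRO": {"CB", "CG", "CD"},
    "PHE": {"CB"},
    "TYR": {"CB"},
    "TRP": {"CB"},
    "LYS": {"CB", "CG", "CD"},
    "ARG": {"CB", "CG"},
    "THR": {"CG2"},
    "GLU": {"CB", "CG"},
    "GLN": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "CYS": {"CB"},
    "HIS": {"CB"},
    "SER": set(),
    "GLY": set(),
}

METAL_ELEMENTS = {
    "ZN", "MG", "CA", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CD", "HG",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# HET codes stripped from the protein by default when not the selected ligand:
# waters, halide counter-ions and glycerol-type cryoprotectants.
DEFAULT_COFACTOR_EXCLUDE = WATER_NAMES | {
    "CL", "BR", "IOD", "F", "NO3", "GOL", "EDO", "PEG", "PG4", "DMS", "MPD",
}

HB_ELEMENTS = {"N", "O"}          # heavy-atom H-bond partners
CHELATION_ELEMENTS = {"N", "O", "S"}


def protein_donors(resname: str, atom_name: str) -> bool:
    if atom_name in BACKBONE_DONORS:
        return resname != "PRO"
    return atom_name in SIDECHAIN_DONORS.get(resname, set())


def protein_acceptors(resname: str, atom_name: str) -> bool:
    if atom_name in BACKBONE_ACCEPTORS:
        return True
    return atom_name in SIDECHAIN_ACCEPTORS.get(resname, set())


def protein_apolar(resname: str, atom_name: str) -> bool:
    return atom_name in APOLAR_ATOMS.get(resname, set())
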