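"""Residue chemistry tables: atom inventories, bonded topology, ring groups.

Everything downstream (hydrogen placement, restraint generation, atom
accounting) is driven by these tables, so they are the single source of
truth for what a nucleotide residue *is* in this package.

Conventions: PDB v3.3 atom names with primed sugar atoms (C1', O5', ...),
OP1/OP2 phosphate oxygens, terminal hydroxyl hydrogens H5T / H3T.
Residue names: RNA A/C/G/U, DNA DA/DC/DG/DT plus DU for deoxyuridine.
"""

from __future__ import annotations

DNA = "DNA"
RNA = "RNA"

#: residue name -> (chemistry, one-letter base code)
RESIDUE_CODES = {
    "A": (RNA, "A"), "C": (RNA, "C"), "G": (RNA, "G"), "U": (RNA, "U"),
    # 5-methyluridine: the transient intermediate right after uracil
    # methylation, before the sugar swap renames it DT
    "T": (RNA, "T"),
    "DA": (DNA, "A"), "DC": (DNA, "C"), "DG": (DNA, "G"),
    "DT": (DNA, "T"), "DU": (DNA, "U"),
}

#: base letter + chemistry -> residue name
def residue_name(base: str, chemistry: str) -> str:
    if chemistry == RNA:
        if base == "T":
            raise KeyError("RNA residues cannot be thymine")
        return base
    return "D" + base

WC_PARTNER = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

PURINES = {"A", "G"}

# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

PHOSPHATE_ATOMS = ["P", "OP1", "OP2"]

SUGAR_COMMON = [
    "O5'", "C5'", "H5'", "H5''", "C4'", "H4'", "O4'",
    "C1'", "H1'", "C2'", "H2'", "C3'", "H3'", "O3'",
]

RNA_SUGAR_EXTRA = ["O2'", "HO2'"]   # 2'-hydroxyl
DNA_SUGAR_EXTRA = ["H2''"]          # second 2' hydrogen

BACKBONE_BONDS_COMMON = [
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"),
    ("O5'", "C5'"), ("C5'", "H5'"), ("C5'", "H5''"), ("C5'", "C4'"),
    ("C4'", "H4'"), ("C4'", "O4'"), ("C4'", "C3'"),
    ("O4'", "C1'"), ("C1'", "H1'"), ("C1'", "C2'"),
    ("C2'", "H2'"), ("C2'", "C3'"), ("C3'", "H3'"), ("C3'", "O3'"),
]

RNA_SUGAR_BONDS = [("C2'", "O2'"), ("O2'", "HO2'")]
DNA_SUGAR_BONDS = [("C2'", "H2''")]

FIVE_PRIME_OH = [("O5'", "H5T")]
THREE_PRIME_OH = [("O3'", "H3T")]

# ---------------------------------------------------------------------------
# bases
# ---------------------------------------------------------------------------

BASE_ATOMS = {
    "A": ["N9", "C8", "H8", "N7", "C5", "C6", "N6", "H61", "H62",
          "N1", "C2", "H2", "N3", "C4"],
    "G": ["N9", "C8", "H8", "N7", "C5", "C6", "O6", "N1", "H1",
          "C2", "N2", "H21", "H22", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "H41", "H42",
          "C5", "H5", "C6", "H6"],
    "T": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5",
          "C7", "H71", "H72", "H73", "C6", "H6"],
    "U": ["N1", "C2", "O2", "N3", "H3", "C4", "O4", "C5", "H5",
          "C6", "H6"],
}

BASE_BONDS = {
    "A": [("N9", "C8"), ("C8", "H8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "N6"), ("N6", "H61"), ("N6", "H62"),
          ("C6", "N1"), ("N1", "C2"), ("C2", "H2"), ("C2", "N3"),
          ("N3", "C4"), ("C4", "N9"), ("C4", "C5")],
    "G": [("N9", "C8"), ("C8", "H8"), ("C8", "N7"), ("N7", "C5"),
          ("C5", "C6"), ("C6", "O6"), ("C6", "N1"), ("N1", "H1"),
          ("N1", "C2"), ("C2", "N2"), ("N2", "H21"), ("N2", "H22"),
          ("C2", "N3"), ("N3", "C4"), ("C4", "N9"), ("C4", "C5")],
    "C": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "C4"),
          ("C4", "N4"), ("N4", "H41"), ("N4", "H42"), ("C4", "C5"),
          ("C5", "H5"), ("C5", "C6"), ("C6", "H6"), ("C6", "N1")],
    "T": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "H3"),
          ("N3", "C4"), ("C4", "O4"), ("C4", "C5"), ("C5", "C7"),
          ("C7", "H71"), ("C7", "H72"), ("C7", "H73"),
          ("C5", "C6"), ("C6", "H6"), ("C6", "N1")],
    "U": [("N1", "C2"), ("C2", "O2"), ("C2", "N3"), ("N3", "H3"),
          ("N3", "C4"), ("C4", "O4"), ("C4", "C5"), ("C5", "H5"),
          ("C5", "C6"), ("C6", "H6"), ("C6", "N1")],
}

#: atoms restrained to a common plane (ring plus exocyclic sp2 substituents)
BASE_PLANE_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"],
    "C": ["N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"],
    "T": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"],
    "U": ["N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"],
}

def glycosidic_nitrogen(base: str) -> str:
    return "N9" if base in PURINES else "N1"

#: Watson-Crick donor/acceptor heavy-atom contacts, (purine atom, pyrimidine
#: atom, target distance in angstroms).
WC_HBONDS = {
    ("A", "T"): [("N1", "N3", 2.82), ("N6", "O4", 2.95)],
    ("A", "U"): [("N1", "N3", 2.82), ("N6", "O4", 2.95)],
    ("G", "C"): [("O6", "N4", 2.91), ("N1", "N3", 2.95), ("N2", "O2", 2.86)],
}

def wc_hbonds(base_a: str, base_b: str):
    """H-bond contacts for an ordered base pair; atoms returned in the same
    order as the arguments."""
    if (base_a, base_b) in WC_HBONDS:
        return [(x, y, d) for x, y, d in WC_HBONDS[(base_a, base_b)]]
    if (base_b, base_a) in WC_HBONDS:
        return [(y, x, d) for x, y, d in WC_HBONDS[(base_b, base_a)]]
    raise KeyError(f"{base_a}-{base_b} is not a Watson-Crick pair")

# ---------------------------------------------------------------------------
# whole-residue inventories
# ---------------------------------------------------------------------------

def expected_atoms(resname: str, *, has_5p_phosphate: bool,
                   is_3p_terminal: bool, is_5p_terminal: bool) -> list[str]:
    """Full atom-name inventory for one residue at a given chain position.

    The default terminal chemistry is 5'-OH / 3'-OH: the 5'-terminal residue
    drops the phosphate group and gains H5T, the 3'-terminal residue gains
    H3T.
    """
    chemistry, base = RESIDUE_CODES[resname]
    atoms: list[str] = []
    if has_5p_phosphate:
        atoms += PHOSPHATE_ATOMS
    atoms += SUGAR_COMMON
    atoms += RNA_SUGAR_EXTRA if chemistry == RNA else DNA_SUGAR_EXTRA
    if is_5p_terminal and not has_5p_phosphate:
        atoms.append("H5T")
    if is_3p_terminal:
        atoms.append("H3T")
    atoms += BASE_ATOMS[base]
    return atoms


def residue_bonds(resname: str, *, has_5p_phosphate: bool,
                  is_3p_terminal: bool, is_5p_terminal: bool):
    """Intra-residue bonded pairs for one residue at a given chain position."""
    chemistry, base = RESIDUE_CODES[resname]
    bonds = []
    if has_5p_phosphate:
        bonds += [("P", "OP1"), ("P", "OP2"), ("P", "O5'")]
    bonds += [b for b in BACKBONE_BONDS_COMMON if b[0] != "P"]
    bonds += RNA_SUGAR_BONDS if chemistry == RNA else DNA_SUGAR_BONDS
    if is_5p_terminal and not has_5p_phosphate:
        bonds += FIVE_PRIME_OH
    if is_3p_terminal:
        bonds += THREE_PRIME_OH
    bonds += BASE_BONDS[base]
    bonds.append(("C1'", glycosidic_nitrogen(base)))
    return bonds


INTER_RESIDUE_BOND = ("O3'", "P")  # i -> i+1 phosphodiester linkage


def element_of(atom_name: str) -> str:
    """Element symbol inferred from a (nucleic acid) PDB v3 atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ChemistryKeyError(atom_name)


class ChemistryKeyError(KeyError):
    pass
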