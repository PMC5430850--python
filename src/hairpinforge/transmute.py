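"""RNA-to-DNA chemistry engine with exact atom accounting.

The third stage of the pipeline converts the RNA-geometry intermediate
into a DNA model in place: hydrogens are completed where missing, every
uracil is methylated at C5 (the H5 atom is replaced by a C7 methyl
group, net +3 atoms, turning U into T), and the ribose is converted to
deoxyribose (O2'/HO2' removed, H2'' added, net -1 atom per residue),
with residues renamed A/C/G/U -> DA/DC/DG/DT.

Terminal chemistry is 5'-hydroxyl / 3'-hydroxyl: the 5'-terminal residue
has no phosphate group and carries H5T, the 3'-terminal residue carries
H3T.  Under this model a DNA chain of the printed pipeline sequences
reproduces the published per-system atom totals, and the formal charge
is -(length - 1), one negative charge per internucleotide phosphate.
"""

from __future__ import annotations

import json
import math

import numpy as np

from . import chem
from .build3d import TemplateLibrary, load_templates
from .errors import ChemistryError, WrongChemistryError
from .nucio import AtomRecord, Model3D, NucSequence

# ---------------------------------------------------------------------------
# closed-form atom accounting
# ---------------------------------------------------------------------------

#: backbone atom count of an internal (phosphate-bearing) residue
BACKBONE_ATOMS_DNA = 18
BACKBONE_ATOMS_RNA = 19
#: base atom counts (hydrogens included)
BASE_ATOM_COUNT = {"A": 14, "G": 15, "C": 12, "T": 14, "U": 11}
#: 5'-OH terminus: drop P/OP1/OP2, gain H5T
FIVE_PRIME_OH_ADJUST = -2
#: 3'-OH terminus: gain H3T
THREE_PRIME_OH_ADJUST = +1


def count_atoms(seq: NucSequence, chemistry: str | None = None) -> int:
    """All-atom count of a protonated chain with 5'-OH/3'-OH termini."""
    chemistry = chemistry or seq.chemistry
    backbone = (BACKBONE_ATOMS_DNA if chemistry == chem.DNA
                else BACKBONE_ATOMS_RNA)
    total = sum(backbone + BASE_ATOM_COUNT[c] for c in seq.residues)
    return total + FIVE_PRIME_OH_ADJUST + THREE_PRIME_OH_ADJUST


def formal_charge(seq: NucSequence) -> int:
    """Formal charge of an OH-terminated chain: one negative charge per
    internucleotide phosphate, i.e. -(length - 1)."""
    return -(len(seq) - 1)


def accounting_report(seq: NucSequence, chemistry: str | None = None) -> str:
    charge = formal_charge(seq)
    return json.dumps({
        "sequence": seq.residues,
        "chemistry": chemistry or seq.chemistry,
        "atoms": count_atoms(seq, chemistry),
        "formal_charge": charge,
        "neutralizing_na": max(0, -charge),
    }, indent=2)


# ---------------------------------------------------------------------------
# hydrogen placement
# ---------------------------------------------------------------------------

def _bond_graph(resname, present):
    """Atom -> bonded neighbours, for the atoms actually present."""
    bonds = chem.residue_bonds(resname, has_5p_phosphate="P" in present,
                               is_3p_terminal="H3T" in present,
                               is_5p_terminal="H5T" in present)
    # include hydrogens that may be about to be added
    graph = {}
    for a1, a2 in bonds:
        graph.setdefault(a1, []).append(a2)
        graph.setdefault(a2, []).append(a1)
    return graph


def add_hydrogens(model: Model3D,
                  templates: TemplateLibrary | None = None) -> Model3D:
    """Complete each residue's hydrogen set (idempotent).

    Every missing hydrogen is placed by rigidly superposing the
    template's local environment of its parent heavy atom (the parent
    plus its heavy neighbours) onto the model, then copying the
    template hydrogen through that transform — canonical bond lengths
    and angles by construction.
    """
    templates = templates or load_templates("builtin")
    out = model.copy()
    n = len(out.residues)
    for ri, res in enumerate(out.residues):
        if res.name not in chem.RESIDUE_CODES:
            raise ChemistryError(f"unknown residue {res.name!r}")
        tpl = templates.template(res.name).atoms
        expected = chem.expected_atoms(
            res.name, has_5p_phosphate=res.has_atom("P"),
            is_3p_terminal=(ri == n - 1), is_5p_terminal=(ri == 0))
        present = set(res.atom_names)
        graph = _bond_graph(res.name, set(expected))
        for name in expected:
            if name in present or not name.startswith("H"):
                continue
            parent = [p for p in graph.get(name, []) if p in present]
            if not parent:
                raise ChemistryError(
                    f"{res.name}{res.index}: cannot place {name}, "
                    f"parent atom missing")
            parent = parent[0]
            anchor_names = [parent] + [
                p for p in graph.get(parent, [])
                if p in present and not p.startswith("H")]
            anchor_names = [a for a in anchor_names if a in tpl]
            if len(anchor_names) < 3:
                # extend with second-shell heavy atoms
                for p in list(graph.get(parent, [])):
                    for q in graph.get(p, []):
                        if (q in present and q in tpl and not
                                q.startswith("H") and q not in anchor_names):
                            anchor_names.append(q)
                anchor_names = anchor_names[:4]
            if name not in tpl or len(anchor_names) < 3:
                raise ChemistryError(
                    f"{res.name}{res.index}: no template geometry "
                    f"for {name}")
            P = np.array([tpl[a] for a in anchor_names])
            Q = np.array([res.atom(a).xyz for a in anchor_names])
            R, t = _rigid_fit(P, Q)
            res.atoms.append(AtomRecord(name, "H", R @ tpl[name] + t))
        # keep canonical atom order
        order = {nm: k for k, nm in enumerate(expected)}
        res.atoms.sort(key=lambda a: order.get(a.name, 99))
    return out


def _rigid_fit(P, Q):
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cq - R @ cp


# ---------------------------------------------------------------------------
# uracil -> thymine (C5 methylation)
# ---------------------------------------------------------------------------

_CC_METHYL = 1.50   # C5-C7 bond length, A
_CH = 1.09          # methyl C-H, A
_TETRA = math.radians(109.5)


def uracil_to_thymine(model: Model3D) -> Model3D:
    """Methylate every uracil at C5: H5 is replaced by C7 + H71/H72/H73.

    One methyl hydrogen is placed anti to C4; the others are staggered
    about the new C5-C7 bond.  U residues become T (DU -> DT), all other
    residues are untouched.
    """
    out = model.copy()
    for res in out.residues:
        base = chem.RESIDUE_CODES.get(res.name, (None, None))[1]
        if base != "U":
            continue
        if not res.has_atom("H5"):
            raise ChemistryError(
                f"{res.name}{res.index}: uracil lacks H5; protonate first")
        c5 = res.atom("C5").xyz
        c4 = res.atom("C4").xyz
        h5 = res.atom("H5").xyz
        axis = h5 - c5
        axis = axis / np.linalg.norm(axis)
        c7 = c5 + _CC_METHYL * axis
        # reference direction for the anti hydrogen: away from C4,
        # perpendicular component relative to the C5-C7 axis
        ref = c5 - c4
        ref = ref - (ref @ axis) * axis
        nref = np.linalg.norm(ref)
        if nref < 1e-6:
            ref = np.array([1.0, 0.0, 0.0])
            ref = ref - (ref @ axis) * axis
            nref = np.linalg.norm(ref)
        ref /= nref
        perp2 = np.cross(axis, ref)
        hs = []
        for k in range(3):
            phi = 2.0 * math.pi * k / 3.0
            direction = (math.cos(_TETRA - math.pi / 2) *
                         (math.cos(phi) * ref + math.sin(phi) * perp2)
                         + math.sin(_TETRA - math.pi / 2) * axis)
            direction /= np.linalg.norm(direction)
            hs.append(c7 + _CH * direction)
        res.atoms.remove(res.atom("H5"))
        i_c5 = [a.name for a in res.atoms].index("C5")
        new = [AtomRecord("C7", "C", c7)] + [
            AtomRecord(f"H7{k+1}", "H", h) for k, h in enumerate(hs)]
        res.atoms[i_c5 + 1:i_c5 + 1] = new
        res.name = "DT" if res.name == "DU" else "T" \
            if res.name == "U" else res.name
    return out


# ---------------------------------------------------------------------------
# ribose -> deoxyribose
# ---------------------------------------------------------------------------

def ribose_to_deoxyribose(model: Model3D) -> Model3D:
    """Replace every ribose with deoxyribose and flip chemistry to DNA.

    Per residue: O2' and HO2' are removed and H2'' is added at the
    vacated tetrahedral position of C2'; residue names map A -> DA,
    C -> DC, G -> DG, U -> DU, and a previously methylated uracil
    (already renamed T) becomes DT.  Coordinates of untouched atoms are
    unchanged.
    """
    if model.chemistry != chem.RNA:
        raise WrongChemistryError("model is already DNA")
    out = model.copy()
    for res in out.residues:
        o2 = res.atom("O2'").xyz if res.has_atom("O2'") else None
        if o2 is None:
            raise ChemistryError(
                f"{res.name}{res.index}: no O2' to remove")
        c2 = res.atom("C2'").xyz
        # H2'' along the old C2'-O2' direction at C-H bond length
        direction = o2 - c2
        direction /= np.linalg.norm(direction)
        h22 = c2 + _CH * direction
        res.atoms = [a for a in res.atoms if a.name not in ("O2'", "HO2'")]
        i_h2 = [a.name for a in res.atoms].index("H2'")
        res.atoms.insert(i_h2 + 1, AtomRecord("H2''", "H", h22))
        if res.name in ("A", "C", "G", "U", "T"):
            res.name = "D" + res.name
    out.chemistry = chem.DNA
    return out


def rna_to_dna(model: Model3D,
               templates: TemplateLibrary | None = None) -> Model3D:
    """The full conversion stage: protonate, methylate uracils, swap the
    sugar.  Returns a DNA-chemistry model."""
    m = add_hydrogens(model, templates)
    m = uracil_to_thymine(m)
    return ribose_to_deoxyribose(m)
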