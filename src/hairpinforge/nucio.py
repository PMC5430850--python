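"""Sequence and structure I/O plus the core domain types.

Handles every on-disk format the pipeline touches: FASTA sequences,
CT (Zuker connect) and dot-bracket secondary structures, PDB v3.3
coordinate files and TSV candidate tables.  PDB parsing and writing is
delegated to gemmi; FASTA parsing to Biopython.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO

from . import chem
from .errors import (
    ChemistryError,
    ConsistencyError,
    FormatOverflowError,
    ParseError,
)

DNA = chem.DNA
RNA = chem.RNA

_ALPHABET = set("ACGTU")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class NucSequence:
    """A validated nucleotide sequence with a chemistry tag.

    A ``U`` inside a DNA chain is legal and denotes deoxyuridine; a ``T``
    inside an RNA chain is not.
    """

    identifier: str
    residues: str
    chemistry: str = DNA

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ChemistryError(f"{self.identifier!r}: empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ChemistryError(
                f"{self.identifier!r}: illegal letters {sorted(bad)}")
        if self.chemistry not in (DNA, RNA):
            raise ChemistryError(f"unknown chemistry {self.chemistry!r}")
        if self.chemistry == RNA and "T" in self.residues:
            raise ChemistryError(
                f"{self.identifier!r}: RNA chain may not contain T")

    def __len__(self):
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]


@dataclasses.dataclass(frozen=True)
class CandidateRecord:
    """One row of the bundled candidate table (one PDB entry).

    ``sequence_raw`` preserves the printed sequence string verbatim, which
    for some excluded entries contains non-standard letters (X, N, P)
    marking chemically modified residues; ``nuc_sequence()`` converts to a
    validated :class:`NucSequence` and only succeeds for standard chains.
    """

    pdb_id: str
    pmid: str
    chain_length: int
    sequence_raw: str
    g_score: int
    has_ligand: bool
    motif_class: str
    excluded: bool
    exclusion_reason: str
    length_conflict: bool = False
    duplicate_conflict: bool = False

    def __post_init__(self):
        if self.excluded != bool(self.exclusion_reason):
            raise ConsistencyError(
                f"{self.pdb_id}: excluded flag must match exclusion_reason")
        if self.g_score < 0:
            raise ConsistencyError(f"{self.pdb_id}: negative G-score")
        if self.chain_length != len(self.sequence_raw):
            raise ConsistencyError(
                f"{self.pdb_id}: chain_length != sequence length")

    def nuc_sequence(self) -> NucSequence:
        return NucSequence(self.pdb_id, self.sequence_raw, DNA)


@dataclasses.dataclass
class AtomRecord:
    name: str
    element: str
    xyz: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)


@dataclasses.dataclass
class Residue3D:
    name: str
    index: int
    atoms: list

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.index} has no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def atom_names(self):
        return [a.name for a in self.atoms]


@dataclasses.dataclass
class Model3D:
    """Ordered all-atom coordinate model of one nucleic acid chain (A)."""

    chain_id: str
    residues: list
    chemistry: str = RNA

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for r in self.residues for a in r.atoms],
                        dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if len(xyz) != self.n_atoms:
            raise ConsistencyError("coordinate array length mismatch")
        k = 0
        for r in self.residues:
            for a in r.atoms:
                a.xyz = xyz[k].copy()
                k += 1

    def atom_index(self):
        """(residue position, residue name, atom name) per flat atom row."""
        out = []
        for ri, r in enumerate(self.residues):
            for a in r.atoms:
                out.append((ri, r.name, a.name))
        return out

    def sequence_letters(self) -> str:
        return "".join(chem.RESIDUE_CODES[r.name][1] for r in self.residues)

    def copy(self) -> "Model3D":
        return Model3D(
            self.chain_id,
            [Residue3D(r.name, r.index,
                       [AtomRecord(a.name, a.element, a.xyz.copy())
                        for a in r.atoms])
             for r in self.residues],
            self.chemistry,
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, chemistry: str = DNA) -> list[NucSequence]:
    """Read a (multi-record) FASTA file into validated sequences.

    Letters are upper-cased; anything outside {A,C,G,T,U} raises a
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            lineno = _find_line(path, sorted(bad)[0], rec.id)
            raise ParseError(
                f"{path}:{lineno}: illegal letter {sorted(bad)[0]!r} "
                f"in record {rec.id!r}")
        try:
            out.append(NucSequence(rec.id, seq, chemistry))
        except ChemistryError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return out


def _find_line(path: Path, letter: str, rec_id: str) -> int:
    """Best-effort line number of an illegal letter, for error messages."""
    in_record = False
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == rec_id if line[1:].strip() else False
            continue
        if in_record and letter in line.upper():
            return i
    return 0


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# CT / dot-bracket
# ---------------------------------------------------------------------------

def write_ct(seq: NucSequence, ss, path) -> None:
    """Write a standard CT (connect) file.

    Header: length and free energy; then one line per base with
    index, letter, i-1, i+1, pairing partner (0 if unpaired), index.
    """
    n = len(seq)
    if len(ss.pair) != n:
        raise ConsistencyError(
            f"pair table length {len(ss.pair)} != sequence length {n}")
    with open(path, "w") as fh:
        fh.write(f"{n}\tdG = {ss.dg:.2f}\t{seq.identifier}\n")
        for i in range(1, n + 1):
            nxt = i + 1 if i < n else 0
            fh.write(f"{i}\t{seq.residues[i-1]}\t{i-1}\t{nxt}\t"
                     f"{ss.pair[i-1]}\t{i}\n")


def read_ct(path, chemistry: str = DNA):
    """Read a CT file back into (NucSequence, SecondaryStructure)."""
    from .fold import SecondaryStructure  # deferred, avoids cycle

    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}:1: bad CT header") from exc
    dg = 0.0
    for tok_i, tok in enumerate(head):
        if tok in ("dG", "ENERGY", "Energy") and tok_i + 2 < len(head) + 1:
            try:
                dg = float(head[tok_i + 2] if head[tok_i + 1] == "="
                           else head[tok_i + 1])
            except (IndexError, ValueError):
                pass
    name = head[-1] if len(head) > 1 else "ct"
    letters = []
    pair = [0] * n
    for ln in lines[1:n + 1]:
        f = ln.split()
        if len(f) < 6:
            raise ParseError(f"{path}: short CT body line: {ln!r}")
        i = int(f[0])
        letters.append(f[1].upper())
        pair[i - 1] = int(f[4])
    seq = NucSequence(name, "".join(letters), chemistry)
    return seq, SecondaryStructure(pair=pair, dg=dg)


def pairs_to_dotbracket(pair) -> str:
    out = []
    for i, j in enumerate(pair, start=1):
        out.append("." if j == 0 else ("(" if j > i else ")"))
    return "".join(out)


def dotbracket_to_pairs(db: str) -> list[int]:
    pair = [0] * len(db)
    stack = []
    for i, c in enumerate(db, start=1):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pair[i - 1] = j
            pair[j - 1] = i
        elif c != ".":
            raise ParseError(f"illegal dot-bracket character {c!r}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return pair


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

#: accepted input spellings -> canonical atom name
_ATOM_DIALECT = {"O1P": "OP1", "O2P": "OP2", "H5T": "H5T", "H3T": "H3T",
                 "HO5'": "H5T", "HO3'": "H3T"}


def _canonical_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return _ATOM_DIALECT.get(name, name)


def read_pdb(path) -> Model3D:
    """Read one nucleic acid chain from a PDB file into a :class:`Model3D`.

    Only MODEL 1 of a multi-model (NMR) file is used.  Both the O1P/O2P and
    OP1/OP2 phosphate dialects and */' sugar primes are accepted; names are
    normalised to OP1/OP2 and primed spelling.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ParseError(f"{path}: no ATOM records")
    model = st[0]  # first model only
    chains = [ch for ch in model if len(ch) > 0]
    if not chains:
        raise ParseError(f"{path}: no ATOM records")
    if len(chains) > 1:
        names = ", ".join(ch.name for ch in chains)
        raise ConsistencyError(
            f"{path}: expected one chain, found several: {names}")
    chain = chains[0]
    residues = []
    chemistries = set()
    for res in chain:
        rname = res.name.strip()
        if rname == "HOH":
            continue
        if rname not in chem.RESIDUE_CODES:
            raise ChemistryError(f"{path}: unknown residue {rname!r}")
        chemistries.add(chem.RESIDUE_CODES[rname][0])
        atoms = [AtomRecord(_canonical_atom_name(a.name),
                            a.element.name if a.element else
                            chem.element_of(_canonical_atom_name(a.name)),
                            np.array([a.pos.x, a.pos.y, a.pos.z]))
                 for a in res]
        residues.append(Residue3D(rname, res.seqid.num, atoms))
    if not residues:
        raise ParseError(f"{path}: no nucleic residues found")
    if len(chemistries) > 1:
        raise ChemistryError(f"{path}: mixed RNA/DNA residue names")
    return Model3D(chain.name or "A", residues, chemistries.pop())


def write_pdb(model: Model3D, path) -> None:
    """Write a fixed-column PDB v3.3 file (occupancy 1.00, B 0.00, TER/END)."""
    for r in model.residues:
        for a in r.atoms:
            if np.any(np.abs(a.xyz) > 9999.999):
                raise FormatOverflowError(
                    f"coordinate out of PDB range in {r.name}{r.index}")
    st = gemmi.Structure()
    st.name = "hairpinforge"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain_id or "A")
    for r in model.residues:
        gr = gemmi.Residue()
        gr.name = r.name
        gr.seqid = gemmi.SeqId(r.index, " ")
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.xyz)
            ga.occ = 1.0
            ga.b_iso = 0.0
            gr.add_atom(ga)
        ch.add_residue(gr)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(seqres_records=False, ter_records=True,
                                     end_record=True)
    st.write_pdb(str(path), doc_opts)
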