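"""Synthetic data and the bundled candidate table.

Everything the test-suite and examples need without network access:
seeded synthetic hairpins (sequence, exact pair table and built 3D
model), seeded Gaussian coordinate perturbations, and the bundled
candidate table of database search results (97 records) that feeds the
screening stage.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources

import numpy as np
import pandas as pd

from . import build3d, chem, refine
from .errors import ConsistencyError
from .fold import SecondaryStructure
from .nucio import CandidateRecord, Model3D, NucSequence

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic hairpin."""

    stem_length: int
    loop_length: int
    seed: int = 0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if self.loop_length < 3:
            raise ConsistencyError("loop_length must be >= 3")
        if self.stem_length < 1:
            raise ConsistencyError("stem_length must be >= 1")


def synthetic_hairpin(spec: FixtureSpec, *, regularized: bool = False,
                      anneal_cycles: int = 0):
    """Random complementary hairpin: sequence, pair table, 3D model.

    The sequence is ``stem + loop + reverse-complement(stem)``; the pair
    table is exact by construction.  The model is the built RNA-geometry
    intermediate; with ``regularized=True`` it is additionally driven to
    a restraint minimum (deterministic), which is what perturbation-
    recovery experiments should use as their reference.
    """
    rng = np.random.default_rng(spec.seed)
    stem = "".join(rng.choice(list("ACGT"), size=spec.stem_length))
    loop = "".join(rng.choice(list("ACGT"), size=spec.loop_length))
    rc = "".join(_WC[c] for c in reversed(stem))
    seq = NucSequence(f"hairpin_s{spec.stem_length}l{spec.loop_length}"
                      f"_seed{spec.seed}", stem + loop + rc)
    n = len(seq)
    pair = [0] * n
    for k in range(spec.stem_length):
        i, j = k + 1, n - k
        pair[i - 1] = j
        pair[j - 1] = i
    ss = SecondaryStructure(pair=pair, dg=0.0)
    model = build3d.build_rna_3d(seq, ss)
    if regularized:
        model, _ = refine.regularize(model, anneal_cycles=anneal_cycles)
    if spec.noise_sigma > 0:
        model = perturb(model, spec.noise_sigma, spec.seed)
    return seq, ss, model


def perturb(model: Model3D, sigma: float, seed: int = 0) -> Model3D:
    """i.i.d. Gaussian displacement of every coordinate (seeded)."""
    if sigma < 0:
        raise ConsistencyError("sigma must be >= 0")
    out = model.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    x = out.coords()
    out.set_coords(x + rng.normal(0.0, sigma, x.shape))
    return out


# ---------------------------------------------------------------------------
# bundled candidate table
# ---------------------------------------------------------------------------

#: exclusion-reason text (as printed) -> curated motif class
_REASON_TO_MOTIF = {
    "N/A": "hairpin",
    "Duplex": "duplex",
    "Triplex": "triplex",
    "Three way junction": "three-way junction",
    "Four way junction": "four-way junction",
    "Dimer": "dimer",
    "Dimer Quadruplex": "dimer G-quadruplex",
    "G-Quadruplex": "G-quadruplex",
    "Quadruplex Duplex Hybrid": "quadruplex-duplex hybrid",
    "Z-DNA": "Z-DNA",
    "Non-nucleotide modified residues": "modified-residue",
    "Complexed with non-protein ligand": "ligand-complex",
}


@functools.lru_cache(maxsize=1)
def _candidate_frame() -> pd.DataFrame:
    path = (importlib.resources.files("hairpinforge.data")
            / "candidates_v1.tsv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def bundled_candidates() -> list:
    """The 97 bundled candidate records, in table order.

    A handful of PDB identifiers appear twice with differing annotation
    (e.g. two G-scores for the same sequence); both rows are kept as
    printed and flagged via ``duplicate_conflict``.  One row's printed
    chain length disagrees with its printed sequence; the loader trusts
    the sequence and flags ``length_conflict``.
    """
    df = _candidate_frame()
    gs = df.groupby("pdb_id")["g_score"].nunique()
    conflicted = set(gs[gs > 1].index)
    records = []
    for _, row in df.iterrows():
        seqstr = row["sequence"]
        reason = row["exclusion_reason"]
        excluded = row["excluded"].strip().lower() == "yes"
        motif = _REASON_TO_MOTIF[reason if excluded else "N/A"]
        printed_len = int(row["chain_length"])
        records.append(CandidateRecord(
            pdb_id=row["pdb_id"],
            pmid="" if row["pmid"] == "N/A" else row["pmid"],
            chain_length=len(seqstr),
            sequence_raw=seqstr,
            g_score=int(row["g_score"]),
            has_ligand=(motif == "ligand-complex"),
            motif_class=motif,
            excluded=excluded,
            exclusion_reason="" if not excluded else reason,
            length_conflict=(printed_len != len(seqstr)),
            duplicate_conflict=row["pdb_id"] in conflicted,
        ))
    return records
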