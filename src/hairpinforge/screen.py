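"""Candidate screening: G-quadruplex propensity and exclusion rules.

Implements a QGRS-style G-score — a sequence is flagged as a potential
G-quadruplex former (score > 0) exactly when four G-runs of length >= 2
fit inside a bounded window, arranged as G(x) N(y1) G(x) N(y2) G(x) N(y3)
G(x) — and the candidate-table exclusion logic that reduces the bundled
search results to the hairpin-only pool.

The positive score magnitude follows the published QGRS principles
(longer tetrad runs score higher, shorter and more even loops score
higher) with coefficients kept in a versioned data file; screening itself
only consumes the zero/non-zero decision.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources
import json
import re

from .errors import ClassificationError, ConsistencyError
from .nucio import CandidateRecord, NucSequence

MOTIF_CLASSES = {
    "hairpin", "duplex", "triplex", "three-way junction",
    "four-way junction", "dimer", "dimer G-quadruplex", "G-quadruplex",
    "quadruplex-duplex hybrid", "Z-DNA", "modified-residue",
    "ligand-complex",
}


# ---------------------------------------------------------------------------
# G-runs and the G-score
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _score_params() -> dict:
    text = (importlib.resources.files("hairpinforge.data")
            / "qgrs_score_v1.txt").read_text()
    out = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            k, v = line.split()
            out[k] = int(v)
    return out


def find_g_runs(seq, min_len: int = 2) -> list:
    """Maximal runs of consecutive G, as 1-based (start, length) tuples."""
    if min_len < 1:
        raise ConsistencyError("min_len must be >= 1")
    residues = seq.residues if isinstance(seq, NucSequence) else str(seq)
    return [(m.start() + 1, len(m.group()))
            for m in re.finditer(r"G+", residues.upper())
            if len(m.group()) >= min_len]


@dataclasses.dataclass(frozen=True)
class GQrsMatch:
    """One candidate quadruplex arrangement inside the scan window."""

    start: int                # 1-based offset of the first G-run
    tetrad_run_length: int    # x: length of each of the four G-runs
    loop_lengths: tuple       # (y1, y2, y3)
    score: int

    @property
    def span(self) -> int:
        return 4 * self.tetrad_run_length + sum(self.loop_lengths)


def find_gqrs(seq, max_len: int = 30) -> list:
    """All QGRS arrangements with span <= max_len, highest score first.

    Loops may be empty, but at most one of the three may have length zero
    (two zero loops would merge three G-runs into one tract).
    """
    params = _score_params()
    residues = (seq.residues if isinstance(seq, NucSequence)
                else str(seq)).upper()
    min_run = params["min_run"]
    runs = find_g_runs(residues, min_run)
    matches = []
    # sub-runs: every run of length L >= x offers start positions for a
    # tract of exactly x consecutive Gs.
    for x in range(min_run, max(
            [l for _, l in runs], default=min_run - 1) + 1):
        tracts = []
        for s0, l in runs:
            tracts.extend(range(s0, s0 + l - x + 1))
        for a in tracts:
            for b in (t for t in tracts if t >= a + x):
                if b + x - a > max_len:
                    break
                for c in (t for t in tracts if t >= b + x):
                    if c + x - a > max_len:
                        break
                    for d in (t for t in tracts if t >= c + x):
                        span = d + x - a
                        if span > max_len:
                            break
                        loops = (b - a - x, c - b - x, d - c - x)
                        if sum(1 for y in loops if y == 0) > \
                                params["max_zero_loops"]:
                            continue
                        score = (params["tetrad_weight"] * (x - 2)
                                 + max(0, params["loop_base"] - sum(loops))
                                 - params["uneven_weight"]
                                 * (max(loops) - min(loops)))
                        score = max(params["min_score"], score)
                        matches.append(GQrsMatch(a, x, loops, score))
    matches.sort(key=lambda m: (-m.score, m.start, m.tetrad_run_length))
    return matches


def g_score(seq, max_len: int = 30) -> int:
    """Best QGRS G-score of the sequence; 0 iff no arrangement exists."""
    matches = find_gqrs(seq, max_len)
    return matches[0].score if matches else 0


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ScreenReport:
    n_input: int
    n_after_polymer_filter: int
    n_ligand_excluded: int
    n_motif_excluded: int
    retained: list
    n_retained: int
    n_unique_sequences: int

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_polymer_filter": self.n_after_polymer_filter,
            "n_ligand_excluded": self.n_ligand_excluded,
            "n_motif_excluded": self.n_motif_excluded,
            "n_retained": self.n_retained,
            "n_unique_sequences": self.n_unique_sequences,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)

    def retained_tsv(self) -> str:
        lines = ["pdb_id\tpmid\tchain_length\tsequence\tg_score"]
        for r in self.retained:
            lines.append(f"{r.pdb_id}\t{r.pmid}\t{r.chain_length}\t"
                         f"{r.sequence_raw}\t{r.g_score}")
        return "\n".join(lines) + "\n"


def apply_exclusions(records) -> ScreenReport:
    """Apply the candidate-selection rules to a list of records.

    Stage 1 removes entries complexed with ligands; stage 2 removes
    entries whose curated motif class is not 'hairpin' and — as part of
    the same structural review — entries whose G-score is positive
    (potential G-quadruplex formers).  The retained pool is therefore
    exactly: no ligand, hairpin motif, G-score zero.
    """
    records = list(records)
    for r in records:
        if r.motif_class not in MOTIF_CLASSES:
            raise ClassificationError(
                f"record {r.pdb_id}: unknown motif class {r.motif_class!r}")
    n_input = len(records)
    no_ligand = [r for r in records if not r.has_ligand]
    n_ligand = n_input - len(no_ligand)
    retained = [r for r in no_ligand
                if r.motif_class == "hairpin" and r.g_score == 0]
    n_motif = len(no_ligand) - len(retained)
    return ScreenReport(
        n_input=n_input,
        n_after_polymer_filter=n_input,
        n_ligand_excluded=n_ligand,
        n_motif_excluded=n_motif,
        retained=retained,
        n_retained=len(retained),
        n_unique_sequences=len({r.sequence_raw for r in retained}),
    )
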