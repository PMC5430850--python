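import numpy as np
import pytest

from hairpinforge import (FixtureSpec, NucSequence, build_restraints,
                          fold_mfe, regularize, synthetic_hairpin)

#: the five pipeline sequences with their published folding summaries
PIPELINE_SEQUENCES = {
    "1BJH": "GTACAAAGTAC",
    "1LA8": "CGCGGTGTCCGCG",
    "2M8Y": "CGCGAAGCATTCGCG",
    "2VAH": "AGGATCCTUTTGGATCCT",
    "2L5K": "CAGTTGATCCTTTGGATACCCTG",
}


@pytest.fixture(scope="session")
def pipeline_folds():
    """MFE structures of the five pipeline sequences (closed folds)."""
    out = {}
    for name, s in PIPELINE_SEQUENCES.items():
        seq = NucSequence(name, s)
        out[name] = (seq, fold_mfe(seq, closed=True))
    return out


@pytest.fixture(scope="session")
def ideal_hairpin():
    """A 4-bp-stem / 3-nt-loop hairpin settled in a deep restraint
    minimum: the reference model for perturbation-recovery experiments.

    Deterministic (fixed seeds); computed once per session because the
    settling run is the most expensive step in the suite.
    """
    seq, ss, built = synthetic_hairpin(
        FixtureSpec(stem_length=4, loop_length=3, seed=11))
    ideal, _ = regularize(built, rounds=2, gd_iterations=2500,
                          anneal_cycles=5, anneal_sigma=0.2)
    restraints = build_restraints(ideal)
    return seq, ss, ideal, restraints


def monotone(trace, tol=1e-9):
    return all(trace[i + 1] <= trace[i] + tol for i in range(len(trace) - 1))


@pytest.fixture
def assert_monotone():
    return monotone


# ---------------------------------------------------------------------------
# brute-force folding oracle: exhaustive enumeration of nested WC
# structures, scored with the package's loop-decomposition evaluator
# ---------------------------------------------------------------------------

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def enumerate_pair_sets(thermo_seq):
    """Every nested Watson-Crick pair set (0-based index pairs) of a
    sequence whose U's were already mapped to T."""
    def gen(i, j):
        if i > j:
            yield []
            return
        yield from gen(i + 1, j)
        for k in range(i + 4, j + 1):
            if _WC[thermo_seq[i]] == thermo_seq[k]:
                for inner in gen(i + 1, k - 1):
                    for outer in gen(k + 1, j):
                        yield [(i, k)] + inner + outer
    yield from gen(0, len(thermo_seq) - 1)


def enumerate_structures(seq):
    """(SecondaryStructure, energy) for every nested WC structure."""
    from hairpinforge import SecondaryStructure, evaluate_energy
    s = seq.residues.replace("U", "T")
    n = len(s)
    for ps in enumerate_pair_sets(s):
        pair = [0] * n
        for i, j in ps:
            pair[i] = j + 1
            pair[j] = i + 1
        ss = SecondaryStructure(pair=pair)
        yield ss, evaluate_energy(seq, ss)
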