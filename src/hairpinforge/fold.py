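"""Nearest-neighbor secondary-structure prediction for ssDNA.

Minimum-free-energy folding by the Zuker dynamic program over nested
Watson-Crick structures, complete suboptimal enumeration within an energy
window (Wuchty-style duplicate-free backtracking), a loop-decomposition
energy evaluator that doubles as the brute-force oracle's scorer, and a
motif summariser (stems, loops, tails).

The thermodynamic model is a table-driven DNA dG37 set (1 M Na+, 37 C)
shipped as a versioned data file; a U residue in a DNA chain is scored
with thymine parameters.  Hairpin loops need at least 3 unpaired bases;
isolated pairs are permitted; no wobble pairs.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources
import math

from . import chem
from .errors import ConsistencyError, IllegalStructureError, WrongChemistryError
from .nucio import NucSequence, pairs_to_dotbracket

_INF = float("inf")
_EPS = 1e-7

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_MIN_HAIRPIN = 3


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EnergyModel:
    """DNA nearest-neighbor dG37 parameter set (kcal/mol)."""

    stack_dg: dict
    hairpin_dg: dict
    bulge_dg: dict
    internal_dg: dict
    mismatch_hairpin: dict
    mismatch_internal: dict
    triloop_bonus: dict
    ml_offset: float
    ml_branch: float
    ml_unpaired: float
    ninio_slope: float
    ninio_max: float
    js_coef: float
    terminal_at_penalty: float
    temperature: float = 37.0
    sodium_molar: float = 1.0
    version: str = "v1"

    # -- table lookups ----------------------------------------------------

    def stack(self, a: str, b: str, c: str, d: str) -> float:
        """Stack 5'-a b-3' / 3'-d c-5' (pairs a.d and b.c)."""
        key = a + b
        if key in self.stack_dg:
            return self.stack_dg[key]
        return self.stack_dg[c + d]

    def _loop_size(self, table: dict, n: int) -> float:
        if n in table:
            return table[n]
        nmax = max(table)
        return table[nmax] + self.js_coef * math.log(n / nmax)

    def hairpin_energy(self, s: str, i: int, j: int) -> float:
        """Hairpin loop closed by pair (i, j); 0-based thermo letters."""
        n = j - i - 1
        e = self._loop_size(self.hairpin_dg, n)
        if n == 3:
            loop = s[i + 1:j]
            for pat, bonus in self.triloop_bonus.items():
                if all(p == "N" or p == c for p, c in zip(pat, loop)):
                    e += bonus
                    break
        else:
            e += self.mismatch_hairpin.get((s[i] + s[j], s[i + 1], s[j - 1]),
                                           0.0)
        return e

    def two_loop_energy(self, s: str, i: int, j: int, k: int, l: int) -> float:
        """Stack / bulge / internal loop between pairs (i,j) and (k,l)."""
        n1, n2 = k - i - 1, j - l - 1
        if n1 == 0 and n2 == 0:
            return self.stack(s[i], s[k], s[l], s[j])
        if n1 == 0 or n2 == 0:
            n = n1 + n2
            e = self._loop_size(self.bulge_dg, n)
            if n == 1:  # single-base bulge keeps the flanking stack
                e += self.stack(s[i], s[k], s[l], s[j])
            return e
        e = self._loop_size(self.internal_dg, n1 + n2)
        e += min(self.ninio_max, self.ninio_slope * abs(n1 - n2))
        e += self.mismatch_internal.get((s[i] + s[j], s[i + 1], s[j - 1]), 0.0)
        e += self.mismatch_internal.get((s[l] + s[k], s[l + 1], s[k - 1]), 0.0)
        return e

    def multiloop_energy(self, n_branches: int, n_unpaired: int) -> float:
        """Affine penalty; n_branches counts the closing helix."""
        return (self.ml_offset + self.ml_branch * n_branches
                + self.ml_unpaired * n_unpaired)

    def helix_end_penalty(self, a: str, b: str) -> float:
        if self.terminal_at_penalty and ("A" in (a, b)):
            return self.terminal_at_penalty
        return 0.0


def _parse_param_file(text: str) -> EnergyModel:
    sections: dict[str, list[list[str]]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        sections[current].append(line.split())

    stack = {f[0]: float(f[1]) for f in sections["stack"]}
    hairpin = {int(f[0]): float(f[1]) for f in sections["hairpin"]}
    bulge = {int(f[0]): float(f[1]) for f in sections["bulge"]}
    internal = {int(f[0]): float(f[1]) for f in sections["internal"]}
    mm_h = {(f[0], f[1], f[2]): float(f[3])
            for f in sections["mismatch_hairpin"]}
    mm_i = {(f[0], f[1], f[2]): float(f[3])
            for f in sections.get("mismatch_internal",
                                  sections["mismatch_hairpin"])}
    triloop = {f[0]: float(f[1]) for f in sections.get("triloop_bonus", [])}
    ml = {f[0]: float(f[1]) for f in sections["multiloop"]}
    ninio = {f[0]: float(f[1]) for f in sections["ninio"]}
    misc = {f[0]: float(f[1]) for f in sections["misc"]}
    return EnergyModel(
        stack_dg=stack, hairpin_dg=hairpin, bulge_dg=bulge,
        internal_dg=internal, mismatch_hairpin=mm_h, mismatch_internal=mm_i,
        triloop_bonus=triloop,
        ml_offset=ml["offset"], ml_branch=ml["branch"],
        ml_unpaired=ml["unpaired"],
        ninio_slope=ninio["slope"], ninio_max=ninio["max"],
        js_coef=misc["js_coef"],
        terminal_at_penalty=misc["terminal_at"],
        temperature=misc.get("temperature_c", 37.0),
        sodium_molar=misc.get("sodium_molar", 1.0),
    )


@functools.lru_cache(maxsize=1)
def default_energy_model() -> EnergyModel:
    text = (importlib.resources.files("hairpinforge.data")
            / "dna_dg37_v1.txt").read_text()
    return _parse_param_file(text)


def load_energy_model(path) -> EnergyModel:
    with open(path) as fh:
        return _parse_param_file(fh.read())


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SecondaryStructure:
    """Nested pair table with total free energy.

    ``pair`` is 1-based: pair[i-1] = j if bases i and j pair, 0 if unpaired.
    """

    pair: list
    dg: float = 0.0

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pair)

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pair, 1) if j > i)

    def pairs(self):
        return [(i, j) for i, j in enumerate(self.pair, 1) if j > i]

    def key(self):
        return tuple(self.pair)


@dataclasses.dataclass(frozen=True)
class FoldConfig:
    window_percent: float = 5.0
    max_folds: int = 50
    max_pair_distance: int | None = None

    def __post_init__(self):
        if self.window_percent < 0:
            raise ConsistencyError("window_percent must be >= 0")
        if self.max_folds < 1:
            raise ConsistencyError("max_folds must be >= 1")


def _thermo_letters(seq: NucSequence) -> str:
    if seq.chemistry != chem.DNA:
        raise WrongChemistryError(
            f"{seq.identifier!r}: folding stage is DNA-only")
    return seq.residues.replace("U", "T")


def _can_pair(s: str, i: int, j: int, maxdist) -> bool:
    if j - i < _MIN_HAIRPIN + 1:
        return False
    if maxdist is not None and j - i > maxdist:
        return False
    return _WC[s[i]] == s[j]


def validate_structure(seq: NucSequence, ss: SecondaryStructure) -> None:
    """Raise IllegalStructureError unless ss is a legal nested WC structure."""
    n = len(seq)
    p = ss.pair
    if len(p) != n:
        raise ConsistencyError(
            f"pair table length {len(p)} != sequence length {n}")
    s = seq.residues.replace("U", "T")
    open_pairs = []
    for i in range(1, n + 1):
        j = p[i - 1]
        if j == 0:
            continue
        if not (1 <= j <= n) or j == i:
            raise IllegalStructureError(f"bad partner {j} for base {i}")
        if p[j - 1] != i:
            raise IllegalStructureError(
                f"pair table is not an involution at base {i}")
        if j > i:
            if _WC[s[i - 1]] != s[j - 1]:
                raise IllegalStructureError(
                    f"non-Watson-Crick pair {s[i-1]}{i}-{s[j-1]}{j}")
            if j - i - 1 < _MIN_HAIRPIN and all(
                    p[k - 1] == 0 for k in range(i + 1, j)):
                raise IllegalStructureError(
                    f"hairpin loop closed by ({i},{j}) shorter than "
                    f"{_MIN_HAIRPIN}")
            while open_pairs and open_pairs[-1] < i:
                open_pairs.pop()
            if open_pairs and j > open_pairs[-1]:
                raise IllegalStructureError(
                    f"pseudoknot: pair ({i},{j}) crosses ({p[open_pairs[-1]-1]},{open_pairs[-1]})")
            open_pairs.append(j)


# ---------------------------------------------------------------------------
# energy evaluation by loop decomposition (also the oracle scorer)
# ---------------------------------------------------------------------------

def _children(p: list, i: int, j: int):
    """Directly enclosed pairs of (i, j); 1-based closed interval."""
    out = []
    k = i + 1
    while k < j:
        if p[k - 1] > k:
            out.append((k, p[k - 1]))
            k = p[k - 1] + 1
        else:
            k += 1
    return out


def evaluate_energy(seq: NucSequence, ss: SecondaryStructure,
                    model: EnergyModel | None = None) -> float:
    """Total free energy of a legal structure; the open chain scores 0."""
    model = model or default_energy_model()
    validate_structure(seq, ss)
    s = _thermo_letters(seq)
    p = ss.pair
    n = len(s)
    e = 0.0
    for (i, j) in _exterior_helices(p, n):
        e += model.helix_end_penalty(s[i - 1], s[j - 1])
    for i in range(1, n + 1):
        j = p[i - 1]
        if j <= i:
            continue
        kids = _children(p, i, j)
        if not kids:
            e += model.hairpin_energy(s, i - 1, j - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            e += model.two_loop_energy(s, i - 1, j - 1, k - 1, l - 1)
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            e += model.multiloop_energy(1 + len(kids), unpaired)
            e += model.helix_end_penalty(s[i - 1], s[j - 1])
            for a, b in kids:
                e += model.helix_end_penalty(s[a - 1], s[b - 1])
    return e


def _exterior_helices(p: list, n: int):
    out = []
    k = 1
    while k <= n:
        if p[k - 1] > k:
            out.append((k, p[k - 1]))
            k = p[k - 1] + 1
        else:
            k += 1
    return out


# ---------------------------------------------------------------------------
# MFE dynamic program
# ---------------------------------------------------------------------------

class _DP:
    """Zuker-style matrices on 0-based thermo letters.

    V[i][j]   best energy of a structure closed by pair (i, j)
    WM1[i][j] best multiloop segment with >= 1 branch
    WM2[i][j] best multiloop segment with >= 2 branches
    W[j]      best energy of prefix 0..j-1 (W[0] = 0)
    W1[j]     best energy of prefix 0..j-1 containing >= 1 pair
    """

    MAX_TWO_LOOP = 30

    def __init__(self, s: str, model: EnergyModel, config: FoldConfig):
        self.s = s
        self.model = model
        self.config = config
        n = self.n = len(s)
        self.V = [[_INF] * n for _ in range(n)]
        self.WM1 = [[_INF] * n for _ in range(n)]
        self.WM2 = [[_INF] * n for _ in range(n)]
        self._fill()

    def can_pair(self, i, j):
        return _can_pair(self.s, i, j, self.config.max_pair_distance)

    def _fill(self):
        n, s, m = self.n, self.s, self.model
        V, WM1, WM2 = self.V, self.WM1, self.WM2
        cap = self.MAX_TWO_LOOP
        for span in range(_MIN_HAIRPIN + 1, n):
            for i in range(0, n - span):
                j = i + span
                if self.can_pair(i, j):
                    best = m.hairpin_energy(s, i, j)
                    for k in range(i + 1, j - _MIN_HAIRPIN):
                        if k - i - 1 > cap:
                            break
                        lmin = max(k + _MIN_HAIRPIN + 1,
                                   j - 1 - (cap - (k - i - 1)))
                        for l in range(lmin, j):
                            if V[k][l] < _INF:
                                e = m.two_loop_energy(s, i, j, k, l) + V[k][l]
                                if e < best:
                                    best = e
                    # multiloop closing
                    if WM2[i + 1][j - 1] < _INF:
                        e = (m.ml_offset + m.ml_branch
                             + WM2[i + 1][j - 1]
                             + m.helix_end_penalty(s[i], s[j]))
                        if e < best:
                            best = e
                    V[i][j] = best
                # WM1 / WM2 (canonical: rightmost base unpaired or paired)
                best1 = best2 = _INF
                if WM1[i][j - 1] < _INF:
                    best1 = WM1[i][j - 1] + m.ml_unpaired
                if WM2[i][j - 1] < _INF:
                    best2 = WM2[i][j - 1] + m.ml_unpaired
                for k in range(i, j - _MIN_HAIRPIN):
                    if V[k][j] < _INF:
                        helix = (V[k][j] + m.ml_branch
                                 + m.helix_end_penalty(s[k], s[j]))
                        e = helix + m.ml_unpaired * (k - i)
                        if e < best1:
                            best1 = e
                        if k > i and WM1[i][k - 1] < _INF:
                            e = helix + WM1[i][k - 1]
                            if e < best1:
                                best1 = e
                            if e < best2:
                                best2 = e
                WM1[i][j] = best1
                WM2[i][j] = best2
        # exterior
        W = self.W = [0.0] * (n + 1)
        W1 = self.W1 = [_INF] * (n + 1)
        for j in range(n):
            W[j + 1] = W[j]
            W1[j + 1] = W1[j]
            for i in range(0, j - _MIN_HAIRPIN):
                if V[i][j] < _INF:
                    e = W[i] + V[i][j] + m.helix_end_penalty(s[i], s[j])
                    if e < W[j + 1]:
                        W[j + 1] = e
                    if e < W1[j + 1]:
                        W1[j + 1] = e

    # -- traceback --------------------------------------------------------

    def traceback(self, closed: bool = False):
        """MFE pair list; ties broken toward the smallest 5' then 3' index."""
        n, s, m = self.n, self.s, self.model
        V, WM1, WM2, W, W1 = self.V, self.WM1, self.WM2, self.W, self.W1
        pairs = []

        def near(a, b):
            return abs(a - b) < _EPS

        def trace_v(i, j):
            pairs.append((i, j))
            e = V[i][j]
            if near(e, m.hairpin_energy(s, i, j)):
                return
            cap = self.MAX_TWO_LOOP
            for k in range(i + 1, j - _MIN_HAIRPIN):
                if k - i - 1 > cap:
                    break
                for l in range(j - 1, max(k + _MIN_HAIRPIN,
                                          j - 2 - (cap - (k - i - 1))), -1):
                    if V[k][l] < _INF and near(
                            e, m.two_loop_energy(s, i, j, k, l) + V[k][l]):
                        trace_v(k, l)
                        return
            if WM2[i + 1][j - 1] < _INF and near(
                    e, m.ml_offset + m.ml_branch + WM2[i + 1][j - 1]
                    + m.helix_end_penalty(s[i], s[j])):
                trace_wm(i + 1, j - 1, 2)
                return
            raise AssertionError("traceback failed in V")

        def trace_wm(i, j, min_branches):
            WMx = WM1 if min_branches == 1 else WM2
            e = WMx[i][j]
            if j > i and WMx[i][j - 1] < _INF and near(
                    e, WMx[i][j - 1] + m.ml_unpaired):
                trace_wm(i, j - 1, min_branches)
                return
            for k in range(i, j - _MIN_HAIRPIN):
                if V[k][j] >= _INF:
                    continue
                helix = (V[k][j] + m.ml_branch
                         + m.helix_end_penalty(s[k], s[j]))
                if min_branches == 1 and near(
                        e, helix + m.ml_unpaired * (k - i)):
                    trace_v(k, j)
                    return
                if k > i and WM1[i][k - 1] < _INF and near(
                        e, helix + WM1[i][k - 1]):
                    trace_wm(i, k - 1, 1)
                    trace_v(k, j)
                    return
            raise AssertionError("traceback failed in WM")

        def trace_w(j_end, constrained):
            """Trace exterior prefix of length j_end."""
            Wx = W1 if constrained else W
            j = j_end
            while j > 0:
                if Wx[j - 1] < _INF and near(Wx[j], Wx[j - 1]):
                    j -= 1
                    continue
                for i in range(0, j - 1 - _MIN_HAIRPIN):
                    if V[i][j - 1] < _INF and near(
                            Wx[j], W[i] + V[i][j - 1]
                            + m.helix_end_penalty(s[i], s[j - 1])):
                        trace_v(i, j - 1)
                        trace_w(i, False)
                        return
                raise AssertionError("traceback failed in W")

        e_final = W1[n] if closed else W[n]
        if e_final >= _INF:
            return [], _INF
        trace_w(n, closed)
        return pairs, e_final


def _build_ss(n: int, pair_list, dg: float) -> SecondaryStructure:
    pair = [0] * n
    for i, j in pair_list:
        pair[i] = j + 1
        pair[j] = i + 1
    return SecondaryStructure(pair=pair, dg=dg)


def fold_mfe(seq: NucSequence, model: EnergyModel | None = None,
             config: FoldConfig | None = None, *,
             closed: bool = False) -> SecondaryStructure:
    """Minimum-free-energy structure of a DNA sequence.

    With ``closed=False`` the minimum is taken over *all* nested WC
    structures including the open chain; with ``closed=True`` the best
    structure containing at least one pair is returned even when its
    energy is positive (the behaviour of a folding server, which always
    reports a fold).
    """
    model = model or default_energy_model()
    config = config or FoldConfig()
    s = _thermo_letters(seq)
    n = len(s)
    if n <= _MIN_HAIRPIN + 1:
        if closed:
            return SecondaryStructure(pair=[0] * n, dg=0.0)
        return SecondaryStructure(pair=[0] * n, dg=0.0)
    dp = _DP(s, model, config)
    if closed and dp.W1[n] >= _INF:
        return SecondaryStructure(pair=[0] * n, dg=0.0)
    pair_list, dg = dp.traceback(closed=closed)
    return _build_ss(n, pair_list, dg)


# ---------------------------------------------------------------------------
# suboptimal enumeration (Wuchty-style, duplicate-free)
# ---------------------------------------------------------------------------

def suboptimal_window(mfe: float, window_percent: float) -> float:
    """Energy ceiling for suboptimal folds.

    5% of |MFE| above the MFE; widened to an absolute 0.5 kcal/mol floor
    when the MFE is non-negative (a percentage of ~0 is degenerate).
    """
    width = abs(mfe) * window_percent / 100.0
    if mfe >= 0:
        width = max(width, 0.5)
    return mfe + width


def fold_suboptimal(seq: NucSequence, model: EnergyModel | None = None,
                    config: FoldConfig | None = None) -> list:
    """All distinct structures within the suboptimality window.

    Sorted by energy (MFE first), truncated at ``config.max_folds``.
    """
    model = model or default_energy_model()
    config = config or FoldConfig()
    s = _thermo_letters(seq)
    n = len(s)
    if n <= _MIN_HAIRPIN + 1:
        return [SecondaryStructure(pair=[0] * n, dg=0.0)]
    dp = _DP(s, model, config)
    mfe = dp.W[n]
    ceiling = suboptimal_window(mfe, config.window_percent)
    m = model
    V, WM1, WM2, W = dp.V, dp.WM1, dp.WM2, dp.W

    results = []
    # state: (list of pending (kind, i, j, extra), energy_so_far, pairs)
    # bound of a state = energy_so_far + sum of matrix optima of pending.
    def bound_of(kind, i, j, extra):
        if kind == "W":
            return W[j]
        if kind == "V":
            return V[i][j]
        if kind == "WM":
            return (WM1 if extra == 1 else WM2)[i][j]
        raise AssertionError(kind)

    start = [("W", 0, n, None)]
    stack = [(start, 0.0, [])]
    guard = 0
    while stack:
        guard += 1
        if guard > 2_000_000:
            break
        pending, acc, pairs = stack.pop()
        if not pending:
            results.append((acc, pairs))
            continue
        kind, i, j, extra = pending[-1]
        rest = pending[:-1]
        rest_bound = acc + sum(bound_of(*p) for p in rest)

        def push(new_items, de, new_pairs=()):
            items = rest + list(new_items)
            b = rest_bound + de + sum(bound_of(*p) for p in new_items)
            if b <= ceiling + _EPS:
                stack.append((items, acc + de, pairs + list(new_pairs)))

        if kind == "W":
            if j == 0:
                push([], 0.0)
                continue
            push([("W", 0, j - 1, None)], 0.0)
            for i2 in range(0, j - 1 - _MIN_HAIRPIN):
                if V[i2][j - 1] < _INF:
                    push([("W", 0, i2, None), ("V", i2, j - 1, None)],
                         m.helix_end_penalty(s[i2], s[j - 1]))
        elif kind == "V":
            de_h = m.hairpin_energy(s, i, j)
            push([], de_h, [(i, j)])
            cap = _DP.MAX_TWO_LOOP
            for k in range(i + 1, j - _MIN_HAIRPIN):
                if k - i - 1 > cap:
                    break
                lmin = max(k + _MIN_HAIRPIN + 1, j - 1 - (cap - (k - i - 1)))
                for l in range(lmin, j):
                    if V[k][l] < _INF:
                        push([("V", k, l, None)],
                             m.two_loop_energy(s, i, j, k, l), [(i, j)])
            if WM2[i + 1][j - 1] < _INF:
                push([("WM", i + 1, j - 1, 2)],
                     m.ml_offset + m.ml_branch
                     + m.helix_end_penalty(s[i], s[j]), [(i, j)])
        elif kind == "WM":
            if j > i:
                push([("WM", i, j - 1, extra)], m.ml_unpaired)
            for k in range(i, j - _MIN_HAIRPIN):
                if V[k][j] >= _INF:
                    continue
                de = (m.ml_branch + m.helix_end_penalty(s[k], s[j]))
                if extra == 1:
                    push([("V", k, j, None)], de + m.ml_unpaired * (k - i))
                if k > i and WM1[i][k - 1] < _INF:
                    push([("WM", i, k - 1, 1), ("V", k, j, None)], de)

    seen = {}
    for dg, plist in results:
        ss = _build_ss(n, plist, dg)
        key = ss.key()
        if key not in seen or dg < seen[key].dg:
            seen[key] = ss
    folds = sorted(seen.values(), key=lambda t: (t.dg, t.key()))
    return folds[:config.max_folds]


# ---------------------------------------------------------------------------
# motif summary
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifSummary:
    """Stems, loops and tails of one secondary structure (1-based indices).

    stems: (5' start, 5' end, 3' start, 3' end, base-pair count)
    hairpin_loops: (start, end, unpaired count)
    internal_loops: (side-1 count, side-2 count); a bulge has one zero side
    multiloops: (branch count incl. closing helix, unpaired count)
    """

    stems: list
    hairpin_loops: list
    internal_loops: list
    multiloops: list
    tail5: int
    tail3: int
    exterior_gaps: list


def describe_motifs(ss: SecondaryStructure) -> MotifSummary:
    p = ss.pair
    n = len(p)
    pair_list = [(i, p[i - 1]) for i in range(1, n + 1) if p[i - 1] > i]
    pair_set = set(pair_list)
    # stems: maximal runs of stacked pairs
    stems = []
    for (i, j) in sorted(pair_list):
        if (i - 1, j + 1) in pair_set:
            continue  # not the outermost pair of its stem
        k = 0
        while (i + k + 1, j - k - 1) in pair_set:
            k += 1
        stems.append((i, i + k, j - k, j, k + 1))
    hairpins = []
    internals = []
    multis = []
    for (i, j) in pair_list:
        kids = _children(p, i, j)
        if not kids:
            hairpins.append((i + 1, j - 1, j - i - 1))
        elif len(kids) == 1:
            k, l = kids[0]
            if (k, l) != (i + 1, j - 1):
                internals.append((k - i - 1, j - l - 1))
        else:
            unpaired = (j - i - 1) - sum(b - a + 1 for a, b in kids)
            multis.append((1 + len(kids), unpaired))
    ext = _exterior_helices(p, n)
    if ext:
        tail5 = ext[0][0] - 1
        tail3 = n - ext[-1][1]
        gaps = [ext[h + 1][0] - ext[h][1] - 1 for h in range(len(ext) - 1)
                if ext[h + 1][0] - ext[h][1] - 1 > 0]
    else:
        tail5, tail3, gaps = n, 0, []
    return MotifSummary(stems=stems, hairpin_loops=hairpins,
                        internal_loops=internals, multiloops=multis,
                        tail5=tail5, tail3=tail3, exterior_gaps=gaps)
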