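"""Restrained geometric refinement.

One configurable minimizer serves both refinement stages of the pipeline:
the short post-build regularisation (100 iterations by default) and the
final clean-up (10,000 iterations).  The objective is a weighted sum of
squared restraint violations — bond lengths, bond angles, base-plane
flatness, backbone torsions — plus a quartic non-bonded repulsion below a
cutoff.  Restraint targets are taken from the nucleotide template library
(bond/angle geometry), canonical phosphodiester-linkage values, and, for
the weakly weighted torsions, the model the restraints were built from.

The default optimiser is gradient descent with a Barzilai-Borwein step
and Armijo backtracking (monotone by construction); a Gauss-Newton
variant is selectable.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree

from . import chem
from .build3d import TemplateLibrary, load_templates
from .errors import ChemistryError, ConsistencyError, MinimizerError
from .nucio import Model3D

DEFAULT_WEIGHTS = {
    "bond": 1.0,        # per A^2
    "angle": 0.02,      # per deg^2
    "plane": 1.0,       # per A^2
    "torsion": 0.01,    # per deg^2
    "repulsion": 10.0,  # per A^4 below the cutoff
}
REPULSION_CUTOFF = 2.0  # A

# the O3'(i)-P(i+1) linkage bond/angle targets are taken from the
# template helix itself (TemplateLibrary.linkage_geometry), so a built
# stem is an exact minimum of the restraint objective

#: intra-residue backbone torsion quadruples (0 = this residue).  The
#: torsions across the phosphodiester linkage are deliberately left
#: unrestrained: the linkage bond and its two flanking angles hold that
#: geometry, and a torsion over a not-yet-formed linkage is degenerate.
_TORSION_DEFS = [
    (("P", 0), ("O5'", 0), ("C5'", 0), ("C4'", 0)),       # beta
    (("O5'", 0), ("C5'", 0), ("C4'", 0), ("C3'", 0)),     # gamma
    (("C5'", 0), ("C4'", 0), ("C3'", 0), ("O3'", 0)),     # delta
]


@dataclasses.dataclass
class RestraintSet:
    """Index-array form of every restraint on one model."""

    bond_idx: np.ndarray      # (nb, 2)
    bond_target: np.ndarray   # (nb,)
    angle_idx: np.ndarray     # (na, 3) ordered a-b-c, angle at b
    angle_target: np.ndarray  # degrees
    plane_groups: list        # list of index arrays
    torsion_idx: np.ndarray   # (nt, 4)
    torsion_target: np.ndarray  # degrees
    exclusions: set           # frozenset pairs excluded from repulsion
    weights: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    repulsion_cutoff: float = REPULSION_CUTOFF

    def counts(self) -> dict:
        return {"bonds": len(self.bond_idx),
                "angles": len(self.angle_idx),
                "planes": len(self.plane_groups),
                "torsions": len(self.torsion_idx)}


@dataclasses.dataclass(frozen=True)
class MinimizerConfig:
    max_iterations: int = 10_000
    convergence_tol: float = 1e-8
    initial_step: float = 1e-3
    backtrack_factor: float = 0.5
    method: str = "gd"          # "gd" or "gauss_newton"

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ConsistencyError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ConsistencyError("convergence_tol must be > 0")


STAGE2_CONFIG = MinimizerConfig(max_iterations=100)
STAGE4_CONFIG = MinimizerConfig(max_iterations=10_000)


# ---------------------------------------------------------------------------
# restraint generation
# ---------------------------------------------------------------------------

def _model_bond_graph(model: Model3D):
    """Flat-index bond list + per-residue atom index maps."""
    index_of = []
    flat = {}
    k = 0
    for ri, res in enumerate(model.residues):
        m = {}
        for a in res.atoms:
            m[a.name] = k
            k += 1
        index_of.append(m)
        flat[ri] = m
    bonds = []
    for ri, res in enumerate(model.residues):
        m = index_of[ri]
        has_p = "P" in m
        rb = chem.residue_bonds(res.name, has_5p_phosphate=has_p,
                                is_3p_terminal="H3T" in m,
                                is_5p_terminal="H5T" in m)
        for a1, a2 in rb:
            if a1 in m and a2 in m:
                bonds.append((ri, a1, a2, m[a1], m[a2]))
        if ri + 1 < len(model.residues) and "P" in index_of[ri + 1]:
            bonds.append((ri, "O3'", "P", m["O3'"],
                          index_of[ri + 1]["P"]))
    return bonds, index_of


def build_restraints(model: Model3D,
                     templates: TemplateLibrary | None = None,
                     weights: dict | None = None) -> RestraintSet:
    """Complete restraint set for a model: every bond, bond angle, base
    plane and backbone torsion, plus repulsion exclusions.

    Bond and angle targets come from the template geometry (canonical
    values for the phosphodiester linkage); torsion targets are the
    model's own values with a weak weight, which restrains conformation
    without freezing it.
    """
    templates = templates or load_templates("builtin")
    weights = dict(DEFAULT_WEIGHTS, **(weights or {}))
    for res in model.residues:
        if res.name not in chem.RESIDUE_CODES:
            raise ChemistryError(f"unknown residue {res.name!r}")
        if res.name not in templates.residues:
            raise ChemistryError(f"no template for residue {res.name!r}")
    bonds, index_of = _model_bond_graph(model)
    coords = model.coords()
    linkage = templates.linkage_geometry(model.chemistry)

    def tpl_dist(resname, a1, a2):
        tpl = templates.template(resname).atoms
        if a1 in tpl and a2 in tpl:
            return float(np.linalg.norm(tpl[a1] - tpl[a2]))
        return None

    bond_idx, bond_t = [], []
    adjacency: dict[int, list] = {}
    for ri, a1, a2, i, j in bonds:
        resname = model.residues[ri].name
        if a1 == "O3'" and a2 == "P" and j not in index_of[ri].values():
            target = linkage["bond"]
        else:
            target = tpl_dist(resname, a1, a2)
            if target is None:
                raise ChemistryError(
                    f"no template target for bond {resname} {a1}-{a2}")
        bond_idx.append((i, j))
        bond_t.append(target)
        adjacency.setdefault(i, []).append(j)
        adjacency.setdefault(j, []).append(i)

    # angles: every bonded triple; targets from templates where both
    # bonds are intra-residue, canonical at the linkage
    name_of = {}
    res_of = {}
    for ri, m in enumerate(index_of):
        for nm, i in m.items():
            name_of[i] = nm
            res_of[i] = ri
    angle_idx, angle_t = [], []
    for b, nbrs in adjacency.items():
        nb = sorted(set(nbrs))
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                a, c = nb[x], nb[y]
                names = (name_of[a], name_of[b], name_of[c])
                same_res = res_of[a] == res_of[b] == res_of[c]
                if same_res:
                    target = _tpl_angle(templates,
                                        model.residues[res_of[b]].name,
                                        *names)
                else:
                    target = linkage.get(names) or \
                        linkage.get(tuple(reversed(names)))
                    if target is None:
                        target = _measure_angle(coords, a, b, c)
                if target is None:
                    target = _measure_angle(coords, a, b, c)
                angle_idx.append((a, b, c))
                angle_t.append(target)

    # base planes
    plane_groups = []
    for ri, res in enumerate(model.residues):
        base = chem.RESIDUE_CODES[res.name][1]
        grp = [index_of[ri][a] for a in chem.BASE_PLANE_ATOMS[base]
               if a in index_of[ri]]
        if len(grp) >= 4:
            plane_groups.append(np.array(grp))

    # torsions: intra-residue quadruples with template-value targets, so
    # that the template conformation is an exact joint minimum
    torsion_idx, torsion_t = [], []
    nres = len(model.residues)
    for ri in range(nres):
        resname = model.residues[ri].name
        tpl = templates.template(resname).atoms
        base = chem.RESIDUE_CODES[resname][1]
        ngly = chem.glycosidic_nitrogen(base)
        ref = "C4" if base in chem.PURINES else "C2"
        quads = [[nm for nm, _ in quad] for quad in _TORSION_DEFS]
        quads.append(["O4'", "C1'", ngly, ref])
        for names in quads:
            if not all(nm in index_of[ri] for nm in names):
                continue
            idxs = tuple(index_of[ri][nm] for nm in names)
            if all(nm in tpl for nm in names):
                target = _torsion_value(*[tpl[nm] for nm in names])
            else:
                target = _measure_torsion(coords, *idxs)
            torsion_idx.append(idxs)
            torsion_t.append(target)

    # exclusions: 1-2 and 1-3
    excl = set()
    for i, j in bond_idx:
        excl.add(frozenset((i, j)))
    for a, b, c in angle_idx:
        excl.add(frozenset((a, c)))

    return RestraintSet(
        bond_idx=np.array(bond_idx, dtype=int),
        bond_target=np.array(bond_t),
        angle_idx=np.array(angle_idx, dtype=int),
        angle_target=np.array(angle_t),
        plane_groups=plane_groups,
        torsion_idx=np.array(torsion_idx, dtype=int),
        torsion_target=np.array(torsion_t),
        exclusions=excl,
        weights=weights,
    )


def _tpl_angle(templates, resname, a1, a2, a3):
    tpl = templates.template(resname).atoms
    if all(a in tpl for a in (a1, a2, a3)):
        v1 = tpl[a1] - tpl[a2]
        v2 = tpl[a3] - tpl[a2]
        cosv = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
    return None


def _measure_angle(coords, a, b, c):
    v1 = coords[a] - coords[b]
    v2 = coords[c] - coords[b]
    cosv = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))


def _measure_torsion(coords, p1, p2, p3, p4):
    return _torsion_value(coords[p1], coords[p2], coords[p3], coords[p4])


def _torsion_value(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(m1 @ n2, n1 @ n2))


# ---------------------------------------------------------------------------
# objective and gradient
# ---------------------------------------------------------------------------

_RAD2DEG = 180.0 / math.pi


def _scatter(G, idx, vals):
    n = len(G)
    for d in range(3):
        G[:, d] += np.bincount(idx, weights=vals[:, d], minlength=n)


def _objective(x: np.ndarray, rs: RestraintSet, want_grad=True):
    """Weighted sum of squared violations and its analytic gradient."""
    n = len(x)
    w = rs.weights
    E = 0.0
    G = np.zeros_like(x)

    # bonds
    if len(rs.bond_idx):
        vi = x[rs.bond_idx[:, 0]] - x[rs.bond_idx[:, 1]]
        d = np.linalg.norm(vi, axis=1)
        dev = d - rs.bond_target
        E += w["bond"] * float(dev @ dev)
        if want_grad:
            g = (2.0 * w["bond"] * dev / d)[:, None] * vi
            _scatter(G, rs.bond_idx[:, 0], g)
            _scatter(G, rs.bond_idx[:, 1], -g)

    # angles (degrees)
    if len(rs.angle_idx):
        pa = x[rs.angle_idx[:, 0]]
        pb = x[rs.angle_idx[:, 1]]
        pc = x[rs.angle_idx[:, 2]]
        v1, v2 = pa - pb, pc - pb
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        u1 = v1 / n1[:, None]
        u2 = v2 / n2[:, None]
        cosv = np.clip(np.sum(u1 * u2, axis=1), -1.0, 1.0)
        theta = np.degrees(np.arccos(cosv))
        dev = theta - rs.angle_target
        E += w["angle"] * float(dev @ dev)
        if want_grad:
            # singularity-guarded: unit in-plane perpendiculars; at a
            # straight angle the direction is arbitrary but bounded
            perp_a = cosv[:, None] * u1 - u2
            perp_c = cosv[:, None] * u2 - u1
            na_ = np.linalg.norm(perp_a, axis=1)
            nc_ = np.linalg.norm(perp_c, axis=1)
            fallback = np.zeros_like(u1)
            fallback[:, 0] = -u1[:, 1]
            fallback[:, 1] = u1[:, 0]
            fb_n = np.linalg.norm(fallback, axis=1)
            small = fb_n < 1e-8
            fallback[small] = [0.0, 0.0, 1.0]
            fb_n[small] = 1.0
            fallback /= fb_n[:, None]
            deg_a = na_ < 1e-8
            perp_a[deg_a] = fallback[deg_a]
            na_[deg_a] = 1.0
            deg_c = nc_ < 1e-8
            perp_c[deg_c] = -fallback[deg_c]
            nc_[deg_c] = 1.0
            da = perp_a / (na_ * n1)[:, None]
            dc = perp_c / (nc_ * n2)[:, None]
            coef = 2.0 * w["angle"] * dev * _RAD2DEG
            _scatter(G, rs.angle_idx[:, 0], coef[:, None] * da)
            _scatter(G, rs.angle_idx[:, 2], coef[:, None] * dc)
            _scatter(G, rs.angle_idx[:, 1], -coef[:, None] * (da + dc))

    # base planes (envelope gradient through the best-fit plane)
    for grp in rs.plane_groups:
        pts = x[grp]
        c = pts.mean(axis=0)
        q = pts - c
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        nrm = vt[2]
        d = q @ nrm
        E += w["plane"] * float(d @ d)
        if want_grad:
            g = 2.0 * w["plane"] * d[:, None] * nrm[None, :]
            g -= g.mean(axis=0)
            np.add.at(G, grp, g)

    # torsions (degrees, wrapped)
    if len(rs.torsion_idx):
        p1 = x[rs.torsion_idx[:, 0]]
        p2 = x[rs.torsion_idx[:, 1]]
        p3 = x[rs.torsion_idx[:, 2]]
        p4 = x[rs.torsion_idx[:, 3]]
        b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / nb2[:, None])
        yv = np.sum(m1 * n2, axis=1)
        xv = np.sum(n1 * n2, axis=1)
        phi = np.degrees(np.arctan2(yv, xv))
        dev = phi - rs.torsion_target
        dev = (dev + 180.0) % 360.0 - 180.0
        E += w["torsion"] * float(dev @ dev)
        if want_grad:
            sq1 = np.clip(np.sum(n1 * n1, axis=1), 1e-8, None)
            sq2 = np.clip(np.sum(n2 * n2, axis=1), 1e-8, None)
            dp1 = (nb2 / sq1)[:, None] * n1
            dp4 = (-nb2 / sq2)[:, None] * n2
            c12 = (np.sum(b1 * b2, axis=1) / nb2 ** 2)
            c32 = (np.sum(b3 * b2, axis=1) / nb2 ** 2)
            dp2 = -(1.0 + c12)[:, None] * dp1 + c32[:, None] * dp4
            dp3 = c12[:, None] * dp1 - (1.0 + c32)[:, None] * dp4
            coef = 2.0 * w["torsion"] * dev * _RAD2DEG
            _scatter(G, rs.torsion_idx[:, 0], coef[:, None] * dp1)
            _scatter(G, rs.torsion_idx[:, 1], coef[:, None] * dp2)
            _scatter(G, rs.torsion_idx[:, 2], coef[:, None] * dp3)
            _scatter(G, rs.torsion_idx[:, 3], coef[:, None] * dp4)

    # quartic repulsion below the cutoff
    cut = rs.repulsion_cutoff
    tree = cKDTree(x)
    pairs = tree.query_pairs(cut, output_type="ndarray")
    if len(pairs):
        keep = np.array([frozenset(p) not in rs.exclusions for p in pairs])
        pairs = pairs[keep]
    if len(pairs):
        vi = x[pairs[:, 0]] - x[pairs[:, 1]]
        d = np.linalg.norm(vi, axis=1)
        gap = cut - d
        E += w["repulsion"] * float(np.sum(gap ** 4))
        if want_grad:
            g = (-4.0 * w["repulsion"] * gap ** 3 / d)[:, None] * vi
            _scatter(G, pairs[:, 0], g)
            _scatter(G, pairs[:, 1], -g)

    return (E, G) if want_grad else E


def objective_value(model: Model3D, rs: RestraintSet) -> float:
    return _objective(model.coords(), rs, want_grad=False)


# ---------------------------------------------------------------------------
# minimisation
# ---------------------------------------------------------------------------

def minimize(model: Model3D, restraints: RestraintSet,
             config: MinimizerConfig | None = None):
    """Minimise the restraint objective; returns (model, trace).

    The trace holds the objective value at the start and after every
    accepted step and is non-increasing.  Raises MinimizerError when a
    step cannot decrease the objective despite full backtracking (and
    the gradient is not already negligible).
    """
    config = config or MinimizerConfig()
    x = model.coords()
    if config.method == "gauss_newton":
        x, trace = _minimize_gn(x, restraints, config)
    else:
        x, trace = _minimize_gd(x, restraints, config)
    out = model.copy()
    out.set_coords(x)
    return out, trace


def _minimize_gd(x, rs, config):
    f, g = _objective(x, rs)
    trace = [f]
    gnorm2 = float(np.sum(g * g))
    alpha = config.initial_step / max(1.0, math.sqrt(gnorm2))
    x_prev, g_prev = None, None
    for _ in range(config.max_iterations):
        if gnorm2 < 1e-18:
            break
        # Barzilai-Borwein step estimate
        if x_prev is not None:
            s = (x - x_prev).ravel()
            yv = (g - g_prev).ravel()
            sy = float(s @ yv)
            if sy > 1e-18:
                alpha = float(s @ s) / sy
            else:
                alpha = config.initial_step / max(1.0, math.sqrt(gnorm2))
        alpha = min(alpha, 1.0)
        # Armijo backtracking
        accepted = False
        a = alpha
        for _bt in range(60):
            x_new = x - a * g
            f_new = _objective(x_new, rs, want_grad=False)
            if f_new <= f - 1e-4 * a * gnorm2:
                accepted = True
                break
            a *= config.backtrack_factor
        if not accepted:
            if f < trace[0] * 1e-9 + 1e-12 or gnorm2 < 1e-12:
                break
            # no decrease possible: treat tiny relative change as converged
            x_new = x - a * g
            f_new = _objective(x_new, rs, want_grad=False)
            if f_new > f + 1e-12:
                raise MinimizerError(
                    f"objective increased after full backtracking "
                    f"(f={f:.6g})", trace)
            break
        x_prev, g_prev = x, g
        x = x_new
        f_old = f
        f, g = _objective(x, rs)
        gnorm2 = float(np.sum(g * g))
        trace.append(f)
        if abs(f_old - f) < config.convergence_tol:
            break
    return x, trace


def _minimize_gn(x, rs, config):
    """Damped Gauss-Newton on the residual vector, with backtracking."""
    f = _objective(x, rs, want_grad=False)
    trace = [f]
    lam = 1e-3
    for _ in range(config.max_iterations):
        r, J = _residuals_jacobian(x, rs)
        JTJ = J.T @ J
        JTr = J.T @ r
        gnorm = float(np.linalg.norm(JTr))
        if gnorm < 1e-12:
            break
        try:
            step = np.linalg.solve(JTJ + lam * np.eye(len(JTJ)), -JTr)
        except np.linalg.LinAlgError:
            step = -JTr
        accepted = False
        a = 1.0
        for _bt in range(40):
            x_new = (x.ravel() + a * step).reshape(x.shape)
            f_new = _objective(x_new, rs, want_grad=False)
            if f_new < f:
                accepted = True
                break
            a *= 0.5
        if not accepted:
            lam *= 10.0
            if lam > 1e8:
                break
            continue
        lam = max(lam * 0.3, 1e-10)
        x = x_new
        f_old, f = f, f_new
        trace.append(f)
        if abs(f_old - f) < config.convergence_tol:
            break
    return x, trace


def _residuals_jacobian(x, rs):
    """Dense residual vector and jacobian (for the Gauss-Newton path)."""
    n3 = x.size
    rows = []
    jac = []
    w = rs.weights

    def add(value, grads):
        rows.append(value)
        row = np.zeros(n3)
        for idx, g in grads:
            row[3 * idx: 3 * idx + 3] = row[3 * idx: 3 * idx + 3] + g
        jac.append(row)

    sqb = math.sqrt(w["bond"])
    for (i, j), t in zip(rs.bond_idx, rs.bond_target):
        v = x[i] - x[j]
        d = float(np.linalg.norm(v))
        u = v / d
        add(sqb * (d - t), [(i, sqb * u), (j, -sqb * u)])
    sqa = math.sqrt(w["angle"])
    for (a, b, c), t in zip(rs.angle_idx, rs.angle_target):
        v1, v2 = x[a] - x[b], x[c] - x[b]
        l1, l2 = np.linalg.norm(v1), np.linalg.norm(v2)
        u1, u2 = v1 / l1, v2 / l2
        cosv = float(np.clip(u1 @ u2, -1, 1))
        sin = math.sqrt(max(1e-12, 1 - cosv * cosv))
        theta = math.degrees(math.acos(cosv))
        da = (cosv * u1 - u2) / (l1 * sin) * _RAD2DEG
        dc = (cosv * u2 - u1) / (l2 * sin) * _RAD2DEG
        add(sqa * (theta - t),
            [(a, sqa * da), (c, sqa * dc), (b, -sqa * (da + dc))])
    sqp = math.sqrt(w["plane"])
    for grp in rs.plane_groups:
        pts = x[grp]
        c0 = pts.mean(axis=0)
        q = pts - c0
        _, _, vt = np.linalg.svd(q, full_matrices=False)
        nrm = vt[2]
        d = q @ nrm
        for kk, idx in enumerate(grp):
            add(sqp * d[kk], [(idx, sqp * nrm * (1 - 1 / len(grp)))])
    cut = rs.repulsion_cutoff
    tree = cKDTree(x)
    pairs = tree.query_pairs(cut, output_type="ndarray")
    sqr = math.sqrt(w["repulsion"])
    for i, j in pairs:
        if frozenset((int(i), int(j))) in rs.exclusions:
            continue
        v = x[i] - x[j]
        d = float(np.linalg.norm(v))
        gap = cut - d
        u = v / d
        add(sqr * gap ** 2, [(i, -2 * sqr * gap * u),
                             (j, 2 * sqr * gap * u)])
    return np.array(rows), np.array(jac)


def write_trace(trace, path) -> None:
    """Objective trace as TSV (iteration, objective)."""
    with open(path, "w") as fh:
        fh.write("iteration\tobjective\n")
        for i, v in enumerate(trace):
            fh.write(f"{i}\t{v:.8g}\n")


# ---------------------------------------------------------------------------
# regularisation recipe (used by the pipeline and fixtures)
# ---------------------------------------------------------------------------

def regularize(model: Model3D, templates: TemplateLibrary | None = None,
               rounds: int = 2, gn_iterations: int = 40,
               gd_iterations: int = 2000,
               convergence_tol: float = 1e-12,
               anneal_cycles: int = 0, anneal_sigma: float = 0.2,
               anneal_seed: int = 1000):
    """Drive a freshly built model to a tight restraint minimum.

    Alternates Gauss-Newton (efficient at closing the long-range
    backbone gaps the builder leaves) with gradient descent, resetting
    hydrogens to their canonical template positions between rounds so a
    hydrogen cannot stay wedged in a repulsive pocket.  Returns
    (model, trace); the concatenated trace is monotone within each
    minimisation leg.
    """
    from .transmute import add_hydrogens  # deferred: avoids module cycle

    templates = templates or load_templates("builtin")
    cur = model
    trace = []
    for _ in range(max(1, rounds)):
        rs = build_restraints(cur, templates)
        cur, t1 = minimize(cur, rs, MinimizerConfig(
            max_iterations=gn_iterations, method="gauss_newton",
            convergence_tol=convergence_tol))
        cur, t2 = minimize(cur, rs, MinimizerConfig(
            max_iterations=gd_iterations,
            convergence_tol=convergence_tol))
        trace += t1 + t2
        # strip and re-place hydrogens at canonical geometry
        stripped = cur.copy()
        for res in stripped.residues:
            res.atoms = [a for a in res.atoms
                         if not a.name.startswith("H")]
        cur = add_hydrogens(stripped, templates)
    rs = build_restraints(cur, templates)
    cur, t3 = minimize(cur, rs, MinimizerConfig(
        max_iterations=gd_iterations, convergence_tol=convergence_tol))
    trace += t3
    # optional seeded perturb-and-minimise cycles: settles the model in
    # a deep restraint minimum (used for reference/fixture models)
    best, fbest = cur, trace[-1]
    for k in range(anneal_cycles):
        rng = np.random.default_rng(anneal_seed + k)
        x = best.coords()
        pert = best.copy()
        pert.set_coords(x + rng.normal(0.0, anneal_sigma, x.shape))
        cand, tk = minimize(pert, rs, MinimizerConfig(
            max_iterations=gd_iterations,
            convergence_tol=convergence_tol))
        trace += tk
        if tk[-1] < fbest:
            fbest = tk[-1]
            best = cand
    return best, trace
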