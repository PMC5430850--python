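"""All-atom 3D model construction from a secondary structure.

Stems are built as ideal A-form double helices from per-residue nucleotide
templates (each template is one nucleotide expressed in a Watson-Crick
pair frame; the partner strand is the 180-degree pair-flip of the partner
base's template).  Hairpin-loop and connector residues are placed on
smooth circular arcs bridging the stem ends, with a deterministic
clash-relief pass.  The intermediate model carries RNA chemistry (T is
rendered as U); the DNA conversion is a separate stage.
"""

from __future__ import annotations

import dataclasses
import functools
import importlib.resources
import math

import numpy as np
from scipy.optimize import brentq

from . import chem
from .errors import ConsistencyError, TemplateValidationError
from .nucio import AtomRecord, Model3D, NucSequence, Residue3D

_FLIP = np.diag([1.0, -1.0, -1.0])

#: C1'-C1' spacing of consecutive single-stranded (loop/tail) residues
_SS_SPACING = 5.9


# ---------------------------------------------------------------------------
# template library
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NucleotideTemplate:
    """Ideal atom coordinates of one residue type in the pair frame."""

    name: str
    atoms: dict  # atom name -> np.ndarray(3)

    def coords(self, names):
        return np.array([self.atoms[a] for a in names])


@dataclasses.dataclass
class TemplateLibrary:
    residues: dict          # residue name -> NucleotideTemplate
    rise: float             # A per pair step
    twist: float            # degrees per pair step
    displacement: dict      # chemistry -> helix-axis (x, y) displacement
    inclination: float
    bond_reference: dict    # (class, atom1, atom2) -> target length

    def template(self, resname: str) -> NucleotideTemplate:
        return self.residues[resname]

    def linkage_geometry(self, chemistry: str) -> dict:
        """Bond and angle values of the O3'->P linkage as realised by the
        template helix (used as refinement targets, so the built stem is
        an exact restraint minimum)."""
        ref = "A" if chemistry == chem.RNA else "DA"
        tpl = self.residues[ref].atoms
        Rz, t = _helix_op(1, self.rise, self.twist,
                          self.displacement[chemistry])
        up = {a: Rz @ v + t for a, v in tpl.items()}

        def ang(p, q, r):
            v1, v2 = p - q, r - q
            c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            return math.degrees(math.acos(max(-1.0, min(1.0, c))))

        return {
            "bond": float(np.linalg.norm(tpl["O3'"] - up["P"])),
            ("C3'", "O3'", "P"): ang(tpl["C3'"], tpl["O3'"], up["P"]),
            ("O3'", "P", "O5'"): ang(tpl["O3'"], up["P"], up["O5'"]),
            ("O3'", "P", "OP1"): ang(tpl["O3'"], up["P"], up["OP1"]),
            ("O3'", "P", "OP2"): ang(tpl["O3'"], up["P"], up["OP2"]),
        }

    def bond_target(self, resname: str, a1: str, a2: str) -> float | None:
        _, base = chem.RESIDUE_CODES[resname]
        cls = "pur" if base in chem.PURINES else "pyr"
        in_base = (a1 in chem.BASE_ATOMS[base]
                   and a2 in chem.BASE_ATOMS[base])
        for key in (((cls if in_base else "bb"), a1, a2),
                    (resname, a1, a2)):
            if key in self.bond_reference:
                return self.bond_reference[key]
        return None


def _parse_templates(text: str) -> TemplateLibrary:
    residues = {}
    helix = {}
    bond_ref = {}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section.startswith("residue "):
                rname = section.split()[1]
                residues[rname] = NucleotideTemplate(rname, {})
                section = ("residue", rname)
            continue
        f = line.split()
        if section == "helix":
            helix[f[0]] = [float(v) for v in f[1:]]
        elif section == "bond_reference":
            bond_ref[(f[0], f[1], f[2])] = float(f[3])
        elif isinstance(section, tuple):
            residues[section[1]].atoms[f[0]] = np.array(
                [float(f[2]), float(f[3]), float(f[4])])
    disp = {}
    for key, ch in (("displacement_rna", chem.RNA),
                    ("displacement_dna", chem.DNA)):
        v = helix[key]
        disp[ch] = (v[0], v[1] if len(v) > 1 else 0.0)
    return TemplateLibrary(
        residues=residues, rise=helix["rise"][0], twist=helix["twist"][0],
        displacement=disp,
        inclination=helix.get("inclination", [0.0])[0],
        bond_reference=bond_ref,
    )


def _validate_library(lib: TemplateLibrary) -> None:
    bad = []
    for rname, tpl in lib.residues.items():
        bonds = chem.residue_bonds(rname, has_5p_phosphate=True,
                                   is_3p_terminal=True, is_5p_terminal=False)
        bonds.append(("O5'", "H5T"))
        for a1, a2 in bonds:
            if a1 not in tpl.atoms or a2 not in tpl.atoms:
                continue
            target = lib.bond_target(rname, a1, a2)
            if target is None:
                continue
            d = float(np.linalg.norm(tpl.atoms[a1] - tpl.atoms[a2]))
            if abs(d - target) > 0.02:
                bad.append(f"{rname} {a1}-{a2}: {d:.3f} vs {target:.3f}")
    if bad:
        raise TemplateValidationError(
            "template bonds out of tolerance: " + "; ".join(bad))
    # Watson-Crick partner templates must place donor-acceptor pairs
    # at hydrogen-bonding distance
    pairs = [("A", "U"), ("G", "C"), ("DA", "DT"), ("DG", "DC"),
             ("DA", "DU")]
    for n1, n2 in pairs:
        if n1 not in lib.residues or n2 not in lib.residues:
            continue
        b1 = chem.RESIDUE_CODES[n1][1]
        b2 = chem.RESIDUE_CODES[n2][1]
        t1, t2 = lib.residues[n1], lib.residues[n2]
        for a1, a2, _ in chem.wc_hbonds(b1, b2):
            d = float(np.linalg.norm(t1.atoms[a1] - _FLIP @ t2.atoms[a2]))
            if not (2.75 <= d <= 3.05):
                raise TemplateValidationError(
                    f"pair {n1}-{n2} contact {a1}..{a2} at {d:.3f} A "
                    f"outside 2.75-3.05")


@functools.lru_cache(maxsize=4)
def _builtin_library() -> TemplateLibrary:
    text = (importlib.resources.files("hairpinforge.data")
            / "templates_v1.txt").read_text()
    lib = _parse_templates(text)
    _validate_library(lib)
    return lib


def load_templates(path="builtin") -> TemplateLibrary:
    """Load and validate a nucleotide template library."""
    if path == "builtin":
        return _builtin_library()
    with open(path) as fh:
        lib = _parse_templates(fh.read())
    _validate_library(lib)
    return lib


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _helix_op(step: float, rise: float, twist_deg: float, disp):
    """Screw transform for a (possibly fractional) pair step."""
    ang = math.radians(twist_deg) * step
    Rz = np.array([[math.cos(ang), -math.sin(ang), 0.0],
                   [math.sin(ang), math.cos(ang), 0.0],
                   [0.0, 0.0, 1.0]])
    c = np.array([disp[0], disp[1], 0.0])
    t = c - Rz @ c + np.array([0.0, 0.0, rise * step])
    return Rz, t


@dataclasses.dataclass
class _Frame:
    """Rigid placement: x -> R @ x + t."""

    R: np.ndarray
    t: np.ndarray

    def apply(self, x):
        return (self.R @ np.asarray(x).T).T + self.t

    def compose(self, other: "_Frame") -> "_Frame":
        return _Frame(self.R @ other.R, self.R @ other.t + self.t)

    @staticmethod
    def identity():
        return _Frame(np.eye(3), np.zeros(3))


def _arc_points(p0, p1, n, spacing=_SS_SPACING, bulge=None):
    """n points on a circular arc from p0 to p1 with arc length
    ~ (n+1)*spacing, bulging along the unit vector ``bulge``."""
    chord = float(np.linalg.norm(p1 - p0))
    L = (n + 1) * spacing
    if L <= chord * 1.001:
        # nearly straight: linear interpolation
        return [p0 + (p1 - p0) * (k / (n + 1)) for k in range(1, n + 1)]

    def f(theta):
        return 2.0 * math.sin(theta / 2.0) / theta - chord / L

    theta = brentq(f, 1e-6, 2.0 * math.pi - 1e-9)
    R = L / theta
    mid = 0.5 * (p0 + p1)
    u = (p1 - p0) / chord
    if bulge is None:
        bulge = np.array([0.0, 0.0, 1.0])
    w = bulge - (bulge @ u) * u
    nw = np.linalg.norm(w)
    w = np.array([0.0, 0.0, 1.0]) if nw < 1e-9 else w / nw
    h = R * math.cos(theta / 2.0)
    centre = mid - h * w
    # rotate p0 about the axis normal to the (u, w) plane
    axis = np.cross(u, w)
    axis /= np.linalg.norm(axis)
    pts = []
    v0 = p0 - centre
    for k in range(1, n + 1):
        ang = theta * k / (n + 1)
        rot = _rotation_about(axis, -ang)
        pts.append(centre + rot @ v0)
    return pts


def _rotation_about(axis, ang):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)


def _frame_from_axes(origin, tangent, inward):
    """Frame mapping template pair-frame axes onto a single-stranded
    residue placement: template +z (chain direction) -> tangent, the
    glycosidic xy direction -> inward."""
    ez = tangent / np.linalg.norm(tangent)
    w = inward - (inward @ ez) * ez
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        w = np.array([1.0, 0.0, 0.0])
        w = w - (w @ ez) * ez
        nw = np.linalg.norm(w)
    ex = w / nw
    ey = np.cross(ez, ex)
    R = np.stack([ex, ey, ez], axis=1)  # columns: images of x, y, z
    return _Frame(R, origin)


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------

def _rna_resname(letter: str) -> str:
    return "U" if letter in ("T", "U") else letter


def build_rna_3d(seq: NucSequence, ss, templates: TemplateLibrary | None
                 = None) -> Model3D:
    """Build the RNA-geometry intermediate model for one structure.

    Deterministic: identical inputs give identical coordinates.  Stems
    become ideal A-form helices; hairpin-loop, connector and tail
    residues are placed on smooth arcs with at least 1.5 A between
    non-bonded atoms (a small deterministic relief pass nudges loop
    residues outward if templates overlap).
    """
    templates = templates or load_templates("builtin")
    n = len(seq)
    if len(ss.pair) != n:
        raise ConsistencyError(
            f"structure length {len(ss.pair)} != sequence length {n}")
    letters = [_rna_resname(c) for c in seq.residues]
    pair = ss.pair
    rise, twist = templates.rise, templates.twist
    dx = templates.displacement[chem.RNA]

    placements: dict[int, _Frame] = {}   # residue index (0-based) -> frame
    strand2: set[int] = set()

    # --- walk the structure, assigning pair steps ------------------------
    # Helix step counter advances along one global axis; every paired
    # residue is placed by its step; single-stranded stretches get arcs.
    def place_pair(i, j, step):
        Rz, t = _helix_op(step, rise, twist, dx)
        placements[i] = _Frame(Rz, t)
        placements[j] = _Frame(Rz, t)
        strand2.add(j)

    step_of: dict[int, float] = {}

    def walk(i, j, step):
        """Place the region enclosed by pair (i, j) (0-based, paired)."""
        place_pair(i, j, step)
        step_of[i] = step_of[j] = step
        k, l = i + 1, j - 1
        while k <= l:
            if pair[k] - 1 == l and pair[l] - 1 == k:
                step = step + 1
                place_pair(k, l, step)
                step_of[k] = step_of[l] = step
                k, l = k + 1, l - 1
            elif pair[k] == 0 and pair[l] == 0 and _no_pairs(pair, k, l):
                return  # hairpin loop: handled by arc pass
            else:
                # internal loop, bulge or multiloop: find children
                kids = _kids(pair, k, l)
                if len(kids) == 1:
                    (a, b) = kids[0]
                    gap = max(a - k, l - b)
                    step = step + 1 + 0.5 * gap
                    walk(a, b, step)
                    return
                # multiloop: branches fan out; first continues coaxially
                prev_end = k
                for bi, (a, b) in enumerate(kids):
                    gap = a - prev_end
                    branch_step = step + 1 + 0.5 * gap + 1.2 * bi
                    walk(a, b, branch_step)
                    prev_end = b + 1
                return

    def _no_pairs(p, k, l):
        return all(p[m] == 0 for m in range(k, l + 1))

    def _kids(p, k, l):
        out = []
        m = k
        while m <= l:
            if p[m] - 1 > m:
                out.append((m, p[m] - 1))
                m = p[m] - 1 + 1
            else:
                m += 1
        return out

    # exterior: helices placed sequentially along the global axis
    ext = _kids(pair, 0, n - 1)
    base_step = 0.0
    for h, (a, b) in enumerate(ext):
        if h > 0:
            gap = a - ext[h - 1][1] - 1
            base_step += (b_steps := 0)  # clarity only
            base_step += 1 + 0.5 * gap
        walk(a, b, base_step)
        base_step += max(st for idx, st in step_of.items()
                         if a <= idx <= b) - step_of[a]

    # --- anchors for single-stranded stretches ---------------------------
    def c1_of(idx):
        tpl = templates.template(letters[idx])
        v = tpl.atoms["C1'"]
        if idx in strand2:
            v = _FLIP @ v
        return placements[idx].apply(v)

    def axis_dir_at(idx):
        # local chain direction: +z of the residue's frame, flipped on
        # strand 2 (which runs 3'->5' as steps increase)
        d = placements[idx].R @ np.array([0.0, 0.0, 1.0])
        return -d if idx in strand2 else d

    # hairpin loops and connectors: arc placement
    visited = set(placements)
    segments = []
    run = []
    for idx in range(n):
        if idx in visited:
            if run:
                segments.append(run)
                run = []
        else:
            run.append(idx)
    if run:
        segments.append(run)

    for run in segments:
        a0 = run[0] - 1            # anchor before (may be -1)
        a1 = run[-1] + 1           # anchor after (may be n)
        m = len(run)
        if a0 >= 0 and a1 < n:
            p0, p1 = c1_of(a0), c1_of(a1)
            bulge = 0.5 * (axis_dir_at(a0) - axis_dir_at(a1))
            if np.linalg.norm(bulge) < 1e-6:
                # connector between coaxial helices: bulge radially out
                mid = 0.5 * (p0 + p1)
                bulge = mid - _helix_axis_point(placements[a0], dx)
                bulge = bulge - (bulge @ axis_dir_at(a0)) * axis_dir_at(a0)
                if np.linalg.norm(bulge) < 1e-6:
                    bulge = axis_dir_at(a0)
            centre_ref = 0.5 * (p0 + p1)
            pts = _arc_points(p0, p1, m, bulge=bulge / np.linalg.norm(bulge))
        elif a0 >= 0:              # 3' tail
            d = axis_dir_at(a0)
            out = c1_of(a0) - _helix_axis_point(placements[a0], dx)
            out = out / np.linalg.norm(out)
            step_v = (d + 0.4 * out)
            step_v /= np.linalg.norm(step_v)
            pts = [c1_of(a0) + step_v * _SS_SPACING * k
                   for k in range(1, m + 1)]
            centre_ref = c1_of(a0)
        elif a1 < n:               # 5' tail
            d = -axis_dir_at(a1)
            out = c1_of(a1) - _helix_axis_point(placements[a1], dx)
            out = out / np.linalg.norm(out)
            step_v = (d + 0.4 * out)
            step_v /= np.linalg.norm(step_v)
            pts = [c1_of(a1) + step_v * _SS_SPACING * (m + 1 - k)
                   for k in range(1, m + 1)]
            centre_ref = c1_of(a1)
        else:                      # fully unpaired chain
            step_v = np.array([1.0, 0.0, 0.0])
            pts = [step_v * _SS_SPACING * k for k in range(m)]
            centre_ref = np.array([0.0, 0.0, -10.0])
        def anchor_atom(ridx, name):
            tpl_a = templates.template(letters[ridx])
            if name not in tpl_a.atoms:
                return None
            v = tpl_a.atoms[name]
            if ridx in strand2:
                v = _FLIP @ v
            return placements[ridx].apply(v)

        prev_o3 = anchor_atom(a0, "O3'") if a0 >= 0 else None
        prev_c3 = anchor_atom(a0, "C3'") if a0 >= 0 else None
        next_p = anchor_atom(a1, "P") if a1 < n else None
        for k, idx in enumerate(run):
            tpl = templates.template(letters[idx])
            c1_t = pts[k]
            targets = [("C1'", c1_t, 1.5)]
            if prev_o3 is not None and "P" in tpl.atoms:
                w = c1_t - prev_o3
                w = w / max(np.linalg.norm(w), 1e-9)
                if prev_c3 is not None:
                    # place P so the C3'-O3'-P angle is near canonical
                    u = prev_o3 - prev_c3
                    u = u / max(np.linalg.norm(u), 1e-9)
                    wp = w - (w @ u) * u
                    nwp = np.linalg.norm(wp)
                    wp = wp / nwp if nwp > 1e-9 else _any_perp(u)
                    ang = math.radians(180.0 - 118.5)
                    w = math.cos(ang) * u + math.sin(ang) * wp
                targets.append(("P", prev_o3 + 1.6 * w, 2.5))
            if k < m - 1:
                nxt = pts[k + 1]
                t_o3 = c1_t + 0.62 * (nxt - c1_t)
            elif next_p is not None:
                u = next_p - c1_t
                u = u / max(np.linalg.norm(u), 1e-9)
                t_o3 = next_p - 1.6 * u
            else:
                direction = (c1_t - pts[k - 1]) if k > 0 else                     np.array([_SS_SPACING, 0.0, 0.0])
                t_o3 = c1_t + 0.62 * direction
            targets.append(("O3'", t_o3, 2.5))
            outward = c1_t - centre_ref
            nout = np.linalg.norm(outward)
            if nout > 1e-6:
                base = chem.RESIDUE_CODES[letters[idx]][1]
                targets.append((chem.glycosidic_nitrogen(base),
                                c1_t + 1.48 * outward / nout, 0.5))
            placements[idx] = _fit_placement(tpl, targets)
            prev_o3 = placements[idx].apply(tpl.atoms["O3'"])
            prev_c3 = placements[idx].apply(tpl.atoms["C3'"])
        _optimise_loop_spins(run, pts, placements, letters, templates, n)

    # --- materialise residues --------------------------------------------
    model = _materialise(seq, letters, placements, strand2, templates)
    _relieve_clashes(model, pair)
    return model


def _helix_axis_point(frame: _Frame, disp):
    return frame.apply(np.array([disp[0], disp[1], 0.0]))


def _any_perp(u):
    v = np.array([1.0, 0.0, 0.0])
    v = v - (v @ u) * u
    if np.linalg.norm(v) < 1e-6:
        v = np.array([0.0, 1.0, 0.0])
        v = v - (v @ u) * u
    return v / np.linalg.norm(v)


def _fit_placement(tpl, targets):
    """Weighted rigid fit of template atoms onto target positions."""
    names = [t[0] for t in targets]
    P = np.array([tpl.atoms[nm] for nm in names])
    Q = np.array([t[1] for t in targets])
    w = np.array([t[2] for t in targets])
    wp = w / w.sum()
    cp = (wp[:, None] * P).sum(axis=0)
    cq = (wp[:, None] * Q).sum(axis=0)
    H = (P - cp).T @ (wp[:, None] * (Q - cq))
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return _Frame(R, cq - R @ cp)


def _optimise_loop_spins(run, pts, placements, letters, templates, n,
                         n_spins=72, sweeps=3):
    """Spin each single-stranded residue about its local chain tangent so
    that its phosphate faces the previous residue's O3' (and its O3' the
    next residue's phosphate).  Deterministic discrete search."""
    def atom_pos(idx, name):
        tpl = templates.template(letters[idx])
        if name not in tpl.atoms:
            return None
        return placements[idx].apply(tpl.atoms[name])

    def _ang(a, b, c):
        v1, v2 = a - b, c - b
        cv = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return math.degrees(math.acos(max(-1.0, min(1.0, cv))))

    for _ in range(sweeps):
        for k, idx in enumerate(run):
            tpl = templates.template(letters[idx])
            c1 = pts[k]
            # tangent axis = local frame z image
            axis = placements[idx].R @ np.array([0.0, 0.0, 1.0])
            axis = axis / np.linalg.norm(axis)
            prev_o3 = atom_pos(idx - 1, "O3'") if idx - 1 >= 0 else None
            prev_c3 = atom_pos(idx - 1, "C3'") if idx - 1 >= 0 else None
            next_p = atom_pos(idx + 1, "P") if idx + 1 < n else None
            next_o5 = atom_pos(idx + 1, "O5'") if idx + 1 < n else None
            has_p = idx > 0 and "P" in tpl.atoms
            base_frame = placements[idx]
            best = None
            for s in range(n_spins):
                ang = 2.0 * math.pi * s / n_spins
                rot = _Frame(_rotation_about(axis, ang)
                             @ np.eye(3), c1 - _rotation_about(axis, ang)
                             @ c1)
                cand = rot.compose(base_frame)
                cost = 0.0
                if prev_o3 is not None and has_p:
                    p = cand.apply(tpl.atoms["P"])
                    cost += abs(np.linalg.norm(p - prev_o3) - 1.6)
                    if prev_c3 is not None:
                        cost += 0.02 * abs(_ang(prev_c3, prev_o3, p) - 118.5)
                    o5 = cand.apply(tpl.atoms["O5'"])
                    cost += 0.02 * abs(_ang(prev_o3, p, o5) - 106.0)
                if next_p is not None:
                    o3 = cand.apply(tpl.atoms["O3'"])
                    cost += abs(np.linalg.norm(o3 - next_p) - 1.6)
                    c3 = cand.apply(tpl.atoms["C3'"])
                    cost += 0.02 * abs(_ang(c3, o3, next_p) - 118.5)
                    if next_o5 is not None:
                        cost += 0.02 * abs(_ang(o3, next_p, next_o5) - 106.0)
                if best is None or cost < best[0] - 1e-12:
                    best = (cost, cand)
            placements[idx] = best[1]


def _materialise(seq, letters, placements, strand2, templates):
    residues = []
    n = len(letters)
    for idx in range(n):
        rname = letters[idx]
        tpl = templates.template(rname)
        is5 = idx == 0
        is3 = idx == n - 1
        names = chem.expected_atoms(rname, has_5p_phosphate=not is5,
                                    is_3p_terminal=is3, is_5p_terminal=is5)
        atoms = []
        for a in names:
            v = tpl.atoms[a]
            if idx in strand2:
                v = _FLIP @ v
            xyz = placements[idx].apply(v)
            atoms.append(AtomRecord(a, chem.element_of(a), xyz))
        residues.append(Residue3D(rname, idx + 1, atoms))
    return Model3D("A", residues, chem.RNA)


def _relieve_clashes(model: Model3D, pair, min_dist=1.5, max_iter=60):
    """Deterministically nudge clashing single-stranded residues apart."""
    n = len(model.residues)
    single = [i for i in range(n) if pair[i] == 0]
    if not single:
        return
    for _ in range(max_iter):
        coords = [np.array([a.xyz for a in r.atoms])
                  for r in model.residues]
        worst = None
        for i in single:
            for j in range(n):
                if abs(i - j) <= 1:
                    continue
                d = np.linalg.norm(coords[i][:, None, :]
                                   - coords[j][None, :, :], axis=-1)
                dmin = d.min()
                if dmin < min_dist and (worst is None or dmin < worst[0]):
                    worst = (dmin, i, j)
        if worst is None:
            return
        _, i, j = worst
        ci = coords[i].mean(axis=0)
        cj = coords[j].mean(axis=0)
        push = ci - cj
        nrm = np.linalg.norm(push)
        push = (push / nrm if nrm > 1e-9
                else np.array([0.0, 0.0, 1.0])) * 0.3
        for a in model.residues[i].atoms:
            a.xyz = a.xyz + push
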