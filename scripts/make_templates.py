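"""Generate the nucleotide template library (data/templates_v1.txt).

One-time generation script.  Starting from ideal chemical-component
coordinates (biotite's bundled CCD), it:

1. optimises a rigid Watson-Crick placement of the pyrimidine base
   against the purine base of each pair class (H-bond distances,
   coplanarity, C1'-C1' separation) and expresses both nucleotides in a
   dyad-symmetric pair frame (origin midway between the C1' atoms,
   y along C1'-C1', z along the base normal),
2. replaces every residue's sugar-phosphate moiety with one canonical
   unit per chemistry (taken from the CCD adenosine/deoxyadenosine),
   attached through a standardized glycosidic frame so that all four
   strand-1 nucleotides share an identical backbone conformation,
3. tunes that unit's exocyclic torsions (glycosidic spin, gamma, beta,
   O3' rotation) together with the helix-axis displacement so that
   consecutive steps of the helix (rise 2.81 A, twist 32.7 deg/pair)
   leave near-bondable O3'(i)-P(i+1) gaps on both strands,
4. writes all residues, helix parameters and a bond-length reference
   table to a plain-text template file.

Run from the repository root:  python scripts/make_templates.py
"""

import sys
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import biotite.structure.info as ccd_info  # noqa: E402

from hairpinforge import chem  # noqa: E402

RISE = 2.81
TWIST = 32.7

RNA_RES = ["A", "C", "G", "U"]
DNA_RES = ["DA", "DC", "DG", "DT", "DU"]
PAIRS = [("A", "U"), ("G", "C"), ("DA", "DT"), ("DG", "DC"), ("DA", "DU")]
FLIP = np.diag([1.0, -1.0, -1.0])


def load_ccd_residue(name):
    arr = ccd_info.residue(name)
    coords = {str(a): arr.coord[i].astype(float)
              for i, a in enumerate(arr.atom_name)}
    wanted = chem.expected_atoms(name, has_5p_phosphate=True,
                                 is_3p_terminal=False, is_5p_terminal=False)
    out = {}
    for atom in wanted:
        if atom not in coords:
            raise KeyError(f"{name}: CCD lacks atom {atom}")
        out[atom] = coords[atom]
    out["H3T"] = coords.get("HO3'", _along(out["O3'"],
                                           2 * out["O3'"] - out["C3'"], 0.96))
    out["H5T"] = _along(out["O5'"], out["P"], 0.96)
    return out


def _along(origin, toward, dist):
    v = toward - origin
    return origin + dist * v / np.linalg.norm(v)


def plane_normal(points):
    pts = np.array(points)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return vt[2], c


def signed_base_normal(base, coords):
    """Base-plane normal with a sign fixed by ring-atom order."""
    a, b, c = (("N9", "C8", "N7") if base in chem.PURINES
               else ("N1", "C2", "N3"))
    v1 = coords[b] - coords[a]
    v2 = coords[c] - coords[b]
    n = np.cross(v1, v2)
    return n / np.linalg.norm(n)


def glyco_frame(resname, coords):
    """Rows of the returned matrix are the frame axes; origin is C1'."""
    base = chem.RESIDUE_CODES[resname][1]
    origin = coords["C1'"]
    e1 = coords[chem.glycosidic_nitrogen(base)] - origin
    e1 /= np.linalg.norm(e1)
    n = signed_base_normal(base, coords)
    e3 = n - (n @ e1) * e1
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    return origin, np.stack([e1, e2, e3])


def place_base_on_anchors(resname, coords, a_half, lam, prop, normal_sign):
    """Rigidly map a base (plus C1') onto the canonical strand-1 anchors.

    Anchors in the pair frame: C1' at (0, a_half, 0); the glycosidic bond
    in the z=0 plane, rotated by lambda from the C1'->C1' axis (-y)
    toward +x; the (ring-order-signed) base normal along
    ``normal_sign * z``; finally a propeller rotation about the
    glycosidic axis.  The C1' anchor and glycosidic direction are shared
    by all strand-1 residues, so one sugar unit fits every base.
    """
    base = chem.RESIDUE_CODES[resname][1]
    keep = {a: coords[a] for a in chem.BASE_ATOMS[base] + ["C1'"]}
    c1 = keep["C1'"]
    ngly = keep[chem.glycosidic_nitrogen(base)]
    e1 = ngly - c1
    e1 /= np.linalg.norm(e1)
    n = signed_base_normal(base, keep)
    e3 = n - (n @ e1) * e1
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    R_local = np.stack([e1, e2, e3])  # local frame rows

    c1_t = np.array([0.0, a_half, 0.0])
    d = np.array([np.sin(lam), -np.cos(lam), 0.0])
    e3_t = np.array([0.0, 0.0, float(normal_sign)])
    e2_t = np.cross(e3_t, d)
    R_target = np.stack([d, e2_t, e3_t])
    M = Rotation.from_rotvec(d * prop).as_matrix() @ (R_target.T @ R_local)
    return {a: c1_t + M @ (v - c1) for a, v in keep.items()}


def _class_sign(resname, s_pur, s_pyr):
    return s_pur if chem.RESIDUE_CODES[resname][1] in chem.PURINES else s_pyr


def _place_pair(raw, pur_name, pyr_name, x, s_pur, s_pyr):  # noqa: D401
    a_half, lam_p, lam_y, prop_p, prop_y = x
    pur = place_base_on_anchors(pur_name, raw[pur_name],
                                a_half, lam_p, prop_p, s_pur)
    pyr1 = place_base_on_anchors(pyr_name, raw[pyr_name],
                                 a_half, lam_y, prop_y, s_pyr)
    pyr = {a: FLIP @ v for a, v in pyr1.items()}
    return pur, pyr


def hbond_errors(raw, x, s_pur, s_pyr, pair_set):
    errs = []
    for pur_name, pyr_name in pair_set:
        pb = chem.RESIDUE_CODES[pur_name][1]
        yb = chem.RESIDUE_CODES[pyr_name][1]
        pur, pyr = _place_pair(raw, pur_name, pyr_name, x, s_pur, s_pyr)
        for a1, a2, dt in chem.wc_hbonds(pb, yb):
            errs.append(np.linalg.norm(pur[a1] - pyr[a2]) - dt)
    return np.array(errs)


def _pair_cost(raw, x, s_pur, s_pyr, pair_set):
    c = (hbond_errors(raw, x, s_pur, s_pyr, pair_set) ** 2).sum()
    # keep the pair physical: canonical C1'-C1' separation, modest
    # glycosidic angles and propeller, no inter-base clashes
    c += 2.0 * (2 * x[0] - 10.4) ** 2
    c += 0.3 * ((x[1] - np.deg2rad(54.5)) ** 2
                + (x[2] - np.deg2rad(54.5)) ** 2)
    c += 0.1 * (x[3] ** 2 + x[4] ** 2)
    for pur_name, pyr_name in pair_set:
        pb = chem.RESIDUE_CODES[pur_name][1]
        yb = chem.RESIDUE_CODES[pyr_name][1]
        pur, pyr = _place_pair(raw, pur_name, pyr_name, x, s_pur, s_pyr)
        hb_atoms = set()
        for a1, a2, _ in chem.wc_hbonds(pb, yb):
            hb_atoms.add((a1, a2))
        A = np.array(list(pur.values()))
        B = np.array(list(pyr.values()))
        names_a = list(pur)
        names_b = list(pyr)
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
        for i in range(len(names_a)):
            for j in range(len(names_b)):
                if (names_a[i], names_b[j]) in hb_atoms:
                    continue
                lim = 2.5 if (names_a[i][0] != "H"
                              and names_b[j][0] != "H") else 1.9
                if d[i, j] < lim:
                    c += 5.0 * (lim - d[i, j]) ** 2
    return c


def choose_pair_geometry(raw, pair_set):
    """Fit pair anchors (separation, per-class lambda and propeller) and
    the per-class normal signs so WC donor-acceptor distances land on
    target."""
    x0 = np.array([5.2, np.deg2rad(54.5), np.deg2rad(54.5), 0.0, 0.0])
    best = None
    for s_pur in (1.0, -1.0):
        for s_pyr in (1.0, -1.0):
            res = minimize(
                lambda x: _pair_cost(raw, x, s_pur, s_pyr, pair_set),
                x0, method="Powell",
                options={"maxiter": 30000, "xtol": 1e-10, "ftol": 1e-13})
            if best is None or res.fun < best[2].fun:
                best = (s_pur, s_pyr, res)
    s_pur, s_pyr, res = best
    x = res.x
    print(f"  C1'-C1' {2 * x[0]:.3f} A, lambda pur/pyr "
          f"{np.rad2deg(x[1]):.2f}/{np.rad2deg(x[2]):.2f} deg, propeller "
          f"{np.rad2deg(x[3]):.2f}/{np.rad2deg(x[4]):.2f} deg, signs "
          f"{s_pur:+.0f}/{s_pyr:+.0f}, hbond rms {np.sqrt(res.fun/5):.4f} A")
    for pur_name, pyr_name in pair_set:
        pb = chem.RESIDUE_CODES[pur_name][1]
        yb = chem.RESIDUE_CODES[pyr_name][1]
        pur, pyr = _place_pair(raw, pur_name, pyr_name, x, s_pur, s_pyr)
        ds = [np.linalg.norm(pur[a1] - pyr[a2])
              for a1, a2, _ in chem.wc_hbonds(pb, yb)]
        print(f"  {pur_name}-{pyr_name}: hbonds "
              + " ".join(f"{d:.3f}" for d in ds))
    return x, s_pur, s_pyr


# ---------------------------------------------------------------------------
# canonical sugar-phosphate unit
# ---------------------------------------------------------------------------

def sugar_unit(resname, coords):
    """Non-base atoms of one residue, in its glycosidic local frame."""
    base = chem.RESIDUE_CODES[resname][1]
    base_set = set(chem.BASE_ATOMS[base])
    origin, R = glyco_frame(resname, coords)
    return {a: R @ (v - origin) for a, v in coords.items()
            if a not in base_set}


def apply_unit_torsions(unit, angles):
    """Rotate exocyclic groups of the local sugar unit (radians)."""
    out = {a: v.copy() for a, v in unit.items()}

    def rotate(group, p0, p1, ang):
        axis = p1 - p0
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(axis * ang)
        for a in group:
            if a in out:
                out[a] = rot.apply(out[a] - p0) + p0

    # chi: spin the whole unit about the glycosidic axis (local e1 = x)
    rot = Rotation.from_rotvec(np.array([angles["chi"], 0.0, 0.0]))
    for a in out:
        out[a] = rot.apply(out[a])
    rotate({"O5'", "H5'", "H5''", "P", "OP1", "OP2", "H5T"},
           out["C4'"], out["C5'"], angles["gamma"])
    rotate({"P", "OP1", "OP2"}, out["C5'"], out["O5'"], angles["beta"])
    rotate({"O3'", "H3T"}, out["C4'"], out["C3'"], angles["delta"])
    return out


def canonical_attach_frame(a_half, lam):
    """The one glycosidic frame shared by all strand-1 residues."""
    origin = np.array([0.0, a_half, 0.0])
    e1 = np.array([np.sin(lam), -np.cos(lam), 0.0])
    e3 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    return origin, np.stack([e1, e2, e3])


def attach(base_coords, resname, unit, geom):
    """Template = pair-frame base atoms + sugar unit, canonical frame."""
    origin, R = canonical_attach_frame(geom[0], 0.5 * (geom[1] + geom[2]))
    tpl = {a: v.copy() for a, v in base_coords.items()
           if a in chem.BASE_ATOMS[chem.RESIDUE_CODES[resname][1]]
           or a == "C1'"}
    for a, v in unit.items():
        if a == "C1'":
            continue
        tpl[a] = origin + R.T @ v
    return tpl


def helix_transform(step, dx, dy=0.0):
    ang = np.deg2rad(TWIST) * step
    Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                   [np.sin(ang), np.cos(ang), 0],
                   [0, 0, 1.0]])
    c = np.array([dx, dy, 0.0])
    t = c - Rz @ c + np.array([0.0, 0.0, RISE * step])
    return Rz, t


def _angle(a, b, c):
    v1, v2 = a - b, c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return np.arccos(np.clip(cosang, -1, 1))


def continuity_cost(templates, partners, res_names, dx):
    c = 0.0
    Rz, t = helix_transform(1, dx)
    for x in res_names:
        for y in res_names:
            lo, up_t = templates[x], templates[y]
            up = {a: Rz @ v + t for a, v in up_t.items()}
            gap = np.linalg.norm(lo["O3'"] - up["P"])
            c += (gap - 1.595) ** 2
            c += 0.5 * (_angle(lo["C3'"], lo["O3'"], up["P"])
                        - np.deg2rad(119.7)) ** 2
            c += 0.5 * (_angle(lo["O3'"], up["P"], up["O5'"])
                        - np.deg2rad(104.0)) ** 2
            lo2 = {a: FLIP @ v for a, v in templates[partners[x]].items()}
            up2 = {a: Rz @ (FLIP @ v) + t
                   for a, v in templates[partners[y]].items()}
            gap2 = np.linalg.norm(up2["O3'"] - lo2["P"])
            c += (gap2 - 1.595) ** 2
            c += 0.5 * (_angle(up2["C3'"], up2["O3'"], lo2["P"])
                        - np.deg2rad(119.7)) ** 2
            A = np.array(list(lo.values()))
            B = np.array(list(up.values()))
            d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
            close = d[d < 1.7]
            c += 5.0 * ((1.7 - close) ** 2).sum()
            # cross-strand clashes: same step and both diagonals
            B2 = np.array(list(lo2.values()))
            d2 = np.linalg.norm(A[:, None, :] - B2[None, :, :], axis=-1)
            close2 = d2[d2 < 1.7]
            c += 5.0 * ((1.7 - close2) ** 2).sum()
            B3 = np.array(list(up2.values()))
            d3 = np.linalg.norm(A[:, None, :] - B3[None, :, :], axis=-1)
            close3 = d3[d3 < 2.1]
            c += 5.0 * ((2.1 - close3) ** 2).sum()
            A2 = np.array(list(lo2.values()))
            B4 = np.array(list(up.values()))
            d4 = np.linalg.norm(A2[:, None, :] - B4[None, :, :], axis=-1)
            close4 = d4[d4 < 2.1]
            c += 5.0 * ((2.1 - close4) ** 2).sum()
    return c


def tune_backbone(bases_pf, unit0, partners, res_names, geom):
    keys = ["chi", "gamma", "beta", "delta"]

    def build(x):
        dx = x[0]
        angles = dict(zip(keys, x[1:]))
        unit = apply_unit_torsions(unit0, angles)
        return ({r: attach(bases_pf[r], r, unit, geom) for r in res_names},
                dx, unit)

    # all residues share one backbone unit, so one purine + one pyrimidine
    # cover every distinct linkage geometry
    cost_set = [r for r in res_names
                if chem.RESIDUE_CODES[r][1] in ("A", "U", "T")][:2]

    def cost(x):
        tpl, dx, _ = build(x)
        return continuity_cost(tpl, partners, cost_set, dx)

    best = None
    rng = np.random.default_rng(20240901)
    starts = [np.array([dx0, chi0, 0.0, 0.0, 0.0])
              for dx0 in (4.4, -4.4, -6.0, 6.0)
              for chi0 in np.deg2rad([0.0, 90.0, 180.0, -90.0])]
    starts += [np.concatenate([[rng.uniform(-7, 7)],
                               rng.uniform(-np.pi, np.pi, 4)])
               for _ in range(12)]
    for x0 in starts:
        res = minimize(cost, x0, method="Powell",
                       options={"maxiter": 4000, "xtol": 1e-8,
                                "ftol": 1e-10})
        if best is None or res.fun < best.fun:
            best = res
    tpl, dx, unit = build(best.x)
    print(f"  axis displacement {dx:.3f} A, residual {best.fun:.4f}")
    Rz, t = helix_transform(1, dx)
    for r in res_names:
        up = {a: Rz @ v + t for a, v in tpl[r].items()}
        gap = np.linalg.norm(tpl[r]["O3'"] - up["P"])
        print(f"    {r}->{r} O3'-P gap {gap:.3f}")
    return tpl, dx



# ---------------------------------------------------------------------------
# backbone tuning: shared sugar unit + helix placement
# ---------------------------------------------------------------------------

from scipy.optimize import least_squares  # noqa: E402


def _unit_internals(unit, resname):
    """Bond, angle and improper targets of the sugar unit (local frame)."""
    names = [a for a in unit if a != "C1'"]
    pos = {a: unit[a] for a in unit}
    pos["C1'"] = np.zeros(3)

    bonds = []
    all_bonds = chem.residue_bonds(resname, has_5p_phosphate=True,
                                   is_3p_terminal=True, is_5p_terminal=False)
    all_bonds.append(("O5'", "H5T"))
    base_set = set(chem.BASE_ATOMS[chem.RESIDUE_CODES[resname][1]])
    for a1, a2 in all_bonds:
        if a1 in base_set or a2 in base_set:
            continue
        if a1 in pos and a2 in pos:
            bonds.append((a1, a2, float(np.linalg.norm(pos[a1] - pos[a2]))))

    neigh = {}
    for a1, a2, _ in bonds:
        neigh.setdefault(a1, []).append(a2)
        neigh.setdefault(a2, []).append(a1)
    neigh.setdefault("C1'", []).append("NGLY")
    pos["NGLY"] = np.array([1.48, 0.0, 0.0])

    angles = []
    for b, nbrs in neigh.items():
        for i in range(len(nbrs)):
            for j in range(i + 1, len(nbrs)):
                a, c = nbrs[i], nbrs[j]
                v1, v2 = pos[a] - pos[b], pos[c] - pos[b]
                ang = np.arccos(np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                    -1, 1))
                angles.append((a, b, c, float(ang)))

    imps = []
    for centre, (a, b, c) in [("C1'", ("NGLY", "O4'", "C2'")),
                              ("C2'", ("C1'", "C3'", "H2'")),
                              ("C3'", ("C2'", "C4'", "O3'")),
                              ("C4'", ("C3'", "O4'", "C5'"))]:
        if all(x in pos for x in (centre, a, b, c)):
            imps.append((centre, a, b, c,
                         _dihe(pos[a], pos[centre], pos[b], pos[c])))
    return names, bonds, angles, imps


def _dihe(p1, p2, p3, p4):
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m1 @ n2, n1 @ n2))


def _rot_x(eta):
    c, s = np.cos(eta), np.sin(eta)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def tune_unit(bases_pf, unit0, res_names, geom, partners):
    """Find the shared sugar conformation, helix-axis displacement and
    pair inclination that close the backbone on both strands without
    steric clashes.  Phase 1 searches rigid exocyclic torsions plus the
    helix placement (7 parameters, Powell); phase 2 lets every sugar
    atom flex under bond/angle/chirality restraints (least squares)."""
    ref = res_names[0]  # a purine
    names, bonds, angles, imps = _unit_internals(unit0, ref)
    origin, R = canonical_attach_frame(geom[0], 0.5 * (geom[1] + geom[2]))
    bases_all = {r: {a: v for a, v in bases_pf[r].items() if a != "C1'"}
                 for r in res_names}

    def residuals(loc, dx, dy, eta):
        r = []
        for a1, a2, d0 in bonds:
            r.append(10.0 * (np.linalg.norm(loc[a1] - loc[a2]) - d0))
        for a, b, c, t0 in angles:
            v1, v2 = loc[a] - loc[b], loc[c] - loc[b]
            ang = np.arccos(np.clip(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
            r.append(2.0 * (ang - t0))
        for centre, a, b, c, t0 in imps:
            d = _dihe(loc[a], loc[centre], loc[b], loc[c])
            r.append(float(np.arctan2(np.sin(d - t0), np.cos(d - t0))))
        Re = _rot_x(eta)
        pf = {a: Re @ (origin + R.T @ v) for a, v in loc.items()
              if a != "NGLY"}
        Rz, t = helix_transform(1, dx, dy)
        tpl = {rr: {**{a: Re @ v for a, v in bases_all[rr].items()}, **pf}
               for rr in res_names}
        # backbone closure and linkage angles (shared unit: the reference
        # purine covers strand 1, its partner covers strand 2)
        t1 = tpl[ref]
        up1 = {a: Rz @ v + t for a, v in t1.items()}
        r.append(4.0 * (np.linalg.norm(t1["O3'"] - up1["P"]) - 1.595))
        t2 = tpl[partners[ref]]
        lo2 = {a: FLIP @ v for a, v in t2.items()}
        up2 = {a: Rz @ (FLIP @ v) + t for a, v in t2.items()}
        r.append(4.0 * (np.linalg.norm(up2["O3'"] - lo2["P"]) - 1.595))
        r.append(1.0 * (_angle(t1["C3'"], t1["O3'"], up1["P"])
                        - np.deg2rad(119.7)))
        r.append(1.0 * (_angle(t1["O3'"], up1["P"], up1["O5'"])
                        - np.deg2rad(104.0)))
        r.append(1.0 * (_angle(up2["C3'"], up2["O3'"], lo2["P"])
                        - np.deg2rad(119.7)))
        r.append(1.0 * (_angle(up2["O3'"], lo2["P"], lo2["O5'"])
                        - np.deg2rad(104.0)))
        r.append(1.0 * (_angle(t1["O3'"], up1["P"], up1["OP1"])
                        - np.deg2rad(108.1)))
        r.append(1.0 * (_angle(t1["O3'"], up1["P"], up1["OP2"])
                        - np.deg2rad(108.3)))
        r.append(1.0 * (_angle(up2["O3'"], lo2["P"], lo2["OP1"])
                        - np.deg2rad(108.1)))
        r.append(1.0 * (_angle(up2["O3'"], lo2["P"], lo2["OP2"])
                        - np.deg2rad(108.3)))
        r.append(0.8 * max(0.0, np.hypot(dx, dy) - 5.5))
        # clash guards as blocks of concatenated distance matrices
        blocks = []
        names_by_res = {}
        k0 = 0
        S1_list, S2_list = [], []
        for rr in res_names:
            d1 = tpl[rr]
            d2 = tpl[partners[rr]]
            S1_list.append(np.array(list(d1.values())))
            S2_list.append((FLIP @ np.array(list(d2.values())).T).T)
            names_by_res[rr] = (k0, list(d1), list(d2))
            k0 += len(d1)
        S1 = np.concatenate(S1_list)
        S2 = np.concatenate(S2_list)
        U1 = (Rz @ S1.T).T + t
        U2 = (Rz @ S2.T).T + t

        def cd(A, B):
            return np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)

        D_stack = cd(S1, U1)
        D_diag1 = cd(S1, U2)
        D_diag2 = cd(S2, U1)
        D_same = cd(S1, S2)
        D_s2 = cd(S2, U2)
        for xr in res_names:
            a0, names_x, _ = names_by_res[xr]
            io3 = a0 + names_x.index("O3'")
            for yr in res_names:
                b0, names_y, _ = names_by_res[yr]
                D_stack[io3, b0 + names_y.index("P")] = 1.8
        # mask strand-2 bonded O3'(upper)-P(lower) contacts
        for xr in res_names:
            a0, _, namespx = names_by_res[xr]
            for yr in res_names:
                b0, _, namespy = names_by_res[yr]
                D_s2[a0 + namespx.index("P"),
                     b0 + namespy.index("O3'")] = 1.8
                D_s2[b0 + namespy.index("O3'"),
                     a0 + namespx.index("P")] = 1.8
        r.append(3.0 * np.sqrt((np.clip(1.8 - D_stack, 0, None) ** 2).sum()))
        r.append(3.0 * np.sqrt((np.clip(1.8 - D_s2.T, 0, None) ** 2).sum()))
        r.append(3.0 * np.sqrt((np.clip(2.1 - D_diag1, 0, None) ** 2).sum()))
        r.append(3.0 * np.sqrt((np.clip(2.1 - D_diag2, 0, None) ** 2).sum()))
        same = 0.0
        for xr in res_names:
            a0, names_x, _ = names_by_res[xr]
            blk = D_same[a0:a0 + len(names_x), a0:a0 + len(names_x)]
            same += (np.clip(1.7 - blk, 0, None) ** 2).sum()
        r.append(3.0 * np.sqrt(same))
        return np.array(r)

    # ----- phase 1: rigid torsions + placement ---------------------------
    def build_loc(tors):
        u = apply_unit_torsions(unit0, dict(zip(
            ("chi", "gamma", "beta", "delta"), tors)))
        loc = {a: u[a] for a in u}
        loc["C1'"] = np.zeros(3)
        loc["NGLY"] = np.array([1.48, 0.0, 0.0])
        return loc

    def cost1(x):
        dx, dy, eta = x[:3]
        return (residuals(build_loc(x[3:]), dx, dy, eta) ** 2).sum()

    best = None
    for dx0 in (-4.4,):
        for eta0 in np.deg2rad([0.0, 19.0, -19.0]):
            for chi0 in np.deg2rad([0.0, 120.0]):
                x0 = np.array([dx0, 0.0, eta0, chi0, 0.0, 0.0, 0.0])
                res = minimize(cost1, x0, method="Powell",
                               options={"maxfev": 1800, "xtol": 1e-6,
                                        "ftol": 1e-8})
                if best is None or res.fun < best.fun:
                    best = res
    dx, dy, eta = best.x[:3]
    loc1 = build_loc(best.x[3:])
    print(f"  phase 1: dx {dx:.2f} dy {dy:.2f} incl {np.rad2deg(eta):.1f} "
          f"deg, cost {best.fun:.3f}")

    # ----- phase 2: all-atom flex ----------------------------------------
    def pack(loc, dx, dy, eta):
        return np.concatenate([[dx, dy, eta]]
                              + [loc[a] for a in names])

    def unpack(x):
        loc = {"C1'": np.zeros(3), "NGLY": np.array([1.48, 0.0, 0.0])}
        for i, a in enumerate(names):
            loc[a] = x[3 + 3 * i: 6 + 3 * i]
        return loc, x[0], x[1], x[2]

    def res2(x):
        loc, dx, dy, eta = unpack(x)
        return residuals(loc, dx, dy, eta)

    sol = least_squares(res2, pack(loc1, dx, dy, eta), method="trf",
                        max_nfev=260, diff_step=1e-4)
    loc, dx, dy, eta = unpack(sol.x)
    print(f"  phase 2: dx {dx:.2f} dy {dy:.2f} incl {np.rad2deg(eta):.1f} "
          f"deg, cost {sol.cost:.4f}")
    Re = _rot_x(eta)
    pf = {a: Re @ (origin + R.T @ v) for a, v in loc.items() if a != "NGLY"}
    templates = {}
    for rr in res_names:
        templates[rr] = {**{a: Re @ v for a, v in bases_all[rr].items()},
                         "C1'": pf["C1'"], **pf}
    return templates, (dx, dy)


def _report_gaps(tpl, dxy, res_names):
    Rz, t = helix_transform(1, *dxy)
    for r in res_names:
        up = {a: Rz @ v + t for a, v in tpl[r].items()}
        gap = np.linalg.norm(tpl[r]["O3'"] - up["P"])
        print(f"    {r}->{r} O3'-P gap {gap:.3f}")


def bond_reference(templates):
    groups = {}
    for rname, coords in templates.items():
        _, base = chem.RESIDUE_CODES[rname]
        cls = "pur" if base in chem.PURINES else "pyr"
        bonds = chem.residue_bonds(rname, has_5p_phosphate=True,
                                   is_3p_terminal=True, is_5p_terminal=False)
        for a1, a2 in bonds:
            if a1 not in coords or a2 not in coords:
                continue
            d = float(np.linalg.norm(coords[a1] - coords[a2]))
            in_base = (a1 in chem.BASE_ATOMS[base]
                       and a2 in chem.BASE_ATOMS[base])
            key = (cls if in_base else "bb", a1, a2)
            groups.setdefault(key, []).append((rname, d))
    refs = {}
    for key, vals in sorted(groups.items()):
        ds = [d for _, d in vals]
        if max(ds) - min(ds) <= 0.015:
            refs[key] = float(np.mean(ds))
        else:
            for rname, d in vals:
                refs[(rname, key[1], key[2])] = d
    return refs


def main():
    out_path = (Path(__file__).resolve().parents[1]
                / "src/hairpinforge/data/templates_v1.txt")
    raw = {r: load_ccd_residue(r) for r in RNA_RES + DNA_RES}
    partners = {"A": "U", "U": "A", "G": "C", "C": "G",
                "DA": "DT", "DT": "DA", "DG": "DC", "DC": "DG", "DU": "DA"}

    print("pair placement (RNA):")
    geom_rna, sp_r, sy_r = choose_pair_geometry(raw, PAIRS[:2])
    print("pair placement (DNA):")
    geom_dna, sp_d, sy_d = choose_pair_geometry(raw, PAIRS[2:])
    bases_pf = {}
    for r in RNA_RES + DNA_RES:
        base = chem.RESIDUE_CODES[r][1]
        is_pur = base in chem.PURINES
        geom, s_pur, s_pyr = ((geom_rna, sp_r, sy_r) if r in RNA_RES
                              else (geom_dna, sp_d, sy_d))
        lam_r = geom[1] if is_pur else geom[2]
        prop_r = geom[3] if is_pur else geom[4]
        bases_pf[r] = place_base_on_anchors(
            r, raw[r], geom[0], lam_r, prop_r, _class_sign(r, s_pur, s_pyr))

    print("backbone tuning (RNA):")
    rna_tpl, dxy_rna = tune_unit(bases_pf, sugar_unit("A", raw["A"]),
                                 RNA_RES, geom_rna, partners)
    _report_gaps(rna_tpl, dxy_rna, RNA_RES)
    print("backbone tuning (DNA):")
    dna_tpl, dxy_dna = tune_unit(bases_pf, sugar_unit("DA", raw["DA"]),
                                 DNA_RES, geom_dna, partners)
    _report_gaps(dna_tpl, dxy_dna, DNA_RES)

    templates = {**rna_tpl, **dna_tpl}
    refs = bond_reference(templates)

    with open(out_path, "w") as fh:
        fh.write("# hairpinforge nucleotide template library, version 1\n")
        fh.write("# coordinates in angstroms, pair frame "
                 "(origin at C1'-C1' midpoint)\n")
        fh.write("[helix]\n")
        fh.write(f"rise {RISE}\ntwist {TWIST}\n")
        fh.write(f"displacement_rna {dxy_rna[0]:.4f} {dxy_rna[1]:.4f}\n")
        fh.write(f"displacement_dna {dxy_dna[0]:.4f} {dxy_dna[1]:.4f}\n")
        fh.write("inclination 0.0\n\n")
        for rname in RNA_RES + DNA_RES:
            fh.write(f"[residue {rname}]\n")
            seen = set()
            for a, v in templates[rname].items():
                if a in seen:
                    continue
                seen.add(a)
                el = chem.element_of(a)
                fh.write(f"{a:5s} {el} {v[0]:9.4f} {v[1]:9.4f} "
                         f"{v[2]:9.4f}\n")
            fh.write("\n")
        fh.write("[bond_reference]\n")
        for (cls, a1, a2), d in sorted(refs.items()):
            fh.write(f"{cls} {a1} {a2} {d:.4f}\n")
    print(f"wrote {out_path}")


if __name__ == "__main__":
    main()
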