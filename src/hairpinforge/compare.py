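"""Structural comparison: Kabsch superposition and backbone RMSD.

The validation stage of the pipeline: each predicted model is rigidly
superposed onto its reference (proper rotations only) and the
root-mean-square deviation of the sugar-phosphate backbone is reported,
optionally as a table over many structure pairs sorted by chain length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import chem
from .errors import CorrespondenceError, DegenerateInputError
from .nucio import Model3D

#: sugar-phosphate backbone atom selection (bases excluded); the
#: 5'-terminal residue contributes no phosphate group
BACKBONE_ATOMS = ["P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
                  "C1'", "C2'", "O4'"]
P_ONLY_ATOMS = ["P"]


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal proper rigid motion and the RMSD it attains.

    Applying ``rotation @ x + translation`` to each mobile point
    superposes the mobile set onto the reference.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return (self.rotation @ np.asarray(xyz).T).T + self.translation


def kabsch_superpose(mobile, reference) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch), reflections excluded.

    Both inputs are (n, 3) arrays with matched rows, n >= 3.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise CorrespondenceError(
            f"point counts differ: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3:
        raise CorrespondenceError("point sets must be (n, 3) arrays")
    if len(P) < 3:
        raise DegenerateInputError(
            f"need at least 3 points, got {len(P)}")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def _backbone_coords(model: Model3D, selection: str):
    if selection == "all":
        return model.coords(), [a.name for r in model.residues
                                for a in r.atoms]
    names = P_ONLY_ATOMS if selection == "p-only" else BACKBONE_ATOMS
    out = []
    labels = []
    for res in model.residues:
        for nm in names:
            if res.has_atom(nm):
                out.append(res.atom(nm).xyz)
                labels.append((res.index, nm))
    return np.array(out), labels


def backbone_rmsd(model_a: Model3D, model_b: Model3D,
                  selection: str = "backbone") -> float:
    """Sugar-phosphate backbone RMSD after optimal superposition.

    Residues are matched by position; the chains must have the same
    length and sequence (U and T count as equivalent).  ``selection``
    may be "backbone" (default), "p-only" or "all".
    """
    if len(model_a.residues) != len(model_b.residues):
        raise CorrespondenceError(
            f"residue counts differ: {len(model_a.residues)} vs "
            f"{len(model_b.residues)}")
    sa = model_a.sequence_letters().replace("U", "T")
    sb = model_b.sequence_letters().replace("U", "T")
    if sa != sb:
        raise CorrespondenceError(f"sequences differ: {sa} vs {sb}")
    xa, la = _backbone_coords(model_a, selection)
    xb, lb = _backbone_coords(model_b, selection)
    if selection == "all" and len(xa) != len(xb):
        raise CorrespondenceError(
            f"atom counts differ: {len(xa)} vs {len(xb)}")
    if selection != "all":
        # intersect on labels in case one model lacks e.g. OP1/OP2
        common = [i for i, lab in enumerate(la) if lab in set(lb)]
        commap = {lab: i for i, lab in enumerate(lb)}
        xa = xa[common]
        xb = xb[[commap[la[i]] for i in common]]
    return kabsch_superpose(xa, xb).rmsd


def rmsd_report(pairs, selection: str = "backbone") -> pd.DataFrame:
    """RMSD table over (label, predicted, reference) pairs.

    One row per pair, sorted by chain length, plus a final summary row
    holding the mean RMSD.
    """
    rows = []
    for label, predicted, reference in pairs:
        try:
            r = backbone_rmsd(predicted, reference, selection)
        except CorrespondenceError as exc:
            raise CorrespondenceError(f"{label}: {exc}") from exc
        rows.append({"label": label,
                     "chain_length": len(predicted.residues),
                     "rmsd": r})
    df = pd.DataFrame(rows).sort_values(
        ["chain_length", "label"]).reset_index(drop=True)
    mean_row = pd.DataFrame([{"label": "mean",
                              "chain_length": pd.NA,
                              "rmsd": df["rmsd"].mean()}])
    return pd.concat([df, mean_row], ignore_index=True)
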