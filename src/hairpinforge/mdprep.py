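"""Simulation-system preparation: solvation box, waters, counterions.

Prepares what an explicit-solvent MD run needs as *inputs*: a rectangular
water box sized by a padding rule (25 A of water beyond the solute extent
in each direction by default), neutralising sodium ions (one per backbone
phosphate), and the bookkeeping summary row (box lengths, atom counts,
ion count).  Running dynamics itself is out of scope; waters are rigid
3-site molecules used for counting and coordinates only.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, GeometryError
from .nucio import AtomRecord, Model3D, NucSequence, Residue3D
from .transmute import formal_charge

WATER_SPACING = 2.8     # lattice spacing, A (~bulk water density)
SOLUTE_CLEARANCE = 2.4  # minimum water-solute distance, A
ION_CLEARANCE = 5.0     # minimum ion-solute distance, A
JITTER = 0.25           # lattice jitter amplitude, A
_OH = 0.9572            # TIP3P-like geometry
_HOH_ANGLE = math.radians(104.52)


@dataclasses.dataclass
class SimSystemSpec:
    """One Table-style summary row for a prepared system."""

    box: tuple              # (Lx, Ly, Lz) in A
    ion_type: str
    ion_count: int
    solute_atoms: int
    water_count: int
    total_atoms: int

    def __post_init__(self):
        expected = self.solute_atoms + 3 * self.water_count + self.ion_count
        if self.total_atoms != expected:
            raise GeometryError(
                f"atom accounting broken: total {self.total_atoms} != "
                f"{expected}")

    def to_json(self) -> str:
        return json.dumps({
            "Lx": self.box[0], "Ly": self.box[1], "Lz": self.box[2],
            "ion_type": self.ion_type, "ion_count": self.ion_count,
            "solute_atoms": self.solute_atoms,
            "water_count": self.water_count,
            "total_atoms": self.total_atoms,
        }, indent=2)


def box_dimensions(model: Model3D, padding: float = 25.0) -> tuple:
    """Box lengths: per axis, solute extent plus twice the padding,
    rounded up to whole angstroms."""
    if model.n_atoms == 0:
        raise DegenerateInputError("cannot size a box around an empty model")
    xyz = model.coords()
    extent = xyz.max(axis=0) - xyz.min(axis=0)
    return tuple(int(math.ceil(e + 2.0 * padding)) for e in extent)


def neutralizing_ions(model: Model3D) -> tuple:
    """Sodium counterions required to neutralise the chain (one per
    internucleotide phosphate under 5'-OH/3'-OH terminal chemistry)."""
    n = len(model.residues)
    if n == 0:
        return ("Na+", 0)
    seq = NucSequence("model", model.sequence_letters(), model.chemistry)
    charge = formal_charge(seq)
    if charge >= 0:
        warnings.warn("solute has no net negative charge; no ions added")
        return ("Na+", 0)
    return ("Na+", -charge)


def solvate(model: Model3D, box: tuple, seed: int = 0) -> tuple:
    """Fill the box with water on a jittered cubic lattice and neutralise.

    Waters sit on a ``WATER_SPACING`` lattice (seeded jitter), excluding
    sites within ``SOLUTE_CLEARANCE`` of any solute atom; neutralising
    ions replace randomly chosen waters at least ``ION_CLEARANCE`` from
    the solute.  Returns (SimSystemSpec, solvated Model3D-like water/ion
    lists) — deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    xyz = model.coords() if model.n_atoms else np.zeros((0, 3))
    box = tuple(float(b) for b in box)
    if model.n_atoms:
        extent = xyz.max(axis=0) - xyz.min(axis=0)
        if any(e > b for e, b in zip(extent, box)):
            raise GeometryError(
                f"box {box} does not enclose solute extent {tuple(extent)}")
        centre = 0.5 * (xyz.max(axis=0) + xyz.min(axis=0))
    else:
        centre = np.zeros(3)

    counts = [max(1, int(b // WATER_SPACING)) for b in box]
    axes = [centre[d] - 0.5 * (counts[d] - 1) * WATER_SPACING
            + WATER_SPACING * np.arange(counts[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    sites = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    sites = sites + rng.uniform(-JITTER, JITTER, size=sites.shape)

    if model.n_atoms:
        tree = cKDTree(xyz)
        dist, _ = tree.query(sites, k=1)
    else:
        dist = np.full(len(sites), np.inf)
    keep = dist >= SOLUTE_CLEARANCE
    waters = sites[keep]
    wdist = dist[keep]

    ion_type, n_ions = neutralizing_ions(model)
    eligible = np.flatnonzero(wdist >= ION_CLEARANCE)
    if len(eligible) < n_ions:
        raise GeometryError(
            f"only {len(eligible)} waters eligible for {n_ions} ions")
    ion_rows = rng.choice(eligible, size=n_ions, replace=False) \
        if n_ions else np.array([], dtype=int)
    ion_positions = waters[ion_rows]
    keep_w = np.ones(len(waters), dtype=bool)
    keep_w[ion_rows] = False
    waters = waters[keep_w]

    spec = SimSystemSpec(
        box=tuple(int(round(b)) for b in box),
        ion_type=ion_type,
        ion_count=int(n_ions),
        solute_atoms=model.n_atoms,
        water_count=int(len(waters)),
        total_atoms=model.n_atoms + 3 * len(waters) + int(n_ions),
    )
    solvated = _assemble_system(model, waters, ion_positions, rng)
    return spec, solvated


def lattice_site_count(box: tuple) -> int:
    """Number of lattice sites an empty box of these lengths holds."""
    return int(np.prod([max(1, int(b // WATER_SPACING)) for b in box]))


def _assemble_system(model: Model3D, waters, ions, rng) -> Model3D:
    """Solute + HOH + NA residues in one coordinate model."""
    residues = [Residue3D(r.name, r.index,
                          [AtomRecord(a.name, a.element, a.xyz.copy())
                           for a in r.atoms])
                for r in model.residues]
    idx = (residues[-1].index if residues else 0)
    for o in waters:
        idx += 1
        # random but seeded rigid water orientation
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        h1 = o + _OH * u
        h2 = o + _OH * (math.cos(_HOH_ANGLE) * u
                        + math.sin(_HOH_ANGLE) * v)
        residues.append(Residue3D("HOH", idx, [
            AtomRecord("O", "O", o),
            AtomRecord("H1", "H", h1),
            AtomRecord("H2", "H", h2),
        ]))
    for p in ions:
        idx += 1
        residues.append(Residue3D("NA", idx,
                                  [AtomRecord("NA", "NA", p)]))
    return Model3D(model.chain_id, residues, model.chemistry)
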