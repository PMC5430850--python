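# Methods

This note documents the models, parameters and design choices behind
`hairpinforge`, in the order the pipeline runs, together with what the
synthetic test data does and does not establish about real molecules.

## 1. Secondary-structure prediction (`fold`)

### Model

Free energies of nested Watson–Crick structures are computed by loop
decomposition at 37 °C and 1 M Na⁺ (no salt correction term). The
shipped table set (`data/dna_dg37_v1.txt`, version 1) contains:

- the ten unique WC nearest-neighbor stack ΔG°₃₇ values of the unified
  DNA parameter set (−1.00 … −2.24 kcal/mol);
- hairpin- and bulge-loop size penalties from the 2004 DNA compilation
  and internal-loop size penalties from the mfold-3.0 DNA line, with
  Jacobson–Stockmayer extrapolation ΔG(n) = ΔG(30) + 1.50·ln(n/30)
  beyond the tables (and below their lower edge, for 1×1/1×2 internal
  loops);
- first-mismatch (terminal-stack) bonuses for hairpin loops of size ≥ 4
  and for both closures of internal loops, from the same compilation
  (one table serves both contexts, as in the source data);
- a −1.0 kcal/mol bonus for GNA-class triloops (loop pattern G,N,A),
  reflecting the documented extra stability of GNA DNA triloops;
  size-3 loops receive no first-mismatch term;
- single-base bulges keep the flanking stack; internal-loop asymmetry
  costs 0.4·|n₁−n₂| capped at 3.0;
- multiloops: affine 3.0 + 0.2·branches + 0.2·unpaired;
- no dangling-end contributions and a 0.0 helix-end A:T penalty (see
  "Parameter provenance" below);
- minimum hairpin loop 3; isolated pairs permitted; no wobble pairs;
  a U inside a DNA chain is scored with thymine parameters.

The MFE recursion is the standard O(n⁴) dynamic program (interior loops
capped at 30 unpaired bases) with matrices for closed structures,
multiloop segments with ≥ 1 and ≥ 2 branches, and the exterior;
traceback ties break toward the smallest 5′ index, then the smallest 3′
index. `fold_mfe(closed=True)` returns the best structure containing at
least one pair even when its energy is positive — the behaviour of a
folding server, which always reports a fold — while the default
minimises over all structures including the open chain (which scores
exactly 0). Suboptimal folds are enumerated by duplicate-free
Wuchty-style backtracking inside the window MFE + 5 %·|MFE|, widened to
an absolute 0.5 kcal/mol floor when the MFE is non-negative (a
percentage of ≈ 0 is degenerate).

### Parameter provenance

No single published DNA table set reproduces both the reference folding
energies and the reference fold topologies that this package is
validated against; the shipped file is therefore a documented hybrid of
published values, chosen once as follows. The stack sums plus plain
loop penalties reproduce two reference hairpin energies essentially
exactly, which fixes the "no dangles, no A:T end penalty, no triloop
mismatch" convention. The hairpin/bulge tables and mismatch bonuses of
the 2004 DNA compilation then land the remaining hairpin energies
inside ±0.3 kcal/mol, with the GNA-triloop bonus accounting for the one
GNA-loop case. Finally, the smaller internal-loop penalties of the
mfold-3.0 DNA line are required for a two-stem fold with a 3+3 internal
loop to beat its inner-hairpin-only competitor, which matches the
reference topology of the longest validation sequence. The evaluator
(`evaluate_energy`) is the single scorer used by the DP, the suboptimal
enumeration and the brute-force test oracle, so internal consistency is
exact by construction.

### Limitations

The exact table version used by the original folding server is not
determinable; printed energies are matched within ±0.3 kcal/mol, two of
them exactly. No partition function, no pseudoknots, no temperature
scans, no salt correction.

## 2. G-quadruplex screening (`screen`)

A QGRS match is four G-runs of exactly x ≥ 2 consecutive guanines,
separated by loops y₁,y₂,y₃ ≥ 0 with at most one empty loop (two empty
loops would merge runs), spanning at most 30 nt. The zero/non-zero
decision is contract-level and checked against a brute-force scanner.
The positive magnitude follows the published scoring principles —
longer tetrads, shorter and more even loops score higher — via
score = 10·(x−2) + max(0, 28 − Σyᵢ) − (max yᵢ − min yᵢ), clamped at a
minimum of 1, with the coefficients in `data/qgrs_score_v1.txt`
calibrated so the thrombin-binding aptamer scores 20. Magnitudes for
other sequences follow the principles but are not expected to equal any
particular web-tool output; the bundled candidate table carries its
printed scores, and screening consumes only the > 0 decision.

Candidate exclusion proceeds in the published order: ligand-complexed
entries first, then (as one structural-review stage) every entry whose
curated motif class is not "hairpin" or whose G-score is positive. The
bundled table keeps all 97 printed rows, including the handful of
entries printed twice with differing annotation (flagged
`duplicate_conflict`) and one row whose printed length disagrees with
its printed sequence (the loader trusts the sequence and flags
`length_conflict`). Motif classes are curated data, not inferred from
coordinates.

## 3. Template library and 3D construction (`build3d`)

### Templates

`data/templates_v1.txt` holds one all-atom template per residue type
(RNA A/C/G/U and DNA DA/DC/DG/DT/DU), expressed in a Watson–Crick pair
frame: origin midway between the C1′ atoms of an ideal pair, y along
C1′–C1′, z along the base normal. The strand-2 partner of any template
is its 180° rotation about x (the pair pseudo-dyad), so pairing is
consistent for all four bases by construction. The generator
(`scripts/make_templates.py`) starts from chemical-component-dictionary
ideal residue coordinates, places each base rigidly on canonical
anchors (C1′ at ±5.2 Å, glycosidic bond at λ ≈ 55°, per-class propeller
fitted so every donor–acceptor contact lands at hydrogen-bond
distance), attaches one shared sugar-phosphate unit per chemistry
through a common glycosidic frame, and then lets that unit flex —
bonds, angles and chiral impropers restrained, pucker free — until
consecutive helix steps (rise 2.81 Å, twist 32.7°, fitted axis
displacement and pair inclination) leave an exactly bondable
O3′(i)–P(i+1) gap of 1.60 Å on both strands with no steric clashes.
Validation on load checks every bond against a pooled reference table
(±0.02 Å) and every WC contact against 2.75–3.05 Å; the RNA pairs used
by the pipeline's intermediate all fall in 2.83–2.97 Å, the DNA pairs
(whose dictionary base geometries are slightly less accommodating under
a rigid dyad-symmetric fit) in 2.80–3.04 Å.

### Builder

Stems are placed by the helix screw operator; every paired residue is
an exact template copy, so WC geometry and the configured rise/twist
are reproduced by construction. Hairpin loops and connectors are placed
on circular arcs between their anchor C1′ atoms (5.9 Å spacing, the
single-stranded C1′–C1′ distance), each residue oriented by a weighted
rigid fit of its P/C1′/O3′/N(glycosidic) onto chain-growing targets
that honour the linkage bond length and the C3′–O3′–P angle, followed
by a discrete spin search about the local chain tangent and a
deterministic clash-relief pass (minimum non-bonded distance 1.5 Å).
Loop bases point outward from the loop centre — inward-pointing bases
crowd the loop interior and trap the subsequent refinement. Multiloop
branches beyond the first are fanned out with fixed offsets; multiloop
3D geometry is a known weak point (the validation panel contains none).
The intermediate carries RNA chemistry with T rendered as U — the
A-form RNA modelling route this pipeline follows before the DNA
conversion; the helix parameters live in the template file and can be
overridden by loading a different library.

The builder's output is deterministic but leaves O3′–P junction gaps of
up to a few Å at loop boundaries; closing them is the refinement
stage's job: model building is always followed by regularisation in
this pipeline.

## 4. Transmutation (`transmute`)

Terminal chemistry is 5′-hydroxyl / 3′-hydroxyl: the 5′-terminal
residue has no phosphate group (−2 atoms net, counting its H5T) and the
3′-terminal residue gains H3T (+1). This convention reproduces four of
the five published per-system atom totals exactly (349/411/474/728);
the published 569 for the uracil-containing 18-mer is one more than
this model yields (568) — the discrepancy is recorded, not guessed
around, and that system is excluded from exact-count assertions.

Hydrogens are placed by rigidly superposing the template's local
environment of each parent heavy atom onto the model and copying the
template hydrogen through that transform — canonical bond lengths and
angles by construction, idempotent on protonated models. Uracil
methylation removes H5 and adds C7 (1.50 Å along the old C5–H5
direction) with three hydrogens at 1.09 Å, one anti to C4 and the
others staggered. The sugar swap removes O2′/HO2′ and adds H2′′ along
the vacated direction; residues are renamed A→DA, C→DC, G→DG,
U(methylated)→DT, with plain DU available for unmethylated
deoxyuridine. Formal charge is −(length − 1), one per internucleotide
phosphate; sodium counts follow.

## 5. Restrained refinement (`refine`)

The objective is a weighted sum of squared violations: bond lengths
(1.0 Å⁻²), bond angles (0.02 deg⁻²), base-plane flatness (1.0 Å⁻², sum
of squared distances to the best-fit plane, exact envelope gradient),
intra-residue backbone torsions β/γ/δ plus glycosidic χ (0.01 deg⁻²),
and a quartic non-bonded repulsion 10·(2.0 − d)⁴ below 2.0 Å excluding
1-2 and 1-3 pairs. Weights are configuration, not code. Torsions across
the phosphodiester linkage are deliberately unrestrained: while a
linkage is still open during regularisation they are geometrically
degenerate (near-collinear atoms) and poison the gradient; the linkage
bond plus its flanking angles hold that geometry instead. All bond and
angle targets come from the template geometry; the linkage targets are
measured from the template helix itself (1.60 Å, 118.5°/106.0° and
108°-ish OP flanks), so a built stem is an exact joint minimum of the
objective.

Two optimisers share the contract (monotone trace, stop on iteration
budget or objective-change tolerance): the default Barzilai–Borwein
gradient descent with Armijo backtracking, and a damped Gauss–Newton
variant (dense normal equations; efficient at the long-range backbone
closure the builder leaves behind). The gradient is analytic and
singularity-guarded (straight angles, collinear torsion atoms) and is
verified against finite differences in the tests. The pipeline's
stage-2/stage-4 iteration budgets (100 / 10 000 by default) set the
gradient-descent leg length.

`regularize` is the orchestration used by the pipeline and fixtures:
alternating Gauss–Newton and gradient-descent legs with a
hydrogen-reset between rounds (a hydrogen wedged in a repulsive pocket
cannot escape by gradient flow; re-placing all hydrogens at template
geometry is deterministic and cheap), optionally followed by seeded
perturb-and-reminimise cycles. Those annealing cycles matter for
reference models: the builder's output sits in a shallow local minimum,
and a σ = 0.3 Å perturbation can hop into a deeper one; settling the
reference first makes perturbation–recovery experiments well-posed
(recovery then reproduces the reference bond lengths to < 0.01 Å and
all-atom RMSD ≈ 0.1 Å). A closed hairpin's loop region equilibrates
within ~0.05 Å of the idealised bond targets — the restraint classes
are mildly inconsistent there, which is a property of the compromise
objective, not an optimisation failure. WC hydrogen-bond contacts
(H…acceptor ≈ 1.85–1.97 Å) legitimately sit just inside the repulsion
cutoff and contribute a negligible quartic penalty.

## 6. Validation (`compare`)

Kabsch superposition (SVD with the determinant correction, proper
rotations only; ≥ 3 points) minimises RMSD over rigid motions; it is
cross-checked in the tests against direct numerical minimisation over
rotation parameters. Backbone RMSD uses the sugar-phosphate set P, OP1,
OP2, O5′, C5′, C4′, C3′, O3′ plus the sugar ring C1′, C2′, O4′ — the
5′-terminal residue contributes no phosphate atoms — with "p-only" and
"all" selections available; residues are matched by position (length
mismatch is an error, never a trim) and U/T count as equivalent.
Per-entry comparisons against experimentally deposited coordinates
require downloading those coordinates and are therefore exercised on
synthetic predicted/reference pairs (a built model against a seeded
perturbation of itself); such pairs validate the machinery —
superposition, atom matching, report aggregation — but say nothing
about the accuracy of the builder against real structures.

## 7. System preparation (`mdprep`)

Box lengths are per-axis solute extent + 2 × padding (default 25 Å),
rounded up to whole Å. Waters are rigid 3-site molecules on a 2.8 Å
cubic lattice with seeded ±0.25 Å jitter, excluding sites within 2.4 Å
of the solute; neutralising Na⁺ (one per phosphate) replace seeded
random waters at least 5 Å from the solute. Counts are exact and
deterministic per seed; seeds move positions, never counts. The
published per-system box lengths are not reproduced as targets: they
encode the original solvation tool's internal extent convention, while
this package contract-checks the stated padding rule instead. No force
field, topology or dynamics — preparation only.

## 8. Synthetic data (`fixtures`)

`synthetic_hairpin` draws a random complementary stem and loop per
seed, yielding sequence, exact pair table and built model (optionally
regularized); `perturb` applies i.i.d. Gaussian coordinate noise.
These fixtures emulate the geometry and bookkeeping of real hairpins —
complementarity, topology, atom inventories — but not their
thermodynamic sequence bias, loop conformational preferences, or any
experimental noise structure; tests passing on them establish the
correctness of the algorithms and accounting, not prediction accuracy
on deposited structures. The bundled candidate table is a transcription
of printed search results and is versioned with the package.

## Numerical choices

- Energies are compared at 1e-9 in self-consistency tests; the DP and
  the enumeration oracle share one evaluator, so equality is exact.
- Minimiser: Armijo constant 1e-4, backtracking factor 0.5, BB step
  capped at 1.0; convergence on objective change (default 1e-8).
- Gradient-descent trajectories are deterministic; two runs of the same
  command are byte-identical. Floating-point path bifurcation means a
  rotated input reproduces the rotated trajectory only over moderate
  iteration windows; the objective itself is exactly
  rotation-invariant.
- PDB output quantises coordinates at 0.001 Å; stage composition via
  files agrees with the in-memory pipeline to that scale (amplified to
  a few hundredths of an Å through a refinement leg).
- Problem sizes in the test suite: folding oracle on 200 random
  sequences of length ≤ 12 plus a fixed panel; recovery experiments on
  an 11-nt hairpin (≈ 350 atoms); screening on the full 97-row table.

## Known limitations

- Multiloop 3D junction placement is simplistic (fan-out); only
  two-stem coaxial topologies are exercised.
- The A-form-like helix uses zero slide/roll with fitted axis
  displacement and inclination; groove dimensions are approximate.
- The restraint set contains no electrostatics, hydrogen-bond or
  stacking terms: refinement is geometry clean-up, and stem pairing is
  maintained by the starting geometry, not enforced.
- The G-score magnitude is package-calibrated, not a reimplementation
  of any specific web tool's internals.
- RNA folding, pseudoknots, G-quadruplex 3D geometry and molecular
  dynamics are out of scope.
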