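# hairpinforge

Sequence-to-3D modelling of single-stranded DNA (ssDNA) hairpins.

DNA aptamers — short single-stranded oligonucleotides selected to bind
molecular targets — are attractive biosensor recognition elements, but
unlike RNA they lack a mature toolchain for predicting three-dimensional
structure from sequence. `hairpinforge` implements, as one coherent
package, a four-step pipeline that closes this gap for the hairpin
motif, the most common ssDNA fold:

1. **Fold** — predict the secondary structure and folding free energy by
   nearest-neighbor free-energy minimisation (Zuker-style dynamic
   program over nested Watson–Crick structures; DNA ΔG°₃₇ tables at
   37 °C, 1 M Na⁺), with complete suboptimal enumeration inside an
   energy window.
2. **Build** — construct an all-atom RNA-geometry intermediate from the
   pair table: stems as ideal A-form helices assembled from nucleotide
   templates, loops and tails on smooth connecting arcs.
3. **Transmute** — convert the intermediate to DNA chemistry atom by
   atom: complete the hydrogens, methylate every uracil at C5
   (U → T, +3 atoms), swap ribose for deoxyribose (−1 atom per residue).
4. **Refine** — restrained geometric minimisation (bonds, angles,
   base-plane flatness, backbone torsions, non-bonded repulsion) with a
   monotone objective trace.

Around the pipeline sit the supporting stages a practitioner needs:
QGRS-style G-quadruplex screening with the published exclusion rules and
the bundled 97-entry candidate table, Kabsch superposition and
sugar-phosphate backbone RMSD for validation, and solvation-box /
counterion preparation for downstream molecular-dynamics work.

## The models in brief

**Folding.** The free energy of a nested Watson–Crick structure is the
loop decomposition
ΔG = Σ stacks + Σ hairpin(n) + Σ bulge/internal(n₁,n₂) + Σ multiloop,
with the unified WC stack values, DNA loop-size tables with
Jacobson–Stockmayer extrapolation, terminal-mismatch bonuses for loops,
and a stable-GNA-triloop bonus (all shipped as a versioned data file).
The MFE recursion is the standard V/WM/W dynamic program; suboptimal
folds come from duplicate-free Wuchty backtracking.

**G-score.** A sequence is a quadruplex candidate (score > 0) exactly
when four G-runs of length ≥ 2 fit in a 30-nt window as
G(x)N(y₁)G(x)N(y₂)G(x)N(y₃)G(x) with at most one empty loop; the
magnitude rewards longer tetrads and shorter, more even loops and is
calibrated so the thrombin-binding aptamer GGTTGGTGTGGTTGG scores 20.

**Refinement.** The objective is Σ wᵢ·(violationᵢ)² over bond lengths
(1.0 Å⁻²), bond angles (0.02 deg⁻²), base planarity (1.0 Å⁻²), backbone
torsions (0.01 deg⁻²) plus a quartic repulsion below 2.0 Å; the default
optimiser is Barzilai–Borwein gradient descent with Armijo backtracking,
with a damped Gauss–Newton variant selectable.

**Validation.** Backbone RMSD = RMS deviation over the sugar-phosphate
atom set (P, OP1, OP2, O5′, C5′, C4′, C3′, O3′, C1′, C2′, O4′) after
optimal proper-rotation (Kabsch) superposition.

## Worked example

```sh
$ hairpinforge run -s GTACAAAGTAC --iterations-stage4 2000 -o out
INFO step 1 (fold): seq GTACAAAGTAC
INFO step 1: dG -0.06 kcal/mol, ((((...))))
INFO step 2 (build + regularise, 100 iterations)
INFO step 3 (transmute to DNA)
INFO step 4 (refine, 2000 iterations)
INFO done: 349 atoms, charge -10
```

The 11-mer folds into a 4-base-pair stem closed by a 3-nucleotide loop
(dot-bracket `((((...))))`) at −0.06 kcal/mol — a marginally stable
hairpin, as expected for so short a stem. The output directory holds the
CT and dot-bracket files (step 1), the RNA-geometry intermediate and its
refinement trace (step 2), the DNA model (step 3), the refined final
model (step 4) and an accounting report:

```sh
$ cat out/seq_accounting.json
{
  "sequence": "GTACAAAGTAC",
  "chemistry": "DNA",
  "atoms": 349,
  "formal_charge": -10,
  "neutralizing_na": 10
}
```

349 atoms is the full-atom count of the protonated 11-mer with
5′-OH/3′-OH termini, and the −10 formal charge (one per internucleotide
phosphate) is what 10 Na⁺ counterions neutralise during system
preparation.

Individual stages are exposed as subcommands:

```sh
$ hairpinforge fold -s CGCGGTGTCCGCG
seq	CGCGGTGTCCGCG	(((((...)))))	-5.02

$ hairpinforge screen          # bundled candidate table
{
  "n_input": 97,
  "n_after_polymer_filter": 97,
  "n_ligand_excluded": 20,
  "n_motif_excluded": 53,
  "n_retained": 24,
  "n_unique_sequences": 21
}

$ hairpinforge rmsd predicted.pdb reference.pdb
$ hairpinforge mdprep out/seq_step4_refined.pdb --padding 25
```

Of the 97 bundled database-search entries, 20 are excluded for bound
ligands and 53 for non-hairpin motifs or positive G-scores, leaving 24
hairpin candidates with 21 distinct sequences (7–27 nt).

## Layout

```
src/hairpinforge/
  nucio.py      FASTA / CT / dot-bracket / PDB I/O and core types
  fold.py       nearest-neighbor MFE + suboptimal folding, motifs
  screen.py     G-runs, G-score, candidate exclusion rules
  build3d.py    template library, A-form stems, loop placement
  transmute.py  hydrogens, U→T methylation, ribose→deoxyribose, counts
  refine.py     restraint generation and minimisation
  compare.py    Kabsch superposition, backbone RMSD, RMSD reports
  mdprep.py     solvation box, waters, Na+ counterions
  fixtures.py   synthetic hairpins, perturbations, bundled table
  cli.py        the `hairpinforge` command
  data/         ΔG°₃₇ tables, templates, scoring weights, candidates
scripts/
  make_templates.py   regenerates the template library
  acceptance.py       recomputes the headline numbers
docs/methods.md       the full methods note
```
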