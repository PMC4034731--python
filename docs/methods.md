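# Methods

This note documents the models behind `fkbpscreen`, the defaults and why
they were chosen, what the synthetic generators emulate, and the
numerical corner cases.

## Descriptors

Molecules are parsed with RDKit and kept as RDKit `Mol` objects; RDKit's
default aromaticity perception is used throughout, and descriptor counts
therefore depend on that model.

* **E-state indices.** The electrotopological state of heavy atom *i* is
  `S_i = I_i + Σ_j (I_i − I_j)/d_ij²`, with intrinsic state
  `I = ((2/N)²·δv + 1)/δ` (N: principal quantum number, δv: valence
  electrons minus attached hydrogens, δ: heavy-atom degree) and `d_ij` =
  topological distance + 1.  Hydrogens are folded into attached-H counts;
  the graph distance uses heavy atoms only.  An isolated heavy atom has
  δ clamped to 1 (logged), so a single-heavy-atom molecule reports
  `S = I`.  Atom types are the standard Kier–Hall strings (`aaCH`,
  `sOH`, `sssN`, …), built from per-bond codes ordered aromatic/double/
  triple/single.  `ES_Count_x` is the number of atoms of type *x* and
  `ES_Sum_x` the sum of their S values, so a zero count forces a zero sum.
* **CHI_2** is the simple (non-valence) second-order connectivity index:
  the sum over 2-edge paths i–j–k of `(δ_i δ_j δ_k)^(−1/2)`.
* **Molecular_PolarSurfaceArea** is RDKit's Ertl fragment-based 2D TPSA.
  **Jurs_TPSA** is defined here as the 3D polar solvent-accessible
  surface: the Shrake–Rupley SASA (1.4 Å probe) summed over N, O and
  hydrogens bonded to them.  The two are deliberately distinct — the Jurs
  family is surface-based, TPSA is a fragment sum — and Jurs_TPSA is
  bounded above by the molecule's total SASA.
* **Shadow_Ylength** orders the principal axes of the coordinate
  covariance by descending variance and reports the extent along the
  second axis including van-der-Waals radii (Bondi set).  This makes the
  value invariant to rigid motions of the input coordinates.
* **Minimized_Energy** is an injectable numeric feature supplied by the
  caller (any forcefield minimizer); the pipeline never computes it.
  Descriptor software packages differ in their energy conventions, and
  the feature enters only as one regression input.

3D descriptors are reported absent when no conformer is present;
requesting them explicitly raises a requires-3D error.  Conformer
generation and protonation-state adjustment are out of scope — supply
prepared structures.

## GFA

Each individual is a descriptor subset of fixed size.  Fitness is the
negative Friedman lack-of-fit, `LOF = SSE/(n·(1 − (c + d·p)/n)²)` with
`c = terms + 1`, `p = terms`, smoothing `d = 1.0` (the canonical GFA
default; configurable).  Rank-deficient subsets receive fitness −∞
instead of raising.  Genetic operators: tournament selection (k = 2),
one-point subset crossover with duplicate repair, single-descriptor swap
mutation (rate 0.1), elitism of one.  Everything is driven by one
`numpy` generator, so runs are bit-reproducible given the seed.  Only a
linear basis is supported.  The published FKBP52 equation ships as a
bundled JSON model usable without retraining, because the 37-ligand
training set is not deposited; its printed training R² (0.9402) is
recorded as metadata, not recomputed.

## pIC50 predictors

* **MLR** is ordinary least squares with an explicit rank check; a
  singular design raises an error naming the collinear columns.  The
  stored training R² allows quick sanity checks.
* **SVR** wraps scikit-learn's RBF ε-SVR behind a z-scoring pipeline.
  Defaults C = 10, ε = 0.1, γ = 1/#descriptors — ordinary middle-of-road
  values, exposed on `SvrSpec`.  Constant descriptor columns are dropped
  with a warning; a single-row table degenerates to a constant predictor.
* **Bayesian network.** Variables (ten descriptors + pIC50) are
  discretized into at most five equal-frequency categories; duplicate
  quantile edges are merged, so the realized bin count can be smaller.
  Structure is learned by greedy hill climbing (add/delete/reverse
  moves, ≤ 3 parents) over the BDeu score with equivalent sample size 1,
  with random restarts, deterministic per seed.  CPTs use add-one
  Dirichlet smoothing so unseen bin combinations never produce zero
  posteriors.  At prediction time the query's descriptor bins are
  observed evidence (out-of-range values clamp to the outer bins, which
  are unbounded); because every non-activity node is observed, the exact
  posterior over pIC50 categories reduces to enumerating the ≤ 5
  activity states.  The reported value is the MAP category's linear
  regression evaluated at the query (ties break toward the lower
  category); a posterior-weighted mean of the category regressions is
  available via `combine="posterior_mean"`.  Each category regression
  uses all ten descriptors (minimum-norm least squares, since a category
  can hold fewer rows than descriptors).

## Consensus screening

Candidates with dock scores strictly below the control are eliminated
(ties with the control survive); the gate is optional because it is
ambiguous whether the published table was assembled before or after
gating — with the bundled table the outcome is identical either way.
Voting: per metric, the top three scorers receive the metric's weight
(1 for dock/SVM/MLR, 2 for the Bayesian network).  Ties spanning rank 3
are inclusive — every tied candidate gets the vote — which keeps the
result independent of input order.  Final ranking sorts by vote sum,
then dock score, then name; all deterministic.

## Interaction profiling

A table cell holds the set of interaction kinds between one ligand and
one residue (`H`, `Hb`, `Pi`).  Per-ligand totals count each kind (a
`Pi/Hb` cell contributes two) — this is the convention that reproduces
the published Total column; `ligand_residue_counts` gives the
once-per-residue count where set semantics are wanted.  Per-residue
percentages count ligands (control included in the denominator), and the
control comparison is plain set algebra on interacting-residue sets.

## Trajectory statistics

Coordinates are Å internally; Rg and SASA are reported in nm and nm².
File IO (PDB, multi-model PDB, DCD, XTC) goes through MDAnalysis.

* **Superposition** is the Kabsch algorithm with the determinant
  correction, so reflections are never returned.  Fewer than three atoms
  or a collinear selection raise a degenerate-geometry error.  RMSD is
  coordinate-only by default (mass weighting optional).
* **RMSD series** fit each frame to frame 0 on the fit selection and
  measure on the measure selection, so ligand RMSD = fit protein,
  measure ligand.
* **RMSF** superposes frames onto an iteratively refined mean structure
  (two passes), then reports per-atom or residue-averaged fluctuations.
* **SASA** is Shrake–Rupley with a Fibonacci sphere lattice (960 points
  per atom by default; accuracy improves as 1/n_points and the 960-point
  total is within 2 % of a 4000-point run on a 50-atom system).
* **H-bonds** use donor–acceptor heavy-atom distances by default (a
  hydrogen–acceptor variant is a flag, since conventions differ between
  tools); occupancy is the percentage of frames inside the 2.3–3.2 Å
  optimal-H-bond window, with the window edges configurable (e.g. the
  common d ≤ 3.5 Å rule).
* **Torsions** report the raw signed dihedral X ∈ (−180°, 180°], the
  rewrap Y = X + 360° for negative X, and the frame-to-frame change
  Z = Y(i+1) − Y(i); collinear middle bonds yield NaN for that frame.
* **Secondary structure** is a Kabsch–Sander implementation: backbone
  N–H···O=C bonds from the electrostatic energy
  `E = 0.084·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)·332 kcal/mol`,
  bond if E < −0.5 kcal/mol; missing amide hydrogens are imputed 1 Å
  from N along the previous residue's O→C direction.  Two consecutive
  i→i+4 turns give helix (3₁₀/π are folded into H for four-class
  reporting), bridge patterns with |i−j| > 2 give sheet, unpromoted
  3/4/5-turns give turn, a Cα direction change > 70° over i±2 gives
  bend, everything else (including residues with missing backbone
  atoms) is coil.  On ideal fixtures the assignment agrees with
  mdtraj's DSSP implementation for all H/E labels.
* **Clustering** is the GROMOS scheme: build the pairwise superposed
  RMSD matrix over the requested time window, repeatedly take the frame
  with the most neighbours within the cutoff (default 1.0 Å — a common
  choice; exposed) as a centre and remove its cluster; the largest
  cluster's centre is the representative conformation.

## Synthetic generators

The generators produce the study-shaped inputs the undeposited data
would have provided; all are pure functions of their seed, and every
artifact ships with a ground-truth sidecar.

* **QSAR tables**: 37 rows split 30/7 train/test (the study's design),
  descriptors drawn uniformly from plausible physical ranges (counts
  0–10, surface areas 0–200 Å², energies −100–0 kcal/mol), activity
  `pIC50 = intercept + Σβ·d + N(0, σ)` with three active descriptors and
  σ = 0.1 pIC50 units by default — roughly the replicate error of a good
  IC50 assay.  The generator plants a *linear* relationship, so passing
  recovery tests demonstrates correctness of the estimators, not that
  real descriptor–activity surfaces are linear; real tables also carry
  inter-descriptor correlation that uniform sampling does not emulate.
* **Score tables**: random candidate records around a designated
  control, spanning both sides of the dock gate.
* **Toy trajectories**: a rigid 10-atom scatter with isotropic Gaussian
  jitter (σ = 0.1 Å), one atom pair whose distance sits at 3.0 Å in a
  planted fraction of frames and 5.0 Å otherwise, and a four-atom
  quartet tracing a scripted dihedral.  This exercises every statistic
  at toy scale; it does not emulate solvent, bonded structure or
  realistic kinetics, so tests on it validate the estimators only.
* **Secondary-structure fixtures**: an ideal 12-residue poly-alanine
  α-helix (φ = −57°, ψ = −47°), two 8-residue antiparallel strands
  (φ = −139°, ψ = 135°) paired by a deterministic grid-plus-refinement
  search that maximizes inter-strand Kabsch–Sander H-bonds, and a fully
  extended chain.  Backbone geometry uses standard bond lengths/angles
  via natural-extension (NeRF) placement.

## Problem sizes and limitations

Tests and the acceptance script run on the bundled published tables
(10 candidates, 4 ligands × 10 residues), 37–60-row planted QSAR tables
(50 seeds for bias estimates, 20 for recovery rates), toy trajectories
of 100–2000 frames and ≤ 50 atoms, and 12–16-residue ideal chains —
sizes at which every check has an exact or oracle answer.  The original
study's per-ligand predictions, R² values, Rg/SASA averages and H-bond
occupancies cannot be reproduced because neither the 37 training ligands
nor the MD trajectories are deposited; those quantities are covered by
the planted-recovery and independent-oracle properties instead.  Numeric
parity with the descriptor values of any particular commercial software
is not attempted — E-state/shadow conventions differ between packages —
and docking and MD themselves are out of scope: dock scores and
trajectories are inputs.
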