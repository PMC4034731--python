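# fkbpscreen

Consensus QSAR virtual screening and MD-trajectory statistics for
FKBP52 ligand discovery.

FKBP52 (FK506-binding protein 52) binds hyperphosphorylated tau and is a
candidate target for non-amyloid-centric Alzheimer's therapies; the
immunosuppressant Tacrolimus (FK506) serves as the reference ligand.
`fkbpscreen` implements the full desk-side analysis used to pick
traditional-Chinese-medicine (TCM) candidate ligands for this target and
to summarize their molecular-dynamics behaviour:

1. **Descriptors** (`fkbpscreen.chem`) — the ten GFA-selected molecular
   descriptors: E-state counts/sums (`ES_Count_aaCH`, `ES_Count_sOH`,
   `ES_Sum_aaCH`, `ES_Sum_sssN`), six-ring count, Ertl 2D TPSA, the
   second-order connectivity index χ², a 3D polar solvent-accessible
   surface area (`Jurs_TPSA`), an injectable minimized energy, and the
   principal-axis shadow length.
2. **GFA** (`fkbpscreen.gfa`) — genetic function approximation: a genetic
   algorithm over fixed-size descriptor subsets, each scored by an OLS fit
   penalized with the Friedman lack-of-fit statistic
   `LOF = SSE / (n·(1 − (c + d·p)/n)²)`.  The package ships the published
   FKBP52 scoring equation (intercept 14.911 over the ten descriptors) as
   a bundled model.
3. **pIC50 predictors** (`fkbpscreen.qsar`) — multiple linear regression,
   RBF ε-insensitive support-vector regression, and a discretized Bayesian
   network (≤ 5 equal-frequency categories per variable, BDeu hill-climb
   structure learning, exact posterior over activity categories, one
   linear regression per category).
4. **Consensus screening** (`fkbpscreen.screen`) — dock-score gate against
   the control, then rank-threshold voting: top-3 per dock/SVM/MLR score
   earn 1 vote each, top-3 per Bayesian-network score earn 2; candidates
   are ranked by vote sum.
5. **Interaction profiling** (`fkbpscreen.interactions`) — statistics over
   recorded protein–ligand interaction tables (H-bond / hydrophobic / π–π
   per residue): per-ligand totals, per-residue interaction percentages,
   and control-vs-candidate residue set algebra.
6. **Trajectory statistics** (`fkbpscreen.traj`) — Kabsch-superposed RMSD
   and RMSF, mass-weighted radius of gyration, Shrake–Rupley SASA,
   H-bond distance series with 2.3–3.2 Å occupancy, torsion series with
   the X/Y/Z rewrap decomposition, Kabsch–Sander secondary structure, and
   GROMOS conformational clustering.
7. **Synthetic data** (`fkbpscreen.synth`) — generators with planted
   ground truth for every stage (descriptor/activity tables, score
   tables, toy trajectories, ideal helix/sheet fixtures), since the
   original 37-ligand training set and MD trajectories are not publicly
   deposited.

## Worked example

Re-rank the packaged candidate table (ten TCM ligands plus the
Tacrolimus control, dock scores and the three model predictions):

```python
>>> from fkbpscreen import bundled_score_table, run_screen
>>> result = run_screen(bundled_score_table(), k=3)
>>> for c in result["selected"]:
...     print(f"{c.name:40s} votes={c.votes} sum={c.vote_sum}")
Daphnetoxin                              votes={'dock': 1, 'svm': 0, 'mlr': 1, 'bn': 2} sum=4
Lythrancine II                           votes={'dock': 0, 'svm': 0, 'mlr': 1, 'bn': 2} sum=3
20-O-(2'E,4'E-Decadienoyl)ingenol        votes={'dock': 0, 'svm': 0, 'mlr': 0, 'bn': 2} sum=2
```

Daphnetoxin tops the ranking with 4 votes (top-3 in dock score, MLR and
the Bayesian network); the three selected ligands are the screening's
candidate set.  The same computation from the shell:

```bash
fkbpscreen screen vote --out ranked.csv
fkbpscreen interactions profile --control Tacrolimus --out report.json
```

The interaction report shows, e.g., that every candidate interacts with
Arg73, Phe77 and Tyr113 (100 % rows) and that Glu85 is the only residue
contacted exclusively by the control.

Evaluating the bundled scoring equation:

```python
>>> from fkbpscreen import bundled_model, evaluate_linear, DESCRIPTOR_NAMES
>>> evaluate_linear(bundled_model(), {n: 0.0 for n in DESCRIPTOR_NAMES})
14.911
```

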