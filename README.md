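# equivs

Conformer-ensemble bioactivity prediction for ligand-based virtual
screening (LBVS).

A molecule's measured potency is produced by whichever 3D conformation
actually engages the target, but computed conformer ensembles mix
binding-relevant and irrelevant geometries.  `equivs` treats each molecule
as a *bag* of M conformer *instances* (multiple-instance learning, MIL):

* a graph-convolution encoder over the bond topology yields a molecule-level
  representation H₁ = Σᵢ σ(W hᵢ + b) ⊙ hᵢ (gated-sum readout);
* per conformer, L = 2 stacked E(3)-equivariant message-passing layers —
  messages mᵢⱼ = φₑ([hᵢ, hⱼ, ‖xᵢ − xⱼ‖², eᵢⱼ]), coordinate updates
  xᵢ ← xᵢ + C Σⱼ (xᵢ − xⱼ) φₓ(mᵢⱼ) — produce per-layer gated readouts whose
  concatenation (skip connection) is the conformer representation H_m;
* softmax attention α_m = exp(w_m)/Σ exp(w_m) with
  w_m = qᵀ tanh(W H_m + b) aggregates H_G = Σ α_m H_m and exposes each
  conformer's importance;
* MLP heads predict potency (in -logM; 1 µM = 6) per conformer (ŷ_m) and
  per molecule (ŷ), trained with L = β·L_ins + (1 − β)·L_bag, where
  L_ins = meanₙ Σ_m α_{n,m}(yₙ − ŷ_{n,m})² and L_bag is molecule-level MSE
  (β = 0.5).

Because coordinates enter only through squared distances and the
coordinate updates are discarded after the last layer, predictions are
exactly invariant under rotations/translations of any conformer, and the
attention coefficients rank which conformer the model considers consistent
with the measured activity — a built-in optimal-conformer interpretation.

The package also provides the surrounding pipeline: bioactivity-table
curation (activity-type whitelist, bucketed value integration, 1 µM
active/inactive threshold, per-target scale filter), RDKit-based structure
standardization, ETKDG + MMFF94 conformer ensembles with alignment and SDF
round-trip, graph featurization (74-dim atoms, 12-dim bonds, n × 3M
coordinates), training/evaluation, attention-based conformer ranking, and a
synthetic-task generator so everything runs self-contained.  Intended
users: computational chemists and ML researchers prototyping
conformer-aware QSAR/LBVS models at desk scale.

## Worked example

Generate a synthetic task, train, predict, and inspect conformer attention:

```bash
equivs synth --n 80 --seed 7 --out task/ --n-conformers 10
equivs train --data task/molecules.csv --sdf task/conformers.sdf \
             --out run/ --seed 7 --epochs 60 --batch-size 32
equivs predict --checkpoint run/checkpoint.npz --sdf task/conformers.sdf \
               --out preds.csv
equivs interpret --checkpoint run/checkpoint.npz --sdf task/conformers.sdf \
                 --out report.csv
```

Output of the run above (a few minutes on one CPU, most of it conformer
generation):

```
wrote 80 molecules to task
test R2=0.848 MSE=0.217 MAE=0.324
wrote 80 predictions
wrote report for 80 molecules
```

The train line reports held-out metrics: R² is the fraction of label
variance explained on the test split, MSE/MAE are in (-logM)² and -logM.
`preds.csv` holds one molecule-level potency prediction per molecule;
`report.csv` holds one row per conformer with its attention coefficient α
(rows per molecule sum to 1; values below the uniform 1/M = 0.1 flag
conformers the model treats as geometric noise), its conformer-level
prediction, and the absolute error against the label.

The same pipeline is importable as a library (`equivs.prepare_ensemble`,
`equivs.assemble_graph`, `equivs.train`, `equivs.rank_conformers`, ...);
see `docs/methods.md` for the model, its assumptions, and the synthetic
task design.

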