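# Methods

## Problem setting

`equivs` predicts per-target molecular bioactivity (potency in -logM, the
negative decadic logarithm of a molar concentration, so 1 µM = 6) from
ensembles of computed 3D conformers, for ligand-based virtual screening.
A molecule's measured potency reflects whichever conformation actually binds;
computed conformer ensembles contain both binding-relevant and irrelevant
geometries.  The model therefore treats a molecule as a *bag* of M conformer
*instances* (multiple-instance learning): only the bag carries a label, and
an attention mechanism decides how much each instance contributes.

## Pipeline

1. **Curation** (`curation`).  Input tables carry
   (molecule, target, activity type, value in -logM, source, match label).
   Records are kept only for the five routinely assayed activity types
   (IC50, Ki, Kd, EC50, Potency) and for structure-consistent cross-source
   matches ("1 structure", "match").  Repeated measurements of one endpoint
   are integrated by binning into half-open unit-width -logM buckets
   [k, k+1) and returning the mean of the most populated bucket; frequency
   ties go to the more potent (higher -logM) bucket.  Molecules are labeled
   active at ≥ 6 -logM (≤ 1 µM).  Targets with fewer than 300 endpoints
   (inclusive threshold, configurable) are dropped: below that scale,
   per-target regression models are unreliable.

2. **Structure preparation** (`chemprep`).  SMILES are standardized with
   RDKit's molecular standardizer (normalization of functional groups,
   charge recombination and neutralization, metal-bond disconnection,
   reionization, canonical tautomer selection, salt/solvent fragment
   removal); structures that fail sanitization are rejected.  Hydrogens are
   added, M = 10 conformers are embedded with ETKDG using per-conformer
   seeds (conformer m uses seed + m, so "different random initializations"
   are reproducible), relaxed with MMFF94 (default cap 200 iterations, the
   library default; convergence is recorded per conformer), rigidly aligned
   onto the first conformer over heavy atoms, and stripped of hydrogens.
   If embedding fails the seed is bumped up to five times, then one
   random-coordinate attempt is made before raising.  Ensembles round-trip
   through multi-record V2000 SDF files (one record per conformer sharing a
   molecule title).

3. **Graph construction** (`molgraph`).  Heavy-atom graphs with binary
   symmetric adjacency (zero diagonal), 74-dim node features
   (43-symbol element vocabulary one-hot, degree 0–10, implicit-H count
   0–6, formal charge, radical-electron count, hybridization
   SP/SP2/SP3/SP3D/SP3D2, aromaticity flag, total-H count 0–4), 12-dim
   bond features (type single/double/triple/aromatic, conjugation, ring
   membership, six-slot stereo one-hot), and an n × 3M coordinate block
   concatenating the M aligned conformer coordinate sets (30 columns at the
   default M = 10).  Out-of-vocabulary elements encode as an all-zero
   element block with a warning rather than a dedicated unknown slot.  Edge
   features are stored per directed edge (both orientations share the
   bond's row) to serve message passing.

## Model

Let A be the adjacency, H_V the node features, H_E the bond features, and
x_m the coordinates of conformer m.

**Topological encoder.**  One graph-convolution step with linear maps:
messages m_ij = φ_e([h_i, h_j]) summed over neighbors, node update
h_i' = φ_h([h_i, Σ_j m_ij]), followed by a gated-sum readout
H1 = Σ_i σ(W_r h_i' + b_r) ⊙ h_i' (σ = sigmoid).  H1 is computed once per
molecule, before the conformer loop.  Isolated nodes receive a zero message
sum (defined, not an error).

**Equivariant conformer stack.**  Per conformer, L = 2 message-passing
layers.  Edge messages m_ij = φ_e([h_i, h_j, ‖x_i − x_j‖², e_ij]) depend on
coordinates only through squared distances, making node features invariant
under rotations/translations.  Coordinates update residually and
equivariantly, x_i ← x_i + C Σ_j (x_i − x_j) φ_x(m_ij), with
C = 1/(n_heavy − 1) (the divisor reading of the neighbor-count constant,
chosen for numerical stability and exposed as `coord_scale_mode`; guarded
to 1 for single-atom molecules).  Node update h_i ← φ_h([h_i, Σ_j m_ij]).
All φ are single linear maps on concatenated inputs; φ_x outputs one
scalar.  Each layer ends in its own gated-sum readout over the layer's
*output* node features (the readout-gate pattern of the topological
encoder, applied consistently).  Updated coordinates feed the next layer
and are then discarded — only invariant readouts reach the predictors, so
every prediction is exactly E(3)-invariant by construction (verified
numerically in the tests).

**Skip connection.**  The conformer representation is the concatenation of
the L per-layer readouts (width L × 128 = 256 by default), preserving
gradient flow to the shallow layer and countering over-smoothing.

**Attention MIL.**  Scores w_m = qᵀ tanh(W H_m + b) are softmax-normalized
within each molecule (never across a batch) into coefficients α_m ≥ 0,
Σα = 1; the molecule representation is H_G = Σ_m α_m H_m.

**Heads.**  A two-layer ReLU MLP on H_m gives conformer-level predictions
ŷ_m; another on [H1, H_G] gives the molecule-level prediction ŷ.

**Ablation variants** (config toggles): single conformer (M = 1); linear
layer instead of the GCN; last-layer readout instead of the skip concat;
unweighted sum instead of attention; no instance predictor/loss.

## Training

Loss L = β L_ins + (1 − β) L_bag with β = 0.5, where
L_ins = mean_n Σ_m α_{n,m}(y_n − ŷ_{n,m})² and L_bag is molecule-level MSE.
The attention weighting lets the instance loss discount conformers the
model considers noise; when the attention variant is disabled, uniform
α = 1/M is used inside L_ins (the variant definition removes attention, not
the instance head).  Setting β = 0 realizes the no-instance-predictor
variant; its instance-MLP weights then receive no updates.

Optimizer: Adam, learning rate 0.001, otherwise standard defaults (only the
rate is treated as a tuned quantity).  Dropout 0.05 after each GNN layer
and each MLP hidden layer, active only at train time; attention operates on
the conformer readouts as computed, i.e. downstream of that dropout.
Datasets split randomly 8:1:1 into train/validation/test, seeded.  Model
selection keeps the parameters of the epoch with the lowest validation
loss; defaults are 200 epochs and batch size 128.  Metrics are R², MSE and
MAE (scikit-learn implementations, cross-checked in the tests against
hand-written closed forms); R² is reported as missing for constant truth.

Weights are Glorot-uniform, biases zero, seeded.  The network and its
gradients run on a small reverse-mode autodiff tape over NumPy
(`autodiff.py`, float32), with every operation's backward pass validated
against central finite differences; all conformers of all molecules in a
minibatch are flattened into one disconnected graph for throughput.  Adam
is implemented directly on the named parameter dict.

## Interpretation

Conformers are ranked by attention coefficient (stable descending order,
ties to the lower index).  Coefficients below the uniform average 1/M flag
conformers the model treats as noise.  The report table pairs each
conformer's α with its instance prediction and absolute error against the
measured label, and leaves an optional external-score column (e.g. docking
scores) for user-supplied values; no docking is performed here.

## Synthetic tasks

The generator enumerates ~350 small drug-like molecules from 18 scaffolds ×
20 substituents (aromatic/heteroaromatic/saturated cores; only
MMFF94-parameterizable elements).

* **Regression task**: label = 1.5 + 0.35·(heavy atoms) + 0.6·(rings) +
  N(0, σ), clipped to the plausible potency window 0.1–21.8 -logM; default
  σ = 0.1.  Labels span roughly 4–11 -logM, so signal dominates noise and a
  model that recovers size and ring content from the graph can fit it.
* **Noisy-conformer MIL task**: per molecule one seeded conformer keeps its
  aligned MMFF94 geometry; the other M − 1 get iid N(0, 2 Å) atomic
  displacements, which destroys covalent geometry.  The label is
  2.0 + 0.8·(mean pairwise heavy-atom distance of the informative
  conformer) + N(0, 0.1).  Only the informative conformer carries signal,
  so attention must find it; a plain sum over conformers mixes in the
  scrambled geometries and fails.
* **Case fixture**: a published CDK2-active sulfonamide with measured
  potency 9.0 -logM and ten generated conformers, used to exercise the
  interpretation report end to end.

What these tasks do *not* emulate: real structure–activity landscapes
(activity cliffs, scaffold effects), assay noise structure, chemical-space
breadth, or any relation between computed conformers and true binding
poses.  Passing them shows the pipeline is implemented correctly and that
attention MIL can isolate an informative instance — not that the model
reaches any particular accuracy on experimental screening data.

## Problem sizes and numerical choices

Desk-scale experiments use n = 200 molecules (regression; standard
hyper-parameters at 80 epochs, reaching held-out R² well above 0.7) and
n = 100 molecules × 3 seeds (MIL ablation; 60 epochs, batch 32, where the
full model's test MSE is far below the unweighted-sum variant's and the
top-attention conformer matches the informative one for nearly all test
molecules).  These sizes were chosen as the smallest at which the learning
and ablation effects are unambiguous.

Degenerate inputs: empty edge sets (single-atom molecules) produce zero
message sums; C is guarded at 1; softmax is computed with max-shift
stabilization; sigmoid uses the numerically stable `expit`.  Alignment
idempotence holds to the aligner's convergence (~1e-7 Å).  SDF coordinates
round-trip to format precision (1e-4 Å).

## Known limitations

* Training is CPU-bound NumPy; fine for desk-scale studies, not for
  million-endpoint benchmarks.
* φ maps are single linear layers by design; expressiveness comes from the
  distance terms, gates, and stacked layers, not from deep φ networks.
* The conformer generator is stochastic chemistry-agnostic sampling; no
  clustering, energy-window pruning, or crystal-structure retrieval.
* One model per target; multi-target or transfer training is out of scope.
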