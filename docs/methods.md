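# Methods

This note documents the models, conventions and numerical choices behind
`heterodta`, the reasons for the defaults, and what the synthetic benchmark
does and does not demonstrate.

## Problem setting

Drug–target affinity prediction is posed as scalar regression of
pKd = −log₁₀(Kd / (mol L⁻¹)) from a triple (drug molecule, target protein,
binding pocket). Higher pKd means tighter binding. The pocket — the residue
subset lining the binding cavity — is treated as a first-class input
alongside the full target, because its composition and geometry carry most
of the binding signal.

## Data conventions

**Protein structures** are read from PDB files with Biopython. Only ATOM
records of one model are used (default the first; NMR ensembles contribute
one structure). Alternate locations keep altloc `' '` or `'A'` only.
Residues without a usable Cα are skipped and counted (`n_skipped`), never
silently dropped; a file yielding zero Cα residues is an error. Nonstandard
residues map to one-letter code `X`, which encodes as an all-zero feature
row. Multi-chain targets are concatenated in file order into one residue
list. Pocket membership is matched by PDB identity (chain, residue number,
insertion code); coordinates serve only as a cross-check.

**Ligands** are read from SDF V2000 or TRIPOS MOL2 text (dialect by
extension, overridable). Atom order and 3D coordinates are preserved; the
bond list is exactly what the file states, undirected and deduplicated —
no valence or bond-order perception is attempted. Malformed counts lines
raise parse errors naming the offending line. These two parsers are
implemented in-package so that the error contract and the exact atom/bond
lists (including hydrogens) are under our control; the test suite
cross-checks them against RDKit where available.

**Sequence profiles**: PSI-BLAST ASCII PSSMs are returned as given (first
20 score columns, integers as reals); HHsuite `.hhm` match-emission codes
`v` become probabilities 2^(−v/1000), with `*` → 0. Profiles must match the
protein length at pairing time.

**Fixed lengths**: target sequences are capped at 2100 residues and pockets
at 125 (config keys); shorter sequences are zero-padded in the
`EncodedSequence` layout, longer ones truncated with a recorded flag.

## Encodings

The residue vocabulary is the 20 standard one-letter codes in alphabetical
order; the drug-atom vocabulary has 27 symbols (C, N, O, S, P, halogens,
metalloids and common metals, plus a catch-all `UNK`). Label encoding is
the 1-based vocabulary index with 0 for unknowns; one-hot encoding gives
unknown symbols an all-zero row rather than a shared UNK indicator, which
keeps the residue feature dimension at exactly 20 as the CNN input requires.
Physico-chemical tables (24 descriptors per residue, 9 per atom) ship as
editable YAML; they are assembled from standard published scales and are
deliberately labeled synthetic stand-ins — any 24/9-column table with the
same layout can be dropped in. Columns are standardized to zero mean and
unit variance over the table's own entries, deterministically.

## Graphs

Residue contact graphs connect residues *i ≠ j* with Cα distance
≤ 8 Å. The comparison uses a closed boundary (`≤`) in double precision;
"within 8 Å" does not specify the boundary, and the closed convention keeps
the stated cutoff itself in-graph. Pocket graphs are built by the same rule
over the pocket's own residues (edges are not inherited from the target
graph). Contacts across chain breaks are allowed: any residue pair
satisfying the distance rule is connected. Molecular graphs drop hydrogens
(and their bonds) by default. Graphs store no self-loops; layer types that
need them (GCN) add them transparently, while GraphSAGE uses an explicit
self term. Graph construction is validated against a brute-force O(n²)
distance oracle by property tests.

## Architecture

* **Sequence module.** 1D-CNN with stride 1, zero 'same' padding, 128
  output channels; kernel 5 for targets, 3 for pockets. Variants: LSTM
  (hidden 128), BiLSTM (64 per direction, concatenated), CNN+LSTM, or
  `none` (one-hot straight to the GNN, with the first GNN layer sized 20).
* **Structure module.** Three independent 3-layer message-passing stacks
  (drug, target, pocket), dimensions 32 → 64 → 128, LeakyReLU (slope 0.01)
  after every layer. Default layer is GraphSAGE with mean neighbor
  aggregation plus a self term; GCN (symmetric normalization), single-head
  GAT, and GIN (sum aggregation, 2-layer MLP, ε = 0) are selectable. The
  internals of the variants are the canonical formulations, since only the
  family names are prescribed.
* **Fusion.** Mean readout per graph (max available), one 128 → 256 linear
  projection per stream with *unshared* weights, concatenation to 768, then
  768 → 256 (LeakyReLU + dropout 0.4) → 1. The fused dimension is stated
  ambiguously in the source description ("256" after concatenating three
  256-d vectors); concatenating to 768 and letting the first FC layer map
  768 → 256 reconciles the layer sizes and is what we implement.
* **Attention.** Unparameterized scaled dot product over the final
  pre-pooling vertex embeddings: S = D·Tᵀ/√128, row-softmaxed in both
  directions. Attention indexed by atoms × residues requires per-vertex
  embeddings, so it is computed before pooling; the softmax rows are
  probability vectors by construction.

Sequence encoders run on the true-length residue window. For the causal
CNN and the forward LSTM this is exactly equivalent to encoding the
zero-padded fixed-length matrix and slicing to the true length (the padding
rows are zero); the BiLSTM backward pass runs over the reversed valid
window. This keeps evaluation outputs invariant to batch composition and
the cost proportional to the true sequence length.

## Autodiff engine

All layers are built on `heterodta.autodiff`, a compact reverse-mode
engine over float64 NumPy arrays: a dynamically recorded tape with the
operations the models need (broadcast arithmetic, matmul, constant-sparse
matmul for neighbor aggregation and readout, row gather/scatter,
concatenation, the usual nonlinearities, row softmax, segment max).
Gradients of every operation and of the full model loss are verified
against central finite differences in the test suite. Float64 throughout
trades speed for exact run-to-run reproducibility at the problem sizes the
package targets.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸), learning rate 10⁻⁴, batch size 128,
MSE loss, 300 epochs by default ("300 iterations" is read as 300 epochs,
the usual convention in this literature; configurable). A validation split
(default 10%, seeded shuffle) drives checkpoint selection (`best_val`;
`last` available) — the source names only train/test sets, so the split
fraction is our choice. The last incomplete batch is kept. There is no
gradient clipping; a NaN guard aborts with a diagnostic naming the epoch
and batch instead. Parameters are initialized Glorot-uniform from a seeded
generator. All random streams (init, shuffle, dropout, split) derive from
one integer seed via named `SeedSequence` children, so (seed, data, config)
determines the history bit-for-bit on one machine.

## Metrics

MAE, RMSE, Pearson, Spearman (average ranks on ties, via scipy), R²
against the mean of the true values (can be negative), and concordance
index. The CI follows the standard DTA-benchmark convention: pairs with
equal true values are not comparable; a comparable pair scores 1 if the
predicted ordering matches, 0.5 on a prediction tie. Zero-variance inputs
make the correlations undefined; they are reported as NaN with a warning.
Every metric is tested to 1e-10 against an independently coded naive
implementation (and CI additionally against lifelines).

## Interpretability

For each complex, every heavy atom ranks all target residues by its
attention row, and every residue ranks the atoms. Reported statistics:

* residue side — fraction of top-k picks (k ∈ {5, 10, 20}) inside the
  pocket, pooled over atoms; at dataset level both the pick-pooled fraction
  and the unweighted mean of per-complex fractions are reported, since the
  aggregation convention is otherwise underdetermined;
* atom side — distinct atoms appearing among the residues' top-k picks
  (k ∈ {3, 5, 8}) over the heavy-atom count. This coverage reading is the
  one that makes the statistic monotone in k.

Ties are broken by ascending index, making reports deterministic.
Visualization is delegated to external viewers via exported plain-text
residue/atom selection lists.

## Synthetic benchmark

The generator emulates benchmark-style complexes at desk scale:

* proteins of 30–60 residues as self-avoiding Cα random walks with exact
  3.8 Å steps (the canonical virtual-bond length) and 3.5 Å non-consecutive
  clearance, random standard-residue sequences, written as fixed-column PDB;
* pockets as contiguous seeded windows of 8–15 residues, written as PDB
  subsets sharing residue identities with the parent;
* drugs of 6–15 heavy atoms as random spanning trees plus up to two
  ring-closing bonds, elements from {C, N, O, S} (70/12/12/6%), ~1.5 Å
  bond lengths, written as SDF V2000;
* affinity = mean over pocket residues of fixed per-type weights
  w(aa) = 6.5 + Kyte–Doolittle hydropathy (range [2.0, 11.0]), plus
  Gaussian noise of sd 0.2. The weight table was fixed a priori so that
  dataset-level affinities disperse like benchmark pKd values
  (sd ≈ 0.9 here), and the label depends *only* on the pocket — making
  "pocket knowledge drives affinity" a directly testable planted
  hypothesis: ordinary least squares on pocket composition recovers the
  weights (a property test), and the trained model must do the same from
  raw structures.

What passing tests show: the full pipeline — parsing, graph construction,
CNN→GNN fusion, training, attention — can extract a composition-level
pocket signal from standard-format files and generalize to held-out
complexes (PCC ≥ 0.8, CI ≥ 0.75 on 50 held-out complexes after training on
200). What they do not show: performance on real complexes, where affinity
depends on geometry, chemistry and long-range context absent from the
planted law; synthetic folds are not physical, ligand valences are not
chemically constrained, and no docking pose relates drug to pocket
spatially.

## Problem sizes

Default experiment sizes are desk-scale by design: 250 complexes
(200 train / 50 test) for the generalization experiment, 16 complexes for
the memorization check, 300 epochs each. On one CPU core the full
acceptance run completes in a few minutes.

## Known limitations

* No edge features (bond order, distances) and no contact maps from
  predicted distograms; the graphs are unweighted.
* Learned sequence embeddings (protein language models, word2vec) are out
  of scope; evidence suggests little gain over one-hot for this
  architecture.
* The CLI covers single-machine runs only; no distributed training or
  hyperparameter search.
* mmCIF is not parsed; profile generation (PSI-BLAST/HHblits) is external —
  only the resulting matrices are read.
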