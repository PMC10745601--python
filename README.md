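# heterodta

Structure-aware **drug–target affinity (DTA)** prediction. Given a drug
(small molecule), a target protein and its binding pocket, the toolkit
regresses the binding affinity pKd = −log₁₀ Kd by fusing *sequence* and
*structural* knowledge through a heterogeneous CNN + graph-neural-network
model, and explains its predictions with bidirectional attention between
drug atoms and target residues.

It is written for computational chemists and ML practitioners who want a
fully tested, dependency-light (NumPy-core) reference pipeline: every stage
— file parsing, featurization, graph construction, model, training,
evaluation, interpretability — is exercisable end-to-end on seeded
synthetic complexes, with no external dataset required.

## The model

Each complex is represented as three graphs:

* **target / pocket** — residue contact graphs: vertices are Cα atoms,
  an edge joins residues *i ≠ j* with ‖Cα<sub>i</sub> − Cα<sub>j</sub>‖ ≤ 8 Å;
* **drug** — the molecular graph from the ligand file's covalent bonds
  (hydrogens stripped), with 27-dimensional one-hot element features.

Target and pocket sequences (20-dim one-hot, fixed lengths 2100 and 125
with zero padding) pass through a 1D-CNN (kernel 5 for targets, 3 for
pockets, stride 1, 128 output channels; LSTM / BiLSTM / CNN+LSTM variants
available). The per-position CNN output becomes the vertex features of the
contact graph, so sequence position *i* feeds vertex *i*. Three independent
3-layer message-passing stacks (GraphSAGE with mean aggregation by default;
GCN / GAT / GIN variants) with dimensions 32 → 64 → 128 and LeakyReLU
encode the three graphs; mean readout and per-stream linear projections
give three 256-d vectors, concatenated (768) into a two-layer fully
connected head (768 → 256 → 1, dropout 0.4) that outputs pKd. Training uses
Adam, learning rate 10⁻⁴, batch size 128, MSE loss, 300 epochs.

For interpretability, scaled dot-product attention over the final
pre-pooling vertex embeddings, S = D·Tᵀ/√128, yields two row-stochastic
matrices (atoms→residues and residues→atoms) from which per-atom residue
rankings, per-residue atom rankings and pocket-hit statistics are derived.

Evaluation reports six metrics: MAE, RMSE, Pearson (PCC), Spearman,
concordance index (CI) and R², each cross-checked in the test suite against
independently coded naive oracles.

The neural components run on a compact reverse-mode automatic
differentiation engine over NumPy (`heterodta.autodiff`), verified by
finite-difference gradient tests — no deep-learning framework is required.

## Worked example

Simulate a synthetic benchmark, train, and evaluate:

```bash
cat > spec.yaml <<EOF
n_complexes: 60
noise_sd: 0.2
seed: 42
EOF
cat > config.yaml <<EOF
train:
  epochs: 300
  seed: 7
  val_fraction: 0.1
EOF

heterodta simulate spec.yaml data/
heterodta train data/manifest.csv run/ --config config.yaml
heterodta evaluate data/manifest.csv run/checkpoint.npz metrics.json
cat metrics.json
```

The evaluate step prints (about half a minute of training on one CPU):

```json
{"mae": 0.3424575214015168, "rmse": 0.4124754418080774,
 "pcc": 0.892670028289825, "spearman": 0.8834120589052517,
 "ci": 0.8502824858757062, "r2": 0.7696874777777463, "n": 60}
```

Each synthetic complex carries a planted affinity law — the mean of fixed
per-residue-type weights over the *pocket* residues plus Gaussian noise
(sd 0.2) — so these numbers say the model has learned to read affinity out
of pocket composition: predictions correlate with truth at PCC ≈ 0.89 and
rank 85% of comparable pairs correctly (CI ≈ 0.85), with RMSE ≈ 0.41 pKd
units, roughly twice the noise floor.

`heterodta explain data/manifest.csv run/checkpoint.npz explain/` then
writes per-complex attention reports (top-k residue/atom picks, pocket-hit
fractions) and plain-text selection lists for molecular viewers.

Real data in PDBbind layout is supported through the same manifest CSV
(`complex_id,protein_path,pocket_path,ligand_path,affinity`) pointing at
PDB / SDF / MOL2 files; PSI-BLAST PSSM and HHsuite `.hhm` profiles can be
parsed into per-residue features with `heterodta.structio.parse_profile`.

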