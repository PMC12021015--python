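# ddgraph

Graph-convolutional prediction of protein stability change (ΔΔG, kcal/mol)
for **arbitrary mutation types** — single and multi-point substitutions and
insertions/deletions — from sequence-derived residue graphs.

## The problem

Most stability predictors accept only point mutations: they encode "the
mutated position" and break as soon as the mutant sequence has a different
length. `ddgraph` follows the siamese graph formulation instead: the
wild-type and the mutant sequence are each turned into a residue graph
(per-residue embeddings as node features; predicted residue–residue contact
probabilities, thresholded at 0.1, as weighted edges) and passed through the
**same** stack of edge-weighted SAGE-style graph convolutions,

```
h'_v = ReLU(W_self h_v + W_neigh · Σ_u w_uv h_u / Σ_u w_uv + b),
```

mean-pooled to fixed-length vectors, combined, and regressed to a single
ΔΔG by a small fully connected head. Because the encoders share weights and
pooling is length-invariant, one model covers any edit of any size.

Thermodynamics demands ΔΔG(mutant→wild) = −ΔΔG(wild→mutant). The training
pipeline enforces this *through data*: every record is merged with its
inversion (sequences swapped, label negated), and the learned antisymmetry
is audited with r_d−i (Pearson correlation between paired direct and
inverse predictions, ideal −1) and ⟨δ⟩ (mean paired sum, ideal 0). An
architecturally antisymmetric variant (`combiner="diff"`) is available for
ablations.

The package ships a synthetic test bed — random proteins with an exact
additive contact energy `E = Σ p_ij φ(a_i,a_j) + Σ ψ(a_i)` — that stands in
for the large-scale experimental data, language-model embeddings and contact
predictions needed at production scale, so every part of the pipeline is
verifiable on a laptop. Two zero-shot analyses are included: stability-based
pathogenicity screening (benign iff |ΔΔG| ≤ 1 kcal/mol) and cross-prediction
matrices over organism growth-temperature classes
(psychrophile/mesophile/thermophile/hyperthermophile at 20/45/80 °C).

## Worked example

```python
import numpy as np
from ddgraph import SyntheticEnergyModel, generate_dataset, TrainConfig
from ddgraph.estimator import StabilityModel
from ddgraph.synthetic import build_samples

energy = SyntheticEnergyModel.random(seed=1)          # exact ddG oracle
records = generate_dataset(1000, model=energy, seed=1)  # mixed subs/indels
model = StabilityModel.from_synthetic(records[:800])  # antisymmetric merge
res = model.fit(TrainConfig(max_epochs=25, patience=10, learning_rate=3e-3, seed=1),
                val_split="record")
print(res.summary())
print(res.evaluate(build_samples(records[800:])))
```

prints

```
Stability network regression results
====================================================
conv type        sage_weighted
conv layers      2   hidden dim 64
weights shared   True   combiner concat
head blocks      2   dropout 0.0
parameters       23617 (conv 10880)
----------------------------------------------------
epochs trained   25   best epoch 24
train RMSE       0.3099 kcal/mol   PCC 0.9892
val   RMSE       0.4664 kcal/mol   PCC 0.9711

n        200
PCC      0.9438
Spearman 0.9375
RMSE     0.6356 kcal/mol
```

The fitted network recovers the generating energy: held-out mutations of
the training scaffolds are predicted with Pearson r ≈ 0.94 and RMSE ≈ 0.64
kcal/mol at this small training size (1 600 samples after augmentation; the
reference experiments below use 4 000 records and reach r ≈ 0.98). The
antisymmetry audit of the same fit,

```python
r, delta = res.antisymmetry(model.samples)
# r_d-i = -0.999, <delta> = 0.171 kcal/mol
```

shows the concatenation model has *learned* near-perfect antisymmetry from
the augmented data alone.

## Command line

```bash
ddgraph simulate --n 2000 --seed 7 --out sim/          # synthetic corpus
ddgraph prepare  --data sim/ --out prep/               # filter + augment
ddgraph train    --data prep/dataset.csv --contacts sim/contacts --out run/
ddgraph evaluate --checkpoint run/checkpoint.npz --data prep/dataset.csv \
                 --contacts sim/contacts --out eval/
ddgraph predict  --checkpoint run/checkpoint.npz --table muts.csv \
                 --contacts sim/contacts --out preds.csv
ddgraph pathogenicity --predictions preds_with_labels.csv --out patho/
ddgraph ogt      --checkpoint run/checkpoint.npz --proteins proteins.tsv \
                 --contacts maps/ --out ogt/
```

Every run writes its resolved configuration and seed next to its outputs
and is byte-for-byte reproducible given the same inputs and seed. Mutation
tables may give the mutant sequence explicitly or as edit notation
(`A2G`, `A2G:D5K`, `C2del`, `C2_D4del`, `3insGG`; positions 1-based).

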