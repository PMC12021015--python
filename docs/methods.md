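# Methods

## The model

`ddgraph` predicts the stability change ΔΔG (kcal/mol) of an arbitrary
protein sequence edit — single or multiple substitutions, insertions,
deletions — from two residue graphs, one for the wild-type and one for the
mutant sequence.

**Graphs.** A sequence of length N becomes a graph with one node per
residue. Node features are per-residue embeddings from a pluggable
provider: in production a protein language model (the package consumes
precomputed N×F matrices, e.g. F = 1024 from a transformer's last hidden
layer); as the self-contained fallback, one-hot encoding over the 20
standard amino acids (F = 20, alphabetical order `ACDEFGHIKLMNPQRSTVWY`).
Edges come from a symmetric residue contact-probability matrix (produced
externally by a contact predictor, or by the synthetic generator): a pair
(i, j) becomes an edge iff p_ij ≥ cutoff, with the probability reused as
the edge weight. The cutoff defaults to 0.1 and the comparison is
inclusive, so a printed cutoff value itself admits edges. Sequential
(backbone) neighbours are *not* connected implicitly; a flag can add
(i, i+1) edges of weight 1.0 for very sparse maps.

**Encoder.** Both graphs pass through the same stack of SAGE-style
convolutions (shared weights — a siamese arrangement, so one parameter set
serves both and any sequence length is accepted):

    h'_v = ReLU(W_self h_v + W_neigh · agg(v) + b),
    agg(v) = Σ_{u∈N(v)} w_uv h_u / Σ_{u∈N(v)} w_uv

The self term doubles as a skip connection; the aggregation is a weighted
*mean*, i.e. normalized, so high-degree nodes do not dominate. Isolated
nodes aggregate to the zero vector. Optional row-wise L2 normalization of
node states is available (`l2_normalize_nodes`) but off by default: the
aggregation is already normalized, and in our experiments the extra
normalization consistently slowed convergence and cost held-out accuracy.
An unweighted sum-aggregation variant (`graphconv_plain`) and an
ignore-edge-weights flag exist for ablations.

**Pooling, combiner, head.** Node states are mean-pooled into one vector
per graph (length-invariant). The two pooled vectors are combined by
concatenation (default) or by difference, then a head of `head_blocks`
repetitions of [affine → layer normalization → ReLU → dropout] and a final
affine map yields the scalar ΔΔG. Dropout defaults to 0.0: with exact
synthetic labels and the small wild-versus-mutant signal the network must
resolve, dropout noise overwhelmed the gradient in every configuration we
tried; the mechanism remains available for noisy real data.

**Antisymmetry.** Thermodynamics forces ΔΔG(m→w) = −ΔΔG(w→m). The default
concatenation model has no structural antisymmetry — like the original
siamese formulation it must *learn* the property from data, which the
training pipeline encourages by merging every record with its inversion
(sequences swapped, label negated). With `combiner="diff"` the head is
instead applied antisymmetrically,

    y(z) = (head(z) − head(−z))/2 + head(0),   z = enc(wild) − enc(mutant),

which makes y(w,m) + y(m,w) = 2·head(0) an identity and, once the head's
additive parameters are zeroed, makes predictions exactly antisymmetric. A
plain ReLU head cannot be odd, so the explicit antisymmetrization is the
only way to get the exact property without restricting the activation.

## Training

Mean-squared-error loss, Adam (default learning rate 1e-3; the reference
experiments use 3e-3, which was the largest stable rate — 1e-2 diverged),
minibatches of graph pairs processed as disjoint unions with segment
pooling (bit-identical to per-graph processing). After every epoch,
validation Pearson r and RMSE are computed; training stops when validation
RMSE has not improved for `patience` consecutive epochs (default 5, with
`max_epochs` 20 as the classic protocol; the reference experiments extend
this to patience 20 / 100 epochs since the desk-scale task is far from
converged at 20). The parameters returned are those of the best validation
epoch. Minibatch composition is fixed by a seeded shuffle at the start of
training and only the visiting order is re-shuffled per epoch; everything
is deterministic given the seeds.

**Splits.** Cross-validation partitions *proteins*, not records: all
mutations of a scaffold (and the direct/inverse twins of each mutation)
fall in the same fold, so no wild-type sequence leaks across folds and the
held-out antisymmetry audit is honest. For single fits the validation split
is protein-grouped by default, with a record-level alternative
(`val_split="record"`) used by the reference experiments, whose target is
held-out mutations of the *training* scaffolds: a protein-grouped monitor
measures scaffold transfer instead and stops long before within-scaffold
recovery has converged (we measured 0.977 vs 0.984 held-out PCC on
identical data). Grid search enumerates config combinations, ranks by mean
cross-validated RMSE (ties: higher PCC, then enumeration order).

## Evaluation

Pearson r (computed with an exact denominator so that mirrored inputs give
exactly ±1), Spearman ρ (average ranks on ties), RMSE; zero-variance inputs
yield NaN correlations — never a silent 0. Antisymmetry is audited on
paired direct/inverse predictions: r_d−i = Pearson(direct, inverse), ideal
−1, and ⟨δ⟩ = mean(direct + inverse), ideal 0. ⟨δ⟩ is the *signed* mean —
the bias reading consistent with a near-antisymmetric predictor having
⟨δ⟩ near zero — with an absolute-value variant available. Classification
uses rank-statistic AUC and confusion-matrix metrics at a stated threshold
(positive = score > threshold).

## Applications

**Pathogenicity.** A variant is benign iff |ΔΔG| ≤ 1 kcal/mol and
pathogenic otherwise — both stabilizing and destabilizing excursions count,
since either direction of a large stability perturbation can impair
function. The report scores AUC on |ΔΔG|, the threshold-rule confusion
metrics, per-class mean |ΔΔG| and a binned pathogenic-fraction curve
(default |ΔΔG| bin edges 0, 0.5, 1, 2, 3, 4, ∞ — the bin layout is
configurable since no canonical choice exists). Clinical labels are
harmonized textually: any label containing "pathogenic" is positive, any
containing "benign" negative, conflicts dropped; sequences longer than
1000 residues are excluded from clinical screens.

**Growth-temperature classes.** Because the encoder accepts arbitrary
pairs, "mutating" one whole protein into an unrelated one is well defined.
Proteins are classed by organism optimum growth temperature with half-open
boundaries psychrophile < 20 °C ≤ mesophile < 45 °C ≤ thermophile < 80 °C ≤
hyperthermophile. Unordered protein pairs are sampled (seeded, capped at
`max_pairs`) and each is predicted in *both* directions, which keeps the
4×4 count matrix symmetric and lets an architecturally antisymmetric model
produce an exactly antisymmetric mean-ΔΔG matrix. Only relative sign
patterns across cells are interpreted, never absolute values.

## The synthetic test bed

Real training would need a large-scale experimental dataset, a protein
language model and a contact predictor. The generator replaces all three
with an exactly solvable system:

* Proteins: uniform-random sequences (default lengths 30–80) with a
  backbone contact band (p = 0.9 on |i−j| = 1) plus on average one seeded
  long-range contact per residue with p ∈ [0.1, 1.0) — every generated
  contact survives the default cutoff.
* Energy: E = Σ_{i<j, p≥cutoff} p_ij φ(a_i, a_j) + Σ_i ψ(a_i) with a fixed
  symmetric 20×20 pair table φ and 20-entry singleton table ψ, drawn once
  from seeded normals (scales 0.3 and 1.0, putting the ΔΔG standard
  deviation near 1.5 kcal/mol — the magnitude regime of experimental
  stability data). The pair sum is thresholded at the *same* cutoff used
  for graph construction, so the network's receptive field can in principle
  represent the target and recovery quality measures the architecture.
* Labels: ΔΔG = E(mutant) − E(wild), exact to float precision, for an edit
  mixture of 40% single substitutions, 20% multi-point (2–5), 20%
  insertions (1–3 residues), 20% deletions (1–3).
* Mutant contact maps are a deterministic transform of the wild map
  (substitutions: unchanged; deletions: rows/columns removed; insertions:
  backbone-only contacts for the new residues), so no contact predictor is
  needed and the oracle stays exact.
* Records are spread over a pool of distinct scaffolds — by default one
  protein per 200 records, at least 10 — mirroring deep mutational data
  where each scaffold carries many mutations (the real training corpora
  have thousands of mutations per protein).

What the generator does *not* emulate: real contact topology (contacts are
random, not distance-derived), epistasis beyond additivity, label noise,
composition bias, and language-model features. Passing the desk-scale
benchmarks therefore demonstrates that the architecture, optimization and
data plumbing work as designed — not that the model reaches any particular
accuracy on experimental data.

## Reference experiments (`ddgraph.benchmarks`)

* **Recovery**: 5 000 records (4 000 train / 1 000 test, the test being
  further mutations of the training scaffolds), default architecture,
  record-split early stopping, Adam 3e-3, batch 32, ≤100 epochs. Singleton
  energy (φ ≡ 0) isolates a target the architecture can represent exactly;
  the full energy adds the contact-pair term, which the normalized
  aggregation can only approximate (the weighted mean discards the
  neighbour weight *sum*, so per-node pair energies are approximated via
  composition context).
* **Learned antisymmetry**: 2 000 singleton-energy records per seed (1 600
  train / 400 test), three seeds; one model per seed trained on
  antisymmetrically augmented data, one on direct-only data, identical
  optimisation budget (30 epochs, no early stop); both audited on the same
  held-out direct/inverse pairs. The singleton energy is used so that
  regression error does not confound the audit (for symmetric errors
  r_d−i ≈ −PCC²). The problem sizes here are the package's desk-scale
  defaults; they keep the full suite in the minutes range on one CPU.

## Numerical choices and edge cases

* All float64; the autodiff engine is deterministic, so equal seeds give
  byte-identical checkpoints (serialized with fixed zip timestamps).
* Layer-norm epsilon 1e-5; L2-normalization leaves all-zero rows at zero.
* Pearson r uses the exact-denominator route when the two centred square
  sums coincide, making r(x, −x) = −1 and r(x, x) = 1 exact identities.
* Ties in grid search break toward higher mean validation PCC, then
  enumeration order. Fold assignment shuffles the sorted unique protein ids
  with the training seed, then deals them round-robin.
* Empty graphs are rejected; an isolated node contributes its self-term
  only. Duplicate (wild, mutant) pairs after augmentation are kept with a
  warning, matching a blind merge.
* Edit notation positions are 1-based in text, 0-based internally;
  insertions anchor *after* the stated position (position −1 prepends),
  which makes inversion to a deletion unambiguous. Overlap is checked on
  wild coordinates with insertions occupying inter-residue slots.
* Sequence identity: Biopython global alignment, match 1 / mismatch 0 /
  gap open −10 / extend −0.5; identity = identical columns / alignment
  length. The <25% screen compares wild sequences only.

## Known limitations

* The energy oracle is additive; nothing here probes non-additive coupling
  between simultaneous edits.
* Inserted residues receive backbone-only contacts, so long insertions are
  energetically blander than real ones.
* The one-hot fallback cannot transfer across scaffolds the way language-
  model embeddings might; protein-grouped validation scores with one-hot
  features mainly reflect composition similarity.
* OGT analysis on synthetic data checks machinery (sampling, symmetry,
  sign bookkeeping), not biology.
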