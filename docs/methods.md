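# Methods

`dbgcnmda` predicts microbe–disease associations by link prediction on a
bipartite network with a dual-branch graph convolutional encoder. This note
documents the model, its numerical choices, the synthetic benchmark, and
the limits of what the benchmark demonstrates.

## Problem setting

The observed data are a binary association matrix `A` (m microbes × n
diseases; `A[i,j] = 1` when an association between microbe *i* and disease
*j* has been experimentally reported) and, optionally, two square
functional-similarity matrices: microbe–microbe (e.g. derived from shared
protein functions) and disease–disease (e.g. derived from disease-gene
overlap). The task is to rank the unobserved cells of `A` by how likely
they are to be true associations. The reference regime is a curated
database of roughly 450 associations between 292 microbes and 39 diseases
— extremely sparse (≈4% density) and heavily imbalanced.

## Pipeline

### 1. Similarity construction

Each microbe's *interaction profile* is its row of `A`; each disease's is
its column. The Gaussian interaction-profile kernel (GAPK) similarity
between two entities is

    GS(i,j) = exp(−Θ · ‖V_i − V_j‖²),    Θ = N / Σ_k ‖V_k‖²,

where N is the number of entities of that type. The bandwidth is the
inverse mean squared profile norm, so the exponent is dimensionless and
the diagonal is exactly 1. (A `raw` bandwidth mode, Θ equal to the mean
squared norm itself, is kept as a sensitivity option; the normalized form
is the default and the convention of the GIP-kernel literature.)

GAPK similarity (network topology) is fused entrywise with functional
similarity FS (biology): the fused entry is `(FS+GS)/2` where FS is
nonzero and `GS` alone where FS is zero or absent. Zero functional entries
are treated as *unknown*, not as evidence of dissimilarity.

### 2. Node features: random walk with restart

Features come from random walk with restart (RWR) on each fused similarity
network. With `P` the row-normalized transition matrix and restart
probability kept at `1 − γ`, the stationary visiting probabilities solve

    M = (1−γ)·I + γ·M·P    ⇒    M = (1−γ)(I − γP)⁻¹.

Row *i* is entity *i*'s feature vector — a probability distribution that
encodes the global topology around it. Defaults: γ = 0.9 (heavily
network-weighted; the value is not dictated by the method and is exposed
in the configuration), closed-form solve below 2000 nodes, otherwise
fixed-point iteration to tolerance 1e-6 (cap 1000 iterations). Entities
with all-zero similarity rows receive a pure-restart (one-hot)
distribution, with a warning.

Disease networks are small, so disease feature rows (n-dimensional) are
expanded with polynomial features: all monomials of total degree ≤ 2 in
graded-lexicographic order, including the constant. For n = 39 this gives
C(41,2) = 820 monomials; generation continues with degree-3 monomials, in
order, until the target width (default 1000) is reached. If the base
monomial set already exceeds the target, the highest-variance features are
kept (ties broken by generation order). Both rules are deterministic, so
the expansion is reproducible.

### 3. Dual-branch GCN encoder

Every GCN layer applies the symmetric-normalized propagation with self
loops: with `S̃ = I + S` and `D̃` its degree matrix,

    E ← δ( D̃^(−1/2) S̃ D̃^(−1/2) · E · W ).

Microbe and disease features are first mapped to a common width by
per-type linear projections (`hidden_dims[0]`, default 256). Then:

* **Global branch** — propagation over the heterogeneous graph with block
  adjacency `[[0, A], [Aᵀ, 0]]`: microbes aggregate their associated
  diseases' representations and vice versa.
* **Local branch** — two independent chains over the microbe-similarity
  and disease-similarity graphs, initialized with the global branch's
  output, refining each node with same-type neighborhood structure.

Layer k of the global chain outputs width `hidden_dims[min(k, last)]`
(extra depth repeats the final width); local layers keep their input
width. Ablation variants drop branches: `GlobalGCNMDA` (global only),
`LocalGCNMDA` (local only, fed the projected features), `FNMDA` (neither —
projections straight into the decoder, structurally free of propagation
weights).

**Activation.** The GCN nonlinearity δ defaults to `tanh`. The similarity
graphs here are dense and the informative part of a propagated signal is
centered; a one-sided activation (ReLU) discards the negative half at
every layer and, in our experiments on the synthetic benchmark, dropped
held-out AUC by ≈0.05 and made training prone to collapse onto the
constant solution. ReLU and identity remain available via
`gcn_activation`; the decoder's hidden layers use ReLU.

### 4. Decoder, scoring and loss

Three dense layers per node type (shared widths, separate weights; ReLU on
the first two, linear last) map embeddings to final representations, and
the association score is bilinear: `Ã = R′_m · R′_dᵀ`.

Training minimizes the positive-enhanced reconstruction loss

    L = ‖A′ − Ã‖²_F + μ‖W‖²₂,

where `A′` equals α (> 0, default 1.0) at retained training positives and
0 everywhere else — including held-out positives, which are deliberately
zeroed so the training view carries no information about them. α raises
the margin of the rare positive class against the overwhelming zero
background; μ (default 5e-4) decays all trainable weights. A
`exclude_test_from_loss` option masks held-out cells out of the Frobenius
sum entirely instead of zero-targeting them; it made no measurable
difference on the synthetic benchmark and the literal zero-target form is
the default.

Optimization is full-batch Adam (default learning rate 1e-3, 500 epochs)
with early stopping on validation AUPR (patience 50). All weights start
from symmetric uniform (Glorot-style fan-based) initialization seeded by
the run configuration; a fixed seed reproduces every score bitwise.

**Feature scaling.** Model inputs are column-standardized before the
projections (`standardize_features`, default on). RWR rows have entries of
order 1/N; without rescaling, gradients start many orders of magnitude too
small and full-batch training reliably collapses to the all-zero
prediction. Standardization is part of model input handling only — the
`rwr_features` operation itself still returns probability rows.

## Evaluation protocol

All known positives plus an equal number of negative pairs, sampled
uniformly from the zero cells, form the labeled universe (the balanced
450/450 design of the reference dataset). A `test_fraction` (default 0.2)
of both sets is held out as an independent test set; the rest is split
into `n_folds` (default 5) equal folds. For each fold, a model is trained
with that fold's positives *and* the test positives removed, and evaluated
on the fold's held-out positives against its held-out negatives; reported
CV metrics are fold means. A final model (only test positives held out)
provides independent-test metrics; both appear in the report because
protocols in this literature are frequently ambiguous about which set
headline numbers refer to.

AUC uses the midrank tie convention; AUPR is step-wise average precision.
Both delegate to scikit-learn and are cross-checked against exhaustive
brute-force oracles in the test suite.

**Leakage control.** By default every derived quantity — GAPK
similarities, fusion, RWR features, polynomial expansion, and the
heterogeneous propagation graph — is recomputed per fold from the masked
training matrix, so a held-out edge is indistinguishable from a
never-present edge (this is asserted exactly in the tests). A
`per_fold_features=False` mode computes everything once from the full
matrix; it reproduces the compute-once protocol common in this literature
but lets held-out edges leak into the kernel similarities, and is provided
for comparison only.

## Synthetic benchmark

`synthetic_data.generate` plants recoverable structure: each entity
carries a rank-r latent factor vector (standard normal; defaults m = 292,
n = 39, r = 4), the true affinity is `logistic(3·z)` of the scaled factor
inner product `z`, and edges are drawn so the expected positive count
matches the target density (default ≈450): cells above the
(1 − density)-affinity-quantile carry a high edge rate (0.97 purity), the
rest share a small noise floor emulating spurious entries in a curated
database. Functional similarities are cosine similarities of the true
factors with negatives clipped to zero — matching the sparse, right-skewed
shape of real functional-similarity matrices — plus clipped symmetric
Gaussian noise (sd 0.1) and a random 10% of entries zeroed so the fusion
rule's fallback branch is exercised. Because the scorer is itself
bilinear, recovery is achievable in principle and the benchmark is a fair
end-to-end oracle.

The benchmark configuration (`benchmark_config`) uses a 64-wide
projection, hidden widths [64, 32], a 2-layer GCN stack, learning rate
1e-2, 600 epochs with patience 150 — selected on validation AUPR during
development; the planted rank-4 signal saturates this smaller model and a
full 5-fold run takes tens of seconds per fold on one CPU.

What passing the benchmark does and does not show: the generator matches
the reference network's scale, sparsity and balanced-evaluation design,
and its similarity matrices are honest noisy proxies of the latent
structure. It does not emulate real taxonomies, hub-dominated degree
distributions, literature-driven reporting bias, or functional
similarities that are only weakly coupled to association structure. One
consequence is measurable: with no propagation layers at all (depth 0),
the dense model still reaches ≈0.66 AUC on synthetic data because the RWR
features themselves share latent factors with the planted truth, whereas
on the real sparse network the same ablation is reported near chance
(≈0.58). Synthetic feature informativeness and depth-0 chance-level
behavior cannot both hold at once; we kept the features informative, since
structure recovery is the benchmark's purpose.

## Numerical and degenerate-input choices

* Similarity matrices must be symmetric within 1e-10; file readers repair
  asymmetry by averaging and clip entries to [0, 1], warning in both cases.
* GAPK of an all-zero matrix is undefined (error); the association-matrix
  type itself rejects networks with no positives.
* RWR probability rows are clipped at zero and renormalized after the
  linear solve to absorb roundoff at the 1e-16 level.
* Prediction ranking breaks score ties by microbe label, so output files
  are bit-reproducible.
* Fold sizes differ by at most one; splits, initialization and training
  are fully determined by the configuration seed.

## Known limitations

* Full-batch dense linear algebra: fine for 10³-node networks, not
  engineered for 10⁵-node graphs (no sparse propagation, no minibatching).
* Transductive only — a disease or microbe absent from the training
  network has no embedding.
* Hyperparameters were chosen on synthetic validation data; real
  deployments should re-tune γ, α, μ, depth and widths by cross-validation
  on their own network.
* Functional-similarity computation from primary sources (protein
  networks, disease-gene sets) is out of scope; the matrices are consumed
  as optional inputs.
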