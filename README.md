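# dbgcnmda

Dual-branch graph convolutional link prediction for microbe–disease
association networks.

Microbial communities are implicated in a wide range of human diseases,
but confirming an individual microbe–disease association experimentally is
slow and expensive. Given a small curated network of known associations
(the reference regime is ~450 associations between 292 microbes and 39
diseases), `dbgcnmda` ranks the unobserved microbe–disease pairs by
predicted association strength, so that laboratory effort can be focused
on the most promising candidates. It is aimed at computational biologists
working on network-based association inference.

## Method

For an m×n binary association matrix **A** with optional functional
similarity matrices for microbes and diseases:

1. **Similarity fusion** — Gaussian interaction-profile kernel similarity
   from the rows/columns of **A**, `GS(i,j) = exp(−Θ‖V_i−V_j‖²)` with
   `Θ = N/Σ‖V_k‖²`, fused entrywise with functional similarity:
   `(FS+GS)/2` where FS ≠ 0, else GS.
2. **Node features** — random walk with restart on each fused similarity
   network, `M = (1−γ)(I−γP)⁻¹`; disease features are expanded with
   polynomial (monomial) features from n to a 1000-dim space.
3. **Dual-branch GCN** — each layer computes
   `E ← δ(D̃^(−1/2)(I+S)D̃^(−1/2) E W)`. A *global* branch propagates over
   the heterogeneous bipartite graph `[[0,A],[Aᵀ,0]]`; a *local* branch
   refines the result over the two homogeneous similarity graphs.
4. **Scoring** — three dense layers per node type, then the bilinear
   score `Ã = R′_m R′_dᵀ`, trained with the positive-enhanced loss
   `‖A′−Ã‖²_F + μ‖W‖²` where A′ carries α at training positives and 0
   elsewhere.

Evaluation follows the balanced design of the field: all positives plus
an equal number of sampled negative pairs, an independent test split, and
k-fold cross-validation with AUC/AUPR. By default every similarity and
feature is recomputed per fold from the masked training matrix, so
held-out edges cannot leak into training. Ablation variants (`FNMDA`,
`GlobalGCNMDA`, `LocalGCNMDA`) and a GCN-depth sweep are built in.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Generate a synthetic network with planted low-rank structure at the
reference scale and cross-validate the full model:

```bash
dbgcnmda synth --m 292 --n 39 --rank 4 --density 0.0395 --seed 0 --out-dir data/
# wrote 292x39 network with 443 positives to data

cat > run.yaml <<EOF
hidden_dims: [64, 32]
n_gcn_layers: 2
epochs: 600
patience: 150
learning_rate: 0.01
seed: 0
EOF

dbgcnmda cv --assoc data/A.tsv --microbe-fs data/MFS.tsv \
    --disease-fs data/DFS.tsv --config run.yaml --out report.json
# DBGCNMDA: cv auc 0.8735 aupr 0.8728 (test auc 0.8756 aupr 0.8725)
```

The CV numbers are means over the five validation folds: an AUC of 0.87
means a randomly chosen held-out true association outranks a randomly
chosen held-out negative pair 87% of the time; AUPR is the corresponding
area under the precision–recall curve against an equal-sized negative
sample. `report.json` additionally contains per-fold metrics and the
independent-test results.

The same pipeline is available as a library:

```python
from dbgcnmda import PlantedModel, generate, benchmark_config, cross_validate

A, mfs, dfs, affinity = generate(PlantedModel(seed=0))
report = cross_validate(A, mfs, dfs, benchmark_config(0), variant="DBGCNMDA")
print(report.auc, report.aupr)
```

Other subcommands: `dbgcnmda similarity` (GAPK + fusion matrices),
`dbgcnmda featurize` (RWR features and the polynomial expansion),
`dbgcnmda train` / `dbgcnmda predict` (fit a final model, write a ranked
candidate table per disease).

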