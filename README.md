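# mgcna

Multi-view graph convolutional prediction of miRNA–drug
resistance/sensitivity associations.

MicroRNAs modulate how tumours respond to chemotherapy: specific miRNAs
confer resistance or restore sensitivity to specific drugs.
Experimentally validated miRNA–drug associations (MDAs) are sparse, so
`mgcna` scores unobserved miRNA–drug pairs by fusing several independent
descriptions of both entity types — a *multi-view* formulation for
computational biologists who want to prioritise candidate miRNAs for a
drug (or drugs for a miRNA) before bench validation.

## Model

Each side of the bipartite problem gets up to three similarity views:

| view | entities | built from |
| --- | --- | --- |
| `mirna_seq` | miRNA | cosine similarity of 84-dim k-mer frequency vectors (k = 1, 2, 3) |
| `mirna_gene` | miRNA | Gaussian interaction-profile kernel (GIPK) over miRNA–gene profiles |
| `mirna_mda` | miRNA | GIPK over known-association profiles (training folds only) |
| `drug_struct` | drug | Tanimoto similarity of 167-bit MACCS fingerprints |
| `drug_gene` | drug | GIPK over drug–gene profiles |
| `drug_mda` | drug | GIPK over known-association profiles (training folds only) |

GIPK similarity between interaction profiles is
`exp(−γ‖IP_i − IP_j‖²)` with `γ = γ′ / mean‖IP‖²` and `γ′ = 1`.  Each
similarity matrix `G` is thresholded into a graph adjacency,
`A(i,j) = 1 iff G(i,j) ≥ θ` (default θ = 0.5, per view), whose unit
diagonal provides self-loops.

A shared random feature matrix `X ∈ R^{n×h}` is encoded per view by a
two-layer graph convolution

```
Z_v^(l) = ReLU( D̂_v^-1/2 Â_v D̂_v^-1/2 · Z_v^(l-1) · W_v^(l) )
```

with view- and layer-specific weights (`h → h/2 → h/4`).  Per entity,
view embeddings are fused by learned softmax attention
`s_v = qᵀ tanh(W_a z_v + b_a)`, `α = softmax(s)`, `z = Σ_v α_v z_v`.
A pair `(zm, zd)` is decoded through a two-layer MLP on the
multi-relational input `[zm + zd ‖ zm ⊙ zd ‖ zm ‖ zd]` with a logistic
output, trained with balanced binary cross-entropy (Adam, lr = 5e-4,
weight decay = 5e-4, dropout 0.5).  Everything is dense NumPy with
analytic gradients; a finite-difference check in the test-suite guards
the backward pass.

Evaluation follows balanced 5-fold cross-validation (negatives sampled
1:1 from unknown pairs) with the two association-derived views rebuilt
per fold from training positives only, three cold-start protocols
(held-out miRNAs, drugs, or both), and a case-study mode that masks one
drug entirely and ranks its candidate miRNAs.  Because view
informativeness is data-dependent, the pipeline includes a model
selection step that compares candidate view combinations by CV before
the final run (`experiment.run_benchmark`).

## Worked example

No external data is required: the synthetic module generates a dataset
with four planted association blocks whose sequences, fingerprints and
gene profiles all leak block identity (see `examples/`).

```
$ python examples/02_cross_validation.py
fold 0: AUC 0.8033  AUPR 0.7825
fold 1: AUC 0.8140  AUPR 0.7931
fold 2: AUC 0.8301  AUPR 0.7835
fold 3: AUC 0.7953  AUPR 0.7307
fold 4: AUC 0.7836  AUPR 0.7440
mean:   AUC 0.8053  AUPR 0.7668
```

A mean AUC of ~0.81 approaches this generator's Bayes ceiling (~0.82: a
perfect oracle for the planted blocks cannot do better because
cross-block positives exist), i.e. the pipeline recovers essentially all
of the planted signal.  `examples/04_case_study.py` masks the
best-connected drug and recovers 5 of its 26 hidden partners within the
top 15 of 200 candidates (chance: ~2).

The same workflows are available from the shell:

```
mgcna simulate --out data/ --seed 1
mgcna cv --data data/ --mode random --folds 5 --seed 1 --out run/
mgcna case-study --data data/ --drug drug016 --top 15 --seed 1 --out case/
```

Every run directory receives the resolved configuration and seed;
re-running with them reproduces outputs exactly.

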