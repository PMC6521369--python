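# pcnet — confounder correction for gene co-expression networks

Technical and unwanted biological variation (batch, RNA quality, mapping
bias) affects many genes at once, inducing broad spurious correlation that
network learning methods readily mistake for co-expression. `pcnet`
implements principal-component confounder correction for expression data
prior to network reconstruction, together with everything needed to study
its effect: a scale-free Gaussian graphical-model simulator with injected
latent confounders, graphical-lasso and signed weighted co-expression
(WGCNA-style) reconstruction over parameter paths, and edge-level
evaluation against ground-truth gene pairs.

The premise: a sparse, scale-free co-expression network never spreads
signal broadly enough across genes to dominate the leading principal
components of the expression matrix, so those components capture latent
confounders instead — and can be regressed out per gene without destroying
the network signal.

## Method

For an expression matrix *E* (genes × samples), per-gene correction with
the top *p* principal components is the linear model

```
E_i = μ_i + β_i · L_{1:p} + ε_i          Ê_i = E_i − (μ_i + β_i · L_{1:p})
```

where *L* are the component scores (right-singular vectors) of the
standardized matrix and *Ê_i* the residual used for reconstruction. The
number of components *p* is chosen by a permutation scheme (parallel
analysis in the style of Buja & Eyuboglu): the observed variance-explained
proportion of each component is compared against the (1 − α) quantile of
the same proportion in data whose gene rows were independently permuted —
permutation destroys gene–gene correlation while preserving every gene's
marginal — and *p* is the longest significant prefix.

Networks are then inferred either by the graphical lasso (L1-penalized
precision estimation on the gene correlation matrix; edges are nonzero
off-diagonal entries, swept over a penalty path λ) or by signed weighted
co-expression analysis (adjacency ((1 + r)/2)^β, topological overlap,
average-linkage clustering with a static cut; modules become cliques).
Inferred edges are scored against ground truth — simulated adjacency or
pathway co-membership pairs from GMT files — as

```
FDR = FP / (TP + FP)        FNR = FN / (TP + FN)
```

## Worked example

```python
from pcnet import SimConfig, PermutationConfig, correct, simulate_dataset, glasso_path
from pcnet.core_io import GroundTruthEdges
from pcnet.evaluate import evaluate_network

sim = simulate_dataset(SimConfig(seed=1))          # 300 genes x 200 samples, 5 confounders
result = correct(sim.confounded_expr, PermutationConfig(seed=1))
print(f"components removed: p = {result.p}")
print(f"variance explained by removed components: "
      f"{100 * result.variance_explained[:result.p].sum():.1f}%")

truth_net = sim.true_network()
truth = GroundTruthEdges(truth_net.edges, {p: 1 for p in truth_net.edges})
universe = frozenset(sim.clean_expr.gene_ids)
for arm, expr in (("uncorrected", sim.confounded_expr),
                  ("pc_corrected", result.residuals)):
    for lam, net in glasso_path(expr):
        report = evaluate_network(net, truth, universe)
        fdr = "n/a" if report.fdr != report.fdr else f"{report.fdr:.3f}"
        print(f"{arm:>13}  lambda={lam:.1f}  edges={net.n_edges:>5}  FDR={fdr}")
```

prints

```
components removed: p = 5
variance explained by removed components: 68.9%
  uncorrected  lambda=0.7  edges= 2548  FDR=0.982
  uncorrected  lambda=0.6  edges= 2989  FDR=0.983
  uncorrected  lambda=0.5  edges= 3274  FDR=0.983
 pc_corrected  lambda=0.7  edges=    0  FDR=n/a
 pc_corrected  lambda=0.6  edges=    3  FDR=0.000
 pc_corrected  lambda=0.5  edges=   19  FDR=0.000
```

The permutation scheme finds exactly the five injected confounders.
Uncorrected, the confounded data yield thousands of edges, ~98% of them
false; after correction the networks are far sparser and essentially free
of false discoveries (an FDR of `n/a` marks an empty network, where the
rate is undefined).

The same pipeline is available from the shell:

```sh
pcnet pipeline --genes 300 --samples 200 --confounders 5 --seed 1 --out run/
pcnet simulate --genes 300 --samples 200 --confounders 5 --seed 1 --out sim/
pcnet correct --expr sim/confounded.tsv --method pc --seed 1 --out corrected/
pcnet reconstruct --expr corrected/residuals.tsv --method glasso --out nets/
pcnet evaluate --edges nets/ --universe sim/genes.txt \
    --truth sim/truth_edges.tsv --out report.tsv
```

Every command writes a JSON config echo (version, full configuration,
config hash, seed) next to its outputs, so any run can be reproduced
bit-for-bit.

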