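# Methods

## Model and rationale

Observed expression is modelled as sparse network signal plus low-rank
confounding plus noise. The network is a Gaussian graphical model: genes
are jointly Gaussian with precision matrix Ω whose off-diagonal support is
the co-expression graph. Confounders are latent per-sample variables that
load additively on subsets of genes. Because a scale-free, sparse graph
concentrates signal in small neighbourhoods while confounders act broadly,
the leading principal components of the (standardized) expression matrix
align with the confounders, not the network; removing them per gene by
ordinary least squares leaves the network signal largely intact. This is a
premise, not a guarantee: it degrades for dense or highly connected
subgraphs, for very small gene sets, and whenever a biological factor of
interest is itself broad (see Limitations).

## Choosing the number of components

`estimate_num_pc` is parallel analysis in the Buja–Eyuboglu style:

1. standardize each gene to mean 0, sd 1 (ddof = 1);
2. compute observed variance-explained proportions of the first
   min(genes, samples) − 1 components from singular values;
3. for each of `n_permutations` replicates (default 20), permute the
   entries of every gene row independently — destroying gene–gene
   correlation, preserving marginals — and recompute the proportions;
4. a component is significant when its observed proportion strictly
   exceeds the (1 − α) empirical quantile (quantile method `higher`,
   default α = 0.10) of its own permuted proportions;
5. return the longest significant prefix.

Replicate b draws from the stream seeded by (seed, b), so the estimate is
reproducible and replicates are independent.

Calibration under an iid null is bounded by exchangeability: the observed
first-component proportion is exchangeable with its B permuted copies, so
the false-detection probability per run cannot drop below roughly
2/(B + 1) (~9.5% at B = 20, α = 0.10) no matter how the quantile is
estimated. Empirically the scheme returns p = 0 on pure noise in ~90% of
runs and recovers 1–5 planted high-SNR factors essentially always at
200 genes × 80 samples. On *correlated* data the scheme detects genuine
correlation too: on clean simulated networks of 300 genes it returns
p ≈ 30. That is expected behaviour of parallel analysis at finite
dimension, and it is why the method's value shows on *confounded* data,
where the confounder components dominate and the prefix stops right after
them (p = 5 for 5 injected confounders in the standard instance).

## Residualization

Scores are the top-p right-singular vectors of the standardized matrix
(sample-space components), with signs fixed so each score's
largest-magnitude entry is positive. The per-gene regression is run on the
*original* scale — the components summarize standardized data, but the
residuals returned are residuals of the data as given
(`on_standardized=True` switches to the standardized target). Because each
standardized gene row is centred, the scores are orthogonal to the
intercept and the fit reduces to μ_i = mean(E_i), β_i = E_i · L; residuals
are orthogonal to every removed score to machine precision. Covariate
correction (`covariate_residualize`) is the same regression with observed
covariates in place of scores; `select_covariates` keeps covariates whose
mean (or median) per-gene adjusted R², fit singly, reaches a threshold
(default 0.01, i.e. 1% of expression variance).

## Simulator

`simulate_dataset` composes four seeded stages (sub-streams derived from
the master seed by fixed offsets):

1. **Graph** — Barabási–Albert preferential attachment
   (`attachment_edges` per new node, default 2), giving a connected graph
   with m(n − m) edges and power-law degree tail (exponent ≈ 3).
2. **Precision** — off-diagonal entries uniform in `edge_weight_range`
   (default 0.3–1.0) with random signs exactly on the graph support;
   diagonal = absolute row sum + 0.1. Strict diagonal dominance guarantees
   positive definiteness without touching the support.
3. **Expression** — iid multivariate Gaussian draws via the precision
   Cholesky factor (the covariance is never formed).
4. **Confounding** — each of `n_confounders` confounders draws per-sample
   values N(0, `confounder_sd`²), picks a uniform random affected subset
   of `round(affected_fraction · n_genes)` genes (subsets may overlap, as
   batch-like artifacts do), and adds loadings ~ N(0, 1) times the
   confounder to those genes.

The default configuration — 300 genes × 200 samples, 5 confounders,
affected fraction 0.3, confounder sd 3 — is the standard instance used by
the package's own experiments; it reproduces the qualitative regime of a
full-size run (thousands of genes, hundreds of samples) at a size where
the whole pipeline can be exercised twenty times over in minutes on one
CPU. What the simulator does **not** emulate: count noise
(negative-binomial mean–variance), library-size and composition effects,
non-Gaussian marginals, and confounders correlated with signal. Passing
tests therefore demonstrate the linear-Gaussian mechanism of confounding
and its removal, not robustness to every property of real RNA-seq data.

`toy_example` is a 20-gene × 50-sample × 1-confounder fixture on a
module-structured graph (six triangles plus one pair) rather than a
preferential-attachment tree: tree hubs have intrinsically weak partial
correlations under the diagonal-dominance construction, whereas small
modules give every true edge a strong partial correlation, making the toy
a clean before/after demonstration.

## Network reconstruction

**Graphical lasso.** The solver (scikit-learn's) maximizes the penalized
Gaussian log-likelihood with the penalty on off-diagonal precision entries
only, applied to the gene *correlation* matrix so λ is scale-free. Edges
are entries with |θ_ij| > `edge_tolerance` (default 1e-8, separating
numerical zeros from true nonzeros). The duality-gap stopping criterion
sums over matrix entries, so the default `convergence_tol` (1e-2) is tight
for hundreds of genes; tests on 3-variable instances use 1e-6. Two solver
modes are exposed: coordinate descent (default, scales better) and LARS
(steadier on small or very sparse problems — the coordinate solver's dual
gap can stall marginally negative near machine precision). The default
penalty path (0.7, 0.6, 0.5) stays above the region where heavily
confounded correlation matrices become numerically singular for the
solver. Path points are solved independently from the same correlation
matrix; by strict convexity this matches a warm-started sweep within
solver tolerance. Non-convergence raises an error naming the penalty.

**Signed WGCNA-style modules.** Signed adjacency a_ij = ((1 + r_ij)/2)^β
(Pearson r; β default 6, the conventional signed power), unsigned
topological overlap

    tom_ij = (Σ_{u∉{i,j}} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

average-linkage hierarchical clustering of 1 − TOM, and a *static* cut at
each height in `cut_heights`: clusters merged below the cut with at least
`min_module_size` genes (default 30) become modules, everything else is
the grey (unassigned) module. Dynamic tree cutting is deliberately out of
scope — a family of static cuts is what a cut-height sweep means. One
clustering is computed per expression matrix and reused across cuts.
SciPy's linkage resolves ties deterministically, so module assignments are
reproducible. Modules are interpreted as cliques when converted to edge
lists, the standard reading of module membership as pairwise association.

## Evaluation

Ground truth is either the simulator's adjacency or pathway co-membership:
any gene pair sharing at least one pathway is a true relationship, with
`db_count` recording how many distinct databases (one GMT file = one
database) support the pair, so "shared" truth can be restricted to pairs
in ≥ 2 databases. Truth is restricted to the evaluation gene universe
*before* counting, so FN never charges a network for genes outside its
input. FDR = FP/(TP + FP) and FNR = FN/(TP + FN) are reported as NaN when
their denominator is zero, and such points are excluded from summaries —
substituting 0 would award perfect scores to empty networks. Topology
diagnostics: density, mean local clustering coefficient over nodes of
degree ≥ 2 (the coefficient is undefined below that; the convention is
recorded in the report's params), and hub count (degree strictly above the
0.95 degree quantile by default, absolute override available).

## Numerical choices

- Variance for gene selection: unbiased (n − 1) estimator; any rescaling
  leaves the ranking unchanged. Ties break by input gene order.
- Gene identifiers match by exact, case-sensitive string equality.
- Singular-vector signs fixed by the largest-magnitude entry; within
  numerically tied singular values the decomposition's ordering is kept.
- Zero-variance genes are an error for standardization/correlation
  operations (filter first with `select_most_variable`).
- Seeds: every stochastic stage accepts one integer seed and derives
  sub-streams with `SeedSequence`; identical configuration implies
  byte-identical outputs.

## Limitations

- The component-count estimate is anti-conservative on small gene sets:
  at toy scale (tens of genes) network correlation itself is broad enough
  to be detected, and automatic correction over-corrects (the toy
  demonstration therefore removes the known confounder count). Hundreds
  of genes or more are the intended regime.
- Under an iid null the permutation scheme's false-detection rate per run
  is bounded below by ~2/(B + 1); calibration better than ~90% at the
  defaults is not attainable by construction.
- Removing components can remove biology when the scale-free assumption
  fails (dense subgraphs, global signals such as large case/control
  differences); correction should be inspected, not applied blindly.
- The uncorrected arm of heavily confounded data is close to singular;
  the graphical-lasso solver needs moderate-to-large penalties there, and
  the default path reflects that.
- No count-based simulation, no eigengene/soft-threshold selection, no
  dynamic tree cut, no protection of a known primary variable during
  correction.
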