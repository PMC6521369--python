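"""Principal-component and covariate-based correction of expression data.

The model: each gene's expression across samples is a linear combination of
a small number of broad latent factors (technical artifacts, batch, sample
quality) plus sparse network signal and noise,

    E_i = mu_i + beta_i . L_{1:p} + e_i ,

where L_{1:p} are the top-p principal component scores of the standardized
expression matrix (sample-space right-singular vectors). Under a sparse,
scale-free network the leading components are dominated by confounding, so
the per-gene OLS residuals

    E_i - (mu_i + beta_i . L_{1:p})

retain the network signal while removing broad artifacts. The number of
components p is chosen by Buja-Eyuboglu-style parallel analysis: compare
the observed per-component variance-explained proportions against those of
row-permuted data (permutation breaks gene-gene correlation but preserves
each gene's marginal distribution).

Components are computed from the standardized matrix (each gene centred and
scaled to unit sd) but residuals are taken on the original scale, i.e. the
regression is of the raw gene values on the standardized-matrix scores.
``pc_residualize(..., on_standardized=True)`` residualizes the standardized
matrix instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pcnet.core_io import CovariateTable, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationConfig:
    """Knobs of the parallel-analysis permutation scheme.

    n_permutations : number of row-permuted replicates (default 20).
    alpha : per-component significance level (default 0.10); a component is
        significant when its observed variance proportion exceeds the
        (1 - alpha) empirical quantile of its permuted proportions.
    seed : master seed; permutation b uses the stream derived from
        (seed, b), so runs are reproducible and parallelizable.
    """

    n_permutations: int = 20
    alpha: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class CorrectionResult:
    """Residual expression plus everything needed to reproduce the fit."""

    residuals: ExpressionMatrix
    p: int
    scores: np.ndarray  # samples x p, the regressors L_{1:p}
    variance_explained: np.ndarray  # per-component proportions, full spectrum
    per_gene_intercept: np.ndarray  # mu_i, length genes
    per_gene_coefficients: np.ndarray  # beta_i, genes x p


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centre and scale each gene row to mean 0, sd 1 (ddof=1)."""
    sd = expr.values.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [expr.gene_ids[i] for i in zero[:10]]
        raise ValueError(f"zero-variance genes (filter first): {names}")
    z = (expr.values - expr.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return expr.with_values(z)


def _variance_proportions(matrix: np.ndarray, ndf: int) -> np.ndarray:
    s = np.linalg.svd(matrix, compute_uv=False)
    s2 = s[:ndf] ** 2
    return s2 / s2.sum()


def estimate_num_pc(expr: ExpressionMatrix, cfg: PermutationConfig) -> int:
    """Number of significant principal components by parallel analysis.

    Procedure: standardize; take the observed variance-explained proportion
    of each of the first min(genes, samples) - 1 components; for each of
    ``cfg.n_permutations`` replicates permute the entries within every gene
    row independently and recompute the proportions; component i is
    significant when its observed proportion strictly exceeds the
    (1 - alpha) empirical quantile (``method='higher'``) of its permuted
    proportions. The returned p is the length of the longest prefix of
    significant components, matching the convention that only leading
    components are removed.
    """
    if expr.n_samples < 3 or expr.n_genes < 2:
        raise ValueError("need >= 3 samples and >= 2 genes")
    z = standardize(expr).values
    ndf = min(z.shape) - 1
    obs = _variance_proportions(z, ndf)
    if not np.isfinite(obs).all():
        raise ValueError("degenerate matrix: rank < 2 after standardization")
    permuted = np.empty((cfg.n_permutations, ndf))
    for b in range(cfg.n_permutations):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, b]))
        permuted[b] = _variance_proportions(rng.permuted(z, axis=1), ndf)
    thresholds = np.quantile(permuted, 1 - cfg.alpha, axis=0, method="higher")
    significant = obs > thresholds
    p = int(np.argmin(significant)) if not significant.all() else ndf
    logger.info(
        "parallel analysis: p=%d (B=%d, alpha=%.3g, seed=%d)",
        p, cfg.n_permutations, cfg.alpha, cfg.seed,
    )
    return p


def _component_scores(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Right-singular vectors (samples x components) of the standardized
    matrix, with deterministic signs, and the variance proportions."""
    z = standardize(expr).values
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = vt.T  # samples x components, orthonormal columns
    # deterministic sign: largest-magnitude entry of each score vector > 0
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    s2 = s**2
    return scores, s2 / s2.sum()


def pc_residualize(
    expr: ExpressionMatrix, p: int, on_standardized: bool = False
) -> CorrectionResult:
    """Regress the top-p component scores out of every gene.

    Scores come from the standardized matrix; the per-gene OLS is on the
    original scale unless ``on_standardized``. Because each gene row of the
    standardized matrix is centred, the scores are orthogonal to the
    intercept and the fit separates into mu_i = mean(E_i) and
    beta_i = E_i . L (L orthonormal).
    """
    max_p = min(expr.n_genes, expr.n_samples) - 1
    if not 0 <= p <= max_p:
        raise ValueError(f"p={p} out of range [0, {max_p}]")
    scores_full, var_explained = _component_scores(expr)
    scores = scores_full[:, :p]
    target = standardize(expr).values if on_standardized else expr.values
    mu = target.mean(axis=1)
    beta = target @ scores  # genes x p; scores orthonormal, mean-zero columns
    fitted = mu[:, None] + beta @ scores.T
    residuals = target - fitted
    return CorrectionResult(
        residuals=expr.with_values(residuals),
        p=p,
        scores=scores,
        variance_explained=var_explained,
        per_gene_intercept=mu,
        per_gene_coefficients=beta,
    )


def correct(
    expr: ExpressionMatrix,
    cfg: PermutationConfig | None = None,
    on_standardized: bool = False,
) -> CorrectionResult:
    """Estimate p by parallel analysis, then residualize.

    The composite mirrors the ``sva_network``-style workflow: choose the
    number of significant components from the data itself, then remove them
    per gene before network reconstruction.
    """
    cfg = cfg or PermutationConfig()
    p = estimate_num_pc(expr, cfg)
    result = pc_residualize(expr, p, on_standardized=on_standardized)
    logger.info(
        "PC correction removed %d components (%.1f%% of variance)",
        p, 100 * result.variance_explained[:p].sum(),
    )
    return result


def _design_matrix(
    expr: ExpressionMatrix, cov: CovariateTable, names: list[str]
) -> np.ndarray:
    missing = [n for n in names if n not in cov.covariate_names]
    if missing:
        raise ValueError(f"covariates not in table: {missing}")
    aligned = cov.aligned_to(expr.sample_ids)
    cols = [cov.covariate_names.index(n) for n in names]
    return np.column_stack([np.ones(expr.n_samples), aligned[:, cols]])


def covariate_residualize(
    expr: ExpressionMatrix, cov: CovariateTable, names: list[str]
) -> ExpressionMatrix:
    """Per-gene OLS residuals after jointly regressing on named covariates.

    This is the baseline family the PC approach is compared against:
    residuals on known quality covariates (RIN, exonic rate, GC bias, ...)
    instead of data-driven components.
    """
    design = _design_matrix(expr, cov, names)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = []
        r = 1  # intercept
        for j, name in enumerate(names, start=1):
            rj = np.linalg.matrix_rank(design[:, : j + 1])
            if rj == r:
                collinear.append(name)
            r = rj
        raise ValueError(f"rank-deficient design; collinear covariates: {collinear}")
    coef, *_ = np.linalg.lstsq(design, expr.values.T, rcond=None)
    residuals = expr.values - (design @ coef).T
    return expr.with_values(residuals)


def select_covariates(
    expr: ExpressionMatrix,
    cov: CovariateTable,
    r2_threshold: float = 0.01,
    aggregate: str = "mean",
) -> list[str]:
    """Covariates explaining at least ``r2_threshold`` of expression variance.

    Each covariate is fit singly, per gene, and its adjusted R^2 values are
    aggregated across genes (mean by default, median available); covariates
    whose aggregate reaches the threshold (default 0.01, i.e. 1% of
    variance) are kept, in table order.
    """
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    n = expr.n_samples
    if n < 4:
        raise ValueError("need >= 4 samples for adjusted R^2")
    aligned = cov.aligned_to(expr.sample_ids)
    y = expr.values - expr.values.mean(axis=1, keepdims=True)
    y_ss = (y**2).sum(axis=1)
    agg = np.mean if aggregate == "mean" else np.median
    kept = []
    for j, name in enumerate(cov.covariate_names):
        x = aligned[:, j] - aligned[:, j].mean()
        x_ss = (x**2).sum()
        if x_ss == 0:
            logger.warning("covariate %r is constant; skipped", name)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (y @ x) ** 2 / (y_ss * x_ss)
        r2 = np.nan_to_num(r2)  # zero-variance genes contribute R^2 = 0
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        score = float(agg(adj))
        logger.info("covariate %r: %s adjusted R^2 = %.4f", name, aggregate, score)
        if score >= r2_threshold:
            kept.append(name)
    return kept
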