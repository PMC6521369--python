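"""Graphical lasso, signed adjacency/TOM and module detection."""

import numpy as np
import pytest

from pcnet.reconstruct import (
    GlassoConfig,
    WgcnaConfig,
    detect_modules,
    glasso_network,
    glasso_path,
    glasso_precision,
    modules_to_network,
    signed_adjacency,
    tom_similarity,
    wgcna_path,
)
from pcnet.simulate import sample_expression
from tests.conftest import make_expression


def brute_force_glasso_3var(corr, lam, n_iter=200_000):
    """Independent oracle: minimize the penalized negative log-likelihood
    -logdet(T) + tr(S T) + lam * ||offdiag(T)||_1 by proximal gradient
    descent with backtracking (soft-thresholding resolves the exact zeros
    that smooth optimizers cannot)."""

    def smooth_value(theta):
        eigs = np.linalg.eigvalsh(theta)
        if eigs.min() <= 0:
            return np.inf
        return -np.log(eigs).sum() + (corr * theta).sum()

    off_mask = 1.0 - np.eye(3)
    theta = np.linalg.inv(corr + 0.1 * np.eye(3))
    step = 1.0
    value = smooth_value(theta)
    for _ in range(n_iter):
        gradient = corr - np.linalg.inv(theta)
        while True:
            candidate = theta - step * gradient
            shrunk = np.sign(candidate) * np.maximum(
                np.abs(candidate) - step * lam * off_mask, 0.0
            )
            new_value = smooth_value(shrunk)
            diff = shrunk - theta
            quadratic = (
                value
                + (gradient * diff).sum()
                + (diff**2).sum() / (2 * step)
            )
            if new_value <= quadratic + 1e-15:
                break
            step *= 0.5
        if np.abs(shrunk - theta).max() < 1e-13:
            theta = shrunk
            break
        theta, value = shrunk, new_value
        step *= 1.05  # cautiously re-grow the step after success
    return theta


def three_var_instances():
    """Small battery of 3-variable correlation structures."""
    rng = np.random.default_rng(99)
    instances = []
    for precision in (
        np.array([[2.0, -0.8, 0.0], [-0.8, 2.0, -0.6], [0.0, -0.6, 1.5]]),
        np.array([[1.5, 0.7, 0.7], [0.7, 1.5, 0.7], [0.7, 0.7, 1.5]]),
        np.eye(3),
    ):
        chol = np.linalg.cholesky(np.linalg.inv(precision))
        data = chol @ rng.normal(size=(3, 500))
        instances.append(np.corrcoef(data))
    return instances


class TestGlasso:
    def test_large_penalty_gives_empty_network(self, rng):
        expr = make_expression(rng.normal(size=(10, 40)))
        corr = np.corrcoef(expr.values)
        lam = np.abs(corr - np.eye(10)).max() + 0.01
        cfg = GlassoConfig(lambdas=(lam,), convergence_tol=1e-6)
        assert glasso_network(expr, lam, cfg).n_edges == 0

    def test_small_penalty_approaches_inverse_correlation(self):
        """With a dense true precision and many samples, the lam->0 support
        matches the (dense) inverse sample correlation."""
        precision = np.array(
            [
                [3.0, 0.8, 0.6, 0.4, 0.5],
                [0.8, 3.0, 0.7, 0.5, 0.4],
                [0.6, 0.7, 3.0, 0.8, 0.6],
                [0.4, 0.5, 0.8, 3.0, 0.7],
                [0.5, 0.4, 0.6, 0.7, 3.0],
            ]
        )
        expr = sample_expression(precision, 1000, seed=0)
        cfg = GlassoConfig(
            lambdas=(1e-3,), convergence_tol=1e-6, max_iter=1000, mode="lars"
        )
        net = glasso_network(expr, 1e-3, cfg)
        assert net.n_edges == 10  # fully dense support on 5 genes

    @pytest.mark.parametrize("lam", [0.05, 0.2])
    def test_matches_brute_force_objective_oracle(self, lam):
        for corr in three_var_instances():
            expr_like = make_expression(
                np.linalg.cholesky(corr) @ np.random.default_rng(0).normal(
                    size=(3, 20_000)
                )
            )
            cfg = GlassoConfig(lambdas=(lam,), convergence_tol=1e-6,
                               max_iter=2000)
            estimated = glasso_precision(expr_like, lam, cfg)
            oracle = brute_force_glasso_3var(
                np.corrcoef(expr_like.values), lam
            )
            np.testing.assert_allclose(estimated, oracle, atol=1e-3)

    def test_solution_symmetric_positive_definite(self, rng):
        expr = make_expression(rng.normal(size=(8, 50)))
        cfg = GlassoConfig(lambdas=(0.3,), convergence_tol=1e-6)
        precision = glasso_precision(expr, 0.3, cfg)
        np.testing.assert_allclose(precision, precision.T, atol=1e-10)
        assert np.linalg.eigvalsh(precision).min() > 0


class TestGlassoPath:
    def test_edge_counts_non_increasing_in_lambda(self):
        precision = np.diag(np.full(12, 2.0))
        for i in range(11):
            precision[i, i + 1] = precision[i + 1, i] = -0.7
        expr = sample_expression(precision, 300, seed=6)
        cfg = GlassoConfig(
            lambdas=(0.9, 0.6, 0.4, 0.2, 0.1), convergence_tol=1e-5,
            max_iter=1000, mode="lars",
        )
        counts = [net.n_edges for _, net in glasso_path(expr, cfg)]
        assert counts == sorted(counts)
        assert counts[0] == 0  # empty at the largest penalty
        assert counts[-1] > 11  # dense-ish at the smallest

    def test_single_lambda_path_equals_single_call(self, rng):
        expr = make_expression(rng.normal(size=(6, 40)))
        cfg = GlassoConfig(lambdas=(0.4,), convergence_tol=1e-6)
        [(lam, from_path)] = glasso_path(expr, cfg)
        direct = glasso_network(expr, 0.4, cfg)
        assert from_path.edges == direct.edges

    def test_lambdas_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            GlassoConfig(lambdas=(0.1, 0.5))


class TestSignedAdjacency:
    def test_closed_form_anchors(self):
        base = np.array([1.0, -1.0, 2.0, -2.0, 0.5, 1.5])
        values = np.vstack([base, base * 2, -base])
        expr = make_expression(values)
        a = signed_adjacency(expr, beta=6.0)
        assert a[0, 1] == pytest.approx(1.0)  # cor = +1
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)  # cor = -1

    def test_zero_correlation_anchor(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        a = signed_adjacency(make_expression(np.vstack([x, y])), beta=3.0)
        assert a[0, 1] == pytest.approx(0.5**3)

    def test_beta_one_matches_hand_computed_correlations(self, rng):
        values = rng.normal(size=(4, 30))
        a = signed_adjacency(make_expression(values), beta=1.0)
        expected = (1 + np.corrcoef(values)) / 2
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(a, expected, atol=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        a = signed_adjacency(make_expression(rng.normal(size=(10, 25))))
        np.testing.assert_allclose(a, a.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1


def tom_oracle(a):
    """Triple-loop reference implementation of unsigned TOM."""
    n = a.shape[0]
    tom = np.eye(n)
    k = a.sum(axis=1) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                a[i, u] * a[u, j] for u in range(n) if u != i and u != j
            )
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_two_gene_reduces_to_adjacency(self):
        a = np.array([[1.0, 0.37], [0.37, 1.0]])
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.37)

    def test_identical_binary_rows_give_full_overlap(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1.0
        a[0, 2] = a[2, 0] = 1.0
        a[1, 2] = a[2, 1] = 1.0
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [6, 15, 20])
    def test_matches_triple_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        raw = rng.uniform(0, 1, size=(n, n))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), tom_oracle(a), atol=1e-12)

    def test_entries_in_unit_interval(self, rng):
        raw = rng.uniform(0, 1, size=(12, 12))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_malformed_adjacency_rejected(self):
        with pytest.raises(ValueError):
            tom_similarity(np.array([[1.0, 2.0], [2.0, 1.0]]))


def block_tom(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for size in sizes:
        tom[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(tom, 1.0)
    return tom


class TestModules:
    def test_perfect_blocks_found(self):
        tom = block_tom([6, 6])
        ids = tuple(f"g{i}" for i in range(12))
        assignment = detect_modules(tom, ids, cut_height=0.5, min_module_size=3)
        assert assignment.n_unassigned == 0
        assert len(assignment.module_sizes()) == 2

    def test_cut_below_all_merges_leaves_everything_grey(self):
        tom = block_tom([6, 6], within=0.5)
        ids = tuple(f"g{i}" for i in range(12))
        assignment = detect_modules(tom, ids, cut_height=0.2, min_module_size=3)
        assert assignment.n_unassigned == 12

    def test_matches_merge_height_filtering_oracle(self):
        """Re-derive the static cut: union-find over linkage merges whose
        height does not exceed the cut."""
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(30)
        tom = block_tom([10, 10, 10], within=0.9, between=0.1)
        tom += rng.uniform(-0.05, 0.05, size=tom.shape)
        tom = np.clip((tom + tom.T) / 2, 0, 1)
        np.fill_diagonal(tom, 1.0)
        ids = tuple(f"g{i}" for i in range(30))
        cut = 0.6
        assignment = detect_modules(tom, ids, cut_height=cut, min_module_size=5)

        merges = linkage(squareform(1 - tom, checks=False), method="average")
        parent = list(range(60))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m, (left, right, height, _) in enumerate(merges):
            if height <= cut:
                parent[find(int(left))] = parent[find(int(right))] = 30 + m
        clusters = {}
        for i in range(30):
            clusters.setdefault(find(i), set()).add(ids[i])
        expected = {frozenset(c) for c in clusters.values() if len(c) >= 5}
        observed = {}
        for gene, label in assignment.labels.items():
            if label != "grey":
                observed.setdefault(label, set()).add(gene)
        assert {frozenset(c) for c in observed.values()} == expected

    def test_modules_to_network_clique_counts(self):
        labels = {f"a{i}": "M1" for i in range(3)}
        labels.update({f"b{i}": "M2" for i in range(4)})
        labels["lonely"] = "grey"
        from pcnet.reconstruct import ModuleAssignment

        net = modules_to_network(ModuleAssignment(labels, 0.9))
        assert net.n_edges == 3 + 6

    def test_all_grey_gives_empty_network(self):
        from pcnet.reconstruct import ModuleAssignment

        net = modules_to_network(
            ModuleAssignment({"a": "grey", "b": "grey"}, 0.5)
        )
        assert net.n_edges == 0


class TestWgcnaPath:
    def make_block_expression(self):
        precision = np.diag(np.full(30, 2.0))
        for b in range(3):
            for i in range(10 * b, 10 * b + 9):
                precision[i, i + 1] = precision[i + 1, i] = -0.9
        return sample_expression(precision, 100, seed=8)

    def test_edge_counts_non_decreasing_in_cut_height(self):
        expr = self.make_block_expression()
        cfg = WgcnaConfig(cut_heights=(0.3, 0.6, 0.9, 1.0), min_module_size=5)
        counts = [net.n_edges for _, net, _ in wgcna_path(expr, cfg)]
        assert counts == sorted(counts)

    def test_highest_cut_merges_everything(self):
        expr = self.make_block_expression()
        cfg = WgcnaConfig(cut_heights=(1.0,), min_module_size=5)
        [(_, net, assignment)] = wgcna_path(expr, cfg)
        assert len(assignment.module_sizes()) == 1
        assert assignment.n_unassigned == 0
        assert net.n_edges == 30 * 29 / 2

    def test_path_equals_per_cut_recomputation(self):
        expr = self.make_block_expression()
        cfg = WgcnaConfig(cut_heights=(0.5, 0.95), min_module_size=5)
        path = wgcna_path(expr, cfg)
        from pcnet.reconstruct import signed_adjacency, tom_similarity

        tom = tom_similarity(signed_adjacency(expr, cfg.beta))
        for cut, net, assignment in path:
            direct = detect_modules(tom, expr.gene_ids, cut, cfg.min_module_size)
            assert direct.labels == assignment.labels
            assert modules_to_network(
                direct, frozenset(expr.gene_ids)
            ).edges == net.edges
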