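"""Network construction, TOM, module detection, eigengenes and merging."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from crossmod.coexpression import (
    GREY,
    Network,
    cluster_and_cut,
    compute_adjacency,
    compute_eigengenes,
    compute_tom,
    merge_close_modules,
    pick_soft_threshold,
    scale_free_fit,
)
from crossmod.data_io import ExpressionMatrix

from conftest import make_expression

RNG = np.random.default_rng(314)


def block_expression(block_sizes, within_r=0.8, n_samples=48, seed=0,
                     n_noise=0):
    """Planted-block expression: within-block correlation ~within_r."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    load = np.sqrt(within_r)
    noise_sd = np.sqrt(1 - within_r)
    for b, size in enumerate(block_sizes):
        signal = rng.normal(size=n_samples)
        for _ in range(size):
            rows.append(load * signal + noise_sd * rng.normal(size=n_samples))
            labels.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.normal(size=n_samples))
        labels.append(GREY)
    return make_expression(np.array(rows)), labels


class TestAdjacency:
    def test_perfectly_correlated_pair(self):
        x = RNG.normal(size=10)
        expr = make_expression([x, 2 * x + 1])
        net = compute_adjacency(expr, soft_power=8)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_orthogonal_pair_power_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        expr = make_expression([x, y])
        net = compute_adjacency(expr, soft_power=1)
        assert net.adjacency[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_power_one_is_absolute_correlation(self):
        values = RNG.normal(size=(10, 20))
        net = compute_adjacency(make_expression(values), soft_power=1)
        expected = np.abs(np.corrcoef(values))
        assert np.allclose(net.adjacency, expected, atol=1e-12)

    def test_zero_variance_gene_named(self):
        values = RNG.normal(size=(3, 8))
        values[1] = 5.0
        with pytest.raises(ValueError, match="g1"):
            compute_adjacency(make_expression(values))


class TestTOM:
    def test_three_gene_hand_value(self):
        a = np.array([[1.0, 0.8, 0.6], [0.8, 1.0, 0.4], [0.6, 0.4, 1.0]])
        net = Network(["a", "b", "c"], a, 1)
        tom, dissim = compute_tom(net)
        assert tom[0, 1] == pytest.approx(1.04 / 1.4)
        assert np.allclose(dissim, 1 - tom, atol=1e-15)

    def test_identity_adjacency_zero_overlap(self):
        net = Network(["a", "b", "c"], np.eye(3), 1)
        tom, _ = compute_tom(net)
        assert np.allclose(tom - np.eye(3), 0.0, atol=1e-15)

    def test_matches_cubic_brute_force_oracle(self):
        """Vectorized TOM equals the O(n^3) triple-loop definition exactly."""
        for _ in range(100):
            n = 20
            raw = RNG.uniform(0, 1, size=(n, n))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 1.0)
            net = Network([f"g{i}" for i in range(n)], a, 1)
            tom, _ = compute_tom(net)
            a0 = a.copy()
            np.fill_diagonal(a0, 0.0)
            k = a0.sum(axis=1)
            expected = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    shared = sum(
                        a0[i, u] * a0[u, j]
                        for u in range(n)
                        if u != i and u != j
                    )
                    val = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
                    expected[i, j] = expected[j, i] = val
            assert np.allclose(tom, expected, atol=1e-12)


class TestSoftThreshold:
    def test_hub_model_reaches_scale_free_fit(self):
        """Expression from a hub-and-spokes model yields a high signed R^2."""
        rng = np.random.default_rng(8)
        n_samples = 60
        rows = []
        n_hubs = 8
        hubs = rng.normal(size=(n_hubs, n_samples))
        # spoke counts decay geometrically: few big hubs, many small ones
        for h in range(n_hubs):
            n_spokes = max(4, int(60 * 0.55 ** h))
            for _ in range(n_spokes):
                w = rng.uniform(0.4, 0.95)
                rows.append(w * hubs[h] + np.sqrt(1 - w * w) * rng.normal(size=n_samples))
        expr = make_expression(np.array(rows))
        power, fit = pick_soft_threshold(expr, r2_target=0.8)
        assert fit.loc[fit["power"] == power, "signed_r2"].iloc[0] >= 0.8

    def test_fit_invariant_under_sample_permutation(self):
        values = RNG.normal(size=(40, 30))
        expr = make_expression(values)
        _, fit_a = pick_soft_threshold(expr, powers=[2, 4, 6])
        perm = RNG.permutation(30)
        _, fit_b = pick_soft_threshold(make_expression(values[:, perm]),
                                       powers=[2, 4, 6])
        assert np.allclose(fit_a["signed_r2"], fit_b["signed_r2"], atol=1e-10)

    def test_identical_connectivities_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.full(50, 3.0))


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_exactly(self):
        expr, labels = block_expression([50, 50], within_r=0.8, seed=1)
        net = compute_adjacency(expr, soft_power=6)
        _, dissim = compute_tom(net)
        _, assignment = cluster_and_cut(dissim, expr.genes, min_size=30)
        predicted = [assignment.labels[g] for g in expr.genes]
        assert adjusted_rand_score(labels, predicted) == 1.0
        assert len(assignment.non_grey()) == 2

    def test_small_block_goes_grey(self):
        expr, labels = block_expression([50, 29], within_r=0.85, seed=2)
        net = compute_adjacency(expr, soft_power=6)
        _, dissim = compute_tom(net)
        _, assignment = cluster_and_cut(dissim, expr.genes, min_size=30)
        small_block = [g for g, lab in zip(expr.genes, labels) if lab == "block1"]
        assert all(assignment.labels[g] == GREY for g in small_block)

    def test_labels_deterministic(self):
        expr, _ = block_expression([40, 35], seed=3)
        net = compute_adjacency(expr, soft_power=6)
        _, dissim = compute_tom(net)
        _, a1 = cluster_and_cut(dissim, expr.genes, min_size=30)
        _, a2 = cluster_and_cut(dissim.copy(), list(expr.genes), min_size=30)
        assert a1.labels == a2.labels
        # size-ranked color naming: largest block is "turquoise"
        sizes = {m: len(g) for m, g in a1.non_grey().items()}
        assert max(sizes, key=sizes.get) == "turquoise"

    def test_min_size_above_gene_count_all_grey(self):
        expr, _ = block_expression([10], n_samples=12, seed=4)
        net = compute_adjacency(expr, soft_power=2)
        _, dissim = compute_tom(net)
        _, assignment = cluster_and_cut(dissim, expr.genes, min_size=30)
        assert set(assignment.labels.values()) == {GREY}


class TestEigengenes:
    def test_identical_genes_explain_everything(self):
        x = RNG.normal(size=12)
        expr = make_expression([x, 2 * x + 3, -1.0 * x])
        from crossmod.coexpression import ModuleAssignment

        me, var_expl = compute_eigengenes(
            expr, ModuleAssignment({"g0": "m", "g1": "m", "g2": "m"})
        )
        assert var_expl["m"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        assert abs(np.corrcoef(me.loc["m"], z)[0, 1]) == pytest.approx(1.0)
        # unit variance and positive mean member correlation
        assert me.loc["m"].std(ddof=1) == pytest.approx(1.0)

    def test_sign_oriented_toward_members(self):
        expr, _ = block_expression([30], seed=5)
        from crossmod.coexpression import ModuleAssignment

        me, _ = compute_eigengenes(
            expr, ModuleAssignment({g: "m" for g in expr.genes})
        )
        cors = [np.corrcoef(expr.data.loc[g], me.loc["m"])[0, 1]
                for g in expr.genes]
        assert np.mean(cors) > 0

    def test_singleton_module_is_standardized_gene(self):
        x = RNG.normal(size=10)
        expr = make_expression([x])
        from crossmod.coexpression import ModuleAssignment

        me, _ = compute_eigengenes(expr, ModuleAssignment({"g0": "m"}))
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(np.abs(me.loc["m"]), np.abs(z), atol=1e-10)

    def test_invariant_under_gene_reordering(self):
        expr, _ = block_expression([20, 20], seed=6)
        from crossmod.coexpression import ModuleAssignment

        labels = {g: ("a" if i < 20 else "b") for i, g in enumerate(expr.genes)}
        me1, _ = compute_eigengenes(expr, ModuleAssignment(labels))
        perm = RNG.permutation(40)
        expr_p = ExpressionMatrix(expr.data.iloc[perm], "log2tpm")
        me2, _ = compute_eigengenes(expr_p, ModuleAssignment(labels))
        assert np.allclose(me1.to_numpy(), me2.loc[me1.index].to_numpy(),
                           atol=1e-10)


class TestMerge:
    def test_correlated_modules_merge(self):
        rng = np.random.default_rng(7)
        signal = rng.normal(size=40)
        rows = [signal + 0.2 * rng.normal(size=40) for _ in range(30)]
        expr = make_expression(np.array(rows))
        from crossmod.coexpression import ModuleAssignment

        labels = {g: ("a" if i < 20 else "b") for i, g in enumerate(expr.genes)}
        merged, me = merge_close_modules(expr, ModuleAssignment(labels),
                                         merge_height=0.25)
        assert set(merged.labels.values()) == {"a"}  # larger module keeps label

    def test_distant_modules_untouched(self):
        expr, _ = block_expression([25, 25], within_r=0.9, seed=8)
        from crossmod.coexpression import ModuleAssignment

        labels = {g: ("a" if i < 25 else "b") for i, g in enumerate(expr.genes)}
        merged, _ = merge_close_modules(expr, ModuleAssignment(labels),
                                        merge_height=0.25)
        assert merged.labels == labels

    def test_merge_order_independent_on_separated_blocks(self):
        """With well-separated blocks the final partition is the same whatever
        the initial (over-split) labeling order."""
        expr, _ = block_expression([30, 30], within_r=0.9, seed=9)
        from crossmod.coexpression import ModuleAssignment

        def partition(label_fn):
            labels = {g: label_fn(i) for i, g in enumerate(expr.genes)}
            merged, _ = merge_close_modules(expr, ModuleAssignment(labels),
                                            merge_height=0.25)
            groups = {}
            for g, lab in merged.labels.items():
                groups.setdefault(lab, set()).add(g)
            return sorted(frozenset(s) for s in groups.values())

        # split each true block into two half-modules, two different ways
        p1 = partition(lambda i: f"m{i // 15}")
        p2 = partition(lambda i: f"m{(i % 2) + 2 * (i // 30)}")
        assert p1 == p2


class TestModuleRecovery:
    def test_planted_modules_recovered_with_noise_background(self):
        """5 planted 50-gene modules at within-module r=0.7 recovered with
        ARI >= 0.8 against truth (single representative seed; the
        multi-seed version is an acceptance criterion)."""
        expr, labels = block_expression([50] * 5, within_r=0.7, seed=10,
                                        n_noise=100)
        net = compute_adjacency(expr, soft_power=8)
        _, dissim = compute_tom(net)
        _, assignment = cluster_and_cut(dissim, expr.genes, min_size=30)
        assignment, _ = merge_close_modules(expr, assignment)
        predicted = [assignment.labels[g] for g in expr.genes]
        assert adjusted_rand_score(labels, predicted) >= 0.8
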