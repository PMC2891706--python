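import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from placa.inference import (EdgeSet, InferenceConfig, SingularResponseError,
                             consensus, edges_to_frame, estimate_activity,
                             gene_contributions, infer_edges, jackknife_edges,
                             mra, sign_filter, write_sif)
from placa.scoring import compute_scores
from tests.conftest import dataset_from_means


def random_true_system(rng, n):
    """Draw (r_true, R) with R = -r_true^-1 p for a random diagonal p."""
    while True:
        r = rng.uniform(-0.9, 0.9, size=(n, n))
        np.fill_diagonal(r, -1.0)
        if np.linalg.cond(r) < 1e3:
            break
    p = np.diag(rng.uniform(0.5, 2.0, size=n) * rng.choice([-1, 1], size=n))
    R = -np.linalg.inv(r) @ p
    return r, R


class TestEstimateActivity:
    def test_zero_weights_give_zero_activity(self, toy_dataset):
        W = np.zeros((2, 3))
        est = estimate_activity(W, toy_dataset)
        assert np.allclose(est.S, 0) and np.allclose(est.R, 0)

    def test_unperturbed_dataset_gives_zero_response(self):
        A = np.array([2.0, 3.0, 1.0])
        ds = dataset_from_means(A, np.tile(A, (2, 1)))
        W = np.arange(6, dtype=float).reshape(2, 3)
        est = estimate_activity(W, ds)
        assert np.allclose(est.R, 0.0)
        assert est.S0 == pytest.approx(list(W @ A))

    def test_r_is_s_minus_s0(self, rich_dataset):
        W = compute_scores(rich_dataset).W
        est = estimate_activity(W, rich_dataset)
        assert np.allclose(est.R, est.S - est.S0[:, None])

    def test_invariant_to_per_gene_rescaling(self, rich_dataset):
        est0 = estimate_activity(compute_scores(rich_dataset).W, rich_dataset)
        scaled = rich_dataset.rescale_genes([2.0, 0.1, 5.0, 1.0, 0.3, 7.0])
        est1 = estimate_activity(compute_scores(scaled).W, scaled)
        assert np.allclose(est1.S, est0.S, rtol=1e-9)
        assert np.allclose(est1.R, est0.R, rtol=1e-9)


class TestMRA:
    def test_diagonal_response_means_no_interactions(self):
        r = mra(np.diag([2.0, -1.0, 0.5])).r
        assert np.allclose(r, -np.eye(3))

    def test_diagonal_is_exactly_minus_one(self, rich_dataset):
        est = estimate_activity(compute_scores(rich_dataset).W, rich_dataset)
        r = mra(est.R).r
        assert np.diag(r) == pytest.approx([-1.0] * 3, abs=0.0)

    def test_recovers_generating_system(self):
        rng = np.random.default_rng(7)
        for n in range(3, 9):
            for _ in range(20):
                r_true, R = random_true_system(rng, n)
                r_hat = mra(R).r
                assert np.allclose(r_hat, r_true, rtol=1e-8, atol=1e-10)

    def test_singular_response_raises_with_condition_number(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularResponseError, match="condition"):
            mra(R)


class TestJackknife:
    def test_sample_count_equals_gene_count(self, rich_dataset):
        edges = jackknife_edges(rich_dataset)
        assert edges.samples.shape == (rich_dataset.m, 3, 3)

    def test_redundant_reporters_agree_in_sign(self):
        # n disjoint perfect reporter pairs (m = 2n): every leave-one-out
        # subproblem sees the same structure, so signs agree across samples
        A = np.array([2.0, 2.0, 3.0, 3.0, 1.0, 1.0])
        resp = np.array([[0.5, 0.5, 0.0, 0.0, 0.0, 0.0],
                         [0.0, 0.0, 0.5, 0.5, 0.0, 0.0],
                         [0.0, 0.0, 0.0, 0.0, 0.5, 0.5]])
        ds = dataset_from_means(A, A[None, :] * (1 - resp))
        edges = jackknife_edges(ds)
        for i in range(3):
            for j in range(3):
                if i != j:
                    s = edges.samples[:, i, j]
                    s = s[np.isfinite(s) & (s != 0)]
                    if s.size:
                        assert (np.sign(s) == np.sign(s)[0]).all()

    def test_equals_definitional_per_subset_recomputation(self, rich_dataset):
        # the batched leave-one-out path must match rerunning the entire
        # scoring pipeline on each gene subset (scores are per-gene, so the
        # two are mathematically identical)
        edges = jackknife_edges(rich_dataset)
        for g in range(rich_dataset.m):
            sub = rich_dataset.drop_gene(g)
            W = compute_scores(sub).W
            r = mra(estimate_activity(W, sub).R).r
            assert np.allclose(edges.samples[g], r, rtol=1e-9)

    def test_bootstrap_resampler_runs(self, rich_dataset):
        cfg = InferenceConfig(resampler="bootstrap", n_bootstrap=25)
        edges = jackknife_edges(rich_dataset, cfg, rng=np.random.default_rng(0))
        assert edges.samples.shape == (25, 3, 3)
        assert np.isfinite(edges.mu).any()

    def test_needs_more_genes_than_components(self):
        ds = dataset_from_means([2.0, 1.0], [[1.0, 1.0], [2.0, 0.5]])
        with pytest.raises(ValueError, match="n\\+1"):
            jackknife_edges(ds)


class TestSignFilter:
    def _edge_set(self, mu, sigma):
        n = mu.shape[0]
        return EdgeSet(components=tuple(f"C{i}" for i in range(n)),
                       samples=np.zeros((1, n, n)), mu=mu, sigma=sigma,
                       significant=np.zeros((n, n), bool),
                       sign=np.zeros((n, n), int),
                       unresolvable=np.zeros((n, n), bool))

    def test_zero_mean_never_significant(self):
        mu = np.zeros((2, 2)); sigma = np.ones((2, 2))
        out = sign_filter(self._edge_set(mu, sigma))
        assert not out.significant.any()

    def test_boundary_ratio_is_inclusive(self):
        crit = stats.norm.ppf(0.95)
        mu = np.array([[0.0, crit], [1.0, 0.0]])
        sigma = np.ones((2, 2))
        out = sign_filter(self._edge_set(mu, sigma), alpha=0.05)
        assert out.significant[0, 1]          # ratio == 1.644854...
        assert not out.significant[1, 0]      # ratio 1.0 < 1.645
        assert out.sign[0, 1] == 1

    def test_zero_sigma_nonzero_mean_is_significant(self):
        mu = np.array([[0.0, -0.4], [0.0, 0.0]])
        sigma = np.zeros((2, 2))
        out = sign_filter(self._edge_set(mu, sigma))
        assert out.significant[0, 1] and out.sign[0, 1] == -1

    def test_two_sided_is_stricter(self):
        mu = np.full((2, 2), stats.norm.ppf(0.95) + 0.01)
        sigma = np.ones((2, 2))
        one = sign_filter(self._edge_set(mu, sigma), alpha=0.05, two_sided=False)
        two = sign_filter(self._edge_set(mu, sigma), alpha=0.05, two_sided=True)
        assert one.significant[0, 1] and not two.significant[0, 1]


class TestConsensus:
    def _edges(self, sign, significant):
        n = sign.shape[0]
        return EdgeSet(components=("A", "B", "C")[:n],
                       samples=np.zeros((1, n, n)),
                       mu=sign.astype(float), sigma=np.zeros((n, n)),
                       significant=significant, sign=sign,
                       unresolvable=np.zeros((n, n), bool))

    def test_unanimous_edge_retained(self):
        sign = np.array([[0, 1], [0, 0]])
        sig = sign != 0
        net = consensus([self._edges(sign, sig)] * 5, K=5)
        assert net.retained[0, 1] and net.sign[0, 1] == 1
        assert net.support[0, 1] == 5

    def test_below_threshold_dropped(self):
        sign = np.array([[0, 1], [0, 0]])
        sig = sign != 0
        empty = self._edges(np.zeros((2, 2), int), np.zeros((2, 2), bool))
        net = consensus([self._edges(sign, sig)] * 3 + [empty] * 2, K=4)
        assert not net.retained.any()

    def test_conflicting_signs_below_majority_dropped(self):
        pos = np.array([[0, 1], [0, 0]])
        neg = np.array([[0, -1], [0, 0]])
        sets = [self._edges(pos, pos != 0)] * 3 + [self._edges(neg, neg != 0)] * 2
        net = consensus(sets, K=4)
        assert not net.retained[0, 1]
        net2 = consensus(sets, K=2)       # both signs reach K: conflict
        assert not net2.retained[0, 1]
        assert (0, 1) in net2.conflicts

    def test_k1_is_union_and_monotone_in_k(self):
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(4):
            sign = rng.choice([-1, 0, 1], size=(3, 3))
            np.fill_diagonal(sign, 0)
            sets.append(self._edges(sign, sign != 0))
        union = np.zeros((3, 3), bool)
        for es in sets:
            union |= es.significant
        nets = [consensus(sets, K=k) for k in range(1, 5)]
        conflict_free = np.ones((3, 3), bool)
        for (i, j) in nets[0].conflicts:
            conflict_free[i, j] = False
        assert np.array_equal(nets[0].retained | ~conflict_free,
                              union | ~conflict_free)
        for lo, hi in zip(nets, nets[1:]):
            assert (hi.retained <= lo.retained | ~conflict_free).all()

    def test_k_out_of_range(self):
        es = self._edges(np.zeros((2, 2), int), np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            consensus([es, es], K=3)


class TestGeneContributions:
    def test_partition_of_response(self, rich_dataset):
        W = compute_scores(rich_dataset).W
        est = estimate_activity(W, rich_dataset)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                table = gene_contributions(W, rich_dataset, source=i, target=j)
                assert table["contribution"].sum() == pytest.approx(
                    est.R[j, i], rel=1e-9, abs=1e-12)

    def test_zero_weight_gene_contributes_nothing(self, rich_dataset):
        W = compute_scores(rich_dataset).W.copy()
        W[2, 0] = 0.0
        table = gene_contributions(W, rich_dataset, source=0, target=2)
        assert table.set_index("gene").loc["g1", "contribution"] == 0.0

    def test_source_must_differ_from_target(self, rich_dataset):
        W = compute_scores(rich_dataset).W
        with pytest.raises(ValueError):
            gene_contributions(W, rich_dataset, source=1, target=1)


class TestPermutationInvariance:
    def test_gene_order_does_not_change_network(self, rich_dataset):
        perm = [3, 0, 5, 1, 4, 2]
        from placa.expression_data import ConditionSummary, ExpressionDataset

        def permute(c):
            idx = np.array(perm)
            return ConditionSummary(c.mean[idx], c.log_mean[idx],
                                    c.log_se[idx], c.n_rep[idx])

        shuffled = ExpressionDataset(
            genes=tuple(rich_dataset.genes[i] for i in perm),
            baseline=permute(rich_dataset.baseline),
            perturbed=tuple(permute(c) for c in rich_dataset.perturbed),
            panel=rich_dataset.panel)
        e0 = infer_edges(rich_dataset)
        e1 = infer_edges(shuffled)
        assert np.allclose(e0.mu, e1.mu, rtol=1e-9)
        assert np.array_equal(e0.significant, e1.significant)


class TestExports:
    def test_edge_frame_columns_and_sif(self, rich_dataset, tmp_path):
        W = compute_scores(rich_dataset).W
        edges = infer_edges(rich_dataset)
        frame = edges_to_frame(edges, ds=rich_dataset, W=W)
        assert {"source", "target", "sign", "mean_coeff", "sd_coeff",
                "zratio", "significant", "top_genes"} <= set(frame.columns)
        assert len(frame) == 6
        sif = tmp_path / "net.sif"
        write_sif(edges, sif)
        text = sif.read_text()
        for line in text.strip().splitlines():
            parts = line.split("\t")
            assert len(parts) == 3
            assert parts[1] in ("functional-activation", "functional-inhibition")
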