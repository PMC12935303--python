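import numpy as np
import pytest

import featuredca as fd
from featuredca.errors import ModelFormatError, ParameterError
from featuredca.model import _rank_value_grad, log_prob_batch

from _reference import ref_conditional_probs, ref_log_prob


def zero_model(L, q, d):
    return fd.ModelParams(
        L=L, q=q, d=d, ordering=np.arange(L),
        J=[np.zeros((k, q, q)) for k in range(L)],
        h=np.zeros((L, q)), G=np.zeros((L, q, d)),
        alphabet=fd.Alphabet("-ACDEFGHIKLMNPQRSTVWY"[:q]),
    )


class TestConditionals:
    def test_zero_parameters_give_zero_logits_and_uniform(self):
        m = zero_model(3, 4, 1)
        logits = fd.conditional_logits(m, [1, 2], np.zeros(1), 2)
        np.testing.assert_array_equal(logits, np.zeros(4))
        np.testing.assert_allclose(
            fd.conditional_distribution(m, [1, 2], np.zeros(1), 2), 0.25
        )

    def test_field_only_case(self):
        m = zero_model(2, 2, 0)
        m.h[0] = [np.log(2), 0.0]
        np.testing.assert_allclose(
            fd.conditional_logits(m, [], np.zeros(0), 0), [np.log(2), 0.0]
        )
        np.testing.assert_allclose(
            fd.conditional_distribution(m, [], np.zeros(0), 0), [2 / 3, 1 / 3]
        )

    def test_feature_dot_product(self):
        m = zero_model(2, 3, 1)
        m.G[0][1, 0] = 0.5
        logits = fd.conditional_logits(m, [], np.array([2.0]), 0)
        np.testing.assert_allclose(logits, [0.0, 1.0, 0.0])

    def test_softmax_shift_invariance(self, tiny_model):
        y = np.array([0.4, -0.2])
        prefix = [1, 0, 2]
        base = fd.conditional_distribution(tiny_model, prefix, y, 3)
        shifted = fd.ModelParams(
            L=tiny_model.L, q=tiny_model.q, d=tiny_model.d,
            ordering=tiny_model.ordering, J=[a.copy() for a in tiny_model.J],
            h=tiny_model.h + 7.3, G=tiny_model.G, alphabet=tiny_model.alphabet,
        )
        np.testing.assert_allclose(
            fd.conditional_distribution(shifted, prefix, y, 3), base, atol=1e-12
        )

    def test_matches_reference_implementation(self, tiny_model):
        y = np.array([0.8, -1.2])
        for k, prefix in [(0, []), (2, [2, 0]), (3, [1, 1, 2])]:
            np.testing.assert_allclose(
                fd.conditional_distribution(tiny_model, prefix, y, k),
                ref_conditional_probs(tiny_model, prefix, y, k),
                atol=1e-12,
            )


class TestSequenceLogProb:
    def test_uniform_baseline(self):
        m = zero_model(3, 21, 0)
        assert fd.sequence_log_prob(m, [0, 5, 20], np.zeros(0)) == pytest.approx(
            -3 * np.log(21)
        )

    def test_enumeration_sums_to_one(self, tiny_model):
        p = fd.brute_force_distribution(tiny_model, np.array([0.3, -1.1]))
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_reference(self, tiny_model):
        y = np.array([-0.5, 0.9])
        rng = np.random.default_rng(0)
        for _ in range(5):
            seq = rng.integers(0, 3, 4)
            assert fd.sequence_log_prob(tiny_model, seq, y) == pytest.approx(
                ref_log_prob(tiny_model, seq, y), abs=1e-10
            )

    def test_d0_reduction(self, tiny_model_d0):
        rng = np.random.default_rng(1)
        for _ in range(5):
            seq = rng.integers(0, 3, 4)
            assert fd.sequence_log_prob(
                tiny_model_d0, seq, np.zeros(0)
            ) == pytest.approx(ref_log_prob(tiny_model_d0, seq, []), abs=1e-12)


class TestJointLogProb:
    def test_additivity_and_flat_flag(self, tiny_model):
        dens = fd.FeatureDensity(mean=np.zeros(2), covariance=np.eye(2), shrinkage=0.0)
        seq = [0, 1, 2, 0]
        y = np.array([0.2, 0.4])
        cond = fd.sequence_log_prob(tiny_model, seq, y)
        assert fd.joint_log_prob(tiny_model, dens, seq, y) == pytest.approx(
            fd.log_density(dens, y) + cond
        )
        assert fd.joint_log_prob(tiny_model, dens, seq, y, flat_density=True) == cond

    def test_joint_integrates_to_one_d1(self):
        # sum over sequences x Gauss-Hermite quadrature over y
        m = fd.make_tiny_model(3, 3, 1, scale=0.6, seed=9)
        dens = fd.FeatureDensity(
            mean=np.array([0.3]), covariance=np.array([[1.7]]), shrinkage=0.0
        )
        nodes, weights = np.polynomial.hermite.hermgauss(60)
        sigma = np.sqrt(1.7)
        total = 0.0
        seqs = fd.enumerate_sequences(3, 3)
        for t, w in zip(nodes, weights):
            y = np.array([dens.mean[0] + np.sqrt(2) * sigma * t])
            cond = np.exp(log_prob_batch(m, seqs, y)).sum()
            total += w / np.sqrt(np.pi) * cond
        assert total == pytest.approx(1.0, abs=1e-8)


class TestNLL:
    def test_uniform_baseline(self, two_cluster_msa):
        aln, _ = two_cluster_msa
        m = zero_model(aln.L, aln.alphabet.q, 0)
        cfg = fd.TrainingConfig(lambda_J=0, lambda_h=0, lambda_G=0)
        value, _ = fd.negative_log_likelihood(m, aln, np.zeros((aln.M, 0)), config=cfg)
        assert value == pytest.approx(aln.L * np.log(aln.alphabet.q))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        M, k, q, d = 40, 3, 4, 2
        X = np.zeros((M, k * q))
        prev = rng.integers(0, q, (M, k))
        X[np.arange(M)[:, None], np.arange(k) * q + prev] = 1.0
        Y = rng.normal(size=(M, d))
        targets = rng.integers(0, q, M)
        wn = rng.random(M)
        wn /= wn.sum()
        theta = rng.normal(0, 0.4, k * q * q + q + q * d)
        args = (X, Y, targets, wn, q, k, d, 1e-2, 1e-4, 1e-4)
        _, grad = _rank_value_grad(theta, *args)
        eps = 1e-6
        for idx in rng.choice(len(theta), 25, replace=False):
            tp = theta.copy(); tp[idx] += eps
            tm = theta.copy(); tm[idx] -= eps
            fd_grad = (_rank_value_grad(tp, *args)[0] - _rank_value_grad(tm, *args)[0]) / (2 * eps)
            assert abs(fd_grad - grad[idx]) / max(abs(fd_grad), 1e-8) < 1e-5

    def test_per_rank_decomposition(self, two_cluster_msa):
        # the full objective equals the weighted mean of -log P(a|y) plus penalties
        aln, _ = two_cluster_msa
        rng = np.random.default_rng(6)
        q = aln.alphabet.q
        m = fd.ModelParams(
            L=aln.L, q=q, d=2, ordering=np.arange(aln.L),
            J=[rng.normal(0, 0.1, (k, q, q)) for k in range(aln.L)],
            h=rng.normal(0, 0.1, (aln.L, q)), G=rng.normal(0, 0.1, (aln.L, q, 2)),
            alphabet=aln.alphabet,
        )
        Y = rng.normal(size=(aln.M, 2))
        cfg = fd.TrainingConfig(lambda_J=1e-2, lambda_h=1e-4, lambda_G=1e-4)
        total, _ = fd.negative_log_likelihood(m, aln, Y, config=cfg)
        direct = -log_prob_batch(m, aln.data, Y).mean()
        direct += cfg.lambda_J * sum(float((Jk**2).sum()) for Jk in m.J)
        direct += cfg.lambda_h * float((m.h**2).sum())
        direct += cfg.lambda_G * float((m.G**2).sum())
        assert total == pytest.approx(direct, abs=1e-10)


class TestTrain:
    def test_row_order_invariance(self, two_cluster_msa):
        # per-rank problems are convex: permuting the data rows leaves the optimum
        aln, _ = two_cluster_msa
        basis = fd.fit_pca(aln, 2)
        Y = fd.project(basis, aln)
        cfg = fd.TrainingConfig(use_sequence_weights=False)
        p1 = fd.train(aln, Y, cfg)
        perm = np.random.default_rng(7).permutation(aln.M)
        aln_p = fd.Alignment(
            ids=[aln.ids[i] for i in perm], data=aln.data[perm], alphabet=aln.alphabet
        )
        p2 = fd.train(aln_p, Y[perm], cfg)
        v1, _ = fd.negative_log_likelihood(p1, aln, Y, config=cfg)
        v2, _ = fd.negative_log_likelihood(p2, aln, Y, config=cfg)
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_entropic_ordering_is_permutation_and_scores_match(self, two_cluster_msa):
        aln, _ = two_cluster_msa
        cfg = fd.TrainingConfig(ordering_mode="entropic", use_sequence_weights=False,
                                max_iterations=100)
        p = fd.train(aln, None, cfg)
        assert sorted(p.ordering.tolist()) == list(range(aln.L))
        # scoring respects the stored ordering
        lp = fd.sequence_log_prob(p, aln.data[0], np.zeros(0))
        assert lp == pytest.approx(ref_log_prob(p, aln.data[0], []), abs=1e-10)

    def test_standardize_features_fold_back(self, two_cluster_msa):
        aln, _ = two_cluster_msa
        basis = fd.fit_pca(aln, 2)
        Y = fd.project(basis, aln) * 10 + 3
        cfg = fd.TrainingConfig(use_sequence_weights=False, max_iterations=150)
        p_std = fd.train(aln, Y, fd.TrainingConfig(
            use_sequence_weights=False, max_iterations=150, standardize_features=True))
        # the folded-back model consumes raw y
        lp = log_prob_batch(p_std, aln.data[:5], Y[:5])
        assert np.all(np.isfinite(lp))

    def test_invalid_config(self):
        with pytest.raises(ParameterError):
            fd.TrainingConfig(gradient_tolerance=0)
        with pytest.raises(ParameterError):
            fd.TrainingConfig(ordering_mode="random")


class TestSample:
    def test_uniform_single_site_frequencies(self):
        m = zero_model(1, 4, 0)
        s = fd.sample(m, np.zeros((1, 0)), n_per_condition=100000, seed=2)
        freqs = np.bincount(s.data[:, 0], minlength=4) / 100000
        se = np.sqrt(0.25 * 0.75 / 100000)
        np.testing.assert_allclose(freqs, 0.25, atol=4 * se)

    def test_seed_determinism(self, tiny_model):
        y = np.array([0.1, 0.2])
        s1 = fd.sample(tiny_model, y, n_per_condition=500, seed=11)
        s2 = fd.sample(tiny_model, y, n_per_condition=500, seed=11)
        np.testing.assert_array_equal(s1.data, s2.data)
        assert s1.ids == s2.ids

    def test_header_provenance(self, tiny_model):
        s = fd.sample(tiny_model, np.array([1.5, -2.0]), n_per_condition=2, seed=3)
        assert s.ids[0].startswith("gen_0|y=1.5,-2|seed=3")

    def test_condition_blocks(self, tiny_model):
        Y = np.array([[0.0, 0.0], [5.0, 5.0]])
        s = fd.sample(tiny_model, Y, n_per_condition=3, seed=4)
        assert s.M == 6

    def test_nonfinite_condition_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            fd.sample(tiny_model, np.array([np.nan, 0.0]), 1, seed=0)


class TestParameterCount:
    @pytest.mark.parametrize(
        "L, q, d, expected",
        [(1, 21, 0, 21), (2, 2, 0, 8), (118, 21, 2, 3_051_657)],
    )
    def test_examples(self, L, q, d, expected):
        assert fd.parameter_count(L, q, d) == expected

    def test_counts_actual_arrays(self, tiny_model):
        actual = (
            sum(Jk.size for Jk in tiny_model.J)
            + tiny_model.h.size
            + tiny_model.G.size
        )
        assert fd.parameter_count(tiny_model.L, tiny_model.q, tiny_model.d) == actual


class TestSerialization:
    def test_round_trip(self, tiny_model, tmp_path):
        basis = fd.PCABasis(
            mean=np.zeros(12), components=np.eye(2, 12),
            explained_variance=np.array([2.0, 1.0]), L=4, q=3,
        )
        dens = fd.FeatureDensity(mean=np.zeros(2), covariance=np.eye(2), shrinkage=0.01)
        path = tmp_path / "model.npz"
        fd.save_model(tiny_model, basis, dens, path)
        params, basis2, dens2 = fd.load_model(path)
        np.testing.assert_array_equal(params.h, tiny_model.h)
        np.testing.assert_array_equal(params.G, tiny_model.G)
        for a, b in zip(params.J, tiny_model.J):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(basis2.components, basis.components)
        np.testing.assert_array_equal(dens2.covariance, dens.covariance)

    def test_d0_archive_has_no_density(self, tiny_model_d0, tmp_path):
        path = tmp_path / "m0.npz"
        fd.save_model(tiny_model_d0, None, None, path)
        params, basis, dens = fd.load_model(path)
        assert params.d == 0
        assert basis is None and dens is None

    def test_tampered_metadata_rejected(self, tiny_model, tmp_path):
        import json
        import zipfile

        path = tmp_path / "m.npz"
        fd.save_model(tiny_model, None, None, path)
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
        meta = json.loads(str(arrays["meta"]))
        meta["q"] = 7
        arrays["meta"] = np.array(json.dumps(meta))
        bad = tmp_path / "bad.npz"
        np.savez(bad, **arrays)
        with pytest.raises(ModelFormatError):
            fd.load_model(bad)
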