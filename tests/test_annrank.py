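"""ANN ranking: splits, single-net training, ranking, interactions."""

import numpy as np
import pandas as pd
import pytest

from orthoarray import annrank, fixtures
from orthoarray.annrank import (
    AnnConfig,
    MarkerInteraction,
    NeuralNetRanker,
    split_data,
    subset_sizes,
    train_single_input_net,
)

FRACTIONS = (0.6, 0.2, 0.2)


class TestSplits:
    def test_ten_samples_split_6_2_2_with_both_classes_in_train(self):
        labels = np.array([0] * 5 + [1] * 5)
        rng = np.random.default_rng(0)
        tr, val, te = split_data(labels, FRACTIONS, rng)
        assert (len(tr), len(val), len(te)) == (6, 2, 2)
        assert set(labels[tr]) == {0, 1}
        assert sorted(np.concatenate([tr, val, te])) == list(range(10))

    def test_same_seed_identical_split(self):
        labels = np.array([0] * 9 + [1] * 9)
        a = split_data(labels, FRACTIONS, np.random.default_rng(7))
        b = split_data(labels, FRACTIONS, np.random.default_rng(7))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_largest_remainder_sizes_exact_over_seeds(self):
        # the subset sizes are a deterministic function of n alone
        assert subset_sizes(18, FRACTIONS) == (11, 4, 3)
        assert subset_sizes(10, FRACTIONS) == (6, 2, 2)
        assert subset_sizes(5, FRACTIONS) == (3, 1, 1)
        labels = np.array([0] * 9 + [1] * 9)
        for seed in range(200):
            tr, val, te = split_data(labels, FRACTIONS, np.random.default_rng(seed))
            assert (len(tr), len(val), len(te)) == (11, 4, 3)
            assert set(labels[tr]) == {0, 1}

    def test_impossible_stratification_raises(self):
        labels = np.array([0] * 5)  # single class: train can never hold both
        with pytest.raises(RuntimeError):
            split_data(np.array([0, 0, 0, 0, 1]), FRACTIONS,
                       np.random.default_rng(0), max_retries=0)
        del labels

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_data(np.array([0, 1]), FRACTIONS, np.random.default_rng(0))


class TestSingleNet:
    def test_perfect_separator_low_test_error(self):
        rng = np.random.default_rng(3)
        labels = np.array([0] * 9 + [1] * 9)
        expr = labels * 4.0 + rng.normal(0, 0.2, 18)
        cfg = AnnConfig(seed=5)
        splits = split_data(labels, FRACTIONS, np.random.default_rng(5))
        err, _ = train_single_input_net(expr, labels, splits, cfg,
                                        np.random.default_rng(5))
        assert err <= 0.05

    def test_constant_transcript_near_prior_baseline(self):
        labels = np.array([0] * 9 + [1] * 9)
        expr = np.full(18, 3.3)
        cfg = AnnConfig(seed=5)
        splits = split_data(labels, FRACTIONS, np.random.default_rng(5))
        err, _ = train_single_input_net(expr, labels, splits, cfg,
                                        np.random.default_rng(5))
        te_labels = labels[splits[2]]
        prior_err = np.mean((te_labels - labels[splits[0]].mean()) ** 2)
        assert abs(err - prior_err) < 0.15

    def test_duplicated_transcripts_equal_errors(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 9 + [1] * 9)
        expr = pd.DataFrame(
            {"a": rng.normal(0, 1, 18), "s1": labels + rng.normal(0, 0.5, 18)}
        )
        expr["a2"] = expr["a"]  # duplicate content, different name/stream
        cfg = dict(n_resamples=8, random_state=4)
        r1 = NeuralNetRanker(**cfg).fit(expr[["a", "s1"]], labels)
        r2 = NeuralNetRanker(**cfg).fit(expr[["a", "s1", "a2"]], labels)
        t1 = r1.ranking_.set_index("probeset_id")
        t2 = r2.ranking_.set_index("probeset_id")
        # identical streams per name: existing transcripts' errors unchanged
        for name in ("a", "s1"):
            assert t1.loc[name, "mean_test_error"] == t2.loc[name, "mean_test_error"]


class TestRanker:
    def test_planted_recovery_small(self):
        expr, labels, informative = fixtures.make_expression_matrix(
            n_transcripts=150, n_informative=8, seed=21
        )
        cfg = AnnConfig(seed=3, n_resamples=20, top_k=30)
        ranking = annrank.rank_transcripts(expr, labels, cfg)
        top = set(ranking["probeset_id"].head(30))
        assert len(top & set(informative)) >= 7

    def test_ranking_deterministic_and_order_independent(self):
        expr, labels, _ = fixtures.make_expression_matrix(
            n_transcripts=60, n_informative=5, seed=8
        )
        cfg = AnnConfig(seed=11, n_resamples=5)
        a = annrank.rank_transcripts(expr, labels, cfg)
        b = annrank.rank_transcripts(expr, labels, cfg)
        pd.testing.assert_frame_equal(a, b)
        shuffled = expr.sample(frac=1.0, random_state=1)
        c = annrank.rank_transcripts(shuffled, labels, cfg)
        pd.testing.assert_frame_equal(a, c)

    def test_full_ranking_is_permutation(self):
        expr, labels, _ = fixtures.make_expression_matrix(
            n_transcripts=25, n_informative=3, seed=9
        )
        ranking = annrank.rank_transcripts(
            expr, labels, AnnConfig(seed=2, n_resamples=3, top_k=25)
        )
        assert sorted(ranking["probeset_id"]) == sorted(expr.index)
        assert ((ranking["mean_test_error"] >= 0) & (ranking["mean_test_error"] <= 1)).all()

    def test_errors_sorted_ascending(self):
        expr, labels, _ = fixtures.make_expression_matrix(
            n_transcripts=30, n_informative=3, seed=10
        )
        ranking = annrank.rank_transcripts(
            expr, labels, AnnConfig(seed=2, n_resamples=3)
        )
        errs = ranking["mean_test_error"].to_numpy()
        assert (np.diff(errs) >= 0).all()

    def test_sklearn_params_contract(self):
        est = NeuralNetRanker(n_resamples=7)
        assert est.get_params()["n_resamples"] == 7
        est.set_params(top_k=12)
        assert est.top_k == 12


class TestInteraction:
    def test_planted_linear_dependency_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (18, 20))
        X[:, 7] = 0.8 * X[:, 3] + rng.normal(0, 0.2, 18)
        names = [f"m{i:02d}" for i in range(20)]
        est = MarkerInteraction(random_state=2).fit(pd.DataFrame(X, columns=names))
        col = est.influence_["m07"].drop("m07")
        assert col.idxmax() == "m03" and col.abs().idxmax() == "m03"

    def test_null_markers_centered_at_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (18, 20))
        est = MarkerInteraction(random_state=2).fit(pd.DataFrame(X))
        vals = est.influence_.to_numpy()[~np.eye(20, dtype=bool)]
        assert abs(vals.mean()) < 0.05

    def test_constant_markers_zeroed_with_warning(self, caplog):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (12, 5))
        X[:, 2] = 1.0
        with caplog.at_level("WARNING"):
            est = MarkerInteraction(random_state=0).fit(pd.DataFrame(X))
        assert (est.influence_.iloc[2, :] == 0).all()
        assert (est.influence_.iloc[:, 2] == 0).all()

    def test_all_constant_inputs_zero_matrix(self):
        X = np.ones((10, 4))
        est = MarkerInteraction(random_state=0).fit(pd.DataFrame(X))
        assert (est.influence_.to_numpy() == 0).all()

    def test_diagonal_zero_and_top_edges_shape(self):
        rng = np.random.default_rng(8)
        est = MarkerInteraction(random_state=1).fit(
            pd.DataFrame(rng.normal(0, 1, (14, 12)))
        )
        assert (np.diag(est.influence_.to_numpy()) == 0).all()
        edges = est.top_edges(10)
        assert len(edges) == 20
        assert (edges.loc[edges["sign"] == "positive", "influence"] >=
                edges.loc[edges["sign"] == "negative", "influence"].max()).all()
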