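import numpy as np
import pandas as pd
import pytest

from drugatlas import (
    SynergyLogit,
    SynergyTable,
    assemble_features,
    covariate_contribution,
    eq2_minimize,
    eq2_objective,
    eq3_pair_scores,
    eq3_simplistic,
    evaluate_auc,
    generate_feature_rows,
    roc_auc,
)
from conftest import random_distance_matrix


def brute_force_auc(labels, scores):
    """Rank oracle: P(random positive scores above random negative),
    ties counted half."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAssembleFeatures:
    @pytest.fixture()
    def inputs(self, toy_annotation):
        dist = random_distance_matrix(3, 4, labels=["dA", "dB", "dC"])
        sens = pd.DataFrame({
            "cell_line": ["c1", "c1", "c1", "c2", "c2", "c2"],
            "tissue": "brain",
            "drug": ["dA", "dB", "dC"] * 2,
            "S": [0.5, 1.5, 1.0, 0.8, 1.2, 1.0],
        })
        return dist, sens, toy_annotation

    def test_one_row_per_line_pair(self, inputs):
        dist, sens, ann = inputs
        table = SynergyTable(pd.DataFrame({
            "cell_line": ["c1"], "drug_a": ["dA"], "drug_b": ["dB"],
            "label": [1]}))
        rows = assemble_features(dist, sens, ann, table)
        assert len(rows) == 1
        assert rows.loc[0, "t"] == 1.0  # dA targets EGFR mutated in c1

    def test_full_pairing_count(self, inputs):
        dist, sens, ann = inputs
        recs = [{"cell_line": c, "drug_a": a, "drug_b": b, "label": 0}
                for c in ("c1", "c2")
                for a, b in (("dA", "dB"), ("dA", "dC"), ("dB", "dC"))]
        rows = assemble_features(dist, sens, ann, SynergyTable(pd.DataFrame(recs)))
        assert len(rows) == 6  # C(3,2) pairs x 2 lines

    def test_unannotated_drug_propagates_baseline_t(self, inputs):
        dist, sens, ann = inputs
        ann.targets_of.pop("dB")
        table = SynergyTable(pd.DataFrame({
            "cell_line": ["c3"], "drug_a": ["dA"], "drug_b": ["dB"],
            "label": [0]}))
        rows = assemble_features(dist, sens, ann, table)
        assert rows.loc[0, "T_j"] == 0.01
        assert rows.loc[0, "C"] == 0  # c3 has no sensitivity rows

    def test_missing_distance_drops_row(self, inputs, caplog):
        dist, sens, ann = inputs
        m = dist.matrix.copy()
        m.loc["dA", "dB"] = m.loc["dB", "dA"] = np.nan
        from drugatlas import DistanceMatrix
        table = SynergyTable(pd.DataFrame({
            "cell_line": ["c1"], "drug_a": ["dA"], "drug_b": ["dB"],
            "label": [1]}))
        with caplog.at_level("WARNING", logger="drugatlas"):
            rows = assemble_features(DistanceMatrix(m), sens, ann, table)
        assert len(rows) == 0


class TestClosedFormScores:
    def test_eq2_zero_without_sensitivity_info(self):
        rows = pd.DataFrame({"C": [0], "S_i": [1.0], "S_j": [1.0],
                             "d": [0.5], "T_i": [1.0], "T_j": [0.01]})
        vals, total = eq2_objective(rows, 1, 1, 1)
        assert total == 0.0

    def test_eq2_hand_arithmetic(self):
        rows = pd.DataFrame({"C": [1], "S_i": [1.0], "S_j": [1.0],
                             "d": [0.5], "T_i": [1.0], "T_j": [0.01]})
        _, total = eq2_objective(rows, 1, 1, 1)
        assert total == pytest.approx(-1 + 0.5 + 1.01)

    def test_eq2_linear_in_params(self):
        rows = pd.DataFrame({"C": [1, 1], "S_i": [0.7, 1.3], "S_j": [1.1, 0.9],
                             "d": [0.2, 0.9], "T_i": [0.01, 1.0],
                             "T_j": [0.01, 0.01]})
        _, t1 = eq2_objective(rows, 1, 2, 3)
        _, t2 = eq2_objective(rows, 2, 4, 6)
        assert t2 == pytest.approx(2 * t1)

    def test_eq2_minimize_runs_within_bounds(self):
        rows = pd.DataFrame({"C": [1, 1], "S_i": [0.7, 1.3], "S_j": [1.1, 0.9],
                             "d": [0.2, 0.9], "T_i": [0.01, 1.0],
                             "T_j": [0.01, 0.01]})
        out = eq2_minimize(rows)
        assert 0 <= out["s"] <= 10

    def test_eq3_values(self):
        assert eq3_simplistic(1.0, 0.0) == pytest.approx(0.5)
        assert eq3_simplistic(1.0, 1.0) == pytest.approx(np.e / (1 + np.e))
        assert eq3_simplistic(0.01, 0.0) == pytest.approx(0.01 / 1.01)

    def test_eq3_is_logistic_of_d_plus_log_t(self):
        ts = np.array([0.01, 1.0])
        ds = np.linspace(0, 2, 9)
        for t in ts:
            got = eq3_simplistic(t, ds)
            expected = 1.0 / (1.0 + np.exp(-(ds + np.log(t))))
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_eq3_pair_averaging(self):
        rows = pd.DataFrame({
            "drug_i": ["a", "a"], "drug_j": ["b", "b"],
            "t": [1.0, 0.01], "d": [0.5, 0.5],
        })
        out = eq3_pair_scores(rows)
        expected = (eq3_simplistic(1.0, 0.5) + eq3_simplistic(0.01, 0.5)) / 2
        assert out.loc[0, "theta"] == pytest.approx(expected)


class TestFitLogistic:
    def test_null_covariates_give_near_zero_slopes(self):
        rng = np.random.default_rng(0)
        n = 3000
        df = pd.DataFrame({
            "d": rng.uniform(0, 1, n),
            "t": np.where(rng.random(n) < 0.4, 1.0, 0.01),
            "S_i": rng.normal(1, 0.5, n), "S_j": rng.normal(1, 0.5, n),
            "label": rng.integers(0, 2, n), "tissue": "all", "C": 1,
        })
        df["S_sum"] = df["S_i"] + df["S_j"]
        fit = SynergyLogit(df, model="IIB").fit(n_resamples=20, seed=1)
        assert abs(fit.params["beta"]) < 0.3
        assert abs(fit.params["delta"]) < 0.3
        assert abs(fit.params["gamma"]) < 0.3

    def test_recovers_generating_coefficients(self):
        df = generate_feature_rows(2000, coeffs=(-2, 2, 3, -1), seed=5)
        fit = SynergyLogit(df, model="IIB").fit(n_resamples=20, seed=5)
        assert fit.params["beta"] == pytest.approx(2.0, rel=0.25)
        assert fit.params["delta"] == pytest.approx(3.0, rel=0.25)
        assert fit.params["gamma"] == pytest.approx(-1.0, rel=0.35)

    def test_small_stratum_skipped_then_error(self):
        df = generate_feature_rows(40, seed=2)
        df["label"] = 0
        df.loc[:2, "label"] = 1  # 3 positives < 5
        with pytest.raises(ValueError, match="stratum"):
            SynergyLogit(df).fit(n_resamples=2, seed=0)

    def test_nested_covariate_sets(self):
        df = generate_feature_rows(500, seed=3)
        fa = SynergyLogit(df, model="IA").fit(n_resamples=2, seed=0)
        fb = SynergyLogit(df, model="IIB").fit(n_resamples=2, seed=0)
        assert set(fa.params.index) <= set(fb.params.index)
        assert list(fb.params.index) == ["alpha", "beta", "delta", "gamma"]

    def test_deterministic_given_seed(self):
        df = generate_feature_rows(600, seed=4)
        f1 = SynergyLogit(df).fit(n_resamples=5, seed=9)
        f2 = SynergyLogit(df).fit(n_resamples=5, seed=9)
        pd.testing.assert_series_equal(f1.params, f2.params)

    def test_separation_handled_with_ridge(self):
        # perfectly separable by d
        df = pd.DataFrame({
            "d": np.r_[np.zeros(10), np.ones(10)],
            "t": 0.01, "S_i": 1.0, "S_j": 1.0,
            "label": np.r_[np.zeros(10, int), np.ones(10, int)],
            "tissue": "all", "C": 1,
        })
        df["S_sum"] = 2.0
        fit = SynergyLogit(df, model="IB").fit(n_resamples=3, seed=0)
        assert fit.n_separated == 3
        assert np.all(np.isfinite(fit.params))

    def test_summary_mentions_model_and_coefs(self):
        df = generate_feature_rows(500, seed=6)
        fit = SynergyLogit(df, model="IB").fit(n_resamples=2, seed=0)
        text = fit.summary()
        assert "IB" in text and "beta" in text and "delta" in text


class TestAUC:
    def test_constant_scores_half(self):
        auc, _, _ = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_perfect_separation_one(self):
        auc, _, _ = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == pytest.approx(1.0)

    def test_one_inversion_matches_rank_oracle(self):
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.8, 0.7, 0.45, 0.5, 0.3, 0.2, 0.1]
        auc, _, _ = roc_auc(labels, scores)
        assert auc == pytest.approx(15 / 16)
        assert auc == pytest.approx(brute_force_auc(labels, scores))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_rank_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.random(30).round(1)  # ties included
        auc, _, _ = roc_auc(labels, scores)
        assert auc == pytest.approx(brute_force_auc(labels, scores))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_cv_folds_grouped_by_pair(self):
        df = generate_feature_rows(400, seed=8)
        rng = np.random.default_rng(0)
        pairs = [f"p{i}" for i in range(20)]
        df["drug_i"] = rng.choice(pairs, len(df))
        df["drug_j"] = "x"
        fit = SynergyLogit(df).fit(n_resamples=3, seed=0)
        out = evaluate_auc(fit, fit.model.features, scheme="cv_kfold",
                           n_folds=4, n_resamples=3, seed=0)
        assert 0.5 < out["auc"] <= 1.0


class TestRanking:
    def test_single_candidate(self):
        df = generate_feature_rows(300, seed=1)
        fit = SynergyLogit(df).fit(n_resamples=2, seed=0)
        one = df.iloc[[0]]
        ranked = fit.rank_predictions(one)
        assert len(ranked) == 1

    def test_monotone_in_distance_for_positive_delta(self):
        df = generate_feature_rows(2000, seed=2)
        fit = SynergyLogit(df, model="IB").fit(n_resamples=5, seed=0)
        assert fit.params["delta"] > 0
        cands = pd.DataFrame({"t": 1.0, "d": [0.1, 0.5, 0.9],
                              "S_i": 1.0, "S_j": 1.0, "S_sum": 2.0,
                              "label": 0, "tissue": "all", "C": 1})
        ranked = fit.rank_predictions(cands)
        assert list(ranked["d"]) == [0.9, 0.5, 0.1]

    def test_tie_break_larger_d_then_lexicographic(self):
        df = generate_feature_rows(500, seed=3)
        fit = SynergyLogit(df, model="IA").fit(n_resamples=2, seed=0)
        cands = pd.DataFrame({
            "t": [0.01, 0.01, 0.01], "d": [0.2, 0.8, 0.8],
            "S_sum": 2.0, "S_i": 1.0, "S_j": 1.0,
            "drug_i": ["b", "a", "a"], "drug_j": ["c", "z", "b"],
            "label": 0, "tissue": "all", "C": 1,
        })
        ranked = fit.rank_predictions(cands)
        # model IA ignores d: all thetas tie; larger d first, then lexicographic
        assert list(zip(ranked["drug_i"], ranked["drug_j"])) == [
            ("a", "b"), ("a", "z"), ("b", "c")]


class TestCovariateContribution:
    def test_distance_free_generator_no_gain(self):
        df = generate_feature_rows(1500, coeffs=(-1.5, 2.0, 0.0, -1.0), seed=4)
        out = covariate_contribution(df, n_resamples=15, seed=1)
        row = out[out["comparison"] == "IB - IA"].iloc[0]
        assert abs(row["delta_auc"]) < 0.02

    def test_distance_driven_generator_detected(self):
        df = generate_feature_rows(2000, coeffs=(-2, 2, 3, -1), seed=5)
        out = covariate_contribution(df, n_resamples=15, seed=2)
        for _, row in out.iterrows():
            assert row["delta_auc"] > 0
            assert row["p_one_sided"] < 0.05
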