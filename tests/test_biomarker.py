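"""AUC, permutation screen, logistic IRLS, LOOCV and stepwise panel growth."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sleepmet.biomarker import (
    BiomarkerError,
    CandidateSet,
    auc,
    classify,
    fit_logistic,
    loocv_auc,
    loocv_probabilities,
    metrics_from_counts,
    permutation_auc_pvalue,
    roc_auc,
    roc_curve,
    stepwise_select,
    _predict_proba,
)
from sleepmet.config import PipelineConfig


class TestAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
            ([1, 2, 3, 4], [0, 1, 0, 1], 0.75),
            ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(BiomarkerError):
            auc([1, 2], [1, 1])


class TestPermutationAuc:
    def test_perfect_separation_tiny_p(self):
        vals = np.r_[np.zeros(10), np.ones(10) + 5]
        labels = np.r_[np.zeros(10), np.ones(10)]
        p = permutation_auc_pvalue(vals, labels, 9999, seed=0)
        assert p <= 0.001

    def test_exhaustive_enumeration_oracle_n3_plus_3(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        obs = max(auc(vals, labels), 1 - auc(vals, labels))
        null = []
        for pos in itertools.combinations(range(6), 3):
            lab = np.zeros(6, dtype=int)
            lab[list(pos)] = 1
            a = auc(vals, lab)
            null.append(max(a, 1 - a))
        exact = np.mean([x >= obs - 1e-12 for x in null])
        p_mc = permutation_auc_pvalue(vals, labels, 9999, seed=2)
        # Monte-Carlo add-one estimate vs the exhaustive 20-arrangement truth
        assert p_mc == pytest.approx(exact, abs=0.03)

    def test_null_pvalues_centred(self):
        rng = np.random.default_rng(3)
        ps = []
        for seed in range(100):
            vals = np.random.default_rng(500 + seed).standard_normal(20)
            labels = np.r_[np.zeros(10), np.ones(10)]
            ps.append(permutation_auc_pvalue(vals, labels, 199, seed=seed))
        assert 0.4 <= np.mean(ps) <= 0.6

    def test_add_one_floor(self):
        vals = np.r_[np.zeros(5), np.ones(5)]
        labels = np.r_[np.zeros(5), np.ones(5)]
        assert permutation_auc_pvalue(vals, labels, 99, seed=0) >= 1 / 100


class TestLogistic:
    def test_symmetric_data_zero_intercept(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        beta, ridge = fit_logistic(x, y)
        assert not ridge or abs(beta[0]) < 1e-6
        assert abs(beta[0]) < 1e-6

    def test_matches_statsmodels_irls_oracle(self):
        import statsmodels.api as sm_api

        # overlapping classes so the MLE exists (no separation)
        X = np.array([[0.5], [1.2], [-0.3], [2.0], [-1.5], [0.1], [1.0], [-0.8]])
        y = np.array([1, 0, 0, 1, 0, 1, 1, 0])
        beta, ridge = fit_logistic(X, y)
        assert not ridge
        oracle = sm_api.Logit(y, sm_api.add_constant(X)).fit(disp=0)
        assert np.allclose(beta, oracle.params, atol=1e-6)

    def test_planted_positive_effect_positive_sign(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        y = (x + 0.3 * rng.standard_normal(60) > 0).astype(int)
        beta, _ = fit_logistic(x, y)
        assert beta[1] > 0

    def test_separable_data_falls_back_to_ridge(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0, 3.0, -3.0])
        y = (x > 0).astype(int)
        beta, ridge = fit_logistic(x, y)
        assert ridge
        assert np.isfinite(beta).all()


class TestLoocv:
    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 2))
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        probs = loocv_probabilities(X, y)
        for i in range(8):
            mask = np.ones(8, dtype=bool)
            mask[i] = False
            beta, _ = fit_logistic(X[mask], y[mask])
            assert probs[i] == pytest.approx(_predict_proba(beta, X[i : i + 1])[0], abs=1e-12)

    def test_strong_marker_high_auc(self):
        rng = np.random.default_rng(6)
        y = np.repeat([0, 1], 12)
        conc = pd.DataFrame({"m": np.exp(rng.standard_normal(24) * 0.2 + 3.0 * y)})
        labels = pd.Series(y, index=conc.index)
        assert loocv_auc(conc, ["m"], labels) > 0.9

    def test_noise_marker_modest_auc(self):
        rng = np.random.default_rng(7)
        y = np.repeat([0, 1], 12)
        conc = pd.DataFrame({"m": np.exp(rng.standard_normal(24))})
        labels = pd.Series(y, index=conc.index)
        assert loocv_auc(conc, ["m"], labels) < 0.7

    def test_loocv_not_optimistic_on_null_data(self):
        # averaged over seeds, held-out AUC stays at/below the resubstitution AUC
        diffs = []
        for seed in range(60):
            rng = np.random.default_rng(2000 + seed)
            y = np.repeat([0, 1], 10)
            x = rng.standard_normal(20)
            conc = pd.DataFrame({"m": np.exp(x)})
            labels = pd.Series(y, index=conc.index)
            cv = loocv_auc(conc, ["m"], labels)
            non_cv = max(auc(x, y), 1 - auc(x, y))
            diffs.append(cv - non_cv)
        assert np.mean(diffs) <= 0


def _candidate_set(ids, q=0.01):
    flags = pd.DataFrame(
        {
            "fdr_pass": True,
            "perm_auc_pass": True,
            "pct_diff_pass": True,
            "q_value": q,
            "auc": np.nan,
            "perm_p": np.nan,
            "pct_diff": np.nan,
        },
        index=pd.Index(ids),
    )
    return CandidateSet(flags)


class TestStepwise:
    def test_single_candidate_one_step(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 12)
        conc = pd.DataFrame({"m": np.exp(0.2 * rng.standard_normal(24) + 2.0 * y)})
        labels = pd.Series(y, index=conc.index)
        model = stepwise_select(_candidate_set(["m"]), conc, labels)
        assert model.selected == ["m"]
        assert len(model.trajectory) == 1

    def test_empty_candidates_null_model(self):
        conc = pd.DataFrame({"m": np.exp(np.random.default_rng(9).standard_normal(10))})
        labels = pd.Series(np.repeat([0, 1], 5), index=conc.index)
        model = stepwise_select(_candidate_set([]), conc, labels)
        assert model.selected == []
        assert model.final_auc == 0.5

    def test_trajectory_strictly_increasing(self, sr_contrast):
        conc, labels = sr_contrast
        ids = ["Kynurenine", "Ile", "Leu", "Phe", "C2"]
        model = stepwise_select(_candidate_set(ids), conc[ids], labels)
        assert all(b > a for a, b in zip(model.trajectory, model.trajectory[1:]))

    def test_selection_invariant_to_candidate_order(self, sr_contrast):
        conc, labels = sr_contrast
        ids = ["Kynurenine", "Ile", "Phe"]
        m1 = stepwise_select(_candidate_set(ids), conc[ids], labels)
        m2 = stepwise_select(_candidate_set(ids[::-1]), conc[ids], labels)
        assert m1.selected == m2.selected
        assert m1.final_auc == pytest.approx(m2.final_auc)


class TestRoc:
    def test_perfect_classifier_passes_corner(self):
        r = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert any(np.allclose(pt, [0, 1]) for pt in r)

    def test_trapezoid_area_equals_mann_whitney(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=30)
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert roc_auc(roc_curve(p, y)) == pytest.approx(auc(p, y), abs=1e-12)

    def test_constant_probabilities_diagonal(self):
        r = roc_curve([0.5] * 10, [0, 1] * 5)
        assert roc_auc(r) == pytest.approx(0.5)

    def test_endpoints_and_monotonicity(self):
        r = roc_curve(np.random.default_rng(11).uniform(size=15), [0, 1] * 7 + [0])
        assert np.allclose(r[0], [0, 0]) and np.allclose(r[-1], [1, 1])
        assert (np.diff(r[:, 0]) >= 0).all() and (np.diff(r[:, 1]) >= 0).all()


class TestClassify:
    def test_published_counts_round_to_seventy_percent_sensitivity(self):
        # 9 of 11 ROT-SR and 7 of 12 SHAM-SR predicted as SR -> 16/23 = 69.6%
        sens = metrics_from_counts({"ROT-SR": (9, 11), "SHAM-SR": (7, 12)})
        assert round(100 * sens) == 70

    def test_perfect_probabilities(self):
        m = classify([1.0, 1.0, 0.0], [1, 1, 0])
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0

    def test_threshold_is_strict(self):
        m = classify([0.5], [1], threshold=0.5)
        assert m["fn"] == 1 and m["tp"] == 0
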