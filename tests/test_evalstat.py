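"""Metrics and paired comparison statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from prommf.evalstat import (
    ComparisonReport,
    PredictionSet,
    cohens_d_paired,
    compare_models,
    group_metrics,
    paired_bootstrap_auc,
    paired_permutation_test,
    power_parametric_mc,
    precision_recall_f1,
    roc_auc,
)
from prommf.syncohort import generate_score_pairs


def _pred(scores, labels, ids=None, groups=None):
    ids = ids or [f"p{i}" for i in range(len(scores))]
    return PredictionSet(ids, np.asarray(scores, float),
                         np.asarray(labels, int), groups or {})


def _auc_bruteforce(scores, labels):
    """All-pairs concordance count with 1/2 for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_and_tied_cases(self):
        assert roc_auc(_pred([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])) == 1.0
        assert roc_auc(_pred([0.5] * 6, [1, 0, 1, 0, 1, 0])) == 0.5

    def test_hand_counted_example(self):
        pred = _pred([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc_auc(pred) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        assert roc_auc(_pred(scores, labels)) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc(_pred([0.1, 0.2], [1, 1]))


class TestPrecisionRecallF1:
    def test_all_correct(self):
        p, r, f = precision_recall_f1(_pred([0.9, 0.9, 0.1], [1, 1, 0]))
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_no_predicted_positives_flagged_zero(self):
        p, r, f = precision_recall_f1(_pred([0.1, 0.2], [1, 0]))
        assert (p, r, f) == (0.0, 0.0, 0.0)

    def test_hand_confusion_counts(self):
        # TP=5, FP=1, FN=3, TN=1
        scores = [0.9] * 5 + [0.9] + [0.1] * 3 + [0.1]
        labels = [1] * 5 + [0] + [1] * 3 + [0]
        p, r, f = precision_recall_f1(_pred(scores, labels))
        assert p == pytest.approx(5 / 6)
        assert r == pytest.approx(5 / 8)
        assert f == pytest.approx(2 * (5 / 6) * (5 / 8) / (5 / 6 + 5 / 8))


class TestGroupMetrics:
    def test_single_group_equals_global(self):
        pred = _pred([0.9, 0.2, 0.7, 0.3], [1, 0, 1, 0],
                     groups={"stage": np.array(["a"] * 4)})
        table = group_metrics(pred, "stage")
        assert len(table) == 1
        assert table.iloc[0]["auc"] == roc_auc(pred)

    def test_group_missing_a_class_gets_nan_auc(self):
        pred = _pred([0.9, 0.2, 0.7, 0.3], [1, 0, 1, 1],
                     groups={"stage": np.array(["a", "a", "b", "b"])})
        table = group_metrics(pred, "stage").set_index("group")
        assert np.isnan(table.loc["b", "auc"])
        assert not np.isnan(table.loc["a", "auc"])


class TestPairedBootstrap:
    def test_identical_models_have_zero_delta_and_equal_cis(self, rng):
        s = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        ci_a, ci_b, delta = paired_bootstrap_auc(s, s, y, n_boot=200, seed=0)
        assert np.all(delta == 0) and ci_a == ci_b

    def test_perfect_separation_gives_degenerate_ci(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        s = np.r_[np.ones(10), np.zeros(10)]
        ci_a, _, _ = paired_bootstrap_auc(s, s * 0.5, y, n_boot=200, seed=1)
        assert ci_a == (1.0, 1.0)

    def test_pairing_applies_same_indices_to_both_models(self, rng):
        """Per-replicate deltas identical when both models are relabeled together."""
        a, b, y = generate_score_pairs(60, 0.9, 0.7, seed=4)
        _, _, d1 = paired_bootstrap_auc(a, b, y, n_boot=300, seed=7)
        _, _, d2 = paired_bootstrap_auc(a, b, y, n_boot=300, seed=7)
        assert np.array_equal(d1, d2)

    def test_coverage_of_known_binormal_auc(self):
        """95% percentile CI covers the true AUC at roughly nominal rate."""
        truth, hits, n_data = 0.8, 0, 120
        for i in range(n_data):
            a, b, y = generate_score_pairs(150, truth, truth, seed=5000 + i)
            ci_a, _, _ = paired_bootstrap_auc(a, b, y, n_boot=800, seed=i)
            hits += ci_a[0] <= truth <= ci_a[1]
        assert abs(hits / n_data - 0.95) <= 0.05


class TestPairedPermutation:
    def test_identical_scores_give_p_one(self, rng):
        s = rng.random(30)
        assert paired_permutation_test(s, s, n_perm=500, seed=0) == 1.0

    def test_three_pairs_match_exhaustive_enumeration(self):
        """Monte-Carlo p within 3 binomial SEs of the exact 2^3-pattern p."""
        a = np.array([0.9, 0.7, 0.55])
        b = np.array([0.3, 0.6, 0.5])
        d = a - b
        t_obs = abs(d.mean())
        exact = np.mean([
            abs(np.mean([s1 * d[0], s2 * d[1], s3 * d[2]])) >= t_obs - 1e-15
            for s1, s2, s3 in itertools.product([-1, 1], repeat=3)
        ])
        n_perm = 4000
        p_mc = paired_permutation_test(a, b, n_perm=n_perm, seed=3)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p_mc - exact) <= 3 * se + 2 / n_perm

    def test_swapping_model_roles_leaves_p_unchanged(self, rng):
        a, b = rng.random(25), rng.random(25)
        p1 = paired_permutation_test(a, b, n_perm=1000, seed=9)
        p2 = paired_permutation_test(b, a, n_perm=1000, seed=9)
        assert p1 == p2

    def test_auc_difference_statistic_variant(self, rng):
        a, b, y = generate_score_pairs(50, 0.95, 0.6, seed=2)
        p = paired_permutation_test(a, b, n_perm=500, seed=1,
                                    statistic="auc_difference", labels=y)
        assert 0 < p <= 1

    def test_empirical_size_near_alpha_under_null(self):
        """Rejection rate at alpha=0.05 within the 99% binomial band."""
        n_data, rej = 200, 0
        for i in range(n_data):
            a, b, _ = generate_score_pairs(57 * 2, 0.8, 0.8, seed=20_000 + i)
            rej += paired_permutation_test(a[:57], b[:57], n_perm=500,
                                           seed=i) <= 0.05
        band = 2.576 * np.sqrt(0.05 * 0.95 / n_data)
        assert abs(rej / n_data - 0.05) <= band

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError, match="labels"):
            paired_permutation_test(np.zeros(5), np.ones(5),
                                    statistic="auc_difference")


class TestCohensD:
    def test_zero_mean_difference(self):
        d, _ = cohens_d_paired(np.array([1.0, -1.0]), np.zeros(2))
        assert d == 0.0

    def test_hand_computed_value(self):
        d, sign = cohens_d_paired(np.array([0.1, 0.2, 0.3]), np.zeros(3))
        assert d == pytest.approx(2.0)
        assert sign == 1

    def test_constant_differences_are_undefined(self):
        d, sign = cohens_d_paired(np.array([0.4, 0.4]), np.zeros(2))
        assert d is None and sign == 1


class TestPower:
    def test_size_equals_alpha_at_zero_effect(self):
        power = power_parametric_mc(0.0, 1.0, 57, n_sim=4000, seed=0)
        se = np.sqrt(0.05 * 0.95 / 4000)
        assert abs(power - 0.05) <= 3 * se

    def test_large_standardised_effect_saturates(self):
        assert power_parametric_mc(2.0, 1.0, 57, n_sim=2000, seed=1) == 1.0

    @pytest.mark.parametrize("effect,n", [(0.3, 20), (0.5, 30), (0.8, 57)])
    def test_matches_noncentral_t_closed_form(self, effect, n):
        n_sim = 8000
        mc = power_parametric_mc(effect, 1.0, n, n_sim=n_sim, seed=42)
        crit = stats.t.ppf(0.975, n - 1)
        ncp = effect * np.sqrt(n)
        closed = 1 - stats.nct.cdf(crit, n - 1, ncp) + stats.nct.cdf(-crit, n - 1, ncp)
        se = np.sqrt(closed * (1 - closed) / n_sim)
        assert abs(mc - closed) <= 3 * se + 1e-9

    def test_monotone_in_effect_size(self):
        grid = [power_parametric_mc(e, 1.0, 30, n_sim=3000, seed=7)
                for e in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert all(b >= a - 0.01 for a, b in zip(grid, grid[1:]))

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            power_parametric_mc(0.5, 0.0, 10)


class TestCompareModels:
    def test_identical_models_are_null(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        rep = compare_models(_pred(s, y), _pred(s, y), n_boot=200, n_perm=200,
                             n_sim=200, seed=0)
        assert rep.p_permutation == 1.0
        assert rep.delta_observed == 0.0
        assert rep.cohen_d is None  # zero-variance differences

    def test_report_fields_within_ranges_and_reproducible(self):
        a, b, y = generate_score_pairs(80, 0.9, 0.7, seed=6)
        kw = dict(n_boot=300, n_perm=400, n_sim=300, seed=11)
        rep1 = compare_models(_pred(a, y), _pred(b, y), **kw)
        rep2 = compare_models(_pred(a, y), _pred(b, y), **kw)
        rep1.validate()
        assert rep1.to_json() == rep2.to_json()
        assert 0 <= rep1.power <= 1
        assert rep1.auc_a > rep1.auc_b

    def test_misaligned_patients_rejected(self, rng):
        s = rng.random(10)
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        pa = _pred(s, y)
        pb = _pred(s, y, ids=[f"q{i}" for i in range(10)])
        with pytest.raises(ValueError, match="identical patients"):
            compare_models(pa, pb)


def test_prediction_set_csv_roundtrip(tmp_path, rng):
    pred = _pred(rng.random(8), rng.integers(0, 2, 8),
                 groups={"stage": np.array(["a", "b"] * 4)})
    pred.to_frame().to_csv(tmp_path / "s.csv", index=False)
    back = PredictionSet.from_csv(tmp_path / "s.csv")
    assert np.allclose(back.scores, pred.scores)
    assert np.array_equal(back.labels, pred.labels)
    assert list(back.groups["stage"]) == list(pred.groups["stage"])


def test_comparison_report_validation_catches_bad_fields():
    rep = ComparisonReport(auc_a=0.9, auc_b=0.8, ci_a=(0.8, 0.95),
                           ci_b=(0.7, 0.9), delta_observed=0.1,
                           p_permutation=0.0, cohen_d=1.0)
    with pytest.raises(ValueError):
        rep.validate()
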