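import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from etho3d.stats import (
    classify_presets,
    compare_groups,
    compare_metric_family,
    lda_loocv_classify,
    null_family_significance_rate,
    zscore_features,
)
from etho3d.vocab import BEHAVIORS_13


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        x = np.arange(10.0)
        res = compare_groups(x, x.copy())
        assert res.p_raw > 0.9
        assert not res.significant

    def test_large_programmed_effect_always_detected(self):
        """Two n=19 normal groups three SDs apart are detected at adjusted
        p < 0.001 for every seed, even with a 13-fold correction."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = rng.normal(0, 1, 19)
            b = rng.normal(3, 1, 19)
            res = compare_groups(a, b, n_comparisons=13)
            assert res.p_adjusted < 0.001

    def test_bonferroni_dunn_arithmetic(self):
        # p_raw 0.01 with 13 comparisons adjusts to 0.13
        assert min(1.0, 13 * 0.01) == pytest.approx(0.13)
        rng = np.random.default_rng(5)
        res = compare_groups(rng.normal(0, 1, 19), rng.normal(1, 1, 19),
                             n_comparisons=13)
        assert res.p_adjusted == pytest.approx(min(1.0, 13 * res.p_raw))
        assert res.p_adjusted >= res.p_raw

    def test_constant_group_falls_through_to_mwu(self):
        res = compare_groups(np.zeros(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert res.test_used == "mann_whitney_u"
        assert "constant" in res.note

    def test_normal_homoscedastic_uses_t_test(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(0.2, 1, 30))
        assert res.test_used == "t_test"

    def test_skewed_data_uses_mwu(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.exponential(1, 40) ** 2,
                             rng.exponential(1, 40) ** 2)
        assert res.test_used == "mann_whitney_u"

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_family_comparison_uses_column_count(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        b = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        out = compare_metric_family(a, b)
        assert len(out) == 4
        assert all(c.n_comparisons == 4 for c in out)


class TestZScore:
    def test_column_standardization(self):
        z = zscore_features(np.array([[1.0], [2.0], [3.0]]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std() == pytest.approx(1.0)

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_features(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert np.all(z[:, 1] == 0.0)

    def test_idempotence(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(20, 5)) * 7 + 3
        z = zscore_features(x)
        assert np.allclose(zscore_features(z), z, atol=1e-12)


class TestLDA:
    def _clouds(self, gap, n=10, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 3))
        b = rng.normal(gap, 1, size=(n, 3))
        x = np.vstack([a, b])
        y = np.array(["control"] * n + ["affected"] * n)
        return x, y

    def test_separable_clouds_perfect_scores(self):
        x, y = self._clouds(gap=20.0)
        rep = lda_loocv_classify(x, y)
        assert rep.macro_f1 == 1.0
        assert rep.auc == 1.0
        assert rep.confusion.to_numpy().sum() == len(y)

    def test_auc_equals_mann_whitney_identity(self):
        x, y = self._clouds(gap=1.0, n=15, seed=3)
        rep = lda_loocv_classify(x, y)
        pos = rep.decision_scores[y == rep.positive_class]
        neg = rep.decision_scores[y != rep.positive_class]
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert rep.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-10)

    def test_label_swap_symmetry(self):
        """Renaming the groups negates every decision score, leaves the AUC
        unchanged (scores re-orient to the positive class), and scoring the
        original orientation against flipped labels gives 1 - AUC."""
        from sklearn.metrics import roc_auc_score

        x, y = self._clouds(gap=1.0, n=12, seed=4)
        rep1 = lda_loocv_classify(x, y)
        swapped = np.where(y == "control", "affected", "control")
        rep2 = lda_loocv_classify(x, swapped)
        assert np.allclose(rep2.decision_scores, -rep1.decision_scores, atol=1e-8)
        assert rep2.auc == pytest.approx(rep1.auc, abs=1e-10)
        y_bin = (y == rep1.positive_class).astype(int)
        assert roc_auc_score(1 - y_bin, rep1.decision_scores) == pytest.approx(
            1.0 - rep1.auc, abs=1e-10
        )

    def test_auc_invariant_under_monotone_transform(self):
        from sklearn.metrics import roc_auc_score

        x, y = self._clouds(gap=1.0, n=12, seed=5)
        rep = lda_loocv_classify(x, y)
        y_bin = (y == rep.positive_class).astype(int)
        assert roc_auc_score(y_bin, np.tanh(rep.decision_scores)) == pytest.approx(
            rep.auc, abs=1e-12
        )

    def test_matches_closed_form_pooled_covariance_discriminant(self):
        """The SVD-solved discriminant agrees with the textbook pooled-
        covariance solution w = S^-1 (mu1 - mu0) on well-conditioned data:
        decision scores are identical up to affine scale, so the held-out
        ranking (and AUC) matches exactly."""
        rng = np.random.default_rng(6)
        x = rng.normal(size=(24, 4))
        y = np.array(["a"] * 12 + ["b"] * 12)
        x[y == "b"] += [1.0, 0.5, -0.5, 0.2]
        rep = lda_loocv_classify(x, y, standardize="per_fold")
        # independent oracle: closed-form discriminant per LOOCV fold
        scores = np.empty(len(y))
        for i in range(len(y)):
            tr = np.ones(len(y), bool)
            tr[i] = False
            xtr = x[tr]
            mu, sd = xtr.mean(0), xtr.std(0)
            xtr = (xtr - mu) / sd
            xte = (x[i] - mu) / sd
            xa, xb = xtr[y[tr] == "a"], xtr[y[tr] == "b"]
            sw = (np.cov(xa.T, bias=False) * (len(xa) - 1)
                  + np.cov(xb.T, bias=False) * (len(xb) - 1)) / (len(xtr) - 2)
            w = np.linalg.solve(sw, xb.mean(0) - xa.mean(0))
            # equal class priors: the boundary is the midpoint of the means
            thresh = w @ (xa.mean(0) + xb.mean(0)) / 2
            scores[i] = xte @ w - thresh
        assert np.allclose(scores, rep.decision_scores, atol=1e-8)

    def test_small_groups_rejected(self):
        x = np.zeros((6, 2))
        y = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError):
            lda_loocv_classify(x, y)


class TestPresets:
    def _cohort_tables(self, effect, n=10, seed=0):
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(
            rng.poisson(40, size=(2 * n, 13)).astype(float), columns=list(BEHAVIORS_13)
        )
        fracs = pd.DataFrame(
            rng.dirichlet(np.ones(13) * 5, size=2 * n), columns=list(BEHAVIORS_13)
        )
        groups = np.array(["control"] * n + ["affected"] * n)
        if effect:
            fracs.loc[groups == "affected", "Pausing"] += 0.3
            fracs.loc[groups == "affected", ["Running", "Trotting", "Walking"]] *= 0.3
            counts.loc[groups == "affected", ["Running", "Trotting", "Walking"]] *= 0.4
        return counts, fracs, groups

    def test_feature_lists(self):
        counts, fracs, groups = self._cohort_tables(effect=False)
        reports = classify_presets(counts, fracs, groups)
        assert len(reports["counts13"].features_used) == 13
        assert reports["fractions4"].features_used == [
            "Running", "Trotting", "Walking", "Pausing"
        ]

    def test_programmed_effect_gives_high_auc(self):
        counts, fracs, groups = self._cohort_tables(effect=True, n=12)
        reports = classify_presets(counts, fracs, groups)
        assert reports["fractions4"].auc > 0.9

    def test_null_cohort_auc_in_chance_band(self):
        aucs = [
            classify_presets(*self._cohort_tables(effect=False, n=19, seed=s))[
                "fractions4"
            ].auc
            for s in range(5)
        ]
        assert all(0.2 <= a <= 0.8 for a in aucs)


class TestNullBattery:
    def test_null_rates_sane_at_small_scale(self):
        """Smoke-level check at 100 families (the precise 1000-family bound
        is asserted in the acceptance suite): rates are far from pathological
        and the per-test rate cannot exceed the family-wise rate."""
        fam_rate, test_rate = null_family_significance_rate(n_families=100, seed=0)
        assert 0.0 <= fam_rate <= 0.15
        assert test_rate <= fam_rate
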