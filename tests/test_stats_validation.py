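import numpy as np
import pytest
from scipy import stats as sps

from sirnarank.io_datasets import SiRNARecord
from sirnarank.stats_validation import (FeatureAssociation, _ridge_fit_predict,
                                        feature_association_table, gc_window,
                                        gc_window_scan, paired_feature_set_test,
                                        position_motif_profile,
                                        ridge_cv_compare, welch_t_test)


class TestWelchTTest:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_separated_means_significant(self):
        rng = np.random.default_rng(0)
        a = np.zeros(4) + rng.normal(0, 1e-9, 4)
        b = np.ones(4) + rng.normal(0, 1e-9, 4)
        _, _, p = welch_t_test(a, b, "less")
        assert p < 1e-6

    def test_hand_evaluated_formulas(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t_exp = (a.mean() - b.mean()) / np.sqrt(se2)
        df_exp = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p_exp = sps.t.cdf(t_exp, df_exp)
        t, df, p = welch_t_test(a, b, "less")
        assert t == pytest.approx(t_exp, abs=1e-6)
        assert df == pytest.approx(df_exp, abs=1e-6)
        assert p == pytest.approx(p_exp, abs=1e-6)

    def test_matches_reference_implementation(self):
        """scipy's unequal-variance t-test as the independent oracle."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            na, nb = rng.integers(3, 30, 2)
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), na)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), nb)
            for alt in ("less", "greater"):
                t, _, p = welch_t_test(a, b, alt)
                ref = sps.ttest_ind(a, b, equal_var=False, alternative=alt)
                assert t == pytest.approx(ref.statistic, abs=1e-9)
                assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_zero_variance_policy(self):
        with pytest.warns(RuntimeWarning):
            _, _, p = welch_t_test([0.0, 0.0], [1.0, 1.0], "less")
        assert p == 0.0


class TestFeatureAssociation:
    def test_feature_equal_to_response(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, 50)
        X = np.column_stack([y, 1 - y])
        out = feature_association_table(X, y, [0, 1])
        assert out[0].r == pytest.approx(1.0)
        assert out[1].r == pytest.approx(-1.0)

    def test_planted_potency_rule(self):
        """A binary flag that lowers the product level by 0.3 must show a
        strong negative correlation and a significant one-tailed p."""
        rng = np.random.default_rng(3)
        flag = rng.integers(0, 2, 200).astype(float)
        y = np.clip(0.6 - 0.3 * flag + rng.normal(0, 0.05, 200), 0, 1)
        out = feature_association_table(flag[:, None], y, [0])
        assert out[0].r < -0.5
        assert out[0].p < 0.01

    def test_constant_feature_flagged_not_crashed(self):
        y = np.linspace(0, 1, 20)
        X = np.ones((20, 1))
        out = feature_association_table(X, y, [0])
        assert out[0].r is None and out[0].p is None

    def test_r_invariant_to_affine_response_rescale(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 100).astype(float)
        y = 0.5 * x + rng.normal(0, 0.3, 100)
        r1 = feature_association_table(x[:, None], y, [0])[0].r
        r2 = feature_association_table(x[:, None], 0.2 * y + 3, [0])[0].r
        assert r1 == pytest.approx(r2, abs=1e-12)


def _records(seq_gc_eff):
    recs = []
    for gc_count, eff in seq_gc_eff:
        seq = "G" * gc_count + "A" * (19 - gc_count)
        recs.append(SiRNARecord(seq, eff))
    return recs


class TestGCWindowScan:
    def test_all_potent_gives_fraction_one(self):
        recs = _records([(5, 0.1), (7, 0.2), (9, 0.05)])
        for res in gc_window_scan(recs):
            if res.n_in_window:
                assert res.fraction_potent == 1.0

    def test_recovers_planted_window(self):
        """Potency enabled only for GC in [0.25, 0.55]: the 0.25 lower bound
        maximises the potent fraction."""
        rng = np.random.default_rng(5)
        recs = []
        for _ in range(400):
            gc_count = int(rng.integers(0, 12))
            gc = gc_count / 19
            potent = 0.25 <= gc <= 0.55
            eff = rng.uniform(0.0, 0.29) if potent else rng.uniform(0.31, 1.0)
            recs.append(SiRNARecord("G" * gc_count + "A" * (19 - gc_count), eff))
        scan = gc_window_scan(recs)
        # widest window at maximal enrichment, as the published scan reads
        best = max((r for r in scan if r.n_in_window),
                   key=lambda r: (r.fraction_potent, r.n_in_window))
        assert best.lower == pytest.approx(0.25)
        diluted = [r for r in scan if r.lower < 0.25 and r.n_in_window]
        assert all(r.fraction_potent < best.fraction_potent for r in diluted)

    def test_empty_window_reported_missing(self):
        recs = _records([(10, 0.1)])  # GC ~ 0.53
        res = gc_window(recs, 0.9, 0.95)
        assert res.n_in_window == 0 and res.fraction_potent is None

    def test_fraction_is_weighted_average_of_subwindows(self):
        rng = np.random.default_rng(6)
        recs = _records([(int(rng.integers(0, 19)), float(rng.uniform(0, 1)))
                         for _ in range(120)])
        whole = gc_window(recs, 0.0, 1.0)
        lo = gc_window(recs, 0.0, 0.5)
        hi_recs = [r for r in recs
                   if (r.sequence.count("G") + r.sequence.count("C")) / 19 > 0.5]
        n_hi = len(hi_recs)
        frac_hi = (np.mean([r.efficacy < 0.3 for r in hi_recs]) if n_hi else 0.0)
        combined = (lo.n_in_window * lo.fraction_potent + n_hi * frac_hi) / whole.n_in_window
        assert whole.fraction_potent == pytest.approx(combined)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            gc_window([], 0.6, 0.5)


class TestPositionMotifProfile:
    def test_absent_motif_all_zero(self):
        recs = [SiRNARecord("A" * 19, 0.1)]
        df = position_motif_profile(recs, "GGG")
        assert (df[["n_all", "n_potent"]].to_numpy() == 0).all()

    def test_single_potent_record(self):
        recs = [SiRNARecord("UCU" + "A" * 16, 0.1)]
        df = position_motif_profile(recs, "UCU")
        row = df[df.position == 1].iloc[0]
        assert (row.n_all, row.n_potent, row.ratio_potent) == (1, 1, 1.0)
        assert (df[df.position != 1][["n_all", "n_potent"]].to_numpy() == 0).all()

    def test_planted_positional_enrichment(self):
        """'UCU' planted at position 1 of potent records only: the
        position-1 potency ratio strictly dominates every other position."""
        rng = np.random.default_rng(7)
        recs = []
        for _ in range(300):
            potent = rng.random() < 0.5
            body = "".join(rng.choice(list("AG"), 19))  # no UCU by chance
            if potent:
                seq = "UCU" + body[3:]
                eff = float(rng.uniform(0, 0.29))
            else:
                pos = int(rng.integers(4, 16))
                seq = body[:pos] + "UCU" + body[pos + 3:]
                eff = float(rng.uniform(0.31, 1.0))
            recs.append(SiRNARecord(seq, eff))
        df = position_motif_profile(recs, "UCU")
        p1 = df[df.position == 1].ratio_potent.iloc[0]
        others = df[(df.position != 1) & (df.n_all > 0)].ratio_potent
        assert (p1 > others).all()

    def test_bad_motif_length_rejected(self):
        with pytest.raises(ValueError):
            position_motif_profile([], "ACGUA")


class TestRidgeComparison:
    def _planted(self, seed=8, n=80, d=12):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        true = [0, 1, 2]
        y = X[:, true] @ np.array([0.5, -0.4, 0.3]) + rng.normal(0, 0.02, n)
        return X, y, true

    def test_true_features_beat_random_ones(self):
        X, y, true = self._planted()
        res = ridge_cv_compare(X, y, true, [5, 6, 7], rounds=100, seed=0, alpha=0.1)
        assert np.mean(res.per_round_a < res.per_round_b) >= 0.95
        assert res.p_a_better < 0.01

    def test_huge_alpha_collapses_to_fold_mean(self):
        X, y, _ = self._planted(seed=9, n=40)
        pred = _ridge_fit_predict(X[:20], y[:20], X[20:], alpha=1e12)
        assert np.allclose(pred, y[:20].mean(), atol=1e-6)

    def test_alpha_zero_matches_ols_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        pred = _ridge_fit_predict(X[:30], y[:30], X[30:], alpha=0.0)
        mu, sd = X[:30].mean(0), X[:30].std(0)
        Z = (X - mu) / sd
        coef = np.linalg.lstsq(np.column_stack([np.ones(30), Z[:30]]), y[:30],
                               rcond=None)[0]
        oracle = coef[0] + Z[30:] @ coef[1:]
        assert np.allclose(pred, oracle, atol=1e-6)

    def test_bit_reproducible(self):
        X, y, true = self._planted()
        a = ridge_cv_compare(X, y, true, [4, 5], rounds=20, seed=3)
        b = ridge_cv_compare(X, y, true, [4, 5], rounds=20, seed=3)
        assert np.array_equal(a.per_round_a, b.per_round_a)
        assert a.rmse_b == b.rmse_b

    def test_paired_test_directionality(self):
        a = [0.10, 0.11, 0.12, 0.10]
        b = [0.15, 0.16, 0.17, 0.14]
        t, p = paired_feature_set_test(a, b)
        assert t < 0 and p < 0.01
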