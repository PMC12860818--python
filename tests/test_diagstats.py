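"""Diagnostic-accuracy statistics against brute-force and hand oracles."""

import numpy as np
import pytest
from scipy import stats

from fractalperf.diagstats import (PAPER_REMOTE_FLOW_BOUNDARIES,
                                   ContingencyTable, cohen_kappa, delong_test,
                                   mcnemar_test, roc_auc, round_half_away,
                                   sens_spec, tertile_stratify, youden_cutoff)
from fractalperf.exceptions import DegenerateInputError, InvalidInputError


class TestSensSpec:
    def test_counts_reproduce_integer_percentages(self):
        r = sens_spec(ContingencyTable(tp=67, fp=6, fn=4, tn=71))
        assert r["sensitivity"]["pct"] == 94
        assert r["specificity"]["pct"] == 92
        r = sens_spec(ContingencyTable(tp=57, fp=28, fn=14, tn=49))
        assert r["sensitivity"]["pct"] == 80
        assert r["specificity"]["pct"] == 64

    def test_ci_contains_point_estimate(self):
        r = sens_spec(ContingencyTable(tp=30, fp=10, fn=5, tn=40))
        lo, hi = r["sensitivity"]["ci"]
        assert lo <= r["sensitivity"]["value"] <= hi
        lo, hi = r["specificity"]["ci"]
        assert lo <= r["specificity"]["value"] <= hi

    def test_zero_denominator_flags_undefined(self):
        r = sens_spec(ContingencyTable(tp=0, fp=5, fn=0, tn=10))
        assert not r["sensitivity"]["defined"]
        assert r["specificity"]["defined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            ContingencyTable(tp=-1, fp=0, fn=0, tn=0)

    def test_tables_add_per_stratum(self):
        a = ContingencyTable(tp=3, fp=1, fn=2, tn=4, stratum="low")
        b = ContingencyTable(tp=5, fp=2, fn=1, tn=7, stratum="high")
        c = a + b
        assert (c.tp, c.fp, c.fn, c.tn) == (8, 3, 3, 11)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(91.5) == 92
        assert round_half_away(92.4999) == 92
        assert round_half_away(-2.5) == -3


class TestROCAUC:
    def test_perfect_and_uninformative(self):
        truth = [True] * 5 + [False] * 5
        perfect = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]   # low = diseased
        assert roc_auc(perfect, truth)["auc"] == 1.0
        flat = [3.0] * 10
        assert roc_auc(flat, truth)["auc"] == 0.5

    def test_matches_brute_force_pairwise_count(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        truth = rng.random(20) < 0.4
        truth[0], truth[1] = True, False    # both classes present
        auc = roc_auc(scores, truth, low_scores_positive=True)["auc"]
        pos = scores[truth]
        neg = scores[~truth]
        wins = sum(
            1.0 if p < n else (0.5 if p == n else 0.0)
            for p in pos for n in neg
        )
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.uniform(0.5, 2.0, 30)
        truth = rng.random(30) < 0.5
        truth[:2] = [True, False]
        a = roc_auc(scores, truth)["auc"]
        b = roc_auc(np.log(scores), truth)["auc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            roc_auc([1, 2, 3], [True, True, True])


class TestDeLong:
    # fixture scores frozen after computing the reference p-value once with
    # R pROC 1.19 (roc.test(..., method="delong"), direction="<"):
    # p = 0.134095156375, AUCs 0.944444 / 0.819444, DeLong CI of the first
    # ROC = (0.866596729629, 1.0)
    A = [3.0289, 3.6419, 3.1467, 1.0268, 0.6072, 2.0672, 2.8614, 2.5092,
         3.8103, 2.7508, 2.6398, 1.2687, -2.0982, 0.6343, -1.1653, 0.7783,
         1.8482, -0.1148, -1.1266, 0.3942, 0.7617, -0.2618, 0.0175, 1.3353,
         1.2655, 0.71, -0.8664, -0.0537, 0.6029, -0.2119]
    B = [0.268, 0.0815, 0.2416, 0.1941, 0.4587, 2.3748, 0.0392, 2.0643,
         1.5011, 1.1677, 0.0071, 0.452, -3.0017, -0.0594, -0.3962, -0.6233,
         2.7844, -2.9682, -0.0267, 0.0828, 0.5608, -1.922, -0.5599, -1.7945,
         -0.1531, 0.2351, 0.1974, -0.2376, 0.2231, 0.2128]
    TRUTH = [True] * 12 + [False] * 18

    def test_matches_independent_reference_implementation(self):
        r = delong_test(self.A, self.B, self.TRUTH, low_scores_positive=False)
        assert r["p"] == pytest.approx(0.134095156375, abs=1e-6)
        assert r["auc_a"] == pytest.approx(0.944444444444, abs=1e-9)
        assert r["auc_b"] == pytest.approx(0.819444444444, abs=1e-9)

    def test_ci_matches_reference(self):
        r = roc_auc(self.A, self.TRUTH, low_scores_positive=False)
        assert r["ci"][0] == pytest.approx(0.866596729629, abs=1e-6)
        assert r["ci"][1] == 1.0

    def test_identical_scores_give_p_one(self):
        r = delong_test(self.A, self.A, self.TRUTH, low_scores_positive=False)
        assert r["p"] == 1.0 and r["z"] == 0.0

    def test_symmetric_in_the_two_methods(self):
        r1 = delong_test(self.A, self.B, self.TRUTH, low_scores_positive=False)
        r2 = delong_test(self.B, self.A, self.TRUTH, low_scores_positive=False)
        assert r1["p"] == pytest.approx(r2["p"], abs=1e-12)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            delong_test([1, 2], [1, 2, 3], [True, False])


class TestMcNemar:
    def test_equal_discordance_gives_p_one(self):
        assert mcnemar_test(7, 7)["p"] == 1.0

    def test_ten_zero_chi_square(self):
        r = mcnemar_test(10, 0)
        assert r["chi2"] == pytest.approx(10.0)
        assert r["p"] == pytest.approx(stats.chi2.sf(10.0, 1), rel=1e-12)
        assert r["p"] == pytest.approx(0.001565, abs=2e-6)

    def test_no_discordant_pairs_degenerate(self):
        r = mcnemar_test(0, 0)
        assert r["p"] == 1.0 and r["degenerate"]

    def test_continuity_correction_option(self):
        assert mcnemar_test(10, 0, continuity_correction=True)["chi2"] \
            == pytest.approx(8.1)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            mcnemar_test(-1, 3)


class TestYouden:
    def test_perfect_separation(self):
        r = youden_cutoff([0.5, 0.6, 0.8, 0.9], [True, True, False, False])
        assert r["cutoff"] == 0.6 and r["J"] == 1.0

    def test_all_scores_equal_gives_zero_j(self):
        r = youden_cutoff([0.7] * 6, [True, False] * 3)
        assert r["J"] == pytest.approx(0.0)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.uniform(0, 1, 50), 2)   # force ties
        truth = rng.random(50) < 0.4
        truth[:2] = [True, False]
        r = youden_cutoff(scores, truth)
        best = None
        for thr in np.unique(scores):
            pos = scores <= thr
            sens = (pos & truth).sum() / truth.sum()
            spec = (~pos & ~truth).sum() / (~truth).sum()
            if best is None or (sens + spec - 1, spec) > best[:2]:
                best = (sens + spec - 1, spec, thr)
        assert r["J"] == pytest.approx(best[0], abs=1e-12)
        assert r["cutoff"] == best[2]

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            youden_cutoff([1, 2], [True, True])


class TestCohenKappa:
    def test_identical_ratings(self):
        r = cohen_kappa(["a", "b", "a", "c"] * 5, ["a", "b", "a", "c"] * 5)
        assert r["kappa"] == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 1000)
        b = rng.permutation(a)
        assert abs(cohen_kappa(a, b)["kappa"]) < 0.1

    def test_hand_computed_two_by_two(self):
        # table {a=45, b=5, c=5, d=45}: p_o = 0.9, p_e = 0.5, kappa = 0.8
        x = ["p"] * 50 + ["n"] * 50
        y = ["p"] * 45 + ["n"] * 5 + ["p"] * 5 + ["n"] * 45
        r = cohen_kappa(x, y)
        assert r["kappa"] == pytest.approx(0.8, abs=1e-12)
        assert r["ci"][0] < 0.8 < r["ci"][1]

    def test_degenerate_chance_agreement(self):
        with pytest.raises(DegenerateInputError):
            cohen_kappa(["a"] * 5, ["a"] * 5)

    def test_unpaired_rejected(self):
        with pytest.raises(InvalidInputError):
            cohen_kappa([1, 2], [1, 2, 3])


class TestTertiles:
    def test_published_boundaries_examples(self):
        g = tertile_stratify([149.0, 114.0, 180.0],
                             boundaries=PAPER_REMOTE_FLOW_BOUNDARIES)
        assert g.assignments == ["intermediate", "low", "high"]

    def test_boundary_values_with_published_preset(self):
        g = tertile_stratify([135.0, 136.0, 171.0, 172.0],
                             boundaries=PAPER_REMOTE_FLOW_BOUNDARIES)
        assert g.assignments == ["low", "intermediate", "intermediate", "high"]

    def test_sample_tertiles_split_evenly(self):
        g = tertile_stratify(list(range(1, 10)))
        assert g.counts() == {"low": 3, "intermediate": 3, "high": 3}

    def test_degenerate_flag_on_identical_flows(self):
        g = tertile_stratify([150.0] * 6)
        assert g.degenerate

    def test_too_few_patients_rejected(self):
        with pytest.raises(InvalidInputError):
            tertile_stratify([100.0, 150.0])


class TestClopperPearsonCoverage:
    def test_simulated_coverage_at_nominal_95(self):
        # 2000 seeded binomial draws at p = 0.7, n = 50: the exact interval
        # must cover the truth in at least 94% of draws
        rng = np.random.default_rng(1234)
        p, n = 0.7, 50
        ks = rng.binomial(n, p, size=2000)
        covered = 0
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(ks, n, alpha=0.05, method="beta")
        covered = np.mean((lo <= p) & (p <= hi))
        assert covered >= 0.94
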