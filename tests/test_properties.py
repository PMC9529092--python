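import numpy as np
import pandas as pd
import pytest

from numconf.properties import (
    bic_distance_comparison,
    bin_accuracy_by_confidence,
    confidence_by_correctness,
    median_split_accuracy,
    normative_illustration,
    run_property_checks,
)


def _table(n, rng, proxy_fn, n_subjects=8, distances=(0.2, 0.5, 0.9, 1.3)):
    subject = rng.integers(0, n_subjects, n)
    dist = rng.choice(distances, n)
    p_correct = 0.75 + 0.15 * (dist / max(distances))
    correct = rng.random(n) < p_correct
    return pd.DataFrame(
        {
            "subject": subject,
            "log_distance": dist,
            "correct": correct,
            "confidence": proxy_fn(correct, rng, n),
        }
    )


class TestAccuracyByProxyBins:
    def test_informative_proxy_passes(self):
        rng = np.random.default_rng(0)
        tab = _table(4000, rng, lambda c, r, n: c + r.normal(0, 0.2, n))
        curve, slope, passed = bin_accuracy_by_confidence(tab)
        assert passed
        assert slope[0] > 0.5
        assert curve["accuracy"].iloc[-1] > curve["accuracy"].iloc[0]

    def test_uninformative_proxy_fails(self):
        rng = np.random.default_rng(1)
        tab = _table(4000, rng, lambda c, r, n: r.random(n))
        _, slope, passed = bin_accuracy_by_confidence(tab)
        assert not passed
        assert slope[1] < 0 < slope[2]  # CI covers zero

    def test_constant_proxy_degenerate(self):
        rng = np.random.default_rng(2)
        tab = _table(500, rng, lambda c, r, n: np.full(n, 0.7))
        with pytest.raises(ValueError):
            bin_accuracy_by_confidence(tab)

    def test_too_few_trials_rejected(self):
        rng = np.random.default_rng(3)
        tab = _table(50, rng, lambda c, r, n: r.random(n))
        with pytest.raises(ValueError):
            bin_accuracy_by_confidence(tab, n_bins=10)


class TestProxyByCorrectness:
    def test_planted_separation_passes(self):
        rng = np.random.default_rng(4)
        tab = _table(3000, rng, lambda c, r, n: np.where(c, 0.7, 0.3) + r.normal(0, 0.1, n))
        curve, contrast, passed = confidence_by_correctness(tab)
        assert passed
        assert contrast[0] == pytest.approx(0.4, abs=0.05)
        assert (curve["mean_conf_correct"] > curve["mean_conf_error"]).all()

    def test_shuffled_proxy_covers_zero(self):
        rng = np.random.default_rng(5)
        tab = _table(3000, rng, lambda c, r, n: np.where(c, 0.7, 0.3) + r.normal(0, 0.1, n))
        tab["confidence"] = rng.permutation(tab["confidence"].to_numpy())
        _, contrast, passed = confidence_by_correctness(tab)
        assert not passed
        assert contrast[1] < 0 < contrast[2]

    def test_no_error_trials_not_evaluable(self):
        rng = np.random.default_rng(6)
        tab = _table(1000, rng, lambda c, r, n: r.random(n))
        tab["correct"] = True
        _, contrast, passed = confidence_by_correctness(tab)
        assert contrast is None and passed is None


class TestMedianSplit:
    def test_split_definition_ties_to_low(self):
        # proxies {0.2,0.4,0.6,0.8}: median 0.5, high half {0.6,0.8};
        # a value equal to the median goes low
        tab = pd.DataFrame(
            {
                "subject": 0,
                "log_distance": [0.5] * 5,
                "correct": [False, False, True, True, True],
                "confidence": [0.2, 0.4, 0.5, 0.6, 0.8],
            }
        )
        med = tab.groupby("subject")["confidence"].transform("median")
        high = tab["confidence"] > med
        assert high.tolist() == [False, False, False, True, True]

    def test_informative_split_passes_and_null_fails(self):
        rng = np.random.default_rng(7)
        good = _table(4000, rng, lambda c, r, n: c + r.normal(0, 0.3, n))
        _, contrast, passed = median_split_accuracy(good)
        assert passed and contrast[0] > 0
        null = _table(4000, rng, lambda c, r, n: r.random(n))
        _, contrast0, passed0 = median_split_accuracy(null)
        assert not passed0
        assert abs(contrast0[0]) < 0.05

    def test_degenerate_proxy_rejected(self):
        tab = pd.DataFrame(
            {"subject": 0, "log_distance": 0.5, "correct": [True] * 4, "confidence": 0.5}
        )
        with pytest.raises(ValueError):
            median_split_accuracy(tab)


class TestNormativeIllustration:
    def test_three_signatures_on_generated_trials(self):
        tab = normative_illustration(40000, percept_sd=0.3, seed=0)
        report = run_property_checks(tab)
        assert all(report.passed.values())
        curve = report.binned_curve
        # accuracy rises monotonically across confidence deciles
        assert np.all(np.diff(curve["accuracy"]) > -0.01)

    def test_noiseless_limit(self):
        tab = normative_illustration(20000, percept_sd=1e-4, seed=1)
        assert tab["correct"].mean() > 0.999
        assert tab["confidence"].mean() > 0.99

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            normative_illustration(20000, percept_sd=0.0)
        with pytest.raises(ValueError):
            normative_illustration(100)


class TestBicDistanceComparison:
    @staticmethod
    def _distance_table(rng, n, use_log):
        pairs = [(8, 7), (7, 5), (8, 5), (5, 3), (7, 3), (5, 2), (8, 3), (7, 2), (8, 2)]
        idx = rng.integers(0, len(pairs), n)
        num_a = np.array([pairs[i][0] for i in idx])
        num_b = np.array([pairs[i][1] for i in idx])
        logd = np.log(num_a) - np.log(num_b)
        lind = (num_a - num_b).astype(float)
        x = logd if use_log else lind
        rt = 0.9 - 0.15 * x + rng.normal(0, 0.08, n)
        return pd.DataFrame(
            {
                "subject": rng.integers(0, 10, n),
                "num_a": num_a,
                "num_b": num_b,
                "log_distance": logd,
                "rt": rt,
            }
        )

    def test_log_generated_outcome_favors_log(self):
        rng = np.random.default_rng(10)
        tab = self._distance_table(rng, 5000, use_log=True)
        bic_log, bic_lin, delta = bic_distance_comparison(tab, outcome="rt")
        assert delta < 0

    def test_linear_generated_outcome_favors_linear(self):
        rng = np.random.default_rng(11)
        tab = self._distance_table(rng, 5000, use_log=False)
        _, _, delta = bic_distance_comparison(tab, outcome="rt")
        assert delta > 0

    def test_constant_regressor_rejected(self):
        rng = np.random.default_rng(12)
        tab = self._distance_table(rng, 200, use_log=True)
        tab["num_a"], tab["num_b"] = 8, 5
        with pytest.raises(ValueError):
            bic_distance_comparison(tab)
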