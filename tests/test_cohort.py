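import numpy as np
import pandas as pd
import pytest

from numconf.cohort import (
    COHORT_PARAM_PRESETS,
    CohortSpec,
    exclude_slow_rts,
    generate_cohort,
    normalize_pressure,
    pressure_from_confidence,
    sample_participant_params,
)
from numconf.design import build_design


@pytest.fixture(scope="module")
def small_cohort():
    spec = CohortSpec(
        n_subjects=6,
        seed=5,
        design=build_design("exp1", trials_per_pair_per_type=6, n_dummy=20),
    )
    return spec, generate_cohort(spec)


class TestParticipantSampling:
    def test_zero_sds_return_exact_means(self):
        zero_sds = {t: {k: 0.0 for k in d["sd"]} for t, d in COHORT_PARAM_PRESETS["exp1"].items()}
        spec = CohortSpec(n_subjects=2, param_sds=zero_sds, seed=0)
        params = sample_participant_params(spec, 0)
        for t, p in params.items():
            m = COHORT_PARAM_PRESETS["exp1"][t]["mean"]
            assert p.dr == pytest.approx(m["dr"])
            assert p.bo == pytest.approx(m["bo"])
            assert p.ndt == pytest.approx(m["ndt"])

    def test_draws_respect_bounds(self):
        spec = CohortSpec(n_subjects=1, seed=1)
        for i in range(500):
            for p in sample_participant_params(spec, i).values():
                assert 0.0 <= p.sym <= 1.0
                assert 0.0 <= p.ic < p.bo
                assert p.dr > 0 and p.ndt >= 0

    def test_deterministic_given_seed_and_subject(self):
        spec = CohortSpec(n_subjects=1, seed=9)
        assert sample_participant_params(spec, 3) == sample_participant_params(spec, 3)
        assert sample_participant_params(spec, 3) != sample_participant_params(spec, 4)

    def test_within_subject_coupling_across_types(self):
        # the shared subject factor orders types consistently: a subject
        # drawn fast for positives is fast for negatives too
        spec = CohortSpec(n_subjects=1, seed=2)
        drs = np.array(
            [
                [sample_participant_params(spec, i)[t].dr for t in ("positive", "negative")]
                for i in range(200)
            ]
        )
        assert np.corrcoef(drs[:, 0], drs[:, 1])[0, 1] > 0.9

    def test_sample_means_match_spec_means(self):
        # parameters whose means sit far from the bounds are unaffected
        # by truncation; check the law-of-large-numbers recovery
        spec = CohortSpec(n_subjects=1, seed=3)
        draws = [sample_participant_params(spec, i)["negative"] for i in range(2000)]
        m = COHORT_PARAM_PRESETS["exp1"]["negative"]["mean"]
        s = COHORT_PARAM_PRESETS["exp1"]["negative"]["sd"]
        for name in ("bo", "ndt"):
            vals = np.array([getattr(p, name) for p in draws])
            assert abs(vals.mean() - m[name]) < 3 * s[name] / np.sqrt(len(vals)) + 0.01

    def test_negative_sd_rejected(self):
        bad = {t: {**d["sd"], "dr": -1.0} for t, d in COHORT_PARAM_PRESETS["exp1"].items()}
        spec = CohortSpec(n_subjects=1, param_sds=bad)
        with pytest.raises(ValueError):
            sample_participant_params(spec, 0)


class TestPressureTransfer:
    def test_zero_gain_is_confidence_independent(self):
        spec = CohortSpec(pressure_gain=0.0, pressure_noise_sd=50.0)
        rng = np.random.default_rng(0)
        conf = np.linspace(0.5, 1.0, 2000)
        raw = pressure_from_confidence(conf, spec, rng)
        assert abs(np.corrcoef(conf, raw)[0, 1]) < 0.05

    def test_noiseless_transfer_is_strictly_monotone(self):
        spec = CohortSpec(pressure_gain=400.0, pressure_noise_sd=0.0)
        rng = np.random.default_rng(0)
        conf = np.linspace(0.01, 0.99, 100)
        raw = pressure_from_confidence(conf, spec, rng)
        assert np.all(np.diff(raw) > 0)

    def test_clipped_to_sensor_range(self):
        spec = CohortSpec(pressure_intercept=1000.0, pressure_gain=400.0, pressure_noise_sd=200.0)
        rng = np.random.default_rng(1)
        raw = pressure_from_confidence(np.full(1000, 0.9), spec, rng)
        assert raw.min() >= 0.0 and raw.max() <= 1023.0


class TestPressureNormalization:
    def test_worked_example_half_of_session_max(self):
        tab = pd.DataFrame(
            {
                "subject": [0, 0, 0],
                "response_side": ["left"] * 3,
                "pressure_raw": [492.0, 984.0, 246.0],
            }
        )
        out = normalize_pressure(tab)
        np.testing.assert_allclose(out["pressure_norm"], [0.5, 1.0, 0.25])

    def test_per_side_maximum(self):
        tab = pd.DataFrame(
            {
                "subject": [0, 0],
                "response_side": ["left", "right"],
                "pressure_raw": [500.0, 1000.0],
            }
        )
        out = normalize_pressure(tab)
        np.testing.assert_allclose(out["pressure_norm"], [1.0, 1.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        tab = pd.DataFrame(
            {
                "subject": rng.integers(0, 3, 60),
                "response_side": rng.choice(["left", "right"], 60),
                "pressure_raw": rng.uniform(10, 900, 60),
            }
        )
        shuffled = tab.sample(frac=1.0, random_state=1)
        out1 = normalize_pressure(tab).sort_index()
        out2 = normalize_pressure(shuffled).sort_index()
        np.testing.assert_allclose(out1["pressure_norm"], out2["pressure_norm"])

    def test_all_zero_session_rejected(self):
        tab = pd.DataFrame(
            {"subject": [0, 0], "response_side": ["left", "left"], "pressure_raw": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            normalize_pressure(tab)


class TestRtExclusion:
    def test_single_outlier_dropped(self):
        tab = pd.DataFrame({"rt": [0.5] * 19 + [10.0]})
        kept, frac = exclude_slow_rts(tab)
        assert len(kept) == 19
        assert frac == pytest.approx(0.05)

    def test_equal_rts_keep_everything(self):
        tab = pd.DataFrame({"rt": [0.7] * 30})
        kept, frac = exclude_slow_rts(tab)
        assert len(kept) == 30 and frac == 0.0

    def test_lognormal_exclusion_fraction_brackets_reported_loss(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"rt": rng.lognormal(-0.3, 0.35, 100_000)})
        _, frac = exclude_slow_rts(tab)
        assert 0.02 < frac < 0.12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exclude_slow_rts(pd.DataFrame({"rt": [0.5]}))


class TestGenerateCohort:
    def test_schema_and_counts(self, small_cohort):
        spec, coh = small_cohort
        design = spec.resolved_design()
        assert len(coh) == spec.n_subjects * design.n_total
        real = coh[~coh["is_dummy"]]
        assert len(real) == spec.n_subjects * design.n_analyzable
        for col in ("confidence", "pressure_norm", "rt", "excluded", "exclusion_reason"):
            assert col in coh.columns

    def test_dummies_carry_no_analysis_fields(self, small_cohort):
        _, coh = small_cohort
        dummies = coh[coh["is_dummy"]]
        assert dummies["excluded"].all()
        assert (dummies["exclusion_reason"] == "dummy").all()
        assert dummies["rt"].isna().all()
        assert dummies["confidence"].isna().all()

    def test_pressure_normalized_per_subject_side(self, small_cohort):
        _, coh = small_cohort
        pressed = coh[coh["pressure_norm"].notna()]
        g = pressed.groupby(["subject", "response_side"])["pressure_norm"].max()
        np.testing.assert_allclose(g.to_numpy(), 1.0)

    def test_byte_for_byte_determinism(self):
        spec = CohortSpec(
            n_subjects=2, seed=11,
            design=build_design("exp1", trials_per_pair_per_type=2, n_dummy=4),
        )
        c1 = generate_cohort(spec).to_csv(index=False)
        c2 = generate_cohort(spec).to_csv(index=False)
        assert c1 == c2

    def test_numerical_distance_effect(self, small_cohort):
        # farther pairs: faster and more accurate (the distance effect)
        _, coh = small_cohort
        real = coh[~coh["is_dummy"] & (coh["choice"] != "timeout")]
        med = real["log_distance"].median()
        near = real[real["log_distance"] <= med]
        far = real[real["log_distance"] > med]
        assert far["rt"].mean() < near["rt"].mean()
        assert far["correct"].mean() >= near["correct"].mean()

    def test_rt_ordering_negative_slower_than_positive(self, small_cohort):
        # the negative-numeral parameter set (higher bound/NDT) is slower
        _, coh = small_cohort
        real = coh[~coh["is_dummy"] & (coh["choice"] != "timeout")]
        by_type = real.groupby("numeral_type")["rt"].mean()
        assert by_type["negative"] > by_type["positive"]
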