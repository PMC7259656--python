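import numpy as np
import pandas as pd
import pytest

from fraximm.calibration import DEFAULT_FREE_NAMES, GroupObservation, fit
from fraximm.cohort_stats import GroupSample, one_way_anova
from fraximm.geo_expression import gene_log2fc
from fraximm.model_core import DEFAULT_PARAMS, simulate
from fraximm.synthetic_data import (
    CYTOKINE_ANALYTES,
    DEFAULT_CONFIG,
    cohort_frame,
    synth_cohort,
    synth_cytokines,
    synth_expression,
    synth_survival,
)


class TestCohort:
    def test_noiseless_cohort_equals_model_predictions(self):
        cfg = DEFAULT_CONFIG.with_values(size_noise_sd=0.0, growth_sd=0.0)
        records = synth_cohort(cfg)
        for r in records:
            expected = simulate(cfg.params, cfg.arms[r.group], cfg.observation_day).final.C
            assert r.area_mm2 == pytest.approx(expected, rel=1e-12)

    def test_default_design_twenty_animals_at_day_18(self):
        records = synth_cohort(DEFAULT_CONFIG)
        assert len(records) == 20
        assert {r.group for r in records} == set(DEFAULT_CONFIG.arms)
        assert all(r.day == 18 for r in records)
        frame = cohort_frame(records)
        assert frame.groupby("group").size().eq(4).all()

    def test_large_sample_mean_matches_lognormal_corrected_prediction(self):
        cfg = DEFAULT_CONFIG.with_values(
            n_per_arm=1000, size_noise_sd=0.2, growth_sd=0.0, seed=4
        )
        frame = cohort_frame(synth_cohort(cfg))
        sub = frame[frame["group"] == "control"]["area_mm2"]
        pred = simulate(cfg.params, cfg.arms["control"], 18).final.C
        expected_mean = pred * np.exp(0.2**2 / 2)  # lognormal bias factor
        se = sub.std() / np.sqrt(len(sub))
        assert abs(sub.mean() - expected_mean) < 2 * se

    def test_bit_reproducible_under_master_seed(self):
        a = cohort_frame(synth_cohort(DEFAULT_CONFIG.with_values(seed=9)))
        b = cohort_frame(synth_cohort(DEFAULT_CONFIG.with_values(seed=9)))
        pd.testing.assert_frame_equal(a, b)
        c = cohort_frame(synth_cohort(DEFAULT_CONFIG.with_values(seed=10)))
        assert not a["area_mm2"].equals(c["area_mm2"])

    def test_noiseless_cohort_fit_recovers_generator_exactly(self):
        cfg = DEFAULT_CONFIG.with_values(size_noise_sd=0.0, growth_sd=0.0)
        frame = cohort_frame(synth_cohort(cfg))
        observations = [
            GroupObservation(g, cfg.arms[g], sub["area_mm2"].tolist(), 18)
            for g, sub in frame.groupby("group", sort=False)
        ]
        res = fit(observations, cfg.params)
        assert res.rss == pytest.approx(0.0, abs=1e-12)
        init = cfg.params.with_values(a=0.15, K=300.0, gamma=0.9, mu=0.045)
        res2 = fit(observations, init)
        for name in DEFAULT_FREE_NAMES:
            assert getattr(res2.params, name) == pytest.approx(
                getattr(cfg.params, name), rel=0.10
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DEFAULT_CONFIG.with_values(n_per_arm=0)
        with pytest.raises(ValueError):
            DEFAULT_CONFIG.with_values(size_noise_sd=-0.1)
        with pytest.raises(ValueError):
            DEFAULT_CONFIG.with_values(censor_day=10)


class TestSurvival:
    def test_no_heterogeneity_gives_deterministic_crossing(self):
        cfg = DEFAULT_CONFIG.with_values(growth_sd=0.0)
        s = synth_survival(cfg, cfg.arms["control"], 8)
        assert len(set(s.times)) == 1
        assert all(e == 1 for e in s.events)

    def test_threshold_below_inoculum_crosses_immediately(self):
        params = DEFAULT_CONFIG.survival_params
        cfg = DEFAULT_CONFIG.with_values(death_threshold_mm2=params.C0 / 2)
        s = synth_survival(cfg, cfg.arms["control"], 5)
        assert s.times == (1.0,) * 5

    def test_never_crossing_censored_at_study_end(self):
        cfg = DEFAULT_CONFIG.with_values(
            survival_params=DEFAULT_CONFIG.survival_params.with_values(a=0.0),
            growth_sd=0.0,
        )
        s = synth_survival(cfg, cfg.arms["control"], 3)
        assert s.times == (100.0,) * 3
        assert s.events == (0,) * 3

    def test_treatment_delays_crossing(self):
        cfg = DEFAULT_CONFIG.with_values(seed=2)
        control = synth_survival(cfg, cfg.arms["control"], 50)
        treated = synth_survival(cfg, cfg.arms["1mt_rt2_long"], 50)
        assert np.median(treated.times) > np.median(control.times)


class TestCytokines:
    def test_panel_has_twelve_analytes(self):
        panel = synth_cytokines(DEFAULT_CONFIG)
        assert [c for c in panel.columns if c not in ("animal_id", "group")] == list(
            CYTOKINE_ANALYTES
        )
        assert len(panel) == 20

    def test_null_panel_type_one_error_calibrated(self):
        # with no spike, the across-group ANOVA p-values are uniform
        rejections = 0
        n_tests = 0
        for rep in range(120):
            cfg = DEFAULT_CONFIG.with_values(cytokine_spike_sds=0.0, seed=1000 + rep)
            panel = synth_cytokines(cfg)
            for analyte in CYTOKINE_ANALYTES:
                groups = [
                    GroupSample(g, sub[analyte].tolist())
                    for g, sub in panel.groupby("group", sort=False)
                ]
                _, p = one_way_anova(groups)
                n_tests += 1
                rejections += p < 0.05
        rate = rejections / n_tests
        assert 0.02 < rate < 0.09  # 1440 tests: ~5% expected

    def test_spiked_analyte_detected_in_majority_of_replicates(self):
        hits = 0
        for rep in range(60):
            panel = synth_cytokines(DEFAULT_CONFIG.with_values(seed=2000 + rep))
            groups = [
                GroupSample(g, sub["IL-1A"].tolist())
                for g, sub in panel.groupby("group", sort=False)
            ]
            _, p = one_way_anova(groups)
            hits += p < 0.05
        assert hits / 60 > 0.5


class TestExpression:
    def test_null_spike_unbiased(self):
        estimates = [
            gene_log2fc(
                synth_expression(
                    DEFAULT_CONFIG.with_values(ido1_spike_log2=0.0, seed=3000 + rep)
                ),
                "IDO1",
            )[0]
            for rep in range(200)
        ]
        se = np.std(estimates) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates)) < 3 * se

    def test_default_spike_recovered_within_confidence_interval(self):
        m = synth_expression(DEFAULT_CONFIG)
        log2fc, p = gene_log2fc(m, "IDO1")
        # 95% CI half-width for the mean difference with sd 1 and n=5 vs 9
        half_width = 1.96 * np.sqrt(1 / 5 + 1 / 9)
        assert abs(log2fc - 2.73) < half_width
        assert p < 0.05

    def test_reproducible_and_correct_shape(self):
        a = synth_expression(DEFAULT_CONFIG)
        b = synth_expression(DEFAULT_CONFIG)
        pd.testing.assert_frame_equal(a.values, b.values)
        assert a.values.shape == (200, 14)
        assert a.genes[0] == "IDO1"
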