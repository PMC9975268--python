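"""Stress-response statistics: phase summaries, correlations, stratified
regressions, per-subject slopes, matched-heart-rate contrasts and
anthropometric covariates."""

import numpy as np
import pandas as pd
import pytest

from pepstress.cohort import generate_cohort
from pepstress.config import GeneratorConfig, StatsConfig
from pepstress.stress_stats import (
    correlate_surrogates,
    covariates_and_anthropometrics,
    matched_hr_contrast,
    per_subject_slopes,
    phase_summaries,
    rest_reference,
    state_anova,
    stratified_hr_regression,
)


@pytest.fixture(scope="module")
def measurements(cohort71):
    return cohort71.measurements


class TestPhaseSummaries:
    def test_relative_pep_is_one_at_rest_reference(self, measurements):
        out = phase_summaries(measurements, seed=0)
        rest = out[out["phase"] == "rest"].iloc[0]
        assert rest["rel_pep_mean"] == pytest.approx(1.0)

    def test_ci_contains_point_estimate(self, measurements):
        out = phase_summaries(measurements, seed=0)
        assert (out["rel_pep_ci_lo"] <= out["rel_pep_mean"] + 1e-12).all()
        assert (out["rel_pep_ci_hi"] >= out["rel_pep_mean"] - 1e-12).all()

    def test_zero_reactivity_cohort_has_flat_mental_response(self):
        cfg = GeneratorConfig(mental_reactivity_mean=0.0, mental_reactivity_sd=0.0,
                              mental_reactivity_bounds=(0.0, 0.0))
        c = generate_cohort(cfg, seed=3, beats="none")
        out = phase_summaries(c.measurements, seed=0)
        mental = out[out["phase"].str.startswith("tsst")]
        assert np.allclose(mental["rel_pep_mean"], 1.0, atol=0.02)

    def test_ergometer_n_declines_with_load(self, measurements):
        out = phase_summaries(measurements, seed=0).set_index("phase")
        assert out.loc["ergo_E7", "n"] <= out.loc["ergo_E4", "n"]

    def test_mental_and_physical_reductions(self, measurements):
        """Stress-question PEP ≈ 90 ms pooled; maximal-load PEP ≈ half of
        rest, reproducing the study's headline stress response."""
        out = phase_summaries(measurements, seed=0).set_index("phase")
        tsst = out[out.index.str.startswith("tsst")]
        assert tsst["pep_mean_ms"].mean() == pytest.approx(90.0, abs=3.5)
        assert out.loc["rest", "pep_mean_ms"] == pytest.approx(104.5, abs=3.0)


class TestCorrelations:
    def test_r_squared_equals_squared_pearson(self, measurements):
        out = correlate_surrogates(measurements)
        valid = measurements[measurements["valid"]]
        r = np.corrcoef(valid["heather_index"], valid["pep_ms"])[0, 1]
        assert out["heather_index"].r_squared == pytest.approx(r**2, abs=1e-12)

    def test_noise_free_coupling_gives_r2_of_one(self):
        cfg = GeneratorConfig(heather_noise=0.0, pep_within_sd=0.0)
        c = generate_cohort(cfg, seed=2, beats="none")
        out = correlate_surrogates(c.measurements)
        assert out["heather_index"].r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_predictor_rejected(self, measurements):
        bad = measurements.copy()
        bad["heather_index"] = 5.0
        with pytest.raises(ValueError):
            correlate_surrogates(bad)

    def test_polynomial_fit_not_worse_than_linear(self, measurements):
        out = correlate_surrogates(measurements)
        assert out["hr_poly"].r_squared >= out["hr"].r_squared - 1e-12


class TestStratifiedRegression:
    def test_strata_present_and_bounded(self, measurements):
        out = stratified_hr_regression(measurements)
        assert set(out) == {"rest", "mental", "physical"}
        for res in out.values():
            assert 0.0 <= res.r_squared <= 1.0
            assert res.n >= 3

    def test_coupling_strengthens_with_load(self, pooled_measurements):
        """PEP–HR coupling is weakest at rest, stronger under mental load and
        strongest while treading."""
        out = stratified_hr_regression(pooled_measurements)
        assert out["rest"].r_squared < out["mental"].r_squared < out["physical"].r_squared

    def test_small_stratum_rejected(self, measurements):
        tiny = measurements[measurements["state"] == "rest"].head(2)
        frame = pd.concat([tiny, measurements[measurements["state"] != "rest"]])
        with pytest.raises(ValueError):
            stratified_hr_regression(frame)

    def test_scale_equivariance(self, measurements):
        """Adding a constant to PEP leaves slope and R² unchanged; scaling
        PEP scales the slope and leaves R² unchanged."""
        base = stratified_hr_regression(measurements)["physical"]
        shifted = measurements.copy()
        shifted["pep_ms"] = shifted["pep_ms"] + 50.0
        scaled = measurements.copy()
        scaled["pep_ms"] = scaled["pep_ms"] * 3.0
        s = stratified_hr_regression(shifted)["physical"]
        m = stratified_hr_regression(scaled)["physical"]
        assert s.slope == pytest.approx(base.slope)
        assert s.r_squared == pytest.approx(base.r_squared)
        assert m.slope == pytest.approx(3.0 * base.slope)
        assert m.r_squared == pytest.approx(base.r_squared)


class TestPerSubjectSlopes:
    def test_matches_two_pass_least_squares_oracle(self, measurements):
        out = per_subject_slopes(measurements).set_index("subject_id")
        valid = measurements[measurements["valid"]]
        for sid, grp in list(valid.groupby("subject_id"))[:8]:
            x = grp["hr_bpm"].to_numpy()
            y = grp["pep_ms"].to_numpy()
            # two-pass normal equations
            slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean())**2).sum()
            assert out.loc[sid, "slope"] == pytest.approx(slope)

    def test_heterogeneity_present(self, measurements):
        out = per_subject_slopes(measurements)
        assert out["slope"].std() > 0.02
        assert out.attrs["summary"]["steepest"] < out.attrs["summary"]["flattest"]

    def test_identical_subjects_have_no_heterogeneity(self):
        cfg = GeneratorConfig(pep_between_sd=0.0, pep_within_sd=0.0,
                              slope_jitter_sd=0.0, hr_rest_sd=0.0,
                              hr_meas_sd=0.0, pep_weight_coef=0.0,
                              pep_height_coef=0.0, pep_sex_offset_female=0.0,
                              pep_hr_rest_coef=0.0)
        c = generate_cohort(cfg, seed=4, beats="none")
        phys = c.measurements[c.measurements["state"] == "physical"]
        out = per_subject_slopes(phys)
        # only age (via HRmax span) differentiates subjects here
        assert out["slope"].std() < 0.05

    def test_parameter_recovery_at_zero_noise(self):
        """With measurement noise off, each subject's fitted treading slope
        converges to the latent load-response slope."""
        cfg = GeneratorConfig(pep_within_sd=0.0, hr_meas_sd=0.0)
        c = generate_cohort(cfg, seed=6, beats="none")
        phys = c.measurements[c.measurements["state"] == "physical"]
        subj = c.subjects.set_index("subject_id")
        for sid, grp in list(phys.groupby("subject_id"))[:10]:
            floor = subj.loc[sid, "pep_rest_mean"] * 0.5
            uncapped = grp[grp["pep_ms"] > floor + 0.5]
            if len(uncapped) < 3:
                continue
            from scipy.stats import linregress
            slope = linregress(uncapped["hr_bpm"], uncapped["pep_ms"]).slope
            assert slope == pytest.approx(subj.loc[sid, "pep_hr_slope"], rel=1e-6)


class TestMatchedHrContrast:
    def test_bin_means_match_groupby_oracle(self, measurements):
        out = matched_hr_contrast(measurements, 12.0)
        valid = measurements[measurements["valid"]]
        valid = valid[valid["state"].isin(["rest", "mental", "physical"])]
        bin0 = out.iloc[0]
        sel = valid[(valid["hr_bpm"] >= bin0["hr_bin_lo"])
                    & (valid["hr_bpm"] < bin0["hr_bin_hi"])]
        for state, col in (("rest", "pep_rest"), ("mental", "pep_mental")):
            grp = sel[sel["state"] == state]["pep_ms"]
            if len(grp):
                assert bin0[col] == pytest.approx(grp.mean())

    def test_ordering_holds_in_most_shared_bins(self, pooled_measurements):
        """Rest > mental > physical PEP at matched heart rate in ≥ 80% of
        shared bins (12 bpm wide)."""
        out = matched_hr_contrast(pooled_measurements, 12.0)
        assert out.attrs["ordering_fraction"] >= 0.8

    def test_state_blind_generator_shows_no_ordering(self):
        cfg = GeneratorConfig(mental_reactivity_mean=0.0, mental_reactivity_sd=0.0,
                              mental_reactivity_bounds=(0.0, 0.0),
                              treading_onset_reduction=0.0,
                              max_physical_reduction=1e-6, recovery_attenuation=0.0)
        # degenerate: PEP does not react to state at all
        c = generate_cohort(cfg, seed=8, beats="none")
        out = matched_hr_contrast(c.measurements, 12.0)
        assert out.attrs["ordering_fraction"] < 0.8

    def test_invalid_bin_width_rejected(self, measurements):
        with pytest.raises(ValueError):
            matched_hr_contrast(measurements, 0.0)


class TestAnthropometrics:
    def test_sex_difference_and_covariates(self, default_config):
        """Resting PEP: females ≈ 6 ms below males; weak positive weight and
        height correlations (R² ≈ 0.13 / 0.08)."""
        diffs, r2w, r2h = [], [], []
        for s in range(130, 150):
            c = generate_cohort(default_config, s, beats="none")
            out = covariates_and_anthropometrics(c.subjects, c.measurements)
            diffs.append(out["sex_difference_ms"])
            r2w.append(out["r2_weight"])
            r2h.append(out["r2_height"])
        assert np.mean(diffs) == pytest.approx(-6.2, abs=1.5)
        assert np.mean(r2w) == pytest.approx(0.13, abs=0.05)
        assert np.mean(r2h) == pytest.approx(0.08, abs=0.05)

    def test_shuffled_sex_labels_remove_difference(self, cohort71):
        diffs = []
        rng = np.random.default_rng(0)
        for _ in range(30):
            subj = cohort71.subjects.copy()
            subj["sex"] = rng.permutation(subj["sex"].to_numpy())
            out = covariates_and_anthropometrics(subj, cohort71.measurements)
            diffs.append(out["sex_difference_ms"])
        assert abs(np.mean(diffs)) < 2.0

    def test_single_sex_cohort_reports_absent_difference(self, cohort71):
        subj = cohort71.subjects.copy()
        subj["sex"] = "female"
        out = covariates_and_anthropometrics(subj, cohort71.measurements)
        assert out["sex_difference_ms"] is None


class TestStateAnova:
    def test_three_condition_contrast_significant(self, measurements):
        out = state_anova(measurements)
        assert out["p"] < 0.001
        means = out["group_means"]
        assert means["rest"] > means["mental_q1"] > means["physical_max"]
        assert all(0 <= p <= 1 for p in out["pairwise_bonferroni"].values())
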