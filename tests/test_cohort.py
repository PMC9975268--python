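"""Generator behaviour: cohort composition, reproducibility, the load- and
stress-response models, and the beat/cuff simulators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepstress.cohort import (
    FULL_BEAT_SCHEDULE,
    expected_pep_at_hr,
    generate_cohort,
    mental_drive,
    simulate_beats,
    simulate_cuff_curve,
    simulate_phase_pep,
)
from pepstress.config import GeneratorConfig
from pepstress.protocol import PHASES, hr_max


class TestCohortComposition:
    def test_size_and_sex_split(self, cohort71):
        subj = cohort71.subjects
        assert len(subj) == 71
        assert (subj["sex"] == "male").sum() == 34
        assert (subj["sex"] == "female").sum() == 37

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=0)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(pep_between_sd=-1.0)

    def test_age_predicted_max_heart_rate(self, cohort71):
        subj = cohort71.subjects
        assert np.allclose(subj["hr_max"], 220.0 - subj["age"])

    def test_phase_vocabulary(self, cohort71):
        assert set(cohort71.measurements["phase"]) <= set(PHASES)

    def test_ergometer_steps_are_weight_adapted(self, cohort71, default_config):
        """Treading wattage is an integer multiple of 0.4 W per kg body mass."""
        m = cohort71.measurements
        subj = cohort71.subjects.set_index("subject_id")
        ergo = m[m["state"] == "physical"]
        step = default_config.watts_per_kg_step * ergo["subject_id"].map(subj["weight_kg"])
        ratio = ergo["load_watts"] / step
        assert np.allclose(ratio, np.round(ratio))
        assert (ratio >= 1).all()

    def test_large_cohort_recovers_configured_rest_mean(self, default_config):
        """Law of large numbers: a 5000-subject cohort's mean resting PEP is
        within 1 ms of the configured 104.5 ms."""
        cfg = default_config.model_copy(update={"n_subjects": 5000, "n_male": 2394})
        c = generate_cohort(cfg, seed=7, beats="none")
        rest = c.measurements[c.measurements["phase"] == "rest"]["pep_ms"]
        assert abs(rest.mean() - cfg.pep_rest_mean) < 1.0

    def test_variance_structure(self, cohort71, default_config):
        """Between-subject spread of resting PEP is much larger than the
        within-subject measurement spread."""
        between = cohort71.subjects["pep_rest_mean"].std()
        assert between > 2 * default_config.pep_within_sd


class TestReproducibility:
    def test_identical_seed_gives_byte_identical_dataset(self, default_config):
        a = generate_cohort(default_config, seed=42, beats="rest")
        b = generate_cohort(default_config, seed=42, beats="rest")
        assert a.subjects.to_csv() == b.subjects.to_csv()
        assert a.measurements.to_csv() == b.measurements.to_csv()
        assert a.beats.to_csv() == b.beats.to_csv()

    def test_different_seed_differs(self, default_config):
        a = generate_cohort(default_config, seed=1, beats="none")
        b = generate_cohort(default_config, seed=2, beats="none")
        assert not a.measurements["pep_ms"].equals(b.measurements["pep_ms"])


class TestPhaseResponse:
    def test_no_load_identity(self, cohort71, default_config):
        subj = cohort71.subjects.iloc[0]
        assert simulate_phase_pep(subj, default_config, "rest") == subj["pep_rest_mean"]

    def test_first_question_reduction_near_14_percent(self, cohort71, default_config):
        """The first stress question reduces expected PEP by ~14% on average."""
        subj = cohort71.subjects
        d1 = mental_drive(subj["mental_reactivity"], 1,
                          default_config.mental_sustained_fraction,
                          default_config.habituation_rate)
        assert abs(d1.mean() - 0.14) < 0.03

    def test_habituation_shrinks_across_questions(self, cohort71, default_config):
        subj = cohort71.subjects.iloc[3]
        drives = [mental_drive(subj["mental_reactivity"], q,
                               default_config.mental_sustained_fraction,
                               default_config.habituation_rate)
                  for q in range(1, 9)]
        assert all(a >= b for a, b in zip(drives, drives[1:]))
        assert drives[-1] < drives[0]

    def test_monotone_load_response(self, cohort71, default_config):
        """Expected PEP is non-increasing in load fraction while treading."""
        subj = cohort71.subjects.iloc[5]
        peps = [simulate_phase_pep(subj, default_config, "physical", load_fraction=lf)
                for lf in np.linspace(0, 1.2, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(peps, peps[1:]))

    def test_maximal_load_halves_pep(self, cohort71, default_config):
        subj = cohort71.subjects.iloc[5]
        pep = simulate_phase_pep(subj, default_config, "physical", load_fraction=1.0)
        assert pep == pytest.approx(subj["pep_rest_mean"] * 0.5, rel=0.1)

    def test_recovery_monotone_during_break(self, cohort71, default_config):
        """Within a break, expected PEP is non-decreasing as heart rate falls."""
        subj = cohort71.subjects.iloc[2]
        peps = [simulate_phase_pep(subj, default_config, "recovery",
                                   load_fraction=lf, treading=False)
                for lf in (0.60, 0.32, 0.16)]
        assert peps[0] <= peps[1] <= peps[2]

    def test_load_fraction_out_of_range_rejected(self, cohort71, default_config):
        subj = cohort71.subjects.iloc[0]
        with pytest.raises(ValueError):
            simulate_phase_pep(subj, default_config, "physical", load_fraction=1.5)
        with pytest.raises(ValueError):
            simulate_phase_pep(subj, default_config, "physical", load_fraction=-0.1)

    def test_state_ordering_at_matched_heart_rate(self, cohort71, default_config):
        """At equal heart rate: rest PEP > mental PEP > physical PEP."""
        for _, subj in cohort71.subjects.head(10).iterrows():
            for hr in np.linspace(subj["hr_rest"] + 3, subj["hr_rest"] + 30, 6):
                rest = expected_pep_at_hr(subj, default_config, "rest", hr)
                mental = expected_pep_at_hr(subj, default_config, "mental", hr)
                physical = expected_pep_at_hr(subj, default_config, "physical", hr)
                assert rest > mental > physical


class TestBeats:
    def test_rest_window_sd_matches_configured_value(self, cohort71):
        """4-beat-averaged resting PEP SD over 60 s windows ≈ 4.5 ms."""
        from pepstress.qc import average_beats
        sds = [average_beats(g, 4)["pep_q_ms"].std()
               for _, g in cohort71.beats.groupby("subject_id")]
        assert np.mean(sds) == pytest.approx(4.5, abs=0.5)

    def test_q_equals_r_plus_qr_interval(self, cohort71):
        b = cohort71.beats
        assert np.allclose(b["pep_q_ms"], b["pep_r_ms"] + b["qr_ms"])
        assert (b["pep_q_ms"] > 0).all() and (b["pep_r_ms"] > 0).all()

    def test_qr_interval_independent_of_heart_rate(self, default_config):
        """Pooled correlation between Q–R interval and heart-rate deviation is
        negligible on a large simulated sample."""
        cfg = default_config.model_copy(update={"n_subjects": 200, "n_male": 96})
        c = generate_cohort(cfg, seed=5, beats="full")
        hr_dev = c.beats.groupby("subject_id")["hr_bpm"].transform(lambda s: s - s.mean())
        r = np.corrcoef(hr_dev, c.beats["qr_ms"])[0, 1]
        assert abs(r) < 0.1

    def test_artifact_rate_zero_gives_clean_series(self, cohort71):
        from pepstress.qc import flag_hr_artifacts
        assert flag_hr_artifacts(cohort71.beats).all()

    def test_injected_artifacts_are_flagged(self, cohort71, default_config, rng):
        from pepstress.qc import flag_hr_artifacts
        subj = cohort71.subjects.iloc[0]
        beats = simulate_beats(subj, [("rest", 60.0)], default_config,
                               np.random.default_rng(3), artifact_rate=0.05)
        assert not flag_hr_artifacts(beats).all()

    def test_non_positive_duration_rejected(self, cohort71, default_config, rng):
        subj = cohort71.subjects.iloc[0]
        with pytest.raises(ValueError):
            simulate_beats(subj, [("rest", 0.0)], default_config,
                           np.random.default_rng(0))


class TestCuffCurves:
    @pytest.fixture()
    def measurement(self, cohort71):
        return cohort71.measurements.iloc[0]

    def test_clean_curve_has_small_deflation_rise(self, measurement):
        curve = simulate_cuff_curve(None, measurement, disturbed=False,
                                    rng=np.random.default_rng(1))
        p = curve["pressure_mmhg"].to_numpy()
        deflation = p[np.argmax(p):]
        rise = np.max(deflation - np.minimum.accumulate(deflation))
        assert rise < 8.0
        assert (p >= 0).all()

    def test_disturbed_curve_exceeds_threshold(self, measurement):
        curve = simulate_cuff_curve(None, measurement, disturbed=True,
                                    rng=np.random.default_rng(1))
        p = curve["pressure_mmhg"].to_numpy()
        deflation = p[np.argmax(p):]
        rise = np.max(deflation - np.minimum.accumulate(deflation))
        assert rise >= 8.0
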