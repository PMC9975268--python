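"""Synthetic stress-study cohort generator.

Emulates the statistical structure of a laboratory cardiovascular stress
study: per-subject latent parameters (resting PEP and its anthropometric and
heart-rate covariates, mental-stress reactivity with habituation, physical
load-response slope), measurement-epoch records across the full protocol
(rest → eight mental-stress questions → bimodal stepped ergometer profile),
beat-level series with a Q-wave/R-wave PEP pair, and cuff-deflation pressure
curves with optional injected disturbances.

The generator is fully deterministic given ``(config, seed)``: one master
seed spawns independent substreams for subjects, measurements, beats and
cuff curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pepstress.config import GeneratorConfig
from pepstress.protocol import (
    MAX_ERGO_STEPS,
    N_TSST_QUESTIONS,
    hr_max,
    phase_state,
    tsst_question,
)

SUBJECT_COLUMNS = [
    "subject_id", "sex", "age", "height_cm", "weight_kg",
    "hr_rest", "hr_max", "hr_per_watt",
    "pep_rest_mean", "pep_within_sd", "pep_hr_slope",
    "mental_reactivity", "habituation_rate",
    "qr_mean_ms", "sbp_rest", "dbp_rest",
]

MEASUREMENT_COLUMNS = [
    "subject_id", "phase", "state", "load_watts", "pep_ms", "hr_bpm",
    "sbp_mmhg", "dbp_mmhg", "lvet_ms", "heather_index", "valid",
]

BEAT_COLUMNS = ["subject_id", "phase", "t_s", "hr_bpm", "pep_q_ms", "pep_r_ms", "qr_ms"]

CUFF_COLUMNS = ["subject_id", "phase", "t_s", "pressure_mmhg"]


@dataclass
class CohortDataset:
    """A complete simulated study: subjects, measurements, optional beat
    series and cuff curves, plus the seed and config that produced them."""

    subjects: pd.DataFrame
    measurements: pd.DataFrame
    beats: pd.DataFrame | None
    cuff_curves: pd.DataFrame | None
    seed: int
    config: GeneratorConfig = field(repr=False)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size):
    if np.any(np.asarray(sd) < 0):
        raise ValueError("negative SD in generator distribution")
    if np.all(np.asarray(sd) == 0):
        return np.full(size, mean, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_subjects(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-subject latent profiles.

    Resting PEP = population mean + weight/height terms (centred at the
    pooled anthropometric means) + sex offset + resting-HR term + residual.
    The physical-load PEP–HR slope is the geometric slope that carries the
    subject from the treading-onset reduction to the maximal reduction at the
    80% HRmax stop line, jittered log-normally for inter-individual dynamics.
    """
    n, n_male = config.n_subjects, config.n_male
    a = config.anthropometrics
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))

    def by_sex(male_args, female_args):
        return np.concatenate([
            _truncnorm(rng, *male_args, size=n_male),
            _truncnorm(rng, *female_args, size=n - n_male),
        ])

    age = by_sex(
        (a.age_mean_male, a.age_sd_male, *a.age_bounds),
        (a.age_mean_female, a.age_sd_female, *a.age_bounds),
    )
    # height and weight correlated within sex via a shared factor
    rho = a.height_weight_corr
    z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * z2
    h_mean = np.where(sex == "male", a.height_mean_male, a.height_mean_female)
    h_sd = np.where(sex == "male", a.height_sd_male, a.height_sd_female)
    w_mean = np.where(sex == "male", a.weight_mean_male, a.weight_mean_female)
    w_sd = np.where(sex == "male", a.weight_sd_male, a.weight_sd_female)
    height = h_mean + h_sd * z1
    weight = np.clip(w_mean + w_sd * z2, 40.0, 130.0)

    hr_rest = _truncnorm(rng, config.hr_rest_mean, config.hr_rest_sd,
                         *config.hr_rest_bounds, size=n)
    hrmax = hr_max(age)

    # pooled anthropometric means implied by the configured sex split; all
    # structural terms are centred so the cohort mean stays at pep_rest_mean
    p_m = n_male / n
    w_pool = p_m * a.weight_mean_male + (1 - p_m) * a.weight_mean_female
    h_pool = p_m * a.height_mean_male + (1 - p_m) * a.height_mean_female
    lo, hi = config.hr_rest_bounds
    if config.hr_rest_sd > 0:
        az, bz = (lo - config.hr_rest_mean) / config.hr_rest_sd, \
                 (hi - config.hr_rest_mean) / config.hr_rest_sd
        hr_rest_center = stats.truncnorm.mean(az, bz, loc=config.hr_rest_mean,
                                              scale=config.hr_rest_sd)
    else:
        hr_rest_center = config.hr_rest_mean
    sex_term = np.where(sex == "female",
                        config.pep_sex_offset_female * p_m,
                        -config.pep_sex_offset_female * (1 - p_m))

    pep_rest = (
        config.pep_rest_mean
        + config.pep_weight_coef * (weight - w_pool)
        + config.pep_height_coef * (height - h_pool)
        + sex_term
        + config.pep_hr_rest_coef * (hr_rest - hr_rest_center)
        + rng.normal(0.0, config.pep_between_sd, n)
    )
    pep_rest = np.clip(pep_rest, 55.0, 160.0)

    hr_stop = 0.8 * hrmax
    jitter = np.exp(rng.normal(0.0, config.slope_jitter_sd, n))
    pep_hr_slope = (
        -(config.max_physical_reduction - config.treading_onset_reduction)
        * pep_rest / (hr_stop - hr_rest) * jitter
    )

    reactivity = _truncnorm(
        rng, config.mental_reactivity_mean, config.mental_reactivity_sd,
        *config.mental_reactivity_bounds, size=n,
    )
    width = max(len(str(n)), 3)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:0{width}d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "height_cm": height,
        "weight_kg": weight,
        "hr_rest": hr_rest,
        "hr_max": hrmax,
        "hr_per_watt": _truncnorm(rng, config.hr_per_watt_mean,
                                  config.hr_per_watt_sd, 0.25, 0.95, size=n),
        "pep_rest_mean": pep_rest,
        "pep_within_sd": np.full(n, config.pep_within_sd),
        "pep_hr_slope": pep_hr_slope,
        "mental_reactivity": reactivity,
        "habituation_rate": np.full(n, config.habituation_rate),
        "qr_mean_ms": _truncnorm(rng, config.qr_mean, config.qr_between_sd,
                                 24.0, 48.0, size=n),
        "sbp_rest": rng.normal(config.sbp_rest_mean, config.sbp_rest_sd, n),
        "dbp_rest": rng.normal(config.dbp_rest_mean, config.dbp_rest_sd, n),
    })[SUBJECT_COLUMNS]


def mental_drive(reactivity, question: int, sustained: float, habituation: float):
    """Fractional PEP reduction at stress question ``question`` (1-based):
    reactivity · (sustained + (1 − sustained) · habituation^(q−1))."""
    if not 1 <= question <= N_TSST_QUESTIONS:
        raise ValueError(f"question index out of range: {question}")
    return reactivity * (sustained + (1.0 - sustained) * habituation ** (question - 1))


def simulate_phase_pep(subject, config: GeneratorConfig, state: str, *,
                       question: int | None = None,
                       load_fraction: float | None = None,
                       treading: bool = True) -> float:
    """Expected (noise-free) PEP for one subject in a given state.

    ``subject`` is a row of the subjects table. For ``mental`` the 1-based
    ``question`` selects the habituation stage; for ``physical`` the
    ``load_fraction`` is the subject's heart-rate position between rest and
    the 80% HRmax stop line (values up to 1.2 tolerated for stop-rule
    overshoot; the PEP reduction is capped at ``max_physical_reduction``).
    ``treading=False`` drops the treading onset offset (recovery phases).
    """
    rest = float(subject["pep_rest_mean"])
    if state == "rest":
        return rest
    if state == "mental":
        if question is None:
            raise ValueError("mental state requires a question index")
        d = mental_drive(float(subject["mental_reactivity"]), question,
                         config.mental_sustained_fraction, config.habituation_rate)
        return rest * (1.0 - d)
    if state in ("physical", "recovery"):
        if load_fraction is None:
            raise ValueError("physical state requires a load_fraction")
        if not 0.0 <= load_fraction <= 1.2:
            raise ValueError(f"load_fraction outside [0, 1.2]: {load_fraction}")
        hr_span = 0.8 * float(subject["hr_max"]) - float(subject["hr_rest"])
        d_hr = load_fraction * hr_span
        onset = config.treading_onset_reduction * rest if treading and state == "physical" else 0.0
        lf = load_fraction ** config.load_response_exponent / max(load_fraction, 1e-12)
        atten = 1.0 if state == "physical" else config.recovery_attenuation
        pep = rest - onset + float(subject["pep_hr_slope"]) * d_hr * lf * atten
        return max(pep, rest * (1.0 - config.max_physical_reduction))
    raise ValueError(f"unknown state: {state!r}")


def expected_pep_at_hr(subject, config: GeneratorConfig, state: str, hr: float) -> float:
    """Expected PEP of a subject at a given heart rate under each state.

    Used for matched-heart-rate contrasts: within a subject, resting PEP does
    not depend on (between-measurement) heart rate, the mental effect is
    inverted through the mental heart-rate gain, and the physical effect
    follows the load-response line from the treading onset offset.
    """
    rest = float(subject["pep_rest_mean"])
    d_hr = max(hr - float(subject["hr_rest"]), 0.0)
    if state == "rest":
        return rest
    if state == "mental":
        d = min(d_hr / config.mental_hr_gain, 0.95)
        return rest * (1.0 - d)
    if state == "physical":
        pep = rest * (1.0 - config.treading_onset_reduction) + float(subject["pep_hr_slope"]) * d_hr
        return max(pep, rest * (1.0 - config.max_physical_reduction))
    raise ValueError(f"unknown state: {state!r}")


def _ergo_schedule(subject, config: GeneratorConfig, rng: np.random.Generator):
    """Stepped ergometer profile: (phase, watts, expected_hr, treading) rows.

    Load rises in weight-adapted steps (``watts_per_kg_step`` × body mass)
    until measured heart rate exceeds 80% of 220 − age (or the step cap).
    Then a three-measurement break, a second ascent (second-to-last step,
    then the top step twice) and three end-of-session rest measurements.
    """
    hr_rest = float(subject["hr_rest"])
    hr_stop = 0.8 * float(subject["hr_max"])
    step_w = config.watts_per_kg_step * float(subject["weight_kg"])
    slope_w = float(subject["hr_per_watt"])

    rows = []
    m = 0
    hr_last = hr_rest
    for s in range(1, config.max_ascent_steps + 1):
        watts = step_w * s
        hr = hr_rest + slope_w * watts + rng.normal(0.0, config.hr_meas_sd)
        rows.append((f"ergo_E{s}", watts, hr, True))
        m, hr_last = s, hr
        if hr > hr_stop:
            break
    elev = hr_last - hr_rest
    for i, frac in enumerate(config.break_recovery_fractions, start=1):
        hr = hr_rest + frac * elev + rng.normal(0.0, config.hr_meas_sd)
        rows.append((f"ergo_B{i}", 0.0, hr, False))
    # second ascent: step m−1, then the top step twice (load never increased
    # beyond the first-phase maximum)
    second = [max(m - 1, 1), m, m]
    for j, s in enumerate(second, start=1):
        label = f"ergo_E{m + j}"
        if m + j > MAX_ERGO_STEPS:
            break
        watts = step_w * s
        hr = hr_rest + slope_w * watts + rng.normal(0.0, config.hr_meas_sd)
        rows.append((label, watts, hr, True))
        hr_last = hr
    elev = hr_last - hr_rest
    nb = len(config.break_recovery_fractions)
    for i, frac in enumerate(config.end_rest_recovery_fractions, start=1):
        if nb + i > 6:
            break
        hr = hr_rest + frac * elev + rng.normal(0.0, config.hr_meas_sd)
        rows.append((f"ergo_B{nb + i}", 0.0, hr, False))
    return rows


def generate_measurements(subjects: pd.DataFrame, config: GeneratorConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Measurement-epoch table across the full protocol for every subject."""
    records = []
    pep_sd = config.pep_within_sd

    for _, subj in subjects.iterrows():
        hr_rest = float(subj["hr_rest"])
        hr_span = 0.8 * float(subj["hr_max"]) - hr_rest
        rows: list[tuple[str, float, float, float]] = []  # phase, watts, hr, expected pep

        for phase_label in ("rest",):
            hr = hr_rest + rng.normal(0.0, config.hr_meas_sd)
            rows.append((phase_label, 0.0, hr, float(subj["pep_rest_mean"])))

        for q in range(1, N_TSST_QUESTIONS + 1):
            d = mental_drive(float(subj["mental_reactivity"]), q,
                             config.mental_sustained_fraction, config.habituation_rate)
            hr = hr_rest + config.mental_hr_gain * d + rng.normal(0.0, config.hr_meas_sd)
            pep = float(subj["pep_rest_mean"]) * (1.0 - d)
            rows.append((f"tsst_Q{q}", 0.0, hr, pep))

        for phase_label, watts, hr, treading in _ergo_schedule(subj, config, rng):
            lf = min(max((hr - hr_rest) / hr_span, 0.0), 1.2)
            pep = simulate_phase_pep(
                subj, config, "physical" if treading else "recovery",
                load_fraction=lf, treading=treading)
            rows.append((phase_label, watts, hr, pep))

        hr = hr_rest + rng.normal(0.0, config.hr_meas_sd)
        rows.append(("final_rest", 0.0, hr, float(subj["pep_rest_mean"])))

        for phase_label, watts, hr, pep_expected in rows:
            pep_obs = pep_expected + rng.normal(0.0, pep_sd)
            heather = (config.heather_base
                       + config.heather_slope * (config.pep_rest_mean - pep_expected)
                       + rng.normal(0.0, config.heather_noise))
            lvet = (config.lvet_base
                    + config.lvet_slope * (pep_expected - config.pep_rest_mean)
                    + rng.normal(0.0, config.lvet_noise_ms))
            sbp = (float(subj["sbp_rest"])
                   + config.sbp_per_pep_ms * (pep_expected - float(subj["pep_rest_mean"]))
                   + rng.normal(0.0, config.sbp_noise_mmhg))
            dbp = (float(subj["dbp_rest"])
                   + config.dbp_per_sbp * (sbp - float(subj["sbp_rest"]))
                   + rng.normal(0.0, config.dbp_noise_mmhg))
            valid = bool(rng.random() >= config.cuff_disturb_rate)
            records.append((
                subj["subject_id"], phase_label, phase_state(phase_label), watts,
                pep_obs, hr, sbp, dbp, lvet, heather, valid,
            ))

    return pd.DataFrame(records, columns=MEASUREMENT_COLUMNS)


def _beat_sigma(config: GeneratorConfig, n_beats: int) -> float:
    """Innovation scale of the beat-level PEP fluctuation process.

    The configured ``beat_pep_sd`` is the *estimated* SD of the 4-beat-averaged
    resting series over a short (~60 s) window. For an AR(1) process both the
    sliding average and the short-window sample variance shrink the measured
    SD below the process SD; both factors are computed analytically here so
    the measured value matches the configured target in expectation.
    """
    rho = config.beat_pep_ar1
    n = max(n_beats, 8)
    # variance factor of a right-aligned 4-beat mean of AR(1)
    w = 4
    avg_factor = sum(rho ** abs(i - j) for i in range(w) for j in range(w)) / w**2
    # small-sample bias of the sample variance of a correlated series
    k = np.arange(1, n)
    bias = 1.0 - 2.0 * np.sum((n - k) * rho**k) / (n * (n - 1))
    target_var = config.beat_pep_sd**2 - (config.beat_pep_white_sd**2 / w) * bias
    # the averaged series is more strongly autocorrelated than the raw AR(1),
    # so the plain-series bias slightly understates the shrinkage; empirical
    # correction calibrated on 60-s windows
    proc_var = 1.15 * max(target_var, 1e-6) / (avg_factor * bias)
    return float(np.sqrt(proc_var))


def simulate_beats(subject, schedule: Sequence[tuple[str, float]],
                   config: GeneratorConfig, rng: np.random.Generator,
                   artifact_rate: float | None = None,
                   inter_phase_gap_s: float = 120.0) -> pd.DataFrame:
    """Beat-level series for one subject over a phase schedule.

    ``schedule`` is a sequence of (phase label, duration in s); consecutive
    windows are separated by ``inter_phase_gap_s`` of unrecorded protocol
    time, as in the study, so between-phase heart-rate steps do not mimic
    within-window artifacts. Beat PEP is
    the phase-expected PEP plus a slow autocorrelated fluctuation (vagal and
    respiratory modulation) plus white jitter; the Q–R interval is drawn
    independently of heart rate. Optional heart-rate artifacts (jumps > 30%
    within < 3 s) are injected at ``artifact_rate`` per beat.
    """
    if artifact_rate is None:
        artifact_rate = config.hr_artifact_rate
    hr_rest = float(subject["hr_rest"])
    hr_span = 0.8 * float(subject["hr_max"]) - hr_rest
    rows = []
    t = 0.0
    for phase_label, duration in schedule:
        if duration <= 0:
            raise ValueError("schedule durations must be positive")
        if rows:
            t += inter_phase_gap_s
        state = phase_state(phase_label)
        if state == "mental":
            q = tsst_question(phase_label)
            d = mental_drive(float(subject["mental_reactivity"]), q,
                             config.mental_sustained_fraction, config.habituation_rate)
            hr_base = hr_rest + config.mental_hr_gain * d
            pep_base = float(subject["pep_rest_mean"]) * (1.0 - d)
        elif state in ("physical", "recovery"):
            step = int(phase_label.split("E")[-1]) if state == "physical" else 0
            watts = config.watts_per_kg_step * float(subject["weight_kg"]) * max(step, 1)
            hr_base = hr_rest + float(subject["hr_per_watt"]) * watts if state == "physical" \
                else hr_rest + 0.2 * hr_span
            lf = min(max((hr_base - hr_rest) / hr_span, 0.0), 1.2)
            pep_base = simulate_phase_pep(subject, config, state, load_fraction=lf,
                                          treading=state == "physical")
        else:
            hr_base, pep_base = hr_rest, float(subject["pep_rest_mean"])

        n_est = int(duration * hr_base / 60.0) + 2
        sigma_p = _beat_sigma(config, n_est)
        innov_p = sigma_p * np.sqrt(1 - config.beat_pep_ar1**2)
        innov_h = config.beat_hr_sd * np.sqrt(1 - config.beat_hr_ar1**2)
        x_p = rng.normal(0.0, sigma_p)
        x_h = rng.normal(0.0, config.beat_hr_sd)
        t_phase = 0.0
        artifact_left = 0
        while t_phase < duration:
            hr = hr_base + x_h
            if artifact_left > 0:
                hr *= 1.5
                artifact_left -= 1
            elif artifact_rate > 0 and rng.random() < artifact_rate:
                artifact_left = 2
                hr *= 1.5
            pep_q = pep_base + x_p + rng.normal(0.0, config.beat_pep_white_sd)
            qr = float(subject["qr_mean_ms"]) + rng.normal(0.0, config.qr_within_sd)
            rows.append((subject["subject_id"], phase_label, t, hr, pep_q, pep_q - qr, qr))
            rr = 60.0 / max(hr, 20.0)
            t += rr
            t_phase += rr
            x_p = config.beat_pep_ar1 * x_p + rng.normal(0.0, innov_p)
            x_h = config.beat_hr_ar1 * x_h + rng.normal(0.0, innov_h)
    return pd.DataFrame(rows, columns=BEAT_COLUMNS)


def simulate_cuff_curve(subject, measurement, disturbed: bool,
                        rng: np.random.Generator, sample_hz: float = 10.0) -> pd.DataFrame:
    """Cuff pressure curve (inflation, hold, linear deflation) for one
    measurement; a disturbance injects a >8 mmHg pressure bump mid-deflation.
    ``subject`` is accepted for interface symmetry and may be ``None`` (the
    curve is fully determined by the measurement's systolic pressure)."""
    sbp = float(measurement["sbp_mmhg"])
    peak = sbp + 35.0
    dt = 1.0 / sample_hz
    t_inf = np.arange(0.0, 8.0, dt)
    p_inf = 5.0 + (peak - 5.0) * t_inf / 8.0
    t_hold = np.arange(8.0, 9.0, dt)
    p_hold = np.full_like(t_hold, peak)
    dur_def = (peak - 40.0) / 3.0
    t_def = np.arange(9.0, 9.0 + dur_def, dt)
    p_def = peak - 3.0 * (t_def - 9.0)
    if disturbed:
        # amplitude chosen so the net rise clears 8 mmHg even after the
        # concurrent deflation ramp is subtracted
        center = 9.0 + dur_def * rng.uniform(0.3, 0.7)
        amp = rng.uniform(14.0, 20.0)
        p_def = p_def + amp * np.exp(-0.5 * ((t_def - center) / 0.6) ** 2)
    t = np.concatenate([t_inf, t_hold, t_def])
    p = np.concatenate([p_inf, p_hold, p_def]) + rng.normal(0.0, 0.15, t.size)
    p = np.maximum(p, 0.0)
    return pd.DataFrame({
        "subject_id": measurement["subject_id"],
        "phase": measurement["phase"],
        "t_s": t,
        "pressure_mmhg": p,
    })[CUFF_COLUMNS]


DEFAULT_BEAT_SCHEDULE: tuple[tuple[str, float], ...] = (("rest", 60.0),)

#: schedule spanning all load states, for beat-level pooled analyses
FULL_BEAT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("rest", 60.0), ("tsst_Q1", 45.0), ("tsst_Q5", 45.0),
    ("ergo_E2", 45.0), ("ergo_E5", 45.0),
)


def generate_cohort(config: GeneratorConfig, seed: int, *,
                    beats: str = "rest",
                    cuff_curves: bool = False) -> CohortDataset:
    """Generate a complete seeded cohort.

    ``beats`` selects the beat-level simulation: ``"none"``, ``"rest"``
    (a 60-s resting window per subject) or ``"full"`` (windows spanning rest,
    mental and physical phases). Identical ``(config, seed)`` yields an
    identical dataset.
    """
    if beats not in ("none", "rest", "full"):
        raise ValueError(f"beats must be none|rest|full, got {beats!r}")
    ss = np.random.SeedSequence(seed)
    rng_subj, rng_meas, rng_beat, rng_cuff = (np.random.default_rng(s) for s in ss.spawn(4))

    subjects = generate_subjects(config, rng_subj)
    measurements = generate_measurements(subjects, config, rng_meas)

    beats_df = None
    if beats != "none":
        schedule = DEFAULT_BEAT_SCHEDULE if beats == "rest" else FULL_BEAT_SCHEDULE
        parts = [simulate_beats(subj, schedule, config, rng_beat)
                 for _, subj in subjects.iterrows()]
        beats_df = pd.concat(parts, ignore_index=True)

    cuff_df = None
    if cuff_curves:
        parts = [
            simulate_cuff_curve(None, meas, disturbed=not meas["valid"], rng=rng_cuff)
            for _, meas in measurements.iterrows()
        ]
        cuff_df = pd.concat(parts, ignore_index=True)

    return CohortDataset(subjects=subjects, measurements=measurements,
                         beats=beats_df, cuff_curves=cuff_df, seed=seed, config=config)
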