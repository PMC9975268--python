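"""Configuration blocks for every pipeline stage.

All models forbid unknown keys and round-trip losslessly through
``model_dump()`` / ``model_validate()`` and YAML/JSON. The generator defaults
encode the study conditions the analyses assume (cohort composition, printed
means and dispersions, calibrated couplings); see ``docs/methods.md`` for the
provenance of each value.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AnthropometricsConfig(_StrictModel):
    """Per-sex age/height/weight distributions (Gaussian, truncated)."""

    age_mean_male: float = 21.4
    age_sd_male: float = 2.3
    age_mean_female: float = 22.3
    age_sd_female: float = 3.2
    age_bounds: tuple[float, float] = (18.0, 35.0)
    height_mean_male: float = 183.3
    height_sd_male: float = 7.1
    height_mean_female: float = 167.6
    height_sd_female: float = 4.9
    weight_mean_male: float = 79.2
    weight_sd_male: float = 10.1
    weight_mean_female: float = 59.2
    weight_sd_female: float = 6.2
    #: within-sex correlation of height and weight
    height_weight_corr: float = 0.4


class GeneratorConfig(_StrictModel):
    """Synthetic-cohort generator parameters.

    Resting PEP is modelled as population mean + weight/height/sex terms +
    a resting-heart-rate term + subject residual. Mental load scales PEP by
    (1 − reactivity · g(q)) with g(q) = sustained + (1 − sustained) ·
    habituation^(q−1). Physical load reduces PEP linearly in the heart-rate
    load fraction, from a treading onset offset down to a capped maximal
    reduction at the 80% HRmax stop line.
    """

    n_subjects: int = 71
    n_male: int = 34
    anthropometrics: AnthropometricsConfig = Field(default_factory=AnthropometricsConfig)

    # --- resting PEP (ms) ---
    pep_rest_mean: float = 104.5
    #: residual between-subject SD after covariates (ms)
    pep_between_sd: float = 10.5
    #: structural weight coefficient (ms/kg), height coefficient (ms/cm)
    pep_weight_coef: float = 0.26
    pep_height_coef: float = 0.02
    #: additive term for females (ms); the raw female−male difference also
    #: carries the weight/height channels
    pep_sex_offset_female: float = -0.3
    #: between-subject coupling of resting PEP to resting HR (ms/bpm)
    pep_hr_rest_coef: float = -0.30
    #: within-subject SD of measurement-epoch PEP (ms)
    pep_within_sd: float = 4.5

    # --- resting heart rate (bpm) ---
    hr_rest_mean: float = 65.0
    hr_rest_sd: float = 8.0
    hr_rest_bounds: tuple[float, float] = (48.0, 92.0)
    hr_meas_sd: float = 2.0

    # --- mental load ---
    #: fractional PEP reduction at the first stress question
    mental_reactivity_mean: float = 0.145
    mental_reactivity_sd: float = 0.10
    mental_reactivity_bounds: tuple[float, float] = (0.02, 0.30)
    #: fraction of the mental effect that does not habituate
    mental_sustained_fraction: float = 0.88
    #: per-question geometric decay of the transient component
    habituation_rate: float = 0.70
    #: heart-rate rise per unit of mental drive (bpm per reactivity unit)
    mental_hr_gain: float = 125.0

    # --- physical load ---
    #: fractional PEP reduction at treading onset (posture/motor activity)
    treading_onset_reduction: float = 0.14
    #: total fractional reduction reached at the 80% HRmax stop line (capped)
    max_physical_reduction: float = 0.50
    #: exponent of the load-fraction response (1 = linear)
    load_response_exponent: float = 1.0
    #: lognormal sigma of per-subject slope heterogeneity
    slope_jitter_sd: float = 0.08
    #: heart-rate response to wattage, bpm per watt (per-subject mean, SD)
    hr_per_watt_mean: float = 0.62
    hr_per_watt_sd: float = 0.05
    #: ergometer step increment, watts per kg body mass
    watts_per_kg_step: float = 0.4
    max_ascent_steps: int = 7
    #: fraction of the exercise PEP reduction still present per unit of
    #: residual heart-rate elevation during recovery (PEP normalises faster
    #: than heart rate after exercise)
    recovery_attenuation: float = 0.30
    #: heart-rate recovery fractions (of the final elevation) at the three
    #: break measurements and the three end-of-session rest measurements
    break_recovery_fractions: tuple[float, ...] = (0.60, 0.32, 0.16)
    end_rest_recovery_fractions: tuple[float, ...] = (0.50, 0.25, 0.12)

    # --- coupled cardiovascular surrogates ---
    #: Heather index: hi = hi_base + hi_slope·(pep_rest_pop − expected PEP) + noise
    heather_base: float = 11.0
    heather_slope: float = 0.28
    #: noise SD in index units (sets the pooled R² to PEP)
    heather_noise: float = 3.9
    lvet_base: float = 295.0
    lvet_slope: float = 1.9
    #: noise SD in LVET ms
    lvet_noise_ms: float = 53.0
    sbp_rest_mean: float = 121.0
    sbp_rest_sd: float = 9.0
    #: mmHg change per ms of PEP change from rest (negative PEP change raises SBP)
    sbp_per_pep_ms: float = -0.8
    sbp_noise_mmhg: float = 9.5
    dbp_rest_mean: float = 72.0
    dbp_rest_sd: float = 7.0
    dbp_per_sbp: float = 0.25
    dbp_noise_mmhg: float = 4.0

    # --- beat-level series ---
    #: target SD of the 4-beat-averaged resting PEP over a 60-s window (ms)
    beat_pep_sd: float = 4.5
    #: lag-1 autocorrelation of the beat-level PEP fluctuation process
    beat_pep_ar1: float = 0.93
    #: additional white beat-to-beat jitter (ms)
    beat_pep_white_sd: float = 1.0
    #: slow heart-rate wander SD (bpm) and AR(1) coefficient
    beat_hr_sd: float = 2.0
    beat_hr_ar1: float = 0.95
    #: Q–R interval: between-subject mean/SD and within-subject beat SD (ms)
    qr_mean: float = 36.0
    qr_between_sd: float = 3.0
    qr_within_sd: float = 2.5
    #: probability per beat of an injected heart-rate artifact (>30% jump)
    hr_artifact_rate: float = 0.0
    #: probability a measurement's cuff curve carries a deflation disturbance
    cuff_disturb_rate: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.n_male <= self.n_subjects:
            raise ValueError("n_male must lie in [0, n_subjects]")
        for name in (
            "pep_between_sd", "pep_within_sd", "hr_rest_sd", "hr_meas_sd",
            "mental_reactivity_sd", "sbp_rest_sd", "sbp_noise_mmhg",
            "beat_pep_sd", "qr_within_sd", "heather_noise", "lvet_noise_ms",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative (got {getattr(self, name)})")
        if self.pep_rest_mean <= 0:
            raise ValueError("pep_rest_mean must be positive")
        if not 0 <= self.mental_reactivity_mean < 1:
            raise ValueError("mental_reactivity_mean must lie in [0, 1)")
        if not 0 <= self.habituation_rate <= 1:
            raise ValueError("habituation_rate must lie in [0, 1]")
        if not 0 <= self.mental_sustained_fraction <= 1:
            raise ValueError("mental_sustained_fraction must lie in [0, 1]")
        if not 0 <= self.treading_onset_reduction < self.max_physical_reduction < 1:
            raise ValueError("need 0 <= treading_onset_reduction < max_physical_reduction < 1")
        if not 0 <= self.hr_artifact_rate <= 1 or not 0 <= self.cuff_disturb_rate <= 1:
            raise ValueError("artifact rates must lie in [0, 1]")
        return self


class QcConfig(_StrictModel):
    """Quality-control thresholds (study defaults)."""

    #: flag heart-rate changes larger than this fraction ...
    hr_jump_fraction: float = 0.30
    #: ... occurring within this many seconds
    hr_window_s: float = 3.0
    #: reject cuff curves whose deflation pressure rises by more than this
    cuff_rise_mmhg: float = 8.0
    #: beat-averaging window (beats)
    avg_beats: int = 4
    #: drop whole measurement epochs ("epoch") or single beats ("beat")
    exclusion_mode: Literal["epoch", "beat"] = "epoch"

    @model_validator(mode="after")
    def _check(self) -> "QcConfig":
        if self.avg_beats < 1:
            raise ValueError("avg_beats must be >= 1")
        if self.hr_jump_fraction <= 0 or self.hr_window_s <= 0:
            raise ValueError("hr artifact thresholds must be positive")
        return self


class StatsConfig(_StrictModel):
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    hr_bin_width: float = 12.0
    hr_poly_degree: int = 2
    #: strata entering pooled surrogate correlations
    pooled_phases: Literal["all", "load_only"] = "all"


class ClassifierConfig(_StrictModel):
    k: int = 13
    n_folds: int = 5
    n_repeats: int = 20
    standardize: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ClassifierConfig":
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        return self


class UncertaintyConfig(_StrictModel):
    model_form: Literal["exponential", "quadratic"] = "exponential"
    #: exponential form: pwv = pwv_ref · exp(pwv_growth · (sbp − sbp_ref))
    pwv_ref: float = 5.0
    sbp_ref: float = 100.0
    pwv_growth: float = 0.008
    #: quadratic form: sbp = q0 + q1·pwv + q2·pwv²
    quad_coefs: tuple[float, float, float] = (30.0, 12.0, 0.4)
    subject_height_m: float = 1.80
    path_length_factor: float = 0.5
    sbp_grid: tuple[float, float, float] = (100.0, 180.0, 1.0)
    #: SBP support over which the model may be inverted
    sbp_support: tuple[float, float] = (40.0, 220.0)
    fit_degree: int = 2
    sbp_bin_width: float = 10.0


class PipelineConfig(_StrictModel):
    """Top-level configuration tying all stages together."""

    seed: int = 0
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    qc: QcConfig = Field(default_factory=QcConfig)
    qc_enabled: bool = True
    stats: StatsConfig = Field(default_factory=StatsConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    uncertainty: UncertaintyConfig = Field(default_factory=UncertaintyConfig)
    out_dir: str = "results"

    def config_hash(self) -> str:
        """Stable hash of the full configuration (seed included)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
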