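"""Data-quality rules applied before analysis.

Three filters mirror the study protocol: beats showing abnormal heart-rate
changes (> 30% within 3 s) are excluded as impedance-cardiography artifacts;
blood-pressure measurements whose cuff pressure rises by more than 8 mmHg
during deflation are rejected; and beat-to-beat data are smoothed with a
four-beat sliding average before entering any regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pepstress.config import QcConfig


@dataclass
class QcReport:
    """Record-count accounting of one QC pass; every excluded record carries
    exactly one primary reason code."""

    n_input: int
    n_excluded_hr_artifact: int = 0
    n_excluded_cuff: int = 0
    reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_valid(self) -> int:
        return self.n_input - self.n_excluded_hr_artifact - self.n_excluded_cuff

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded_hr_artifact": self.n_excluded_hr_artifact,
            "n_excluded_cuff": self.n_excluded_cuff,
            "n_valid": self.n_valid,
            "reasons": dict(self.reasons),
        }


def flag_hr_artifacts(beats: pd.DataFrame, config: QcConfig | None = None) -> np.ndarray:
    """Per-beat validity flags for abnormal heart-rate changes.

    A beat is invalid when its heart rate differs by more than
    ``hr_jump_fraction`` (default 30%) from *any* beat up to ``hr_window_s``
    (default 3 s) earlier — the strictest reading of the exclusion rule.
    Requires time-ordered beats (per subject); raises on unsorted timestamps.
    """
    config = config or QcConfig()
    if "subject_id" in beats.columns and beats["subject_id"].nunique() > 1:
        flags = np.ones(len(beats), dtype=bool)
        for _, idx in beats.groupby("subject_id", sort=False).indices.items():
            flags[idx] = flag_hr_artifacts(beats.iloc[idx], config)
        return flags

    t = beats["t_s"].to_numpy(dtype=float)
    hr = beats["hr_bpm"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("beat timestamps are not sorted")
    valid = np.ones(t.size, dtype=bool)
    start = 0
    for j in range(t.size):
        while t[j] - t[start] >= config.hr_window_s:
            start += 1
        for i in range(start, j):
            if abs(hr[j] - hr[i]) > config.hr_jump_fraction * hr[i]:
                valid[j] = False
                break
    return valid


def check_cuff_curve(curve: pd.DataFrame, config: QcConfig | None = None) -> bool:
    """Validity of one cuff pressure curve.

    The deflation segment (from the pressure peak onward) must not rise by
    more than ``cuff_rise_mmhg`` (default 8 mmHg, strict inequality). The
    rise is the maximum cumulative positive excursion — the largest climb
    from any earlier deflation sample to a later one — which is robust to
    sampling rate, unlike a single-sample difference.
    """
    config = config or QcConfig()
    if len(curve) == 0:
        raise ValueError("empty cuff curve")
    p = curve["pressure_mmhg"].to_numpy(dtype=float)
    deflation = p[int(np.argmax(p)):]
    if deflation.size < 2:
        return True
    rise = float(np.max(deflation - np.minimum.accumulate(deflation)))
    return rise <= config.cuff_rise_mmhg


def average_beats(beats: pd.DataFrame, window: int = 4,
                  valid: np.ndarray | None = None) -> pd.DataFrame:
    """Right-aligned sliding mean over ``window`` beats for PEP/HR columns.

    Only valid beats enter the averages; each output row keeps its source
    beat's timestamp (series length is preserved, the first ``window − 1``
    valid positions average over the shorter available history). Rows for
    invalid beats are dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if valid is None:
        valid = np.ones(len(beats), dtype=bool)
    out = beats.loc[np.asarray(valid, dtype=bool)].copy()
    cols = [c for c in ("hr_bpm", "pep_q_ms", "pep_r_ms", "qr_ms") if c in out.columns]
    group = out["subject_id"] if "subject_id" in out.columns else np.zeros(len(out))
    for c in cols:
        out[c] = (out.groupby(group, sort=False)[c]
                     .transform(lambda s: s.rolling(window, min_periods=1).mean()))
    return out


def apply_qc(beats: pd.DataFrame, config: QcConfig | None = None) -> tuple[pd.DataFrame, QcReport]:
    """Flag artifacts, drop invalid beats and smooth with the 4-beat average."""
    config = config or QcConfig()
    valid = flag_hr_artifacts(beats, config)
    report = QcReport(
        n_input=len(beats),
        n_excluded_hr_artifact=int((~valid).sum()),
        reasons={"hr_artifact": int((~valid).sum())},
    )
    return average_beats(beats, config.avg_beats, valid), report


def screen_measurements(measurements: pd.DataFrame,
                        cuff_curves: pd.DataFrame | None = None,
                        config: QcConfig | None = None) -> tuple[pd.DataFrame, QcReport]:
    """Apply cuff-curve screening to the measurement table.

    With cuff curves available, each measurement's curve is checked for
    deflation disturbances; otherwise the generator's validity flag (which
    encodes the injected disturbances) is honoured as-is.
    """
    config = config or QcConfig()
    out = measurements.copy()
    if cuff_curves is not None:
        ok = {}
        for (sid, phase), grp in cuff_curves.groupby(["subject_id", "phase"], sort=False):
            ok[(sid, phase)] = check_cuff_curve(grp, config)
        keys = list(zip(out["subject_id"], out["phase"]))
        out["valid"] = [ok.get(k, v) for k, v in zip(keys, out["valid"])]
    n_bad = int((~out["valid"]).sum())
    report = QcReport(n_input=len(out), n_excluded_cuff=n_bad,
                      reasons={"cuff_disturbance": n_bad} if n_bad else {})
    return out, report


def compare_q_vs_r(beats: pd.DataFrame) -> dict:
    """Compare the two PEP starting points (ECG Q-wave vs R-wave).

    Returns the pooled Pearson correlation between Q-start and R-start PEP,
    the mean per-subject SD of the Q–R interval, and the across-subject
    correlation (with p-value) between each subject's Q–R-interval change and
    heart-rate increase under load. With a single resting window the latter
    falls back to the beat-level correlation of Q–R interval with heart-rate
    deviation. Downstream analyses use the Q-wave PEP, the physiological
    onset of the pre-ejection period.
    """
    if len(beats) < 3:
        raise ValueError("need at least 3 beats")
    r = float(np.corrcoef(beats["pep_q_ms"], beats["pep_r_ms"])[0, 1])
    qr_sd = float(beats.groupby("subject_id")["qr_ms"].std().mean())

    per_subject = []
    for sid, grp in beats.groupby("subject_id"):
        rest = grp[grp["phase"].str.startswith(("rest", "final_rest"))]
        load = grp[~grp["phase"].str.startswith(("rest", "final_rest"))]
        if len(rest) >= 2 and len(load) >= 2:
            per_subject.append((load["hr_bpm"].mean() - rest["hr_bpm"].mean(),
                                load["qr_ms"].mean() - rest["qr_ms"].mean()))
    if len(per_subject) >= 3:
        d_hr, d_qr = np.array(per_subject).T
        corr, p = stats.pearsonr(d_hr, d_qr)
    else:
        hr_dev = beats.groupby("subject_id")["hr_bpm"].transform(lambda s: s - s.mean())
        if np.ptp(hr_dev) == 0 or np.ptp(beats["qr_ms"]) == 0:
            corr, p = 0.0, 1.0
        else:
            corr, p = stats.pearsonr(hr_dev, beats["qr_ms"])
    return {
        "pearson_r_q_vs_r": r,
        "qr_sd_ms": qr_sd,
        "qr_vs_dhr_r": float(corr),
        "qr_vs_dhr_p": float(p),
        "n_subjects": int(beats["subject_id"].nunique()),
    }
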