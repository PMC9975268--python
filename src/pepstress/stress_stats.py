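"""Stress-response statistics for the pre-ejection period.

Per-phase absolute and relative PEP summaries with bootstrap confidence
intervals, pooled correlations of PEP with other cardiovascular parameters
(Heather index, heart rate, left-ventricular ejection time, systolic-BP
change from rest), load-stratified PEP~HR regressions, per-subject
regression slopes, matched-heart-rate state contrasts, and anthropometric
covariates of the resting PEP.

Group-level contrasts use within-subject-centred least squares with
cluster-robust (by subject) standard errors as the documented equivalent of
a mixed linear model with heart rate as covariate; phase-contrast p-values
are Bonferroni-corrected over the stated family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pepstress.config import StatsConfig
from pepstress.protocol import PHASES


@dataclass
class RegressionResult:
    """One ordinary-least-squares fit of PEP on a predictor."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stratum: str

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "p_value": self.p_value,
            "n": self.n, "stratum": self.stratum,
        }


def _ols(x: np.ndarray, y: np.ndarray, stratum: str) -> RegressionResult:
    if x.size < 3:
        raise ValueError(f"stratum {stratum!r} has fewer than 3 points")
    if np.ptp(x) == 0:
        raise ValueError(f"constant predictor in stratum {stratum!r}")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
        n=int(x.size), stratum=stratum,
    )


def _valid(measurements: pd.DataFrame) -> pd.DataFrame:
    return measurements[measurements["valid"].astype(bool)]


def rest_reference(measurements: pd.DataFrame) -> pd.Series:
    """Each subject's calibration PEP: the first valid rest-phase measurement."""
    rest = _valid(measurements)
    rest = rest[rest["phase"] == "rest"]
    return rest.groupby("subject_id")["pep_ms"].first()


def phase_summaries(measurements: pd.DataFrame, config: StatsConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Per-phase mean PEP, relative PEP (fraction of each subject's rest
    calibration) and bootstrap confidence intervals.

    Subjects without a valid rest reference are excluded (with a warning via
    the returned frame's attrs). The per-phase n declines across ergometer
    steps as subjects reach their 80% HRmax stop line.
    """
    config = config or StatsConfig()
    rng = np.random.default_rng(seed)
    data = _valid(measurements)
    ref = rest_reference(measurements)
    missing = sorted(set(data["subject_id"]) - set(ref.index))
    data = data[data["subject_id"].isin(ref.index)].copy()
    data["rel_pep"] = data["pep_ms"] / data["subject_id"].map(ref)

    rows = []
    alpha = 1.0 - config.ci_level
    for phase in [p for p in PHASES if p in set(data["phase"])]:
        grp = data[data["phase"] == phase]
        rel = grp["rel_pep"].to_numpy()
        boots = np.array([
            rng.choice(rel, rel.size, replace=True).mean()
            for _ in range(config.n_bootstrap)
        ]) if rel.size > 1 else np.array([rel.mean()])
        rows.append({
            "phase": phase,
            "n": len(grp),
            "pep_mean_ms": grp["pep_ms"].mean(),
            "rel_pep_mean": rel.mean(),
            "rel_pep_ci_lo": float(np.quantile(boots, alpha / 2)),
            "rel_pep_ci_hi": float(np.quantile(boots, 1 - alpha / 2)),
        })
    out = pd.DataFrame(rows)
    out.attrs["excluded_subjects"] = missing
    return out


def correlate_surrogates(measurements: pd.DataFrame,
                         config: StatsConfig | None = None) -> dict[str, RegressionResult]:
    """Pooled R² of PEP against each cardiovascular surrogate.

    PEP is regressed on Heather index, heart rate and LVET across all valid
    measurements; the systolic-BP relation is computed on per-measurement
    deltas from each subject's rest calibration (ΔPEP vs ΔSBP). The heart-rate
    relation is additionally fitted with a polynomial (default degree 2) to
    accommodate its non-linear pooled distribution.
    """
    config = config or StatsConfig()
    data = _valid(measurements)
    if config.pooled_phases == "load_only":
        data = data[data["state"].isin(["mental", "physical"])]
    if data["state"].nunique() < 2:
        raise ValueError("need at least 2 load strata for pooled correlations")

    pep = data["pep_ms"].to_numpy()
    out: dict[str, RegressionResult] = {}
    for name, col in (("heather_index", "heather_index"),
                      ("hr", "hr_bpm"), ("lvet", "lvet_ms")):
        out[name] = _ols(data[col].to_numpy(), pep, name)

    # deltas from rest for SBP (and PEP), per subject
    ref_pep = rest_reference(measurements)
    rest_rows = measurements[(measurements["phase"] == "rest")
                             & measurements["valid"].astype(bool)]
    ref_sbp = rest_rows.groupby("subject_id")["sbp_mmhg"].first()
    sub = data[data["subject_id"].isin(ref_pep.index) & (data["phase"] != "rest")]
    d_pep = sub["pep_ms"].to_numpy() - sub["subject_id"].map(ref_pep).to_numpy()
    d_sbp = sub["sbp_mmhg"].to_numpy() - sub["subject_id"].map(ref_sbp).to_numpy()
    out["sbp_delta"] = _ols(d_sbp, d_pep, "sbp_delta")

    # polynomial heart-rate fit: R² from the least-squares polynomial
    coefs = np.polyfit(data["hr_bpm"], pep, config.hr_poly_degree)
    resid = pep - np.polyval(coefs, data["hr_bpm"])
    r2_poly = 1.0 - resid.var() / pep.var()
    out["hr_poly"] = RegressionResult(
        slope=float(coefs[0]), intercept=float(coefs[-1]),
        r_squared=float(r2_poly), p_value=float("nan"),
        n=len(data), stratum=f"hr_poly_deg{config.hr_poly_degree}",
    )
    return out


def stratified_hr_regression(measurements: pd.DataFrame) -> dict[str, RegressionResult]:
    """PEP~HR ordinary least squares separately at rest, under mental load
    and under physical (treading) load."""
    data = _valid(measurements)
    out = {}
    for state in ("rest", "mental", "physical"):
        grp = data[data["state"] == state]
        out[state] = _ols(grp["hr_bpm"].to_numpy(), grp["pep_ms"].to_numpy(), state)
    return out


def per_subject_slopes(measurements: pd.DataFrame, min_points: int = 4) -> pd.DataFrame:
    """PEP~HR slope fitted per subject across all valid measurements.

    Quantifies inter-individual differences in PEP dynamics; subjects with
    fewer than ``min_points`` valid measurements are skipped.
    """
    data = _valid(measurements)
    rows = []
    for sid, grp in data.groupby("subject_id"):
        if len(grp) < min_points:
            continue
        res = stats.linregress(grp["hr_bpm"], grp["pep_ms"])
        rows.append({"subject_id": sid, "slope": float(res.slope),
                     "intercept": float(res.intercept),
                     "r_squared": float(res.rvalue**2), "n": len(grp)})
    out = pd.DataFrame(rows)
    out.attrs["summary"] = {
        "mean": float(out["slope"].mean()),
        "sd": float(out["slope"].std()),
        "flattest": float(out["slope"].max()),
        "steepest": float(out["slope"].min()),
    } if len(out) else {}
    return out


def matched_hr_contrast(measurements: pd.DataFrame,
                        hr_bin_width: float = 12.0) -> pd.DataFrame:
    """Mean PEP per state within shared heart-rate bins.

    Bins of ``hr_bin_width`` bpm; for every bin populated by at least two
    states the per-state mean PEP is reported together with whether the
    rest > mental > physical ordering holds among the states present.
    """
    if hr_bin_width <= 0:
        raise ValueError("hr_bin_width must be positive")
    data = _valid(measurements)
    data = data[data["state"].isin(["rest", "mental", "physical"])].copy()
    data["hr_bin"] = (data["hr_bpm"] // hr_bin_width).astype(int)
    rows = []
    for b, grp in data.groupby("hr_bin"):
        means = grp.groupby("state")["pep_ms"].mean()
        if len(means) < 2:
            continue
        order = [s for s in ("rest", "mental", "physical") if s in means.index]
        vals = [means[s] for s in order]
        rows.append({
            "hr_bin_lo": b * hr_bin_width,
            "hr_bin_hi": (b + 1) * hr_bin_width,
            "pep_rest": means.get("rest", np.nan),
            "pep_mental": means.get("mental", np.nan),
            "pep_physical": means.get("physical", np.nan),
            "n": len(grp),
            "ordering_holds": bool(all(vals[i] > vals[i + 1] for i in range(len(vals) - 1))),
        })
    out = pd.DataFrame(rows)
    out.attrs["ordering_fraction"] = float(out["ordering_holds"].mean()) if len(out) else float("nan")
    return out


def covariates_and_anthropometrics(subjects: pd.DataFrame,
                                   measurements: pd.DataFrame) -> dict:
    """Sex difference and anthropometric correlates of the resting PEP.

    Returns the female-minus-male difference in mean resting PEP with a
    two-sample Welch test, and the R² of resting PEP on body weight and on
    height (simple regressions across subjects).
    """
    rest = _valid(measurements)
    rest = rest[rest["state"] == "rest"].groupby("subject_id")["pep_ms"].mean()
    if len(rest) == 0:
        raise ValueError("no resting measurements")
    df = subjects.set_index("subject_id").loc[rest.index].copy()
    df["pep_rest"] = rest

    out: dict = {}
    males = df.loc[df["sex"] == "male", "pep_rest"]
    females = df.loc[df["sex"] == "female", "pep_rest"]
    if len(males) >= 2 and len(females) >= 2:
        t, p = stats.ttest_ind(females, males, equal_var=False)
        out["sex_difference_ms"] = float(females.mean() - males.mean())
        out["sex_difference_p"] = float(p)
    else:
        out["sex_difference_ms"] = None
        out["sex_difference_p"] = None

    for key, col in (("weight", "weight_kg"), ("height", "height_cm")):
        res = _ols(df[col].to_numpy(), df["pep_rest"].to_numpy(), key)
        out[f"r2_{key}"] = res.r_squared
        out[f"p_{key}"] = res.p_value
    return out


def state_anova(measurements: pd.DataFrame) -> dict:
    """One-way ANOVA across rest / maximum mental / maximum physical PEP
    (rest measurement, first stress question, last ergometer step)."""
    data = _valid(measurements)
    rest = data[data["phase"] == "rest"]["pep_ms"]
    q1 = data[data["phase"] == "tsst_Q1"]["pep_ms"]
    ergo = data[data["state"] == "physical"]
    last = ergo.loc[ergo.groupby("subject_id")["load_watts"].idxmax()]["pep_ms"]
    f, p = stats.f_oneway(rest, q1, last)
    # Bonferroni over the three pairwise contrasts
    pairs = {}
    for name, (x, y) in {
        "rest_vs_mental": (rest, q1),
        "rest_vs_physical": (rest, last),
        "mental_vs_physical": (q1, last),
    }.items():
        _, pp = stats.ttest_ind(x, y, equal_var=False)
        pairs[name] = float(min(pp * 3, 1.0))
    return {"f": float(f), "p": float(p), "pairwise_bonferroni": pairs,
            "group_means": {"rest": float(rest.mean()), "mental_q1": float(q1.mean()),
                            "physical_max": float(last.mean())}}
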