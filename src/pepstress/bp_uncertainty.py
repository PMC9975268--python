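"""Propagation of PEP variability into PWV-based blood-pressure uncertainty.

An ECG-referenced pulse-arrival time decomposes as PAT = PEP + PTT, where
PTT = arterial path length / PWV(SBP). Because published PWV↔BP relations
vary, the mapping is a pluggable component with two built-in monotone forms
(exponential PWV growth in SBP; quadratic SBP in PWV); every analysis here is
form-agnostic. Given a polynomial fit of PEP on SBP with binned residual
SDs, confidence bands for PTT at ±1 SD and ±2 SD of the PEP estimate are
mapped back through the inverted PTT–SBP relation into SBP error bounds, and
three estimation strategies (neglect PEP, estimate PEP from SBP, calibrate
with the subject's resting PEP) are compared on simulated (SBP, PAT) pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from pepstress.config import UncertaintyConfig


class PwvBpModel:
    """Monotone SBP ↔ PWV mapping plus standard-human geometry.

    ``exponential``: PWV(SBP) = pwv_ref · exp(pwv_growth · (SBP − sbp_ref)).
    ``quadratic``: SBP(PWV) = q0 + q1·PWV + q2·PWV² (inverted numerically).
    Path length = subject height × path-length factor (heart-to-periphery
    convention); PTT(SBP) = path length / PWV(SBP) in ms.
    """

    def __init__(self, config: UncertaintyConfig | None = None):
        self.config = config or UncertaintyConfig()
        c = self.config
        self.path_length_m = c.subject_height_m * c.path_length_factor
        if self.path_length_m <= 0:
            raise ValueError("path length must be positive")
        lo, hi = c.sbp_support
        if not self.pwv(np.asarray(hi)) > self.pwv(np.asarray(lo)) > 0:
            raise ValueError("PWV must be positive and increasing over the SBP support")

    def _check_support(self, sbp) -> None:
        lo, hi = self.config.sbp_support
        if np.any(np.asarray(sbp) < lo) or np.any(np.asarray(sbp) > hi):
            raise ValueError(f"SBP outside model support [{lo}, {hi}]")

    def pwv(self, sbp):
        """Pulse-wave velocity (m/s) at a given SBP (mmHg)."""
        c = self.config
        sbp = np.asarray(sbp, dtype=float)
        if c.model_form == "exponential":
            return c.pwv_ref * np.exp(c.pwv_growth * (sbp - c.sbp_ref))
        q0, q1, q2 = c.quad_coefs
        # invert sbp = q0 + q1 v + q2 v² for v > 0
        disc = q1**2 - 4 * q2 * (q0 - sbp)
        if np.any(disc <= 0):
            raise ValueError("quadratic PWV model not invertible at requested SBP")
        return (-q1 + np.sqrt(disc)) / (2 * q2)

    def ptt(self, sbp):
        """Pulse-transit time (ms) over the arterial path at a given SBP."""
        self._check_support(sbp)
        return 1000.0 * self.path_length_m / self.pwv(sbp)

    def sbp_from_ptt(self, ptt_ms, clip: bool = False):
        """Invert PTT (ms) → SBP (mmHg); PTT decreases monotonically in SBP.

        Out-of-range PTT raises, or is clipped to the support edge with a
        warning when ``clip=True``.
        """
        lo, hi = self.config.sbp_support
        ptt_lo, ptt_hi = self.ptt(hi), self.ptt(lo)  # ptt decreasing in sbp
        scalar = np.isscalar(ptt_ms)
        ptt_arr = np.atleast_1d(np.asarray(ptt_ms, dtype=float))
        out = np.empty_like(ptt_arr)
        clipped = False
        for i, p in enumerate(ptt_arr):
            if p < ptt_lo or p > ptt_hi:
                if not clip:
                    raise ValueError(f"PTT {p:.1f} ms outside invertible range "
                                     f"[{ptt_lo:.1f}, {ptt_hi:.1f}]")
                clipped = True
                out[i] = hi if p < ptt_lo else lo
                continue
            out[i] = brentq(lambda s: self.ptt(s) - p, lo, hi, xtol=1e-10)
        if clipped:
            warnings.warn("PTT band edge left the invertible SBP support; clipped",
                          RuntimeWarning, stacklevel=2)
        return float(out[0]) if scalar else out


def pat_from_sbp(model: PwvBpModel, sbp, pep_ms):
    """Pulse-arrival time PAT = PTT(SBP) + PEP, in ms."""
    return model.ptt(sbp) + np.asarray(pep_ms, dtype=float)


@dataclass
class PepSbpFit:
    """Polynomial expectation of PEP given SBP, with binned residual SDs."""

    coefs: np.ndarray
    sbp_min: float
    sbp_max: float
    bin_edges: np.ndarray = field(repr=False)
    bin_sd: np.ndarray = field(repr=False)
    pooled_sd: float = 0.0

    def pep(self, sbp):
        sbp = np.asarray(sbp, dtype=float)
        return np.polyval(self.coefs, np.clip(sbp, self.sbp_min, self.sbp_max))

    def sd(self, sbp):
        """Residual SD at a given SBP (nearest populated bin; pooled SD where
        a bin is empty)."""
        sbp = np.asarray(sbp, dtype=float)
        idx = np.clip(np.digitize(sbp, self.bin_edges) - 1, 0, len(self.bin_sd) - 1)
        out = self.bin_sd[idx]
        return np.where(np.isnan(out), self.pooled_sd, out)


def fit_pep_sbp(measurements: pd.DataFrame, degree: int = 2,
                bin_width: float = 10.0) -> PepSbpFit:
    """Least-squares polynomial of PEP on SBP over all valid measurements,
    with residual SD per SBP bin on a documented grid."""
    data = measurements[measurements["valid"].astype(bool)]
    sbp = data["sbp_mmhg"].to_numpy(dtype=float)
    pep = data["pep_ms"].to_numpy(dtype=float)
    if len(np.unique(sbp)) < degree + 2:
        raise ValueError("insufficient distinct SBP values for the requested degree")
    coefs = np.polyfit(sbp, pep, degree)
    resid = pep - np.polyval(coefs, sbp)
    lo = np.floor(sbp.min() / bin_width) * bin_width
    hi = np.ceil(sbp.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    idx = np.clip(np.digitize(sbp, edges) - 1, 0, len(edges) - 2)
    bin_sd = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        r = resid[idx == b]
        if r.size >= 2:
            bin_sd[b] = r.std(ddof=1)
    return PepSbpFit(coefs=coefs, sbp_min=float(sbp.min()), sbp_max=float(sbp.max()),
                     bin_edges=edges, bin_sd=bin_sd, pooled_sd=float(resid.std(ddof=1)))


def build_uncertainty_band(model: PwvBpModel, fit: PepSbpFit,
                           sbp_grid: np.ndarray | None = None) -> pd.DataFrame:
    """PTT confidence bands and implied SBP error bounds over an SBP grid.

    Central PTT(s) = PAT(s) − fitted PEP(s); band edges place the PEP at
    ±1 SD and ±2 SD of its binned residual SD, and each PTT edge is mapped
    back through the inverted PTT–SBP relation (clipped at the support edge
    with a warning). Also reports PEP's fraction of PAT per grid point.
    """
    c = model.config
    if sbp_grid is None:
        lo, hi, step = c.sbp_grid
        sbp_grid = np.arange(lo, hi + step / 2, step)
    pep_c = fit.pep(sbp_grid)
    sd = fit.sd(sbp_grid)
    ptt_c = model.ptt(sbp_grid)
    pat_c = ptt_c + pep_c
    rows = {"sbp_mmhg": sbp_grid, "pat_ms": pat_c, "ptt_ms": ptt_c,
            "pep_ms": pep_c, "pep_sd_ms": sd,
            "pep_fraction_of_pat": pep_c / pat_c}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for z in (1, 2):
            # overestimating PEP by z·SD shrinks inferred PTT → higher SBP
            rows[f"ptt_lo_{z}sd"] = ptt_c - z * sd
            rows[f"ptt_hi_{z}sd"] = ptt_c + z * sd
            sbp_hi = model.sbp_from_ptt(ptt_c - z * sd, clip=True)
            sbp_lo = model.sbp_from_ptt(ptt_c + z * sd, clip=True)
            rows[f"sbp_err_lo_{z}sd"] = sbp_lo - sbp_grid
            rows[f"sbp_err_hi_{z}sd"] = sbp_hi - sbp_grid
    return pd.DataFrame(rows)


def compare_neglect_vs_estimate(model: PwvBpModel, fit: PepSbpFit,
                                measurements: pd.DataFrame,
                                subjects: pd.DataFrame | None = None) -> dict:
    """Absolute SBP error of three PEP-handling strategies.

    For each valid measurement with true SBP s and observed PEP p, the
    simulated arrival time is PAT = PTT(s) + p. Strategies: ``neglect``
    treats PAT as PTT; ``estimate`` solves the fixed point
    PTT(ŝ) = PAT − fitted PEP(ŝ); ``calibrate`` subtracts the subject's
    rest-calibration PEP. Reports per-strategy absolute-error summaries.
    """
    data = measurements[measurements["valid"].astype(bool)]
    lo, hi = model.config.sbp_support
    data = data[(data["sbp_mmhg"] >= lo + 1) & (data["sbp_mmhg"] <= hi - 1)]
    rest_pep = data[data["phase"] == "rest"].groupby("subject_id")["pep_ms"].first()
    data = data[data["subject_id"].isin(rest_pep.index)]

    sbp_true = data["sbp_mmhg"].to_numpy(dtype=float)
    pep_obs = data["pep_ms"].to_numpy(dtype=float)
    pat = model.ptt(sbp_true) + pep_obs
    cal = data["subject_id"].map(rest_pep).to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est_neglect = model.sbp_from_ptt(pat, clip=True)
        est_calibrate = model.sbp_from_ptt(pat - cal, clip=True)
        est_estimate = np.empty_like(sbp_true)
        for i, a in enumerate(pat):
            f = lambda s: model.ptt(s) + float(fit.pep(s)) - a
            if f(lo) * f(hi) > 0:
                est_estimate[i] = lo if abs(f(lo)) < abs(f(hi)) else hi
            else:
                est_estimate[i] = brentq(f, lo, hi, xtol=1e-8)

    out = {}
    for name, est in (("neglect", est_neglect), ("estimate", est_estimate),
                      ("calibrate", est_calibrate)):
        err = np.abs(est - sbp_true)
        out[name] = {"median_abs_err_mmhg": float(np.median(err)),
                     "mean_abs_err_mmhg": float(err.mean()),
                     "p90_abs_err_mmhg": float(np.quantile(err, 0.9)),
                     "n": int(err.size)}
    return out
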