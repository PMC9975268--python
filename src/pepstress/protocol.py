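"""Experimental-protocol vocabulary: phase labels, ordering and state mapping.

One session is: seated rest (calibration measurement), eight mental-stress
questions (four interview + four mental-arithmetic), then a bimodal stepped
ergometer profile: ascent 1 until heart rate exceeds 80% of the age-predicted
maximum (220 − age), a three-measurement break, a short second ascent
(second-to-last step, then the top step twice), three end-of-session rest
measurements, and a final fully recovered baseline.
"""

from __future__ import annotations

N_TSST_QUESTIONS = 8
MAX_ERGO_STEPS = 10
MAX_BREAK_MEASUREMENTS = 6

TSST_PHASES = tuple(f"tsst_Q{q}" for q in range(1, N_TSST_QUESTIONS + 1))
ERGO_PHASES = tuple(f"ergo_E{s}" for s in range(1, MAX_ERGO_STEPS + 1))
BREAK_PHASES = tuple(f"ergo_B{b}" for b in range(1, MAX_BREAK_MEASUREMENTS + 1))

#: Controlled vocabulary, in protocol order.
PHASES: tuple[str, ...] = ("rest", *TSST_PHASES, *ERGO_PHASES, *BREAK_PHASES, "final_rest")

#: States used by the stratified analyses and the load classifier.
STATES = ("rest", "mental", "physical")


def phase_state(phase: str) -> str:
    """Map a phase label to its analysis state.

    Treading measurements are ``physical``; stress-question measurements are
    ``mental``; the calibration rest and the recovered final baseline are
    ``rest``. Break/recovery measurements (``ergo_B*``) carry transient
    post-exercise dynamics and belong to no state (returned as ``recovery``);
    they enter phase summaries but not the three-state contrasts.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase label: {phase!r}")
    if phase.startswith("tsst_"):
        return "mental"
    if phase.startswith("ergo_E"):
        return "physical"
    if phase.startswith("ergo_B"):
        return "recovery"
    return "rest"


def tsst_question(phase: str) -> int:
    """1-based question index of a mental-stress phase label."""
    if not phase.startswith("tsst_Q"):
        raise ValueError(f"not a TSST phase: {phase!r}")
    return int(phase[len("tsst_Q"):])


def hr_max(age_years: float) -> float:
    """Age-predicted maximum heart rate, 220 − age (bpm)."""
    return 220.0 - age_years
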