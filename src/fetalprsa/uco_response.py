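"""Occlusion-response dynamics and phase windowing.

During a cord occlusion the fetal RR interval rises (the heart
decelerates) along a saturating exponential and, once pressure is
released, relaxes back much faster along a decaying exponential:

    onset:    rr(t) = A + B * (1 - exp(-t / tau_stim))
    release:  rr(t) = C + D * exp(-t / tau_rec)

with ``t`` measured from occlusion onset/release.  The two branches are
fitted independently by Levenberg–Marquardt least squares on the beats of
every occlusion (respectively recovery) of a phase, pooled after aligning
on the corresponding event.  ``A``–``D`` are nuisance scalars; the time
constants ``tau_stim`` and ``tau_rec`` are the quantities of interest.

"Stable" series exclude the occlusion-induced decelerations: the beats
kept span from 30 s after the end of each occlusion (over three times the
longest recovery constant, so the rate is substantially back at baseline)
to the start of the next one.  Because those stretches are at most about
a minute long, they are concatenated — with recorded junctions — so PRSA
can be run at larger ``T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import (
    BiomarkerSample,
    DegenerateInputError,
    FitFailureError,
    OcclusionSchedule,
    RRSeries,
)

__all__ = [
    "STABLE_MARGIN_S",
    "UCOResponseModel",
    "PhaseWindow",
    "extract_aligned_responses",
    "fit_time_constants",
    "stable_intervals",
    "concatenate_stable_segments",
    "phase_analysis_window",
]

logger = logging.getLogger(__name__)

#: Post-occlusion margin excluded from stable intervals (s); larger than
#: three times the longest recovery constant observed in the cohort.
STABLE_MARGIN_S = 30.0

#: Analysis window at the end of each phase (s).
ANALYSIS_WINDOW_S = 1800.0

_MIN_POINTS_PER_BRANCH = 10


@dataclass
class UCOResponseModel:
    """Fitted occlusion-response parameters for one subject."""

    a: float
    b: float
    c: float
    d: float
    tau_stim: float
    tau_rec: float
    residual_rms: float
    n_points: int
    tau_at_bound: bool = False


@dataclass(frozen=True)
class PhaseWindow:
    """Analysis interval of a phase with its time-matched blood sample."""

    phase: str
    start: float
    end: float
    biomarker: BiomarkerSample


def extract_aligned_responses(
    series: RRSeries,
    schedule: OcclusionSchedule,
    phase: str,
    alignment: str = "onset",
) -> tuple[np.ndarray, np.ndarray]:
    """Pool beats of every occlusion (or recovery) of a phase.

    ``alignment="onset"`` keeps beats inside each occlusion, with time
    measured from its start; ``alignment="release"`` keeps beats between
    an occlusion's end and the next occlusion's start (or the phase end),
    with time measured from the release.  Returns ``(t_rel_s, rr_ms)``.
    """
    if alignment not in ("onset", "release"):
        raise ValueError(f"unknown alignment {alignment!r}")
    events = schedule.events_in_phase(phase)
    if not events:
        raise DegenerateInputError(f"phase {phase} contains no occlusions")
    pend = schedule.phase(phase).end
    t_out: list[np.ndarray] = []
    rr_out: list[np.ndarray] = []
    t = series.onset_time
    for i, ev in enumerate(events):
        if alignment == "onset":
            lo, hi, ref = ev.start, ev.end, ev.start
        else:
            nxt = events[i + 1].start if i + 1 < len(events) else pend
            lo, hi, ref = ev.end, nxt, ev.end
        keep = (t >= lo) & (t < hi)
        t_out.append(t[keep] - ref)
        rr_out.append(series.rr[keep])
    return np.concatenate(t_out), np.concatenate(rr_out)


def _fit_branch(
    t: np.ndarray, rr: np.ndarray, kind: str
) -> tuple[float, float, float, np.ndarray, bool]:
    """Fit one exponential branch; returns (offset, amplitude, tau, resid, at_bound)."""
    if t.size < _MIN_POINTS_PER_BRANCH:
        raise DegenerateInputError(
            f"{kind} branch has only {t.size} points (< {_MIN_POINTS_PER_BRANCH})"
        )
    span = float(t.max() - t.min())
    if span <= 0:
        raise DegenerateInputError(f"{kind} branch has zero time span")
    lo = t <= t.min() + 0.1 * span
    hi = t >= t.max() - 0.1 * span
    early = float(np.median(rr[lo]))
    late = float(np.median(rr[hi]))

    if kind == "onset":
        def model(tt, off, amp, tau):
            return off + amp * (1.0 - np.exp(-tt / tau))
        p0_off, p0_amp = early, late - early
    else:
        def model(tt, off, amp, tau):
            return off + amp * np.exp(-tt / tau)
        p0_off, p0_amp = late, early - late

    tau0 = span / 3.0
    last_exc: Exception | None = None
    for factor in (1.0, 0.3, 3.0):
        try:
            popt, _ = curve_fit(
                model, t, rr,
                p0=(p0_off, p0_amp, tau0 * factor),
                method="lm", maxfev=20000,
            )
        except RuntimeError as exc:
            last_exc = exc
            continue
        off, amp, tau = map(float, popt)
        if tau <= 0:
            last_exc = FitFailureError(f"{kind} branch: non-positive tau {tau:.3g}")
            continue
        resid = rr - model(t, *popt)
        at_bound = tau > 10.0 * span or tau < 1e-3
        if at_bound:
            logger.warning("%s-branch tau %.3g s at bound (span %.3g s)", kind, tau, span)
        return off, amp, tau, resid, at_bound
    raise FitFailureError(
        f"{kind} branch fit did not converge after bounded restarts: {last_exc}"
    )


def fit_time_constants(
    onset_points: tuple[np.ndarray, np.ndarray],
    release_points: tuple[np.ndarray, np.ndarray],
) -> UCOResponseModel:
    """Fit the two exponential branches and return the time constants.

    ``onset_points`` and ``release_points`` are ``(t_rel_s, rr_ms)`` pairs
    as produced by :func:`extract_aligned_responses`.  The fits are
    independent, deterministic (fixed initialization: offset from the
    branch-endpoint medians, amplitude from their difference, ``tau`` a
    third of the branch span, with x0.3/x3 restarts), and fail loudly on
    non-convergence.
    """
    t_on, rr_on = (np.asarray(v, float) for v in onset_points)
    t_off, rr_off = (np.asarray(v, float) for v in release_points)
    a, b, tau_stim, res_on, bound_on = _fit_branch(t_on, rr_on, "onset")
    c, d, tau_rec, res_off, bound_off = _fit_branch(t_off, rr_off, "release")
    resid = np.concatenate((res_on, res_off))
    return UCOResponseModel(
        a=a, b=b, c=c, d=d,
        tau_stim=tau_stim, tau_rec=tau_rec,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(resid.size),
        tau_at_bound=bound_on or bound_off,
    )


def stable_intervals(
    schedule: OcclusionSchedule,
    phase: str,
    margin_s: float = STABLE_MARGIN_S,
) -> list[tuple[float, float]]:
    """Deceleration-free intervals of a phase.

    For each occlusion ending at ``e`` and followed by the next occlusion
    starting at ``s`` (or by the phase end), the interval
    ``[e + margin_s, s)`` is stable; non-positive intervals are dropped.
    A phase without occlusions (BASELINE, RECOVERY) is one stable interval.
    """
    p = schedule.phase(phase)
    events = schedule.events_in_phase(phase)
    if not events:
        return [(p.start, p.end)]
    out = []
    for i, ev in enumerate(events):
        start = ev.end + margin_s
        end = events[i + 1].start if i + 1 < len(events) else p.end
        if end > start:
            out.append((start, end))
    return out


def concatenate_stable_segments(
    series: RRSeries, intervals: list[tuple[float, float]]
) -> RRSeries:
    """Keep beats fully inside the intervals; record segment junctions.

    A beat belongs to an interval when the whole RR interval it terminates
    lies inside it.  All per-beat flags are carried over; the returned
    series records a segment boundary at every junction between
    consecutive non-empty intervals.
    """
    if not intervals:
        raise DegenerateInputError("no stable intervals to concatenate")
    t = series.onset_time
    beat_start = t - series.rr / 1000.0
    parts: list[np.ndarray] = []
    for lo, hi in intervals:
        keep = np.flatnonzero((beat_start >= lo) & (t < hi))
        if keep.size:
            parts.append(keep)
    if not parts:
        raise DegenerateInputError("no beats inside the stable intervals")
    boundaries = np.cumsum([p.size for p in parts[:-1]])
    idx = np.concatenate(parts)
    return RRSeries(
        series.onset_time[idx],
        series.rr[idx],
        series.reconstructed[idx],
        series.anchor_eligible[idx],
        series.subject_id,
        boundaries if len(parts) > 1 else np.empty(0, np.int64),
    )


def phase_analysis_window(
    schedule: OcclusionSchedule,
    biomarkers: list[BiomarkerSample],
    phase: str,
    window_s: float = ANALYSIS_WINDOW_S,
) -> PhaseWindow:
    """Last ``window_s`` of a phase with its time-matched blood sample.

    The window is clipped at the phase start (with a warning for phases
    shorter than ``window_s``); the matched sample is the last one drawn
    at or before the phase end.  Acid-base status is maximal at the end of
    each occlusion phase, so this pairing matches AC/DC with the most
    informative sample while keeping one sample per subject and phase.
    """
    p = schedule.phase(phase)
    start = p.end - window_s
    if start < p.start:
        logger.warning(
            "phase %s (%.0f s) shorter than analysis window (%.0f s); using whole phase",
            phase, p.end - p.start, window_s,
        )
        start = p.start
    in_phase = [s for s in biomarkers if p.start <= s.time <= p.end]
    if not in_phase:
        raise DegenerateInputError(f"no blood sample inside phase {phase}")
    matched = max(in_phase, key=lambda s: s.time)
    return PhaseWindow(phase, start, p.end, matched)
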