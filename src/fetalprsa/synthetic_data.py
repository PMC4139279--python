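"""Seeded synthetic UCO-protocol datasets (fRR + schedule + biomarkers).

The generator emulates the repetitive cord-occlusion experiment: after a
rest period (BASELINE), 1-minute occlusions alternate with 1.5-minute
recoveries through three escalating phases (MILD 60 min, MODERATE 60 min,
SEVERE ~2 h), followed by a RECOVERY period.  The deterministic RR
component during an occlusion follows the saturating exponential of the
occlusion-response model with a per-subject ``tau_stim``, and decays with
``tau_rec`` after release; on top of that sit a slow sinusoidal
oscillation and white beat-to-beat noise whose amplitudes grow with the
phase, plus sporadic merged-beat artifacts (> 1500 ms).  Blood-gas
trajectories interpolate between per-phase-end targets, with the SEVERE
phase ending below pH 7.00 as in the protocol's stopping rule.

Randomness is split from a single seed with ``numpy.random.SeedSequence``:
the root sequence spawns one child per subject, and each subject child
spawns three streams in fixed order — (time-constant draw, beat noise,
artifact placement) — so any subject's data is reproducible in isolation.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from math import exp, floor, pi, sin
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import reference
from .io_formats import (
    BiomarkerSample,
    OcclusionEvent,
    OcclusionSchedule,
    PHASE_ORDER,
    ProtocolPhase,
    RRSeries,
    UCO_PHASES,
    ValidationError,
)

__all__ = [
    "PhaseVariability",
    "SyntheticConfig",
    "SubjectRecord",
    "generate_protocol_schedule",
    "generate_frr_series",
    "inject_artifacts",
    "generate_biomarker_trajectory",
    "generate_cohort",
]


class PhaseVariability(BaseModel):
    """Slow-oscillation and beat-to-beat noise amplitudes for one phase."""

    period_s: float = Field(25.0, gt=0)
    amp_ms: float = Field(0.0, ge=0)
    sd_ms: float = Field(0.0, ge=0)


def _default_variability() -> dict[str, PhaseVariability]:
    return {
        "BASELINE": PhaseVariability(amp_ms=4.0, sd_ms=2.5),
        "MILD": PhaseVariability(amp_ms=4.0, sd_ms=2.5),
        "MODERATE": PhaseVariability(amp_ms=8.0, sd_ms=5.0),
        "SEVERE": PhaseVariability(amp_ms=12.0, sd_ms=8.0),
        "RECOVERY": PhaseVariability(amp_ms=4.0, sd_ms=2.5),
    }


class SyntheticConfig(BaseModel):
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_subjects: int = Field(7, ge=1)
    baseline_rr_mean: float = Field(400.0, gt=0)

    occlusion_duration_s: float = Field(60.0, gt=0)
    recovery_s: float = Field(90.0, gt=0)
    phase_durations_s: dict[str, float] = Field(
        default_factory=lambda: {
            "BASELINE": 1800.0,
            "MILD": 3600.0,
            "MODERATE": 3600.0,
            "SEVERE": 7200.0,
            "RECOVERY": 1800.0,
        }
    )
    #: RR elevation (ms) at the deceleration plateau, per occlusion phase.
    deceleration_depth_ms: dict[str, float] = Field(
        default_factory=lambda: {"MILD": 40.0, "MODERATE": 120.0, "SEVERE": 250.0}
    )
    variability: dict[str, PhaseVariability] = Field(
        default_factory=_default_variability
    )

    #: Fixed per-subject time constants; when None, drawn uniformly from the
    #: empirical cohort ranges below.
    tau_stim_s: Optional[float] = None
    tau_rec_s: Optional[float] = None
    tau_stim_range_s: tuple[float, float] = (
        min(reference.COHORT_TAU_STIM_S),
        max(reference.COHORT_TAU_STIM_S),
    )
    tau_rec_range_s: tuple[float, float] = (
        min(reference.COHORT_TAU_REC_S),
        max(reference.COHORT_TAU_REC_S),
    )

    artifact_rate_per_hour: float = Field(2.0, ge=0)
    artifact_threshold_ms: float = Field(1500.0, gt=0)

    biomarker_interval_s: float = Field(1200.0, gt=0)
    #: (pH, lactate mEq/L, base deficit mEq/L) reached at each phase end.
    biomarker_targets: dict[str, tuple[float, float, float]] = Field(
        default_factory=lambda: {
            "BASELINE": (7.35, 1.60, 1.08),
            "MILD": (7.33, 1.65, 0.29),
            "MODERATE": (7.28, 3.80, -2.46),
            "SEVERE": (6.98, 11.40, -14.07),
            "RECOVERY": (7.25, 6.00, -8.00),
        }
    )

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        for name, dur in self.phase_durations_s.items():
            if name not in PHASE_ORDER:
                raise ValueError(f"unknown phase {name!r}")
            if dur <= 0:
                raise ValueError(f"phase {name} has non-positive duration")
        ts = self.tau_stim_s
        tr = self.tau_rec_s
        if ts is not None and tr is not None and not ts > tr > 0:
            raise ValueError("need tau_stim > tau_rec > 0")
        if self.tau_stim_range_s[0] <= self.tau_rec_range_s[1] and ts is None:
            raise ValueError(
                "tau_stim range must lie entirely above tau_rec range"
            )
        sev = self.biomarker_targets.get("SEVERE")
        if sev is not None and not sev[0] < 7.00:
            raise ValueError("SEVERE terminal pH target must be < 7.00")
        for name, (ph, lac, _) in self.biomarker_targets.items():
            if not 6.5 < ph < 7.8 or lac < 0:
                raise ValueError(f"biomarker target for {name} out of range")
        return self


@dataclass
class SubjectRecord:
    """One simulated subject: series (with artifacts), schedule, biomarkers."""

    subject_id: str
    series: RRSeries
    schedule: OcclusionSchedule
    biomarkers: list[BiomarkerSample]
    tau_stim: float
    tau_rec: float


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------


def generate_protocol_schedule(config: SyntheticConfig) -> OcclusionSchedule:
    """Tile each occlusion phase with (occlusion, recovery) cycles.

    Phases run back to back in protocol order; partial trailing cycles are
    dropped.  BASELINE and RECOVERY contain no events.
    """
    phases: list[ProtocolPhase] = []
    t = 0.0
    for name in PHASE_ORDER:
        if name in config.phase_durations_s:
            dur = config.phase_durations_s[name]
            phases.append(ProtocolPhase(name, t, t + dur))
            t += dur
    events: list[OcclusionEvent] = []
    cycle = config.occlusion_duration_s + config.recovery_s
    for p in phases:
        if p.name not in UCO_PHASES:
            continue
        n_cycles = int(floor((p.end - p.start) / cycle))
        if n_cycles < 1:
            raise ValidationError(
                f"phase {p.name} shorter than one occlusion cycle ({cycle} s)"
            )
        for k in range(n_cycles):
            start = p.start + k * cycle
            events.append(OcclusionEvent(start, start + config.occlusion_duration_s, p.name))
    sched = OcclusionSchedule(events, phases)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# fRR series
# ---------------------------------------------------------------------------


class _ElevationModel:
    """Piecewise-exponential RR elevation caused by the occlusion train."""

    def __init__(self, schedule: OcclusionSchedule, config: SyntheticConfig,
                 tau_stim: float, tau_rec: float) -> None:
        self.tau_stim = tau_stim
        self.tau_rec = tau_rec
        self.starts: list[float] = []
        self.ends: list[float] = []
        self.depths: list[float] = []
        self.entry: list[float] = []
        self.exit: list[float] = []
        prev_elev, prev_time = 0.0, None
        for ev in schedule.events:
            depth = config.deceleration_depth_ms.get(ev.phase, 0.0)
            e_in = 0.0 if prev_time is None else prev_elev * exp(
                -(ev.start - prev_time) / tau_rec
            )
            e_out = depth + (e_in - depth) * exp(-(ev.end - ev.start) / tau_stim)
            self.starts.append(ev.start)
            self.ends.append(ev.end)
            self.depths.append(depth)
            self.entry.append(e_in)
            self.exit.append(e_out)
            prev_elev, prev_time = e_out, ev.end

    def __call__(self, t: float) -> float:
        j = bisect_right(self.starts, t) - 1
        if j < 0:
            return 0.0
        if t <= self.ends[j]:
            d = self.depths[j]
            return d + (self.entry[j] - d) * exp(-(t - self.starts[j]) / self.tau_stim)
        return self.exit[j] * exp(-(t - self.ends[j]) / self.tau_rec)


def _draw_taus(config: SyntheticConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Per-subject time constants; always consumes two draws for stream stability."""
    u1, u2 = rng.uniform(size=2)
    lo, hi = config.tau_stim_range_s
    tau_stim = config.tau_stim_s if config.tau_stim_s is not None else lo + u1 * (hi - lo)
    lo, hi = config.tau_rec_range_s
    tau_rec = config.tau_rec_s if config.tau_rec_s is not None else lo + u2 * (hi - lo)
    return float(tau_stim), float(tau_rec)


def generate_frr_series(
    config: SyntheticConfig,
    schedule: OcclusionSchedule,
    subject_id: str = "subject-01",
    tau_stim: float | None = None,
    tau_rec: float | None = None,
    rng: np.random.Generator | None = None,
) -> RRSeries:
    """Simulate the beat series for the whole protocol.

    Beat *i* terminating at time ``t`` has
    ``rr = baseline + elevation(t) + amp sin(2 pi t / period) + sd z_i``
    with the elevation model above and per-phase (amp, sd); the implicit
    relation ``t = t_prev + rr/1000`` is solved by fixed-point iteration so
    the recorded (time, rr) pairs lie exactly on the deterministic model
    when the noise terms are zero.  Identical seed implies identical output.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if tau_stim is None or tau_rec is None:
        tau_stim, tau_rec = _draw_taus(config, rng)
    elev = _ElevationModel(schedule, config, tau_stim, tau_rec)
    phase_starts = [p.start for p in schedule.phases]
    var = [
        config.variability.get(p.name, PhaseVariability())
        for p in schedule.phases
    ]
    total = schedule.total_duration_s
    base = config.baseline_rr_mean

    times: list[float] = []
    rrs: list[float] = []
    t = 0.0
    rr = base
    # draw noise in blocks so the stream is identical regardless of chunking
    noise_buf = rng.standard_normal(4096)
    buf_i = 0
    while t < total:
        if buf_i == noise_buf.size:
            noise_buf = rng.standard_normal(4096)
            buf_i = 0
        z = noise_buf[buf_i]
        buf_i += 1
        j = max(0, bisect_right(phase_starts, t) - 1)
        v = var[j]
        guess = rr
        for _ in range(64):
            tn = t + guess / 1000.0
            val = (
                base
                + elev(tn)
                + v.amp_ms * sin(2.0 * pi * tn / v.period_s)
                + v.sd_ms * z
            )
            if abs(val - guess) < 1e-10:
                guess = val
                break
            guess = val
        rr = max(guess, 50.0)
        t = t + rr / 1000.0
        times.append(t)
        rrs.append(rr)
    n = len(rrs)
    return RRSeries(
        np.asarray(times), np.asarray(rrs),
        np.zeros(n, bool), np.ones(n, bool), subject_id,
    )


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def inject_artifacts(
    series: RRSeries,
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
) -> RRSeries:
    """Merge random short runs of beats into single long intervals.

    Emulates beat misdetection: each artifact replaces the smallest run of
    consecutive beats whose summed RR exceeds the artifact threshold
    (so every injected interval is > 1500 ms by construction) with one
    merged interval.  The artifact count is Poisson with mean
    ``rate x duration``; total recording time is conserved.  Per-beat
    flags are left untouched — labeling artifacts is preprocessing's job.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    duration_h = series.duration_s / 3600.0
    n_art = int(rng.poisson(config.artifact_rate_per_hour * duration_h))
    if n_art == 0 or series.n_beats < 10:
        return series.copy()
    starts = np.sort(rng.integers(1, series.n_beats - 5, size=n_art))
    rr = series.rr
    drop = np.zeros(series.n_beats, bool)
    merged: dict[int, float] = {}  # last index of run -> merged rr
    prev_end = -1
    for a in starts:
        if a <= prev_end:
            continue
        total = 0.0
        b = a
        while b < series.n_beats and total <= config.artifact_threshold_ms:
            total += rr[b]
            b += 1
        if total <= config.artifact_threshold_ms:
            break  # ran off the end
        drop[a : b - 1] = True
        merged[b - 1] = total
        prev_end = b - 1
    new_rr = rr.copy()
    for last, tot in merged.items():
        new_rr[last] = tot
    keep = ~drop
    return RRSeries(
        series.onset_time[keep],
        new_rr[keep],
        series.reconstructed[keep],
        series.anchor_eligible[keep],
        series.subject_id,
    )


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------


def generate_biomarker_trajectory(
    config: SyntheticConfig, schedule: OcclusionSchedule
) -> list[BiomarkerSample]:
    """Blood samples on a fixed grid (default every 20 min).

    Values interpolate linearly between per-phase-end targets, each target
    being reached at the last grid time inside its phase; BASELINE is flat
    at its target.  With the default targets the last SEVERE sample sits
    below pH 7.00, mirroring the protocol's stopping rule.
    """
    total = schedule.total_duration_s
    step = config.biomarker_interval_s
    grid = np.arange(0.0, total + 1e-9, step)
    anchor_t = [0.0]
    anchor_v = [np.asarray(config.biomarker_targets["BASELINE"], float)]
    for p in schedule.phases:
        in_phase = grid[(grid >= p.start) & (grid <= p.end)]
        if in_phase.size == 0:
            continue
        ta = float(in_phase.max())
        if ta <= anchor_t[-1]:
            continue
        anchor_t.append(ta)
        anchor_v.append(np.asarray(
            config.biomarker_targets.get(p.name, config.biomarker_targets["BASELINE"]),
            float,
        ))
    anchor_v_arr = np.vstack(anchor_v)
    out = []
    for t in grid:
        vals = [
            float(np.interp(t, anchor_t, anchor_v_arr[:, k])) for k in range(3)
        ]
        out.append(BiomarkerSample(float(t), vals[0], vals[1], vals[2]))
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: SyntheticConfig) -> list[SubjectRecord]:
    """Simulate ``n_subjects`` animals from one seed (see module docstring)."""
    schedule = generate_protocol_schedule(config)
    biomarkers = generate_biomarker_trajectory(config, schedule)
    root = np.random.SeedSequence(config.seed)
    out = []
    for i, child in enumerate(root.spawn(config.n_subjects)):
        tau_ss, noise_ss, art_ss = child.spawn(3)
        tau_stim, tau_rec = _draw_taus(config, np.random.default_rng(tau_ss))
        sid = f"subject-{i + 1:02d}"
        series = generate_frr_series(
            config, schedule, sid, tau_stim, tau_rec,
            rng=np.random.default_rng(noise_ss),
        )
        series = inject_artifacts(series, config, np.random.default_rng(art_ss))
        out.append(
            SubjectRecord(sid, series, schedule, biomarkers, tau_stim, tau_rec)
        )
    return out
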