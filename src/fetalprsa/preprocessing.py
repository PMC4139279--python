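"""Artifact reconstruction, anchor-exclusion marking and beat-quality QC.

The cleaning rules implemented here are the ones used for fetal RR series
from chronically instrumented sheep, where beat misdetections appear as
spuriously long RR intervals:

* every maximal run of intervals longer than ``threshold_ms`` (default
  1500 ms, i.e. below 40 bpm) is treated as one gap and replaced by an
  equivalent number of beats, the number obtained by dividing the gap
  length by the median of the 20 nearby valid intervals;
* reconstructed beats, and beats exceeding their predecessor by more than
  20 %, are barred from serving as PRSA anchor points (their values still
  enter moving averages and PRSA windows);
* a recording window qualifies for analysis only when original (non
  reconstructed) beats cover more than 90 % of it.
"""

from __future__ import annotations

import numpy as np

from .io_formats import DegenerateInputError, RRSeries, ValidationError

__all__ = [
    "ARTIFACT_THRESHOLD_MS",
    "JUMP_FRACTION",
    "QUALITY_MIN",
    "reconstruct_artifacts",
    "mark_anchor_exclusions",
    "beat_quality_fraction",
]

ARTIFACT_THRESHOLD_MS = 1500.0
JUMP_FRACTION = 0.20
QUALITY_MIN = 0.90

#: Valid neighbours used for the reconstruction median: 10 before + 10 after.
_NEIGHBORS_PER_SIDE = 10


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges ``[a, b)``."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def reconstruct_artifacts(
    series: RRSeries, threshold_ms: float = ARTIFACT_THRESHOLD_MS
) -> RRSeries:
    """Replace artifact gaps by an equivalent number of reconstructed beats.

    Each maximal run of intervals with ``rr > threshold_ms`` is merged into a
    single gap of duration ``G`` (the sum of the run's intervals).  The gap
    is filled with ``n = round(G / m)`` beats (at least one), where ``m`` is
    the median of up to 10 preceding and 10 following valid intervals
    (original beats not part of any artifact run; fewer near the record
    edges).  Every inserted beat has ``rr = G / n`` so total time is
    conserved; inserted beats are flagged ``reconstructed`` and
    anchor-ineligible.  The operation is idempotent.

    Raises
    ------
    DegenerateInputError
        If the whole series is artifact, or a gap has no valid neighbour.
    ValidationError
        If the series is not contiguous (has segment boundaries).
    """
    if series.segment_boundaries.size:
        raise ValidationError("artifact reconstruction requires a contiguous series")
    rr = series.rr
    artifact = rr > threshold_ms
    if not artifact.any():
        return series.copy()
    if artifact.all():
        raise DegenerateInputError("series consists entirely of artifacts")
    # valid == usable for the neighbourhood median
    valid = ~artifact & ~series.reconstructed
    if not valid.any():
        raise DegenerateInputError("no valid beats available for reconstruction")

    out_t: list[np.ndarray] = []
    out_rr: list[np.ndarray] = []
    out_rec: list[np.ndarray] = []
    out_elig: list[np.ndarray] = []
    pos = 0
    for a, b in _runs(artifact):
        keep = slice(pos, a)
        out_t.append(series.onset_time[keep])
        out_rr.append(rr[keep])
        out_rec.append(series.reconstructed[keep])
        out_elig.append(series.anchor_eligible[keep])

        gap = float(rr[a:b].sum())
        before = np.flatnonzero(valid[:a])[-_NEIGHBORS_PER_SIDE:]
        after = np.flatnonzero(valid[b:])[:_NEIGHBORS_PER_SIDE] + b
        neighbors = rr[np.concatenate((before, after))]
        if neighbors.size == 0:
            raise DegenerateInputError(
                f"gap at beat index {a} has no valid neighbour"
            )
        m = float(np.median(neighbors))
        n = max(1, int(np.floor(gap / m + 0.5)))  # round, ties away from zero
        gap_start = series.onset_time[a] - rr[a] / 1000.0
        step = gap / n
        out_t.append(gap_start + step * np.arange(1, n + 1) / 1000.0)
        out_rr.append(np.full(n, step))
        out_rec.append(np.ones(n, bool))
        out_elig.append(np.zeros(n, bool))
        pos = b
    keep = slice(pos, series.n_beats)
    out_t.append(series.onset_time[keep])
    out_rr.append(rr[keep])
    out_rec.append(series.reconstructed[keep])
    out_elig.append(series.anchor_eligible[keep])

    return RRSeries(
        np.concatenate(out_t),
        np.concatenate(out_rr),
        np.concatenate(out_rec),
        np.concatenate(out_elig),
        series.subject_id,
    )


def mark_anchor_exclusions(
    series: RRSeries, jump_fraction: float = JUMP_FRACTION
) -> RRSeries:
    """Recompute anchor eligibility from RR values and provenance.

    A beat is anchor-ineligible iff any of:

    * it exceeds the immediately preceding interval by more than
      ``jump_fraction`` (one-sided rule: only increases disqualify);
    * it is a reconstructed beat;
    * it is the first beat of its segment (no predecessor to compare with).

    The result is a pure function of ``(rr, provenance, segment layout)``;
    pre-existing eligibility flags are overwritten.
    """
    out = series.copy()
    n = series.n_beats
    eligible = np.ones(n, bool)
    if n == 0:
        out.anchor_eligible = eligible
        return out
    rr = series.rr
    jump = np.zeros(n, bool)
    jump[1:] = rr[1:] > (1.0 + jump_fraction) * rr[:-1]
    eligible &= ~jump
    eligible[series.segment_starts()] = False
    eligible &= ~series.reconstructed
    out.anchor_eligible = eligible
    return out


def beat_quality_fraction(
    series: RRSeries, window: tuple[float, float]
) -> float:
    """Fraction of a time window covered by original (non-reconstructed) beats.

    Each beat covers ``[onset - rr/1000, onset]``.  The subject-selection
    rule of the analysis keeps a recording only when this fraction exceeds
    0.9 (strictly) in the MODERATE and SEVERE phases.
    """
    t0, t1 = window
    if not t1 > t0:
        raise DegenerateInputError("empty quality window")
    starts = series.onset_time - series.rr / 1000.0
    ends = series.onset_time
    lo = np.maximum(starts, t0)
    hi = np.minimum(ends, t1)
    cover = np.where(~series.reconstructed, np.clip(hi - lo, 0.0, None), 0.0)
    return float(cover.sum() / (t1 - t0))
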