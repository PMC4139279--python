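"""Domain containers and CSV I/O for fetal RR-interval analysis.

The package works on three kinds of tables, all plain CSV with a header
row, comma separator, ``.`` decimal point, times in seconds from the start
of the recording and RR intervals in milliseconds:

``RR series``
    columns ``time_s, rr_ms`` plus optional ``provenance``
    (``original``/``reconstructed``), ``anchor_eligible`` (0/1) and
    ``segment`` (integer id for concatenated series).
``Occlusion schedule``
    columns ``kind, start_s, end_s, phase`` where ``kind`` is ``phase``
    (protocol-phase extent) or ``occlusion`` (one cord-occlusion event).
``Biomarkers``
    columns ``time_s, pH, lactate_meq_l, base_deficit_meq_l``.

``rr_ms`` of beat *i* is the interval *ending* at ``time_s`` of beat *i*,
so inside a contiguous segment ``time_s[i+1] - time_s[i] ==
rr_ms[i+1] / 1000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_ORDER",
    "UCO_PHASES",
    "FetalPRSAError",
    "MalformedInputError",
    "ValidationError",
    "DegenerateInputError",
    "FitFailureError",
    "RRSeries",
    "OcclusionEvent",
    "ProtocolPhase",
    "OcclusionSchedule",
    "BiomarkerSample",
    "read_rr_series",
    "write_rr_series",
    "read_occlusion_schedule",
    "write_occlusion_schedule",
    "read_biomarkers",
    "write_biomarkers",
    "write_capacity_table",
    "read_capacity_table",
]

#: Protocol phases in chronological order.
PHASE_ORDER = ("BASELINE", "MILD", "MODERATE", "SEVERE", "RECOVERY")

#: Phases during which umbilical-cord occlusions are applied.
UCO_PHASES = ("MILD", "MODERATE", "SEVERE")

#: Tolerance (ms) for the beat-time/RR consistency invariant.
TIME_RR_TOL_MS = 1.0


class FetalPRSAError(Exception):
    """Base class for all errors raised by this package."""


class MalformedInputError(FetalPRSAError):
    """An input file or table violates its declared schema or invariants."""


class ValidationError(FetalPRSAError):
    """A domain object violates one of its invariants."""


class DegenerateInputError(FetalPRSAError):
    """The input is formally valid but the requested statistic is undefined."""


class FitFailureError(FetalPRSAError):
    """A nonlinear fit did not converge; carries diagnostics in ``args``."""


# ---------------------------------------------------------------------------
# RR series
# ---------------------------------------------------------------------------


@dataclass
class RRSeries:
    """An ordered series of beats with per-beat provenance and anchor flags.

    Parameters
    ----------
    onset_time : ndarray of float
        Beat onset times in seconds from the start of the recording.
    rr : ndarray of float
        RR interval in milliseconds ending at each onset time.
    reconstructed : ndarray of bool
        True for beats inserted by artifact reconstruction.
    anchor_eligible : ndarray of bool
        False for beats that must never serve as PRSA anchor points.
    subject_id : str
        Identifier of the animal/recording.
    segment_boundaries : ndarray of int
        Indices of the first beat of every segment after the first, for
        series assembled by concatenating stable intervals.  Empty for a
        contiguous recording.
    """

    onset_time: np.ndarray
    rr: np.ndarray
    reconstructed: np.ndarray
    anchor_eligible: np.ndarray
    subject_id: str = ""
    segment_boundaries: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.onset_time = np.asarray(self.onset_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.reconstructed = np.asarray(self.reconstructed, dtype=bool)
        self.anchor_eligible = np.asarray(self.anchor_eligible, dtype=bool)
        self.segment_boundaries = np.asarray(self.segment_boundaries, dtype=np.int64)

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_rr(
        cls,
        rr_ms: Sequence[float],
        start_time_s: float = 0.0,
        subject_id: str = "",
    ) -> "RRSeries":
        """Build a contiguous series from RR values alone.

        Onset times are the cumulative sum of the intervals, offset so the
        first beat falls at ``start_time_s + rr[0]/1000``.
        """
        rr = np.asarray(rr_ms, dtype=float)
        t = start_time_s + np.cumsum(rr) / 1000.0
        n = rr.size
        return cls(t, rr, np.zeros(n, bool), np.ones(n, bool), subject_id)

    # -- basic introspection -------------------------------------------------

    @property
    def n_beats(self) -> int:
        return int(self.rr.size)

    @property
    def duration_s(self) -> float:
        """Total time covered by the beats (sum of RR intervals)."""
        return float(self.rr.sum() / 1000.0)

    def segment_starts(self) -> np.ndarray:
        """Start index of every segment, including index 0."""
        return np.concatenate(([0], self.segment_boundaries)).astype(np.int64)

    def segment_slices(self) -> list[slice]:
        starts = self.segment_starts()
        stops = np.concatenate((self.segment_boundaries, [self.n_beats]))
        return [slice(int(a), int(b)) for a, b in zip(starts, stops)]

    def segment_ids(self) -> np.ndarray:
        """Per-beat integer segment id (0-based)."""
        ids = np.zeros(self.n_beats, dtype=np.int64)
        for b in self.segment_boundaries:
            ids[b:] += 1
        return ids

    def copy(self) -> "RRSeries":
        return RRSeries(
            self.onset_time.copy(),
            self.rr.copy(),
            self.reconstructed.copy(),
            self.anchor_eligible.copy(),
            self.subject_id,
            self.segment_boundaries.copy(),
        )

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any series invariant fails."""
        n = self.n_beats
        if not (
            self.onset_time.size == n
            and self.reconstructed.size == n
            and self.anchor_eligible.size == n
        ):
            raise ValidationError("field lengths disagree")
        if n == 0:
            return
        if np.any(self.rr <= 0):
            i = int(np.flatnonzero(self.rr <= 0)[0])
            raise ValidationError(f"non-positive rr at beat index {i}")
        if self.segment_boundaries.size:
            b = self.segment_boundaries
            if np.any(b <= 0) or np.any(b >= n) or np.any(np.diff(b) <= 0):
                raise ValidationError("segment boundaries out of order or range")
        for seg in self.segment_slices():
            t = self.onset_time[seg]
            if np.any(np.diff(t) <= 0):
                i = seg.start + int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
                raise ValidationError(
                    f"onset times not strictly increasing at beat index {i}"
                )
            dt_ms = np.diff(t) * 1000.0
            rr_next = self.rr[seg][1:]
            bad = np.abs(dt_ms - rr_next) > TIME_RR_TOL_MS
            if np.any(bad):
                i = seg.start + int(np.flatnonzero(bad)[0]) + 1
                raise ValidationError(
                    f"onset-time step and rr disagree by >1 ms at beat index {i}"
                )
        if np.any(self.reconstructed & self.anchor_eligible):
            raise ValidationError("reconstructed beat marked anchor-eligible")

    # -- selection -----------------------------------------------------------

    def slice_time_window(self, start_s: float, end_s: float) -> "RRSeries":
        """Beats whose onset time lies in ``[start_s, end_s]``.

        Segment boundaries falling inside the window are carried over
        (re-indexed); flags are preserved.
        """
        keep = (self.onset_time >= start_s) & (self.onset_time <= end_s)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            return RRSeries(
                np.empty(0), np.empty(0), np.empty(0, bool), np.empty(0, bool),
                self.subject_id,
            )
        lo = idx[0]
        b = self.segment_boundaries
        b = b[(b > lo) & (b <= idx[-1])] - lo
        return RRSeries(
            self.onset_time[keep],
            self.rr[keep],
            self.reconstructed[keep],
            self.anchor_eligible[keep],
            self.subject_id,
            b,
        )


# ---------------------------------------------------------------------------
# Occlusion schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OcclusionEvent:
    start: float
    end: float
    phase: str


@dataclass(frozen=True)
class ProtocolPhase:
    name: str
    start: float
    end: float


@dataclass
class OcclusionSchedule:
    """Timed cord-occlusion events plus the protocol-phase extents."""

    events: list[OcclusionEvent]
    phases: list[ProtocolPhase]

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.start)
        order = {name: i for i, name in enumerate(PHASE_ORDER)}
        self.phases = sorted(self.phases, key=lambda p: p.start)
        for p in self.phases:
            if p.name not in order:
                raise ValidationError(f"unknown phase label {p.name!r}")

    def validate(self) -> None:
        for p in self.phases:
            if not p.end > p.start:
                raise ValidationError(f"phase {p.name} has non-positive length")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start < a.end:
                raise ValidationError(f"phases {a.name} and {b.name} overlap")
        order = {name: i for i, name in enumerate(PHASE_ORDER)}
        ranks = [order[p.name] for p in self.phases]
        if sorted(ranks) != ranks:
            raise ValidationError("phases out of protocol order")
        for a, b in zip(self.events, self.events[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"events starting at {a.start} and {b.start} overlap"
                )
        for e in self.events:
            if not e.end > e.start:
                raise ValidationError(f"event at {e.start} has non-positive length")
            holders = [
                p for p in self.phases if p.start <= e.start and e.end <= p.end
            ]
            if len(holders) != 1:
                raise ValidationError(
                    f"event at {e.start} does not lie within exactly one phase"
                )
            if holders[0].name != e.phase:
                raise ValidationError(
                    f"event at {e.start} labeled {e.phase} but lies in "
                    f"{holders[0].name}"
                )

    def phase(self, name: str) -> ProtocolPhase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(name)

    def has_phase(self, name: str) -> bool:
        return any(p.name == name for p in self.phases)

    def events_in_phase(self, name: str) -> list[OcclusionEvent]:
        return [e for e in self.events if e.phase == name]

    @property
    def total_duration_s(self) -> float:
        return max(p.end for p in self.phases) if self.phases else 0.0


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiomarkerSample:
    """One fetal blood sample: time, pH, lactate and base deficit."""

    time: float
    ph: float
    lactate: float
    base_deficit: float

    def validate(self) -> None:
        if not 6.5 < self.ph < 7.8:
            raise ValidationError(f"pH {self.ph} outside (6.5, 7.8)")
        if self.lactate < 0:
            raise ValidationError(f"negative lactate {self.lactate}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MalformedInputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise MalformedInputError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MalformedInputError(f"{path}: missing columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: str | Path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(np.isnan(vals))
    if bad.size:
        raise MalformedInputError(
            f"{path}: non-numeric value in column {col!r} at data row {bad[0] + 1}"
        )
    return vals


def read_rr_series(path: str | Path, subject_id: str | None = None) -> RRSeries:
    """Read an RR-series CSV (``time_s, rr_ms`` plus optional flag columns).

    Absent flag columns default to ``original`` provenance and anchor
    eligibility.  Row numbers in error messages are 1-based data rows
    (the header is row 0).
    """
    df = _read_csv(path, ["time_s", "rr_ms"])
    t = _numeric(df, "time_s", path)
    rr = _numeric(df, "rr_ms", path)
    n = len(df)
    if "provenance" in df.columns:
        labels = df["provenance"].astype(str).str.strip()
        unknown = ~labels.isin(["original", "reconstructed"])
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
            raise MalformedInputError(
                f"{path}: unknown provenance label at data row {row}"
            )
        recon = (labels == "reconstructed").to_numpy()
    else:
        recon = np.zeros(n, bool)
    if "anchor_eligible" in df.columns:
        eligible = df["anchor_eligible"].astype(int).to_numpy().astype(bool)
    else:
        eligible = ~recon
    if "segment" in df.columns:
        seg = _numeric(df, "segment", path).astype(np.int64)
        if np.any(np.diff(seg) < 0):
            row = int(np.flatnonzero(np.diff(seg) < 0)[0]) + 2
            raise MalformedInputError(
                f"{path}: segment ids decrease at data row {row}"
            )
        boundaries = np.flatnonzero(np.diff(seg) > 0) + 1
    else:
        boundaries = np.empty(0, dtype=np.int64)
    series = RRSeries(
        t, rr, recon, eligible,
        subject_id if subject_id is not None else path_stem(path),
        boundaries,
    )
    try:
        series.validate()
    except ValidationError as exc:
        msg = str(exc)
        # translate beat index to 1-based data row for the caller
        if "beat index" in msg:
            i = int(msg.rsplit(" ", 1)[1])
            raise MalformedInputError(
                f"{path}: {msg.rsplit(' at ', 1)[0]} at data row {i + 1}"
            ) from exc
        raise MalformedInputError(f"{path}: {msg}") from exc
    return series


def path_stem(path: str | Path) -> str:
    return Path(path).stem


def write_rr_series(series: RRSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.onset_time,
            "rr_ms": series.rr,
            "provenance": np.where(series.reconstructed, "reconstructed", "original"),
            "anchor_eligible": series.anchor_eligible.astype(int),
            "segment": series.segment_ids(),
        }
    )
    df.to_csv(path, index=False)


def read_occlusion_schedule(
    path: str | Path, phase_path: str | Path | None = None
) -> OcclusionSchedule:
    """Read an occlusion schedule.

    Phase extents come either from embedded rows (``kind == "phase"``) or
    from a companion table at ``phase_path`` with columns
    ``phase, start_s, end_s``.
    """
    df = _read_csv(path, ["start_s", "end_s", "phase"])
    if "kind" not in df.columns:
        df = df.assign(kind="occlusion")
    kinds = df["kind"].astype(str).str.strip()
    unknown = ~kinds.isin(["occlusion", "phase"])
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
        raise MalformedInputError(f"{path}: unknown kind at data row {row}")
    start = _numeric(df, "start_s", path)
    end = _numeric(df, "end_s", path)
    labels = df["phase"].astype(str).str.strip()
    bad = ~labels.isin(PHASE_ORDER)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise MalformedInputError(f"{path}: unknown phase label at data row {row}")
    events = [
        OcclusionEvent(s, e, lab)
        for s, e, lab, k in zip(start, end, labels, kinds)
        if k == "occlusion"
    ]
    phases = [
        ProtocolPhase(lab, s, e)
        for s, e, lab, k in zip(start, end, labels, kinds)
        if k == "phase"
    ]
    if phase_path is not None:
        pdf = _read_csv(phase_path, ["phase", "start_s", "end_s"])
        phases += [
            ProtocolPhase(str(r["phase"]).strip(), float(r["start_s"]), float(r["end_s"]))
            for _, r in pdf.iterrows()
        ]
    if not phases:
        raise MalformedInputError(
            f"{path}: no phase rows and no companion phase table given"
        )
    sched = OcclusionSchedule(events, phases)
    sched.validate()
    return sched


def write_occlusion_schedule(schedule: OcclusionSchedule, path: str | Path) -> None:
    rows = [("phase", p.start, p.end, p.name) for p in schedule.phases]
    rows += [("occlusion", e.start, e.end, e.phase) for e in schedule.events]
    pd.DataFrame(rows, columns=["kind", "start_s", "end_s", "phase"]).to_csv(
        path, index=False
    )


def read_biomarkers(path: str | Path) -> list[BiomarkerSample]:
    df = _read_csv(path, ["time_s", "pH", "lactate_meq_l", "base_deficit_meq_l"])
    t = _numeric(df, "time_s", path)
    ph = _numeric(df, "pH", path)
    lac = _numeric(df, "lactate_meq_l", path)
    bd = _numeric(df, "base_deficit_meq_l", path)
    samples = [BiomarkerSample(*vals) for vals in zip(t, ph, lac, bd)]
    for i, s in enumerate(samples):
        try:
            s.validate()
        except ValidationError as exc:
            raise MalformedInputError(f"{path}: data row {i + 1}: {exc}") from exc
    if np.any(np.diff(t) <= 0):
        row = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise MalformedInputError(
            f"{path}: sample times not increasing at data row {row}"
        )
    return samples


def write_biomarkers(samples: Sequence[BiomarkerSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": [s.time for s in samples],
            "pH": [s.ph for s in samples],
            "lactate_meq_l": [s.lactate for s in samples],
            "base_deficit_meq_l": [s.base_deficit for s in samples],
        }
    ).to_csv(path, index=False)


CAPACITY_COLUMNS = [
    "subject",
    "phase",
    "variant",
    "T",
    "s",
    "AC_abs_ms",
    "DC_abs_ms",
    "n_anchors_dec",
    "n_anchors_acc",
    "reliable_dec",
    "reliable_acc",
]


def write_capacity_table(results: Sequence, path: str | Path) -> None:
    """Write AC/DC results, one row per (subject, phase, variant, T).

    ``results`` are :class:`~fetalprsa.prsa.CapacityResult` records.
    Duplicate keys are rejected.
    """
    if not results:
        raise ValidationError("empty capacity-result list")
    rows = [
        (
            r.subject,
            r.phase,
            r.variant,
            r.T,
            r.s,
            r.ac_abs,
            r.dc_abs,
            r.n_anchors_dec,
            r.n_anchors_acc,
            int(r.reliable_dec),
            int(r.reliable_acc),
        )
        for r in results
    ]
    keys = [(r.subject, r.phase, r.variant, r.T) for r in results]
    if len(set(keys)) != len(keys):
        seen: set = set()
        dup = next(k for k in keys if k in seen or seen.add(k))
        raise ValidationError(f"duplicate capacity-table key {dup}")
    pd.DataFrame(rows, columns=CAPACITY_COLUMNS).to_csv(path, index=False)


def read_capacity_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, CAPACITY_COLUMNS[:9])
    return df
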