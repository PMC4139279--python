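"""Phase-rectified signal averaging (PRSA) and AC/DC capacity.

PRSA extracts quasi-periodic structure from a nonstationary beat series by
averaging windows aligned on *anchor points*.  A beat ``i`` is a
deceleration anchor when the mean of the ``T`` intervals starting at ``i``
exceeds the mean of the ``T`` intervals before it,

    mean(rr[i .. i+T-1]) > mean(rr[i-T .. i-1]),

and an acceleration anchor with ``<`` (strict inequalities; ties are never
anchors).  Averaging the ``2L``-beat windows centred on the anchors gives
the PRSA series ``X(k)``, ``k = -L .. L-1`` with the anchor at ``k = 0``.
The deceleration/acceleration capacity is the Haar-wavelet coefficient of
``X`` at scale ``s`` and the anchor location,

    capacity = ( sum_{k=0}^{s-1} X(k) - sum_{k=-s}^{-1} X(k) ) / (2 s),

which for ``s = 2`` reduces to the familiar adult-cardiology expression
``(X(0) + X(1) - X(-1) - X(-2)) / 4``.  Deceleration capacity is positive
and acceleration capacity negative; results are reported as absolute
values in ms.

``T`` acts as a low-pass filter on the oscillations that can select
anchors: the 3 dB pass-band edge is approximately ``1 / (2 T rr)`` Hz for
a mean interval ``rr`` in seconds.  In this package the wavelet scale is
tied to the filter length, ``s = T``, unless set explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import DegenerateInputError, RRSeries, ValidationError

__all__ = [
    "PRSAParams",
    "PRSACurve",
    "CapacityResult",
    "select_anchor_points",
    "compute_prsa_curve",
    "compute_capacity",
    "capacity_spectrum",
    "t_to_cutoff_frequency",
]

DEFAULT_L = 50
DEFAULT_MIN_ANCHORS = 150


@dataclass(frozen=True)
class PRSAParams:
    """Parameters of one PRSA computation.

    ``T``: moving-average length (beats) for anchor detection;
    ``L``: window half-length (beats); ``s``: Haar scale (defaults to ``T``);
    ``mode``: ``"deceleration"`` or ``"acceleration"``;
    ``min_anchors``: reliability floor (strictly more anchors required);
    ``allow_cross_boundary``: let averages/windows span concatenation
    junctions (used for stable series at large ``T``);
    ``apply_eligibility``: honour per-beat anchor-eligibility flags.
    """

    T: int = 1
    L: int = DEFAULT_L
    s: int | None = None
    mode: str = "deceleration"
    min_anchors: int = DEFAULT_MIN_ANCHORS
    allow_cross_boundary: bool = False
    apply_eligibility: bool = True

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValidationError("T must be >= 1")
        if self.min_anchors < 1:
            raise ValidationError("min_anchors must be >= 1")
        if not 1 <= self.scale <= self.L:
            raise ValidationError("scale must satisfy 1 <= s <= L")
        if self.mode not in ("deceleration", "acceleration"):
            raise ValidationError(f"unknown mode {self.mode!r}")

    @property
    def scale(self) -> int:
        return self.T if self.s is None else self.s


@dataclass
class PRSACurve:
    """Averaged phase-rectified series ``X(k)``, ``k = -L .. L-1``."""

    values: np.ndarray
    n_anchors: int
    params: PRSAParams

    def x(self, k: int) -> float:
        """Value at signed lag ``k`` (anchor at ``k = 0``)."""
        return float(self.values[k + self.params.L])


@dataclass
class CapacityResult:
    """|AC| and |DC| (ms) for one (subject, phase, variant, T)."""

    subject: str
    phase: str
    variant: str
    T: int
    s: int
    ac_abs: float
    dc_abs: float
    n_anchors_dec: int
    n_anchors_acc: int
    reliable_dec: bool
    reliable_acc: bool


# ---------------------------------------------------------------------------
# Anchor selection
# ---------------------------------------------------------------------------


def _margins_ok(series: RRSeries, margin: int, allow_cross: bool) -> np.ndarray:
    """Boolean mask of indices whose +-margin neighbourhood stays in-segment."""
    n = series.n_beats
    ok = np.zeros(n, bool)
    if allow_cross:
        if n >= 2 * margin:
            ok[margin : n - margin + 1] = True
        return ok
    for seg in series.segment_slices():
        a, b = seg.start, seg.stop
        lo, hi = a + margin, b - margin  # need i-margin >= a and i+margin <= b
        if hi >= lo:
            ok[lo : hi + 1] = True
    return ok


def select_anchor_points(series: RRSeries, params: PRSAParams) -> np.ndarray:
    """Indices of anchor beats, ascending.

    A candidate needs both ``T``-beat averages and the full ``±L`` window
    inside one contiguous segment (inside the record when
    ``allow_cross_boundary``).  Ineligible beats are never anchors but
    their RR values still enter the averages.
    """
    n = series.n_beats
    T = params.T
    margin = max(T, params.L)
    if n < 2 * margin + 1:
        raise DegenerateInputError(
            f"series of {n} beats shorter than 2*max(T, L)+1 = {2 * margin + 1}"
        )
    rr = series.rr
    c = np.concatenate(([0.0], np.cumsum(rr)))
    idx = np.arange(margin, n - margin + 1)
    fwd = (c[idx + T] - c[idx]) / T          # mean rr[i .. i+T-1]
    bwd = (c[idx] - c[idx - T]) / T          # mean rr[i-T .. i-1]
    if params.mode == "deceleration":
        hit = fwd > bwd
    else:
        hit = fwd < bwd
    ok = _margins_ok(series, margin, params.allow_cross_boundary)[idx]
    if params.apply_eligibility:
        ok &= series.anchor_eligible[idx]
    return idx[hit & ok]


# ---------------------------------------------------------------------------
# Curve and capacity
# ---------------------------------------------------------------------------


def compute_prsa_curve(
    series: RRSeries, anchors: Sequence[int] | np.ndarray, params: PRSAParams
) -> PRSACurve:
    """Average the ``2L`` windows centred on the anchors."""
    anchors = np.asarray(anchors, dtype=np.int64)
    if anchors.size == 0:
        raise DegenerateInputError("no anchor points")
    L = params.L
    if anchors.min() < L or anchors.max() > series.n_beats - L:
        raise ValidationError("anchor without a full ±L window")
    offsets = np.arange(-L, L)
    X = series.rr[anchors[:, None] + offsets[None, :]].mean(axis=0)
    return PRSACurve(X, int(anchors.size), params)


def compute_capacity(curve: PRSACurve) -> float:
    """Signed Haar-wavelet capacity (ms) of a PRSA curve at its anchor."""
    s = curve.params.scale
    L = curve.params.L
    X = curve.values
    return float((X[L : L + s].sum() - X[L - s : L].sum()) / (2.0 * s))


def _capacity_streaming(series: RRSeries, anchors: np.ndarray, s: int) -> float:
    """Capacity without materializing windows (cumulative-sum form)."""
    c = np.concatenate(([0.0], np.cumsum(series.rr)))
    a = anchors
    fwd = c[a + s] - c[a]
    bwd = c[a] - c[a - s]
    return float((fwd - bwd).mean() / (2.0 * s))


def capacity_spectrum(
    series: RRSeries,
    T_range: Iterable[int] = range(1, 51),
    L: int = DEFAULT_L,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    *,
    subject: str = "",
    phase: str = "",
    variant: str = "entire",
    allow_cross_boundary: bool = False,
) -> list[CapacityResult]:
    """|AC| and |DC| across a spectrum of ``T`` values with ``s = T``.

    One result per ``T``.  Entries whose anchor count does not exceed
    ``min_anchors`` are flagged unreliable rather than dropped; a ``T``
    with no anchors at all yields NaN capacity with ``n_anchors = 0``.
    """
    results = []
    for T in T_range:
        caps: dict[str, float] = {}
        counts: dict[str, int] = {}
        for mode in ("deceleration", "acceleration"):
            params = PRSAParams(
                T=T, L=L, s=T, mode=mode, min_anchors=min_anchors,
                allow_cross_boundary=allow_cross_boundary,
            )
            anchors = select_anchor_points(series, params)
            counts[mode] = int(anchors.size)
            if anchors.size:
                caps[mode] = abs(_capacity_streaming(series, anchors, T))
            else:
                caps[mode] = float("nan")
        results.append(
            CapacityResult(
                subject=subject,
                phase=phase,
                variant=variant,
                T=T,
                s=T,
                ac_abs=caps["acceleration"],
                dc_abs=caps["deceleration"],
                n_anchors_dec=counts["deceleration"],
                n_anchors_acc=counts["acceleration"],
                reliable_dec=counts["deceleration"] > min_anchors,
                reliable_acc=counts["acceleration"] > min_anchors,
            )
        )
    return results


def t_to_cutoff_frequency(T: int, mean_rr_s: float) -> float:
    """Approximate 3 dB cutoff (Hz) of the ``T``-beat anchor filter."""
    if T < 1 or mean_rr_s <= 0:
        raise ValidationError("need T >= 1 and mean_rr_s > 0")
    return 1.0 / (2.0 * T * mean_rr_s)
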