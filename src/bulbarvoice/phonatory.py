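"""Glottal-cycle estimation and the 15 phonatory-subsystem features.

Pitch is estimated per frame with the normalized-autocorrelation method
(autocorrelation peak inside the configured period range, parabolic
interpolation for sub-sample precision); the per-frame harmonics-to-noise
ratio is ``10*log10(r/(1-r))`` with ``r`` the normalized autocorrelation at
the fundamental period.  Cycle marking is pitch-guided peak picking: each
successive waveform peak is searched within [0.8, 1.25] times the current
period after the previous mark.

Feature summary (15 values): jitter absolute/relative/rap/ppq5, shimmer
dB/relative/apq3/apq5/apq11, HNR mean/SD, pitch mean/SD/min/max.

Index conventions: the perturbation-quotient measures (rap, ppq5, apqP)
average over every cycle whose full window fits inside the cycle table,
dividing by the number of such terms (the standard P-point convention).
The literal three-term window for every P is available via
``literal_window=True`` in :func:`shimmer_features`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientCyclesError, UnvoicedSegmentError
from .preprocess import Segment

__all__ = [
    "PitchTrack",
    "CycleMarks",
    "PHONATORY_FEATURE_NAMES",
    "estimate_pitch_track",
    "mark_cycles",
    "jitter_features",
    "shimmer_features",
    "hnr_and_pitch_stats",
    "extract_phonatory_features",
]

PHONATORY_FEATURE_NAMES = (
    "jitter_absolute", "jitter_relative", "jitter_rap", "jitter_ppq5",
    "shimmer_dB", "shimmer_relative", "shimmer_apq3", "shimmer_apq5",
    "shimmer_apq11",
    "hnr_mean", "hnr_sd",
    "pitch_mean", "pitch_sd", "pitch_min", "pitch_max",
)

HNR_CEILING_DB = 60.0
_R_CLIP = 1.0 - 1e-6


@dataclass
class PitchTrack:
    times: np.ndarray     # frame centres, s
    f0: np.ndarray        # Hz; NaN on unvoiced frames
    hnr: np.ndarray       # dB; NaN on unvoiced frames
    voiced: np.ndarray    # bool mask

    @property
    def n_voiced(self) -> int:
        return int(self.voiced.sum())


@dataclass
class CycleMarks:
    T: np.ndarray   # cycle durations, s
    A: np.ndarray   # peak-to-peak amplitudes, dimensionless

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=np.float64)
        self.A = np.asarray(self.A, dtype=np.float64)

    @property
    def n(self) -> int:
        return len(self.T)


def _parabolic(y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete peak at index i by fitting a parabola to its 3 points."""
    if i <= 0 or i >= len(y) - 1:
        return float(i), float(y[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0 or not np.isfinite(denom):
        return float(i), float(b)
    d = 0.5 * (a - c) / denom
    d = float(np.clip(d, -0.5, 0.5))
    return i + d, float(b - 0.25 * (a - c) * d)


def _hnr_from_r(r: float) -> float:
    r = min(max(r, 0.0), _R_CLIP)
    if r >= _R_CLIP:
        return HNR_CEILING_DB
    return float(10.0 * np.log10(r / (1.0 - r)))


def estimate_pitch_track(
    seg: Segment,
    floor: float = 75.0,
    ceiling: float = 600.0,
    frame_step: float = 0.010,
    voicing_threshold: float = 0.45,
) -> PitchTrack:
    """Frame-wise f0 and HNR from the normalized autocorrelation peak."""
    x = seg.samples
    rate = seg.rate
    win = int(round(max(0.040, 3.0 / floor) * rate))
    step = max(1, int(round(frame_step * rate)))
    lag_lo = max(2, int(np.floor(rate / ceiling)))
    lag_hi = int(np.ceil(rate / floor))
    if win + lag_lo >= len(x):
        win = len(x) - lag_hi - 1
    if win < 3 * lag_lo or len(x) < win + lag_hi:
        raise UnvoicedSegmentError(
            f"segment of {len(x)} samples too short for pitch analysis "
            f"(window {win}, max lag {lag_hi})"
        )

    starts = np.arange(0, len(x) - win - lag_hi + 1, step)
    if len(starts) == 0:
        starts = np.array([0])
    times, f0s, hnrs, voiced = [], [], [], []
    diags = []
    for s in starts:
        frame = x[s : s + win + lag_hi]
        frame = frame - frame.mean()
        # normalized cross-correlation between the window and its lagged copy
        e0 = float(np.dot(frame[:win], frame[:win]))
        r = np.empty(lag_hi + 1)
        r[:] = -np.inf
        for lag in range(lag_lo, lag_hi + 1):
            a = frame[:win]
            b = frame[lag : lag + win]
            eb = float(np.dot(b, b))
            if e0 <= 0 or eb <= 0:
                r[lag] = 0.0
            else:
                r[lag] = float(np.dot(a, b)) / np.sqrt(e0 * eb)
        i = int(np.argmax(r[lag_lo : lag_hi + 1])) + lag_lo
        lag_star, r_star = _parabolic(r, i)
        times.append((s + win / 2.0) / rate)
        if r_star >= voicing_threshold and lag_star > 0:
            f0s.append(rate / lag_star)
            hnrs.append(_hnr_from_r(r_star))
            voiced.append(True)
        else:
            f0s.append(np.nan)
            hnrs.append(np.nan)
            voiced.append(False)
        diags.append((s, i, r_star))

    track = PitchTrack(
        times=np.array(times), f0=np.array(f0s),
        hnr=np.array(hnrs), voiced=np.array(voiced, dtype=bool),
    )
    if track.n_voiced == 0:
        raise UnvoicedSegmentError("no voiced frames found", diagnostics=diags)
    return track


def mark_cycles(seg: Segment, track: PitchTrack) -> CycleMarks:
    """Pitch-guided peak picking; returns per-cycle durations and p2p amplitudes."""
    x = seg.samples
    rate = seg.rate
    f0 = float(np.nanmedian(track.f0))
    if not np.isfinite(f0) or f0 <= 0:
        raise UnvoicedSegmentError("pitch track has no usable f0")
    period = rate / f0

    # anchor on the strongest positive peak in the middle of the segment
    mid = len(x) // 2
    lo = max(0, mid - int(period))
    anchor = lo + int(np.argmax(x[lo : lo + 2 * int(period)]))

    def refine(i: int) -> float:
        return _parabolic(x, i)[0]

    marks = [refine(anchor)]
    # forward pass
    while True:
        prev = marks[-1]
        lo_i = int(np.floor(prev + 0.8 * period))
        hi_i = int(np.ceil(prev + 1.25 * period))
        if hi_i >= len(x):
            break
        i = lo_i + int(np.argmax(x[lo_i : hi_i + 1]))
        m = refine(i)
        marks.append(m)
        period = 0.7 * period + 0.3 * (m - prev)
    # backward pass
    period = rate / f0
    while True:
        first = marks[0]
        hi_i = int(np.ceil(first - 0.8 * period))
        lo_i = int(np.floor(first - 1.25 * period))
        if lo_i < 0:
            break
        i = lo_i + int(np.argmax(x[lo_i : hi_i + 1]))
        m = refine(i)
        marks.insert(0, m)
        period = 0.7 * period + 0.3 * (first - m)

    marks = np.array(marks)
    if len(marks) < 3:
        raise InsufficientCyclesError(f"only {len(marks)} cycle marks found")
    T = np.diff(marks) / rate
    A = np.empty(len(marks) - 1)
    for i in range(len(marks) - 1):
        a, b = int(round(marks[i])), int(round(marks[i + 1]))
        b = max(b, a + 2)
        cyc = x[a:b]
        # parabolic refinement of both extrema: sampled peak heights otherwise
        # alternate with the fractional peak position (quantization shimmer)
        hi = _parabolic(x, a + int(np.argmax(cyc)))[1]
        lo = -_parabolic(-x, a + int(np.argmin(cyc)))[1]
        A[i] = float(hi - lo)
    return CycleMarks(T=T, A=A)


def _warn_missing(name: str, n: int, need: int) -> float:
    warnings.warn(f"{name}: needs >= {need} cycles, got {n}; emitting NaN")
    return np.nan


def jitter_features(marks: CycleMarks) -> tuple[float, float, float, float]:
    """(jitter_absolute [s], jitter_relative [%], jitter_rap [%], jitter_ppq5 [%])."""
    t = marks.T
    n = len(t)
    if n < 2:
        raise InsufficientCyclesError(f"jitter needs >= 2 cycles, got {n}")
    mean_t = float(np.mean(t))
    absolute = float(np.mean(np.abs(np.diff(t))))
    relative = absolute / mean_t * 100.0

    if n >= 3:
        avg3 = np.convolve(t, np.ones(3) / 3.0, mode="valid")  # i = 1..n-2
        rap = float(np.mean(np.abs(t[1:-1] - avg3))) / mean_t * 100.0
    else:
        rap = _warn_missing("jitter_rap", n, 3)

    if n >= 5:
        avg5 = np.convolve(t, np.ones(5) / 5.0, mode="valid")  # i = 2..n-3
        ppq5 = float(np.mean(np.abs(t[2:-2] - avg5))) / mean_t * 100.0
    else:
        ppq5 = _warn_missing("jitter_ppq5", n, 5)

    return absolute, relative, rap, ppq5


def _apq(a: np.ndarray, p: int) -> float:
    """P-point amplitude perturbation quotient, % (centred moving-average window)."""
    n = len(a)
    if n < p:
        return _warn_missing(f"shimmer_apq{p}", n, p)
    avg = np.convolve(a, np.ones(p) / p, mode="valid")
    h = (p - 1) // 2
    core = a[h : n - h]
    return float(np.mean(np.abs(core - avg))) / float(np.mean(a)) * 100.0


def _apq_literal(a: np.ndarray, p: int) -> float:
    """Printed-formula variant: 3-term inner window for every P."""
    n = len(a)
    if n < 3:
        return _warn_missing(f"shimmer_apq{p}(literal)", n, 3)
    avg3 = np.convolve(a, np.ones(3), mode="valid") / p
    return float(np.mean(np.abs(a[1:-1] - avg3))) / float(np.mean(a)) * 100.0


def shimmer_features(
    marks: CycleMarks, *, literal_window: bool = False
) -> tuple[float, float, float, float, float]:
    """(shimmer_dB, shimmer_relative [%], apq3 [%], apq5 [%], apq11 [%])."""
    a = marks.A
    n = len(a)
    if n < 2:
        raise InsufficientCyclesError(f"shimmer needs >= 2 cycles, got {n}")
    if np.any(a <= 0):
        raise DegenerateInputError("non-positive peak-to-peak amplitude in cycle table")
    ratio = a[1:] / a[:-1]
    db = float(np.mean(np.abs(20.0 * np.log10(ratio))))
    relative = float(np.mean(np.abs(np.diff(a)))) / float(np.mean(a)) * 100.0
    apq_fn = _apq_literal if literal_window else _apq
    return db, relative, apq_fn(a, 3), apq_fn(a, 5), apq_fn(a, 11)


def hnr_and_pitch_stats(track: PitchTrack) -> tuple[float, float, float, float, float, float]:
    """(hnr_mean, hnr_sd, pitch_mean, pitch_sd, pitch_min, pitch_max) over voiced frames."""
    if track.n_voiced == 0:
        raise UnvoicedSegmentError("no voiced frames")
    hnr = track.hnr[track.voiced]
    f0 = track.f0[track.voiced]
    sd = float(np.std(hnr, ddof=1)) if len(hnr) > 1 else 0.0
    f0_sd = float(np.std(f0, ddof=1)) if len(f0) > 1 else 0.0
    return (float(np.mean(hnr)), sd,
            float(np.mean(f0)), f0_sd, float(np.min(f0)), float(np.max(f0)))


def extract_phonatory_features(
    seg: Segment,
    floor: float = 75.0,
    ceiling: float = 600.0,
    voicing_threshold: float = 0.45,
) -> dict[str, float]:
    """All 15 phonatory features of a segment, keyed by canonical column name."""
    track = estimate_pitch_track(seg, floor=floor, ceiling=ceiling,
                                 voicing_threshold=voicing_threshold)
    marks = mark_cycles(seg, track)
    j_abs, j_rel, j_rap, j_ppq5 = jitter_features(marks)
    s_db, s_rel, s_apq3, s_apq5, s_apq11 = shimmer_features(marks)
    hnr_m, hnr_sd, p_m, p_sd, p_min, p_max = hnr_and_pitch_stats(track)
    values = (j_abs, j_rel, j_rap, j_ppq5, s_db, s_rel, s_apq3, s_apq5, s_apq11,
              hnr_m, hnr_sd, p_m, p_sd, p_min, p_max)
    return dict(zip(PHONATORY_FEATURE_NAMES, values))
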