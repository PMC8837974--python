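import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import chirp, lfilter

from bulbarvoice.errors import InsufficientCyclesError, UnvoicedSegmentError
from bulbarvoice.phonatory import (
    PHONATORY_FEATURE_NAMES,
    CycleMarks,
    estimate_pitch_track,
    extract_phonatory_features,
    hnr_and_pitch_stats,
    jitter_features,
    mark_cycles,
    shimmer_features,
)
from bulbarvoice.preprocess import Segment

RATE = 8820.0


# ---------------------------------------------------------------- oracles
# literal loop transcriptions of the perturbation formulas, independent of
# the vectorized implementations


def oracle_jitter(t):
    n = len(t)
    mean_t = sum(t) / n
    absolute = sum(abs(t[i] - t[i - 1]) for i in range(1, n)) / (n - 1)
    relative = absolute / mean_t * 100.0
    rap_terms = [abs(t[i] - (t[i - 1] + t[i] + t[i + 1]) / 3.0)
                 for i in range(1, n - 1)]
    rap = (sum(rap_terms) / len(rap_terms)) / mean_t * 100.0 if rap_terms else None
    ppq_terms = [abs(t[i] - sum(t[i - 2 : i + 3]) / 5.0) for i in range(2, n - 2)]
    ppq5 = (sum(ppq_terms) / len(ppq_terms)) / mean_t * 100.0 if ppq_terms else None
    return absolute, relative, rap, ppq5


def oracle_shimmer(a):
    n = len(a)
    mean_a = sum(a) / n
    db = sum(abs(20.0 * np.log10(a[i + 1] / a[i])) for i in range(n - 1)) / (n - 1)
    rel = sum(abs(a[i] - a[i + 1]) for i in range(n - 1)) / (n - 1) / mean_a * 100.0

    def apq(p):
        h = (p - 1) // 2
        terms = [abs(a[i] - sum(a[i - h : i + h + 1]) / p)
                 for i in range(h, n - h)]
        return sum(terms) / len(terms) / mean_a * 100.0 if terms else None

    return db, rel, apq(3), apq(5), apq(11)


def _pulse_train_segment(periods_ms, rate=8000.0, ring=True):
    """Place pulses at the given inter-pulse intervals and add resonator ring.

    The default 8000 Hz rate makes an 8 ms period an exact 64 samples, so a
    constant-period train is strictly periodic on the sample grid.
    """
    onsets = np.cumsum([5.0] + list(periods_ms)) * 1e-3 * rate
    n = int(onsets[-1] + 60)
    x = np.zeros(n)
    x[np.round(onsets).astype(int)] = 1.0
    if ring:
        x = lfilter([1.0], [1.0, -1.4, 0.72], x)
    return Segment(samples=x, rate=rate)


# ---------------------------------------------------------------- pitch


class TestPitchTrack:
    def test_pure_sinusoid_200hz(self, tone_segment):
        track = estimate_pitch_track(tone_segment(200.0))
        assert track.n_voiced >= 3
        np.testing.assert_allclose(track.f0[track.voiced], 200.0, atol=1.0)

    def test_pulse_train_f0_and_hnr_cap(self):
        seg = _pulse_train_segment([8.0] * 25)
        track = estimate_pitch_track(seg)
        f0 = np.nanmean(track.f0)
        assert f0 == pytest.approx(125.0, abs=2.0)
        # periodic signal: r(T0) -> 1, HNR at the 60 dB ceiling
        assert np.nanmax(track.hnr) == 60.0

    def test_hnr_power_accounting(self):
        # harmonic stack : white noise at 10:1 power -> ~10 dB (Eq. oracle:
        # r(T0) = Ph/(Ph+Pn) by power accounting of the construction)
        rng = np.random.default_rng(1)
        t = np.arange(1323) / RATE
        h = sum(np.sin(2 * np.pi * 150 * k * t + k) for k in range(1, 10))
        h /= np.sqrt(np.mean(h**2))
        noise = rng.normal(size=len(t))
        noise *= np.sqrt(0.1 / np.mean(noise**2))
        track = estimate_pitch_track(Segment(samples=h + noise, rate=RATE))
        assert np.nanmean(track.hnr) == pytest.approx(10.0, abs=1.0)

    def test_gliding_pitch_min_max(self):
        t = np.arange(int(RATE)) / RATE
        seg = Segment(samples=chirp(t, 100.0, 1.0, 110.0), rate=RATE)
        track = estimate_pitch_track(seg)
        assert np.nanmin(track.f0) == pytest.approx(100.0, abs=1.0)
        assert np.nanmax(track.f0) == pytest.approx(110.0, abs=1.0)

    def test_unvoiced_noise_raises(self):
        rng = np.random.default_rng(0)
        seg = Segment(samples=rng.normal(size=1323), rate=RATE)
        with pytest.raises(UnvoicedSegmentError):
            estimate_pitch_track(seg, voicing_threshold=0.9)

    def test_too_short_raises(self):
        with pytest.raises(UnvoicedSegmentError):
            estimate_pitch_track(Segment(samples=np.zeros(64), rate=RATE))


# ---------------------------------------------------------------- cycles


class TestMarkCycles:
    def test_strict_pulse_train_count_and_periods(self):
        # 150 ms at 8 ms periods -> 17-18 cycles (one may fall off the edge)
        rate = 8000.0
        seg = _pulse_train_segment([8.0] * 20)
        seg = Segment(samples=seg.samples[: int(0.150 * rate)], rate=rate)
        track = estimate_pitch_track(seg)
        marks = mark_cycles(seg, track)
        assert marks.n in (16, 17, 18)
        np.testing.assert_allclose(marks.T, 8.0e-3, atol=1.0 / rate)

    def test_constant_amplitude(self):
        seg = _pulse_train_segment([8.0] * 30)
        marks = mark_cycles(seg, estimate_pitch_track(seg))
        inner = marks.A[2:-2]
        assert np.ptp(inner) < 1e-9

    def test_alternating_periods(self):
        seg = _pulse_train_segment([7.5, 8.5] * 15)
        marks = mark_cycles(seg, estimate_pitch_track(seg))
        t_ms = marks.T * 1e3
        lo, hi = np.sort([t_ms[::2].mean(), t_ms[1::2].mean()])
        assert lo == pytest.approx(7.5, abs=1e3 / 8000.0)
        assert hi == pytest.approx(8.5, abs=1e3 / 8000.0)

    def test_insufficient_cycles(self):
        seg = _pulse_train_segment([8.0] * 30)
        track = estimate_pitch_track(seg)
        short = Segment(samples=seg.samples[:150], rate=RATE)
        with pytest.raises(InsufficientCyclesError):
            mark_cycles(short, track)


# ---------------------------------------------------------------- jitter


class TestJitter:
    def test_constant_period_all_zero(self):
        marks = CycleMarks(T=np.full(20, 8e-3), A=np.ones(20))
        assert all(v <= 1e-10 for v in jitter_features(marks))

    def test_alternating_7_9(self):
        t = np.array([7, 9] * 5, dtype=float) * 1e-3
        absolute, relative, _, _ = jitter_features(CycleMarks(T=t, A=np.ones(10)))
        assert absolute == pytest.approx(2e-3, abs=1e-15)
        assert relative == pytest.approx(25.0, abs=1e-9)

    def test_rap_oracle_five_cycles(self):
        t = np.array([8, 8, 10, 8, 8], dtype=float) * 1e-3
        _, _, rap, _ = jitter_features(CycleMarks(T=t, A=np.ones(5)))
        assert rap == pytest.approx(oracle_jitter(list(t))[2], abs=1e-12)

    @given(st.lists(st.floats(min_value=5e-3, max_value=12e-3), min_size=6,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence(self, periods):
        t = np.array(periods)
        got = jitter_features(CycleMarks(T=t, A=np.ones(len(t))))
        want = oracle_jitter(periods)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-12, rel=1e-9)

    def test_time_scaling(self):
        t = np.array([7.5, 8.3, 8.0, 7.9, 8.6, 8.1, 7.7]) * 1e-3
        base = jitter_features(CycleMarks(T=t, A=np.ones(7)))
        doubled = jitter_features(CycleMarks(T=2 * t, A=np.ones(7)))
        assert doubled[0] == pytest.approx(2 * base[0], rel=1e-12)
        for i in (1, 2, 3):
            assert doubled[i] == pytest.approx(base[i], rel=1e-12)

    def test_too_few_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            jitter_features(CycleMarks(T=np.array([8e-3]), A=np.array([1.0])))

    def test_short_table_missing_values_warn(self):
        marks = CycleMarks(T=np.array([8e-3, 8.2e-3]), A=np.ones(2))
        with pytest.warns(UserWarning):
            _, _, rap, ppq5 = jitter_features(marks)
        assert np.isnan(rap) and np.isnan(ppq5)


# ---------------------------------------------------------------- shimmer


class TestShimmer:
    def test_all_equal_zero(self):
        marks = CycleMarks(T=np.full(15, 8e-3), A=np.full(15, 2.5))
        assert all(v <= 1e-10 for v in shimmer_features(marks))

    def test_alternating_double_amplitude(self):
        a = np.array([1.0, 2.0] * 6)
        db, rel, *_ = shimmer_features(CycleMarks(T=np.full(12, 8e-3), A=a))
        assert db == pytest.approx(20.0 * np.log10(2.0), abs=1e-12)
        assert rel == pytest.approx(oracle_shimmer(list(a))[1], abs=1e-12)

    def test_apq3_oracle(self):
        a = np.array([1.0, 1.0, 1.2, 1.0, 1.0])
        got = shimmer_features(CycleMarks(T=np.full(5, 8e-3), A=a))
        assert got[2] == pytest.approx(oracle_shimmer(list(a))[2], abs=1e-12)

    @given(st.lists(st.floats(min_value=0.5, max_value=3.0), min_size=12,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence(self, amps):
        a = np.array(amps)
        got = shimmer_features(CycleMarks(T=np.full(len(a), 8e-3), A=a))
        want = oracle_shimmer(amps)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, abs=1e-12, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance(self, gain):
        a = np.array([1.0, 1.1, 0.95, 1.04, 1.2, 0.9, 1.0, 1.15, 0.97, 1.02,
                      1.08, 0.93])
        base = shimmer_features(CycleMarks(T=np.full(12, 8e-3), A=a))
        scaled = shimmer_features(CycleMarks(T=np.full(12, 8e-3), A=gain * a))
        np.testing.assert_allclose(scaled, base, rtol=1e-9)

    def test_literal_window_variant_differs(self):
        a = np.array([1.0, 1.1, 0.95, 1.04, 1.2, 0.9, 1.0, 1.15, 0.97, 1.02,
                      1.08, 0.93])
        marks = CycleMarks(T=np.full(12, 8e-3), A=a)
        std = shimmer_features(marks)
        lit = shimmer_features(marks, literal_window=True)
        assert std[2] == pytest.approx(lit[2], abs=1e-12)  # P=3 agrees
        assert std[4] != pytest.approx(lit[4])             # P=11 differs


# ------------------------------------------------------- track statistics


class TestHnrPitchStats:
    def _track(self, f0, hnr):
        from bulbarvoice.phonatory import PitchTrack

        n = len(f0)
        return PitchTrack(times=np.arange(n) * 0.01, f0=np.asarray(f0, float),
                          hnr=np.asarray(hnr, float), voiced=np.ones(n, bool))

    def test_constant_track(self):
        t = self._track([150.0] * 5, [20.0] * 5)
        hnr_m, hnr_sd, p_m, p_sd, p_min, p_max = hnr_and_pitch_stats(t)
        assert (p_m, p_sd, p_min, p_max) == (150.0, 0.0, 150.0, 150.0)
        assert (hnr_m, hnr_sd) == (20.0, 0.0)

    def test_r_half_gives_zero_db(self):
        from bulbarvoice.phonatory import _hnr_from_r

        assert _hnr_from_r(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_glide_min_max(self):
        t = self._track(np.linspace(100, 110, 11), np.full(11, 15.0))
        *_, p_min, p_max = hnr_and_pitch_stats(t)
        assert p_min == 100.0 and p_max == 110.0


# ------------------------------------------------------------- top level


class TestExtract:
    def test_fifteen_named_features(self, vowel_segment):
        feats = extract_phonatory_features(vowel_segment)
        assert tuple(feats) == PHONATORY_FEATURE_NAMES
        assert len(feats) == 15
        assert all(np.isfinite(v) for v in feats.values())

    def test_all_non_negative(self, vowel_segment):
        feats = extract_phonatory_features(vowel_segment)
        assert all(v >= 0 for v in feats.values())

    def test_periodic_segment_zero_perturbation(self, periodic_segment):
        feats = extract_phonatory_features(periodic_segment)
        for name in ("jitter_absolute", "jitter_relative", "jitter_rap",
                     "jitter_ppq5", "shimmer_dB", "shimmer_relative",
                     "shimmer_apq3", "shimmer_apq5", "shimmer_apq11"):
            assert feats[name] < 1e-10, name
        assert feats["hnr_mean"] == 60.0
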