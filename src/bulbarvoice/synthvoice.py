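"""Synthetic sustained-vowel generator with known ground-truth perturbations.

Source-filter synthesis: a band-limited pulse train with per-cycle period
perturbation (jitter) and per-cycle amplitude perturbation (shimmer) is fed
through a cascade of formant resonators; white noise is added at a scale set
by the requested harmonics-to-noise ratio.  Every generated cycle (onset,
period, amplitude) is recorded so downstream estimators can be checked
against the generator's own cycle table.

Calibration: per-cycle relative perturbations are i.i.d. Gaussian with
scale ``sqrt(pi)/2 * target/100`` so that the expected value of the
mean-absolute-consecutive-difference estimators (relative jitter/shimmer)
equals the requested percentage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import firwin, lfilter

from .preprocess import VOWELS, VowelRecording, write_wav

__all__ = [
    "VoiceSpec",
    "GroundTruth",
    "FORMANT_TABLE",
    "synthesize_vowel",
    "make_cohort",
    "GROUP_PROFILES",
]

# E|eps_i - eps_j| for i.i.d. N(0, s): s * 2/sqrt(pi).  Invert it.
_GAUSS_ABS_DIFF = 2.0 / np.sqrt(np.pi)

# Adult Spanish vowel formants (F1-F3 centre Hz); standard phonetics tables,
# female values scaled up ~18%.  Bandwidths chosen broad enough that resonator
# ringing decays well within one glottal cycle.
FORMANT_TABLE = {
    "M": {
        "a": [(700, 110), (1190, 140), (2600, 200), (3300, 90)],
        "e": [(460, 100), (1960, 150), (2600, 200), (3300, 90)],
        "i": [(280, 90), (2250, 150), (2900, 220), (3350, 90)],
        "o": [(460, 100), (850, 130), (2600, 200), (3250, 90)],
        "u": [(310, 90), (680, 120), (2500, 200), (3250, 90)],
    },
    "F": {
        "a": [(830, 120), (1400, 150), (2900, 220), (3450, 110)],
        "e": [(540, 110), (2300, 160), (3000, 230), (3500, 110)],
        "i": [(330, 100), (2650, 170), (3300, 250), (3550, 110)],
        "o": [(540, 110), (1000, 140), (2900, 220), (3450, 110)],
        "u": [(370, 100), (800, 130), (2800, 220), (3400, 110)],
    },
}


@dataclass
class VoiceSpec:
    """Parameters of one synthetic sustained vowel."""

    f0: float = 120.0
    jitter_rel: float = 0.5       # target relative jitter, %
    shimmer_rel: float = 2.0      # target relative shimmer, %
    hnr_db: float = 25.0          # target harmonics-to-noise ratio, dB (inf = no noise)
    vowel: str = "a"
    sex: str = "M"
    formants: list | None = None  # override (centre Hz, bandwidth Hz) pairs
    tilt: float = 0.0             # 0..1, high-frequency attenuation (one-pole low-pass)
    voice_type: int = 1           # 2 adds an f0/2 subharmonic and slow AM
    duration: float = 3.0
    rate: float = 44_100.0
    seed: int = 0

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.jitter_rel < 0 or self.shimmer_rel < 0:
            raise ValueError("perturbation targets must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.vowel not in VOWELS:
            raise ValueError(f"unknown vowel {self.vowel!r}")
        if self.voice_type not in (1, 2):
            raise ValueError("voice_type must be 1 or 2")


@dataclass
class GroundTruth:
    """Per-cycle table and achieved parameters recorded by the generator."""

    onsets: np.ndarray            # cycle onset times, samples (float)
    periods: np.ndarray           # cycle periods, samples (float)
    amplitudes: np.ndarray        # per-cycle source amplitudes
    achieved_hnr_db: float        # 10*log10(Ph/Pn) of the actual components
    spec: VoiceSpec = field(repr=False, default=None)

    @property
    def jitter_relative(self) -> float:
        """Relative jitter (%) of the generated cycle table."""
        t = self.periods
        return float(np.mean(np.abs(np.diff(t))) / np.mean(t) * 100.0)

    @property
    def shimmer_relative(self) -> float:
        """Relative shimmer (%) of the generated amplitude table."""
        a = self.amplitudes
        return float(np.mean(np.abs(np.diff(a))) / np.mean(a) * 100.0)


def _bandlimited_pulse(frac: float, half: int = 24) -> np.ndarray:
    # windowed-sinc impulse at fractional offset `frac` in [0, 1): flat
    # spectrum up to ~0.9 Nyquist, so harmonics populate every band.  The
    # window is shifted along with the sinc so the rendered pulse is an exact
    # translate (its amplitude must not depend on the fractional position).
    k = np.arange(-half, half + 1) - frac
    w = 0.5 * (1.0 + np.cos(np.pi * np.clip(k / (half + 1), -1.0, 1.0)))
    return np.sinc(0.9 * k) * w


def synthesize_vowel(spec: VoiceSpec) -> tuple[VowelRecording, GroundTruth]:
    """Render one sustained vowel; returns the recording and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    rate = spec.rate
    n = int(round(spec.duration * rate))
    t0 = rate / spec.f0  # mean period in samples

    n_cycles = int(np.ceil(n / t0)) + 2
    sig_eps = spec.jitter_rel / 100.0 / _GAUSS_ABS_DIFF
    sig_eta = spec.shimmer_rel / 100.0 / _GAUSS_ABS_DIFF
    eps = rng.normal(0.0, sig_eps, n_cycles) if sig_eps > 0 else np.zeros(n_cycles)
    eta = rng.normal(0.0, sig_eta, n_cycles) if sig_eta > 0 else np.zeros(n_cycles)
    periods = t0 * np.clip(1.0 + eps, 0.5, 1.5)
    amps = np.clip(1.0 + eta, 0.05, None)

    if spec.voice_type == 2:
        # f0/2 subharmonic: alternate-cycle amplitude modulation
        amps = amps * (1.0 + 0.15 * np.where(np.arange(n_cycles) % 2 == 0, 1.0, -1.0))

    onsets = np.concatenate(([t0 * 0.5], t0 * 0.5 + np.cumsum(periods[:-1])))
    keep = onsets < n - t0 * 0.5
    onsets, periods, amps = onsets[keep], periods[keep], amps[keep]

    half = 24
    source = np.zeros(n + 2 * half)
    for onset, a in zip(onsets, amps):
        i = int(np.floor(onset))
        source[i : i + 2 * half + 1] += a * _bandlimited_pulse(onset - i, half)
    source = source[half : half + n]

    if spec.voice_type == 2:
        tt = np.arange(n) / rate
        source = source * (1.0 + 0.2 * np.sin(2.0 * np.pi * 3.0 * tt))

    if spec.tilt > 0:
        # one-pole low-pass; tilt in (0, 1) is the pole radius
        source = lfilter([1.0 - spec.tilt], [1.0, -spec.tilt], source)

    formants = spec.formants
    if formants is None:
        formants = FORMANT_TABLE[spec.sex][spec.vowel]
    harmonic = source
    for fc, bw in formants:
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * fc / rate
        # unity DC gain: resonance peaks ride on a flat base, so harmonics
        # populate every analysis band
        b = [1.0 - 2.0 * r * np.cos(theta) + r * r]
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        harmonic = lfilter(b, a, harmonic)

    p_h = float(np.mean(harmonic**2))
    if np.isfinite(spec.hnr_db):
        # noise is band-limited to the analysis band (< 4410 Hz) so the
        # harmonic/noise power ratio survives the decimation stage
        p_n = p_h / 10.0 ** (spec.hnr_db / 10.0)
        raw = rng.normal(0.0, 1.0, n)
        cutoff = min(3300.0, 0.45 * rate)
        raw = lfilter(firwin(301, cutoff, fs=rate), [1.0], raw)
        noise = raw * np.sqrt(p_n / np.mean(raw**2))
        achieved = 10.0 * np.log10(p_h / np.mean(noise**2))
    else:
        noise = np.zeros(n)
        achieved = np.inf
    samples = harmonic + noise

    rec = VowelRecording(samples=samples, rate=rate, vowel=spec.vowel, sex=spec.sex)
    truth = GroundTruth(onsets=onsets, periods=periods, amplitudes=amps,
                        achieved_hnr_db=achieved, spec=spec)
    return rec, truth


# Healthy / intermediate / affected sampling profiles for the three cohort
# groups.  B is well separated from C (strong perturbations, low HNR, strong
# high-band tilt) while NB straddles the range between them so that B-vs-NB
# classification is genuinely harder than C-vs-B.
GROUP_PROFILES = {
    "C": dict(jitter=(0.25, 0.55), shimmer=(1.0, 2.5), hnr=(24.0, 30.0),
              tilt=(0.0, 0.1), type2_prob=0.0),
    "NB": dict(jitter=(0.5, 3.0), shimmer=(2.0, 8.5), hnr=(10.0, 26.0),
               tilt=(0.1, 0.7), type2_prob=0.15),
    "B": dict(jitter=(1.0, 3.5), shimmer=(3.5, 10.0), hnr=(8.0, 18.0),
              tilt=(0.3, 0.85), type2_prob=0.3),
}

_F0_RANGE = {"M": (100.0, 140.0), "F": (170.0, 230.0)}


def make_cohort(
    n_per_group: int,
    sex: str = "F",
    seed: int = 0,
    out_dir: str | None = None,
    duration: float = 3.0,
    groups: tuple[str, ...] = ("C", "B", "NB"),
) -> tuple[list[VowelRecording], pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort of ``n_per_group`` subjects per group.

    Each subject phonates all five vowels.  Returns (recordings, metadata,
    ground_truth); when ``out_dir`` is given, WAV files plus ``metadata.csv``
    and ``ground_truth.csv`` are written there.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    recordings: list[VowelRecording] = []
    meta_rows, truth_rows = [], []

    for group in groups:
        prof = GROUP_PROFILES[group]
        for k in range(n_per_group):
            subject = f"{sex}{group}{k:03d}"
            f0 = rng.uniform(*_F0_RANGE[sex])
            jitter = rng.uniform(*prof["jitter"])
            shimmer = rng.uniform(*prof["shimmer"])
            hnr = rng.uniform(*prof["hnr"])
            tilt = rng.uniform(*prof["tilt"])
            vtype = 2 if rng.random() < prof["type2_prob"] else 1
            for vowel in VOWELS:
                spec = VoiceSpec(
                    f0=f0, jitter_rel=jitter, shimmer_rel=shimmer, hnr_db=hnr,
                    vowel=vowel, sex=sex, tilt=tilt, voice_type=vtype,
                    duration=duration, seed=int(rng.integers(0, 2**31 - 1)),
                )
                rec, truth = synthesize_vowel(spec)
                rec.subject_id, rec.group = subject, group
                recordings.append(rec)
                path = f"{subject}_{vowel}.wav"
                meta_rows.append(dict(subject_id=subject, sex=sex, group=group,
                                      vowel=vowel, path=path))
                truth_rows.append(dict(
                    subject_id=subject, vowel=vowel, group=group, f0=f0,
                    jitter_rel=jitter, shimmer_rel=shimmer, hnr_db=hnr,
                    tilt=tilt, voice_type=vtype,
                    achieved_jitter_rel=truth.jitter_relative,
                    achieved_shimmer_rel=truth.shimmer_relative,
                    achieved_hnr_db=truth.achieved_hnr_db,
                ))

    metadata = pd.DataFrame(meta_rows)
    ground_truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for rec, row in zip(recordings, meta_rows):
            write_wav(os.path.join(out_dir, row["path"]), rec)
        metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
        ground_truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
    return recordings, metadata, ground_truth
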