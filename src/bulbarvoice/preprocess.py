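"""Recording I/O and the decimate → z-score → cut preprocessing chain.

The standard chain takes a 44,100 Hz sustained-vowel recording, decimates it
by a factor of 5 to 8,820 Hz with an anti-aliasing filter, standardizes the
whole decimated signal to zero mean / unit SD, and cuts a 150 ms analysis
segment centred on the temporal midpoint of the phonation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import decimate as _sp_decimate
from scipy.signal import resample_poly

from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "VowelRecording",
    "Segment",
    "read_wav",
    "write_wav",
    "decimate_signal",
    "standardize",
    "cut_segment",
    "preprocess_recording",
]

VOWELS = ("a", "e", "i", "o", "u")
DEFAULT_RATE = 44_100
DEFAULT_DECIMATION = 5
DEFAULT_SEGMENT_DURATION = 0.150


@dataclass
class VowelRecording:
    """A mono sustained-vowel recording plus its subject metadata."""

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    vowel: str = ""
    sex: str = ""
    group: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError(
                f"recording must be single-channel, got shape {self.samples.shape}"
            )
        if self.rate <= 0:
            raise InputError(f"sampling rate must be positive, got {self.rate}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class Segment:
    """A standardized mid-phonation excerpt; the unit of all feature extraction."""

    samples: np.ndarray
    rate: float
    duration: float = field(default=DEFAULT_SEGMENT_DURATION)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path, *, mixdown: bool = False, **metadata) -> VowelRecording:
    """Read a RIFF PCM WAV file into a :class:`VowelRecording`.

    Integer PCM (16/24/32-bit) is rescaled to [-1, 1]; float data is kept
    as-is.  Stereo input is rejected unless ``mixdown=True``, in which case
    channels are averaged.
    """
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        if not mixdown:
            raise InputError(
                f"{path}: expected mono input; pass mixdown=True to average channels"
            )
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return VowelRecording(samples=data, rate=float(rate), **metadata)


def write_wav(path, rec: VowelRecording) -> None:
    """Write a recording as 32-bit float WAV (lossless for our float pipeline)."""
    wavfile.write(path, int(round(rec.rate)), rec.samples.astype(np.float32))


def decimate_signal(rec: VowelRecording, factor: int) -> VowelRecording:
    """Decimate by an integer factor with zero-phase anti-alias filtering.

    The anti-aliasing stage is the order-8 Chebyshev type-I low-pass applied
    forward-backward (zero phase) with cutoff 0.8x the new Nyquist, i.e.
    ``scipy.signal.decimate(..., ftype="iir", zero_phase=True)``.
    """
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if len(rec.samples) == 0:
        raise InputError("cannot decimate an empty signal")
    if rec.rate % factor != 0:
        raise ConfigurationError(
            f"rate {rec.rate} Hz is not divisible by decimation factor {factor}"
        )
    if factor == 1:
        return replace(rec, samples=rec.samples.copy())
    out = _sp_decimate(rec.samples, factor, ftype="iir", zero_phase=True)
    return replace(rec, samples=out, rate=rec.rate / factor)


def standardize(rec: VowelRecording, *, ddof: int = 0) -> VowelRecording:
    """z-score the whole signal: subtract the mean, divide by the SD.

    Population SD (``ddof=0``) is the default convention; pass ``ddof=1``
    for the sample-SD variant.
    """
    x = rec.samples
    if len(x) == 0:
        raise InputError("cannot standardize an empty signal")
    sd = np.std(x, ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant signal has zero standard deviation")
    return replace(rec, samples=(x - np.mean(x)) / sd)


def cut_segment(rec: VowelRecording, duration: float = DEFAULT_SEGMENT_DURATION) -> Segment:
    """Cut a window of ``round(duration * rate)`` samples centred at the midpoint.

    Window arithmetic is the half-open interval ``[c - L//2, c - L//2 + L)``
    with ``c = N//2``; the cut is a contiguous slice (no resampling).
    """
    n = len(rec.samples)
    length = int(round(duration * rec.rate))
    if length < 1:
        raise ConfigurationError(f"segment duration {duration}s too short at rate {rec.rate}")
    if n < length:
        raise InputError(
            f"recording of {n} samples is shorter than the requested "
            f"{length}-sample segment"
        )
    start = n // 2 - length // 2
    return Segment(samples=rec.samples[start : start + length].copy(),
                   rate=rec.rate, duration=duration)


def preprocess_recording(
    rec: VowelRecording,
    *,
    factor: int = DEFAULT_DECIMATION,
    duration: float = DEFAULT_SEGMENT_DURATION,
    allow_resample: bool = False,
) -> Segment:
    """Run the standard chain: decimate, then z-score, then cut.

    If the rate is not divisible by ``factor`` and ``allow_resample`` is set,
    the recording is first resampled to 44,100 Hz (with a warning).
    """
    if rec.rate % factor != 0:
        if not allow_resample:
            raise ConfigurationError(
                f"rate {rec.rate} not divisible by {factor}; "
                "pass allow_resample=True to resample to 44100 Hz first"
            )
        warnings.warn(
            f"resampling {rec.rate} Hz recording to {DEFAULT_RATE} Hz before decimation"
        )
        g = np.gcd(int(rec.rate), DEFAULT_RATE)
        resampled = resample_poly(rec.samples, DEFAULT_RATE // g, int(rec.rate) // g)
        rec = replace(rec, samples=resampled, rate=float(DEFAULT_RATE))
    return cut_segment(standardize(decimate_signal(rec, factor)), duration)
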