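"""Discrete Wigner distribution, Choi-Williams smoothing, marginals and moments.

The discrete Wigner distribution of a segment x is evaluated on a decimated
time lattice (every ``time_step``-th sample) with ``n_freq`` frequency bins
covering [0, rate/2):

    WD[k, j] = sum_m x[n_j + m] conj(x[n_j - m]) exp(-2*pi*i*m*k / M)

with the lag sum truncated at the segment boundaries.  By default the
analytic signal (Hilbert transform) is analysed, which suppresses the
positive/negative frequency cross-terms that would otherwise contaminate the
lowest band; ``use_analytic=False`` gives the literal real-signal reading.

Choi-Williams smoothing multiplies the ambiguity function (2-D Fourier
transform of the WD) by ``exp(-theta^2 * tau^2 / sigma)`` where ``theta`` is
doppler in rad/sample and ``tau`` is lag in samples, then transforms back and
normalizes the grid to unit mass (the CWDN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .errors import DegenerateInputError, InputError
from .preprocess import Segment

__all__ = [
    "TFRGrid",
    "Marginals",
    "DensityGrid",
    "wigner_distribution",
    "choi_williams",
    "marginals",
    "joint_density",
    "joint_moments",
    "export_grid",
    "render_density_image",
]

DEFAULT_TIME_STEP = 4
DEFAULT_SIGMA = 1.0


@dataclass
class TFRGrid:
    values: np.ndarray          # (n_freq, n_time)
    freqs: np.ndarray           # Hz
    times: np.ndarray           # s
    meta: dict = field(default_factory=dict)

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class Marginals:
    mt: np.ndarray              # instantaneous power over time bins; sums to 1
    mf: np.ndarray              # spectral energy density over freq bins; sums to 1
    times: np.ndarray
    freqs: np.ndarray


@dataclass
class DensityGrid:
    pD: np.ndarray              # (n_freq, n_time) outer product of mf and mt
    freqs: np.ndarray
    times: np.ndarray


def wigner_distribution(
    seg: Segment,
    use_analytic: bool = True,
    n_freq: int | None = None,
    time_step: int = DEFAULT_TIME_STEP,
) -> TFRGrid:
    """Discrete Wigner distribution on a decimated time lattice."""
    x = np.asarray(seg.samples, dtype=np.float64)
    n = len(x)
    if n < 64:
        raise InputError(f"segment of {n} samples too short for a Wigner distribution")
    z = hilbert(x) if use_analytic else x.astype(np.complex128)
    m_bins = n_freq if n_freq is not None else (n + 1) // 2

    centers = np.arange(0, n, time_step)
    tau_max = np.minimum(np.minimum(centers, n - 1 - centers), m_bins - 1)

    # lag kernel K[m, j] = z[n_j + m] * conj(z[n_j - m]), zero beyond tau_max
    m = np.arange(m_bins)[:, None]
    c = centers[None, :]
    valid = m <= tau_max[None, :]
    ip = np.clip(c + m, 0, n - 1)
    im = np.clip(c - m, 0, n - 1)
    kern = np.where(valid, z[ip] * np.conj(z[im]), 0.0)

    # full lag sum via Hermitian symmetry: W = 2*Re(FFT(kern)) - K[0]
    spec = np.fft.fft(kern, axis=0)
    values = 2.0 * spec.real - kern[0].real[None, :]

    rate = seg.rate
    freqs = np.arange(m_bins) * rate / (2.0 * m_bins)
    times = centers / rate
    return TFRGrid(values=values, freqs=freqs, times=times,
                   meta={"time_step": time_step, "analytic": use_analytic,
                         "rate": rate})


def normalize_grid(grid: TFRGrid) -> TFRGrid:
    """Scale a TFR grid to unit total mass."""
    total = grid.values.sum()
    if total <= 0:
        raise DegenerateInputError("TFR grid has non-positive total mass")
    return TFRGrid(values=grid.values / total, freqs=grid.freqs,
                   times=grid.times, meta=dict(grid.meta))


def choi_williams(wd: TFRGrid, sigma: float = DEFAULT_SIGMA) -> TFRGrid:
    """Ambiguity-domain Choi-Williams smoothing; output normalized to unit mass."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    v = wd.values
    n_f, n_t = v.shape
    # (f, t) -> (lag, doppler)
    amb = np.fft.fft(np.fft.ifft(v, axis=0), axis=1)

    time_step = wd.meta.get("time_step", 1)
    # frequency bins span [0, rate/2) over n_f bins, so the conjugate lag
    # variable advances 2 signal samples per lag bin
    tau = 2.0 * n_f * np.fft.fftfreq(n_f)          # samples
    theta = 2.0 * np.pi * np.fft.fftfreq(n_t) / time_step  # rad/sample
    kernel = np.exp(-np.minimum(
        (theta[None, :] ** 2) * (tau[:, None] ** 2) / sigma, 700.0))
    sm = np.fft.fft(np.fft.ifft(amb * kernel, axis=1), axis=0).real

    out = TFRGrid(values=sm, freqs=wd.freqs, times=wd.times,
                  meta={**wd.meta, "sigma": sigma})
    return normalize_grid(out)


def _clip_negatives(p: np.ndarray, what: str) -> np.ndarray:
    # smoothing leaves benign negative sidelobes; diagnose only when the
    # total clipped mass is a substantial fraction of the positive mass
    neg = -p[p < 0].sum()
    pos = p[p > 0].sum()
    if pos > 0 and neg > 0.05 * pos:
        warnings.warn(
            f"{what}: clipping negative mass {neg:.3e} "
            f"({100.0 * neg / pos:.1f}% of positive mass)"
        )
    return np.clip(p, 0.0, None)


def marginals(cwdn: TFRGrid) -> Marginals:
    """Time and frequency marginal densities of a normalized grid."""
    if not np.isclose(cwdn.values.sum(), 1.0, atol=1e-6):
        raise InputError("marginals expect a unit-mass (normalized) grid")
    mt = _clip_negatives(cwdn.values.sum(axis=0), "time marginal")
    mf = _clip_negatives(cwdn.values.sum(axis=1), "frequency marginal")
    if mt.sum() <= 0 or mf.sum() <= 0:
        raise DegenerateInputError("marginal collapsed to zero after clipping")
    return Marginals(mt=mt / mt.sum(), mf=mf / mf.sum(),
                     times=cwdn.times, freqs=cwdn.freqs)


def joint_density(m: Marginals) -> DensityGrid:
    """Interference-free joint density: outer product of the two marginals."""
    return DensityGrid(pD=np.outer(m.mf, m.mt), freqs=m.freqs, times=m.times)


def joint_moments(
    cwdn: TFRGrid,
    orders: list[tuple[int, int]] = ((1, 1), (7, 7), (15, 15)),
    standardized: bool = True,
) -> dict[str, float]:
    """Central joint time-frequency moments of a normalized grid.

    ``orders`` lists (n, m) pairs with n the frequency order and m the time
    order; keys in the result are ``t{n}f{m}`` style names.  Moments are
    standardized (divided by sigma_t**m * sigma_f**n) unless
    ``standardized=False``.
    """
    w = cwdn.values
    total = w.sum()
    if not np.isfinite(total) or abs(total) < 1e-12:
        raise DegenerateInputError("grid mass is zero")
    w = w / total
    wt = w.sum(axis=0)
    wf = w.sum(axis=1)
    t_idx = np.arange(len(wt), dtype=np.float64)
    f_idx = np.arange(len(wf), dtype=np.float64)
    mu_t = float(wt @ t_idx)
    mu_f = float(wf @ f_idx)
    var_t = float(wt @ (t_idx - mu_t) ** 2)
    var_f = float(wf @ (f_idx - mu_f) ** 2)
    if var_t <= 0 or var_f <= 0:
        raise DegenerateInputError("zero variance along the time or frequency axis")
    zt = t_idx - mu_t
    zf = f_idx - mu_f
    if standardized:
        zt = zt / np.sqrt(var_t)
        zf = zf / np.sqrt(var_f)
    out = {}
    for n, m in orders:
        out[f"t{n}f{m}"] = float(zf ** n @ w @ zt ** m)
    return out


def export_grid(path, grid) -> None:
    """Write a (frequency x time) grid as a portable whitespace text matrix.

    The frequency and time axes are stored in comment header lines.
    """
    values = grid.pD if isinstance(grid, DensityGrid) else grid.values
    header = ("freqs_hz: " + " ".join(f"{f:.6g}" for f in grid.freqs) + "\n"
              + "times_s: " + " ".join(f"{t:.9g}" for t in grid.times))
    np.savetxt(path, values, header=header)


def render_density_image(path, density: DensityGrid, *, log_floor: float = 1e-8,
                         title: str | None = None) -> None:
    """Render pD(f, t) as a log-scaled PNG heat map for visual inspection."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    img = 10.0 * np.log10(np.maximum(density.pD, log_floor))
    ax.imshow(img, origin="lower", aspect="auto",
              extent=(density.times[0], density.times[-1],
                      density.freqs[0], density.freqs[-1]),
              cmap="magma")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
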