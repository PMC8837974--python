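"""The 35 per-segment time-frequency features.

Band features (21): the spectrum [0, 4410] Hz is partitioned into 7 bands;
for each band the energy fraction (E_Bn), the dominant-frequency time average
(f_Cres) and the centroid-frequency time average (f_Med) are computed from
the interference-free joint density pD(f, t).  The remaining 14: Shannon
entropies of the two marginals and their sum (H_t, H_f, H_tf), per-band mean
spectral information (IE_Bn), kurtosis of the time marginal (K), and three
joint time-frequency moments of the CWDN (t1f1, t7f7, t15f15).

Time-varying band quantities are reduced to a single number per band:
E_Bn is the total band mass (the time integral of the instantaneous band
energy), f_Cres and f_Med are energy-weighted time averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .preprocess import Segment
from .tfr import (
    DensityGrid,
    Marginals,
    choi_williams,
    joint_density,
    joint_moments,
    marginals,
    wigner_distribution,
)

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "TF_FEATURE_NAMES",
    "band_energy",
    "band_freq_peak",
    "band_freq_mean",
    "entropies",
    "spectral_information",
    "kurtosis_feature",
    "extract_tf_features",
]


@dataclass(frozen=True)
class BandScheme:
    """Half-open frequency intervals [lo, hi) Hz; the last band includes hi."""

    edges: tuple = (0.0, 80.0, 250.0, 550.0, 900.0, 1500.0, 3000.0, 4410.0)

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    def masks(self, freqs: np.ndarray) -> list[np.ndarray]:
        out = []
        for b in range(self.n_bands):
            lo, hi = self.edges[b], self.edges[b + 1]
            if b == self.n_bands - 1:
                out.append((freqs >= lo) & (freqs <= hi))
            else:
                out.append((freqs >= lo) & (freqs < hi))
        return out


DEFAULT_BANDS = BandScheme()

TF_FEATURE_NAMES = tuple(
    [f"E_Bn{b}" for b in range(1, 8)]
    + [f"f_Cres{b}" for b in range(1, 8)]
    + [f"f_Med{b}" for b in range(1, 8)]
    + ["H_t", "H_f", "H_tf"]
    + [f"IE_Bn{b}" for b in range(1, 8)]
    + ["K", "t1f1", "t7f7", "t15f15"]
)


def band_energy(
    pd_grid: DensityGrid, bands: BandScheme = DEFAULT_BANDS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-band energy fractions E_Bn and instantaneous profiles E_b(t).

    E_b(t) integrates pD over the band's frequency rows; the reported feature
    is its time integral (the band's share of total mass), so the 7 values
    sum to 1.
    """
    profiles = np.stack(
        [pd_grid.pD[m].sum(axis=0) for m in bands.masks(pd_grid.freqs)]
    )
    return profiles.sum(axis=1), profiles


def band_freq_peak(
    pd_grid: DensityGrid, bands: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Energy-weighted time average of the within-band peak frequency (f_Cres).

    Ties in the per-time argmax break toward the lower frequency bin.
    """
    out = np.full(bands.n_bands, np.nan)
    for b, mask in enumerate(bands.masks(pd_grid.freqs)):
        sub = pd_grid.pD[mask]
        w = sub.sum(axis=0)
        total = w.sum()
        if sub.size == 0 or total <= 0:
            warnings.warn(f"band {b + 1} has zero mass; f_Cres{b + 1} is NaN")
            continue
        f_band = pd_grid.freqs[mask]
        peak_f = f_band[np.argmax(sub, axis=0)]
        out[b] = float((peak_f * w).sum() / total)
    return out


def band_freq_mean(
    pd_grid: DensityGrid, bands: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Energy-weighted time average of the within-band centroid frequency (f_Med)."""
    out = np.full(bands.n_bands, np.nan)
    for b, mask in enumerate(bands.masks(pd_grid.freqs)):
        sub = pd_grid.pD[mask]
        w = sub.sum(axis=0)
        total = w.sum()
        if sub.size == 0 or total <= 0:
            warnings.warn(f"band {b + 1} has zero mass; f_Med{b + 1} is NaN")
            continue
        f_band = pd_grid.freqs[mask]
        # time average of the per-time centroid, weighted by band energy E_b(t):
        # sum_t E(t) * [sum_f f*pD / E(t)] / sum_t E(t) = total band centroid
        out[b] = float((f_band @ sub).sum() / total)
    return out


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def entropies(m: Marginals) -> tuple[float, float, float]:
    """Shannon entropies (bits) of the marginals and their sum: (H_t, H_f, H_tf)."""
    h_t = _entropy_bits(m.mt)
    h_f = _entropy_bits(m.mf)
    return h_t, h_f, h_t + h_f


def spectral_information(
    mf: np.ndarray, freqs: np.ndarray, bands: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Per-band mean of the pointwise spectral information -log2(mf) (bits).

    Zero-mass bins are excluded from the band mean; an all-zero band yields NaN.
    """
    out = np.full(bands.n_bands, np.nan)
    ie = np.where(mf > 0, -np.log2(np.where(mf > 0, mf, 1.0)), np.nan)
    for b, mask in enumerate(bands.masks(freqs)):
        vals = ie[mask]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            warnings.warn(f"band {b + 1} has no nonzero bins; IE_Bn{b + 1} is NaN")
            continue
        out[b] = float(vals.mean())
    return out


def kurtosis_feature(m: Marginals) -> float:
    """Standardized 4th central moment of the time marginal."""
    p = m.mt
    idx = np.arange(len(p), dtype=np.float64)
    mu = float(p @ idx)
    var = float(p @ (idx - mu) ** 2)
    if var <= 0:
        raise DegenerateInputError("time marginal has zero variance")
    return float(p @ ((idx - mu) / np.sqrt(var)) ** 4)


def extract_tf_features(
    seg: Segment,
    bands: BandScheme = DEFAULT_BANDS,
    sigma: float = 1.0,
    use_analytic: bool = True,
    time_step: int = 4,
    moment_orders: tuple = ((1, 1), (7, 7), (15, 15)),
) -> dict[str, float]:
    """Full TF path: WD -> Choi-Williams -> marginals -> pD -> 35 features."""
    wd = wigner_distribution(seg, use_analytic=use_analytic, time_step=time_step)
    cwdn = choi_williams(wd, sigma=sigma)
    marg = marginals(cwdn)
    pd_grid = joint_density(marg)

    e_bn, _ = band_energy(pd_grid, bands)
    f_cres = band_freq_peak(pd_grid, bands)
    f_med = band_freq_mean(pd_grid, bands)
    h_t, h_f, h_tf = entropies(marg)
    ie_bn = spectral_information(marg.mf, marg.freqs, bands)
    k = kurtosis_feature(marg)
    moments = joint_moments(cwdn, orders=moment_orders)

    values: dict[str, float] = {}
    for b in range(bands.n_bands):
        values[f"E_Bn{b + 1}"] = float(e_bn[b])
    for b in range(bands.n_bands):
        values[f"f_Cres{b + 1}"] = float(f_cres[b])
    for b in range(bands.n_bands):
        values[f"f_Med{b + 1}"] = float(f_med[b])
    values["H_t"], values["H_f"], values["H_tf"] = h_t, h_f, h_tf
    for b in range(bands.n_bands):
        values[f"IE_Bn{b + 1}"] = float(ie_bn[b])
    values["K"] = k
    values.update(moments)
    assert tuple(values) == TF_FEATURE_NAMES
    return values
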