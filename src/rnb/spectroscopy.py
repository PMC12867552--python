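"""Epoch-ensemble spectral summaries of rhythmic series.

"Spectroscopy" here means the joint description of (1) the distribution of
scale-free exponents ``beta*`` across epochs and (2) the across-epoch
average Fourier spectrum of the rhythmic component.  The dyadic wavelet
scales are too coarse to serve as a spectrum, so the rhythmic series are
taken back to the Fourier domain: single-taper (Hann) periodograms per
epoch, averaged across epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

from rnb.core import RhythmicEpoch


@dataclass
class SpectroscopyResult:
    """Frequency grid, per-epoch and mean rhythmic PSD, and the ``beta*``
    ensemble with its Gaussian kernel density."""

    freq: np.ndarray
    psd_epochs: np.ndarray            # (n_epochs, n_freq)
    psd_mean: np.ndarray
    beta_values: np.ndarray
    beta_density: object | None       # gaussian_kde over beta, or None

    @property
    def n_epochs(self) -> int:
        return self.psd_epochs.shape[0]


def periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann-taper periodogram (power spectral density).

    The Hann taper suppresses leakage from residual epoch edges; density
    scaling keeps the integral of the PSD equal to the signal variance.
    """
    return _sig.periodogram(x, fs=fs, window="hann", detrend="constant")


def _epoch_series(e, which: str) -> np.ndarray:
    if isinstance(e, RhythmicEpoch):
        return e.s_R if which == "rhythmic" else e.s_denoised
    return np.asarray(e, dtype=float)


def rhythmic_spectra(epochs, fs: float, series: str = "rhythmic") -> SpectroscopyResult:
    """Ensemble spectroscopy of a list of epochs.

    ``epochs`` may be `RhythmicEpoch` objects or plain arrays (raw series).
    ``series`` selects which reconstruction of a `RhythmicEpoch` is used:
    ``"rhythmic"`` (whitened ``s_R``) or ``"denoised"`` (shrinkage-only,
    original amplitude units).
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch")
    arrays = [_epoch_series(e, series) for e in epochs]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("heterogeneous epoch lengths")
    psds = []
    for a in arrays:
        f, p = periodogram(a, fs)
        psds.append(p)
    psd_epochs = np.vstack(psds)
    betas = np.array(
        [e.beta_star for e in epochs if isinstance(e, RhythmicEpoch)], dtype=float
    )
    kde = None
    if betas.size >= 2 and np.ptp(betas) > 0:
        kde = _stats.gaussian_kde(betas, bw_method="silverman")
    return SpectroscopyResult(
        freq=f,
        psd_epochs=psd_epochs,
        psd_mean=psd_epochs.mean(axis=0),
        beta_values=betas,
        beta_density=kde,
    )


def find_peaks(
    result: SpectroscopyResult, fmin: float, fmax: float, min_prominence: float = 1.0
) -> list[tuple[float, float]]:
    """Prominence-filtered local maxima of the mean rhythmic PSD in a band.

    ``min_prominence`` is a factor of the median in-band PSD; a peak needs
    strict inequality against both neighbors (plateaus are not peaks).
    Returns (frequency, power) pairs sorted by power, descending.
    """
    if fmin >= fmax:
        raise ValueError("empty band: fmin must be < fmax")
    mask = (result.freq >= fmin) & (result.freq <= fmax)
    if not np.any(mask):
        raise ValueError("band outside the frequency grid")
    p = result.psd_mean[mask]
    f = result.freq[mask]
    # the median floor degenerates on sparse (near-zero) spectra; a tiny
    # fraction of the band maximum keeps numerical wiggles out
    floor = max(float(np.median(p)), 1e-9 * float(p.max(initial=0.0)))
    idx, _ = _sig.find_peaks(p, prominence=min_prominence * floor, plateau_size=(None, 1))
    return sorted(((float(f[i]), float(p[i])) for i in idx), key=lambda t: -t[1])


def band_amplitude(
    result: SpectroscopyResult, band: tuple[float, float], mode: str = "peak"
) -> float:
    """Band readout of the mean rhythmic PSD.

    ``mode="peak"`` returns the maximal in-band PSD (the "maximal rhythmic
    amplitude" readout); ``mode="integral"`` the trapezoidal band power.
    """
    lo, hi = band
    mask = (result.freq >= lo) & (result.freq <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} outside the frequency grid")
    p = result.psd_mean[mask]
    if mode == "peak":
        return float(p.max())
    if mode == "integral":
        return float(np.trapezoid(p, result.freq[mask]))
    raise ValueError(f"unknown mode {mode!r}")


def band_peak_amplitude(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Maximal Hann-periodogram PSD of a single series inside ``band``.

    The per-epoch amplitude readout used by the simulation recovery
    experiments; shares the estimator of `rhythmic_spectra` so oscillation
    amplitude levels and readouts live on the same scale.
    """
    f, p = periodogram(np.asarray(x, dtype=float), fs)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} outside the frequency grid")
    return float(p[mask].max())


def write_tables(result: SpectroscopyResult, prefix: str) -> list[str]:
    """Write the spectroscopy tables as TSV: (freq, psd_mean) and
    (epoch_id, beta_star).  Returns the written paths."""
    import pandas as pd

    p1 = f"{prefix}_psd.tsv"
    pd.DataFrame({"freq": result.freq, "psd_mean": result.psd_mean}).to_csv(
        p1, sep="\t", index=False
    )
    paths = [p1]
    if result.beta_values.size:
        p2 = f"{prefix}_beta.tsv"
        pd.DataFrame(
            {"epoch_id": np.arange(result.beta_values.size), "beta_star": result.beta_values}
        ).to_csv(p2, sep="\t", index=False)
        paths.append(p2)
    return paths
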