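"""Welch power spectra, wavelet spectrograms, dB conversion and band powers.

Conventions follow the analysis pipeline this package implements: Welch PSD
with 2 s Hamming windows and 50 % overlap; continuous-wavelet spectrograms in
5 s segments on a 1-90 Hz grid at 1 Hz resolution; decibel conversion via
20*log10 by default (the ``power10`` convention, 10*log10, is available);
band powers as the arithmetic mean of the linear PSD over each band, converted
to dB afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "PowerSpectrum",
    "Spectrogram",
    "welch_psd",
    "to_decibels",
    "cwt_spectrogram",
    "band_power",
    "average_channels",
    "DB_FLOOR",
]

#: dB value reported for exactly-zero power (log10 undefined); far below any
#: physical value so it reads as "off scale" rather than as data.
DB_FLOOR = -120.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, half-open interval [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: need lo < hi, got [{self.lo}, {self.hi})")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.lo) & (freqs < self.hi)


#: The canonical LFP bands: delta, theta, alpha, beta, low gamma, high gamma.
#: Half-open intervals keep the shared 4 and 8 Hz edges unambiguous; the
#: 12-15 Hz gap between alpha and beta is part of the definition, not bridged.
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 30.0),
    BandDefinition("low_gamma", 30.0, 50.0),
    BandDefinition("high_gamma", 50.0, 90.0),
)


def to_decibels(values: np.ndarray | float, floor_db: float = DB_FLOOR,
                convention: str = "amplitude20") -> np.ndarray:
    """Convert non-negative linear power values to decibels.

    ``amplitude20`` (default) applies 20*log10, ``power10`` applies 10*log10.
    Zeros map to ``floor_db``; negative input is an error.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("decibel conversion requires non-negative values")
    if convention == "amplitude20":
        factor = 20.0
    elif convention == "power10":
        factor = 10.0
    else:
        raise ValueError(f"unknown dB convention {convention!r}")
    out = np.full_like(v, floor_db, dtype=float)
    nz = v > 0
    out[nz] = factor * np.log10(v[nz])
    return out if out.ndim else float(out)


@dataclass
class PowerSpectrum:
    """Welch power spectral density: linear density plus its dB image."""

    freqs: np.ndarray
    psd: np.ndarray
    psd_db: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(x: np.ndarray, fs: float, window_s: float = 2.0,
              overlap: float = 0.5, db_convention: str = "amplitude20",
              db_floor: float = DB_FLOOR) -> PowerSpectrum:
    """Welch PSD with Hamming tapers of ``window_s`` seconds and fractional overlap.

    Density normalisation: the integral of ``psd`` over [0, fs/2] equals the
    signal variance (up to estimator noise).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(f"signal ({x.size} samples) shorter than one "
                         f"{window_s} s window ({nperseg} samples)")
    freqs, psd = sps.welch(x, fs=fs, window="hamming", nperseg=nperseg,
                           noverlap=int(round(overlap * nperseg)),
                           detrend="constant", scaling="density")
    return PowerSpectrum(freqs=freqs, psd=psd,
                         psd_db=to_decibels(psd, db_floor, db_convention))


@dataclass
class Spectrogram:
    """Time-frequency power from a segmented continuous wavelet transform.

    ``power_db`` has one row per segment (``times`` holds segment centres in
    seconds) and one column per frequency of the 1 Hz grid.
    """

    times: np.ndarray
    freqs: np.ndarray
    power_db: np.ndarray


def cwt_spectrogram(x: np.ndarray, fs: float, segment_s: float = 5.0,
                    f_lo: float = 1.0, f_hi: float = 90.0, f_step: float = 1.0,
                    wavelet: str = "cmor6.0-1.0",
                    db_convention: str = "amplitude20") -> Spectrogram:
    """Complex-Morlet CWT power per ``segment_s`` segment on a fixed Hz grid.

    The record is divided into consecutive non-overlapping segments; within
    each, the squared wavelet magnitude is averaged over time, giving one
    spectrogram row per segment.  The default mother wavelet (complex Morlet,
    time-bandwidth 6) is narrow enough in frequency that a pure tone peaks in
    its own 1 Hz grid row; shorter wavelets skew the peak by the scale
    normalisation.
    """
    x = np.asarray(x, dtype=float)
    seg_len = int(round(segment_s * fs))
    if x.size < seg_len:
        raise ValueError(f"signal shorter than one {segment_s} s segment")
    freqs = np.arange(f_lo, f_hi + 0.5 * f_step, f_step)
    if freqs[-1] >= fs / 2:
        raise ValueError("spectrogram frequency grid reaches the Nyquist rate")
    scales = pywt.frequency2scale(wavelet, freqs / fs)
    n_segments = x.size // seg_len
    power = np.empty((n_segments, freqs.size))
    for k in range(n_segments):
        seg = x[k * seg_len:(k + 1) * seg_len]
        coefs, _ = pywt.cwt(seg, scales, wavelet, sampling_period=1.0 / fs,
                            method="fft")
        power[k] = np.mean(np.abs(coefs) ** 2, axis=1)
    times = (np.arange(n_segments) + 0.5) * segment_s
    return Spectrogram(times=times, freqs=freqs,
                       power_db=to_decibels(power, convention=db_convention))


def band_power(ps: PowerSpectrum, bands: Iterable[BandDefinition] = CANONICAL_BANDS,
               db_convention: str = "amplitude20") -> pd.DataFrame:
    """Mean linear PSD per band, with its dB conversion.

    Averaging is done on the linear scale; the dB column is the dB of the mean
    (never a mean of dB values).  A band containing no grid frequency is an
    error.
    """
    rows = []
    for band in bands:
        mask = band.contains(ps.freqs)
        if not mask.any():
            raise ValueError(f"band {band.name} [{band.lo}, {band.hi}) contains "
                             f"no frequency grid point (df={ps.df} Hz)")
        mean_power = float(np.mean(ps.psd[mask]))
        rows.append({"band": band.name, "power": mean_power,
                     "power_db": float(to_decibels(mean_power,
                                                   convention=db_convention))})
    return pd.DataFrame(rows)


def average_channels(per_channel: Mapping[str, float] | Sequence[float] | np.ndarray) -> float:
    """Arithmetic mean of a derived metric over channels (the subject-level value)."""
    if isinstance(per_channel, Mapping):
        values = np.asarray(list(per_channel.values()), dtype=float)
    else:
        values = np.asarray(per_channel, dtype=float)
    if values.size == 0:
        raise ValueError("no channels to average")
    return float(np.mean(values))
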