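"""Signal conditioning chain: downsample, 50 Hz notch, drift removal, 1-90 Hz bandpass.

The stages are applied per channel, in that order.  All IIR filters default to
zero-phase (forward-backward) application: instantaneous phase downstream of
this chain feeds the phase-amplitude coupling estimator, and any phase lag
introduced here would corrupt it.  A single-pass (causal) mode is available
via ``zero_phase=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

__all__ = [
    "PreprocessConfig",
    "downsample",
    "notch_filter",
    "remove_baseline_drift",
    "bandpass",
    "preprocess_recording",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning parameters.

    Defaults: 50 Hz notch of 3 Hz bandwidth (Q = f0/bw), order-5 polynomial
    drift removal over the whole record, order-2 Butterworth bandpass at
    1-90 Hz, target rate 1 kHz, zero-phase filtering.
    """

    notch_freq: float = 50.0
    notch_bandwidth: float = 3.0
    drift_poly_order: int = 5
    band_lo: float = 1.0
    band_hi: float = 90.0
    iir_order: int = 2
    target_fs: float = 1000.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < self.target_fs / 2:
            raise ValueError(f"need 0 < band_lo < band_hi < target_fs/2, got "
                             f"({self.band_lo}, {self.band_hi}) at fs {self.target_fs}")
        if not self.notch_freq < self.target_fs / 2:
            raise ValueError("notch frequency must be below Nyquist")


def _apply_sos(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    return sps.sosfiltfilt(sos, x) if zero_phase else sps.sosfilt(sos, x)


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass (cutoff 0.45*fs_out) then integer decimation.

    Requires ``fs_in`` to be an integer multiple of ``fs_out`` (non-integer
    resampling is out of scope).  Output length is floor(n * fs_out / fs_in).
    """
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    ratio = fs_in / fs_out
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(f"fs_in={fs_in} is not an integer multiple of fs_out={fs_out}")
    sos = sps.butter(8, 0.45 * fs_out, btype="lowpass", fs=fs_in, output="sos")
    y = sps.sosfiltfilt(sos, x)[::q]
    n_out = int(x.shape[-1] * fs_out // fs_in)
    return y[..., :n_out]


def notch_filter(x: np.ndarray, fs: float, f0: float = 50.0, bw: float = 3.0,
                 zero_phase: bool = True) -> np.ndarray:
    """Second-order IIR notch at ``f0`` with quality factor Q = f0/bw."""
    if f0 >= fs / 2:
        raise ValueError(f"notch frequency {f0} Hz at or above Nyquist ({fs / 2} Hz)")
    b, a = sps.iirnotch(f0, Q=f0 / bw, fs=fs)
    sos = sps.tf2sos(b, a)
    return _apply_sos(sos, np.asarray(x, dtype=float), zero_phase)


def remove_baseline_drift(x: np.ndarray, fs: float, poly_order: int = 5) -> np.ndarray:
    """Fit and subtract a least-squares polynomial in time of the given order.

    Order 0 is mean subtraction.  The fit uses a Chebyshev basis on the
    normalised time axis for numerical stability; the subtracted curve is the
    same least-squares polynomial either way.
    """
    x = np.asarray(x, dtype=float)
    if poly_order >= x.shape[-1]:
        raise ValueError("polynomial order must be below the sample count")
    t = np.linspace(-1.0, 1.0, x.shape[-1])
    fit = np.polynomial.chebyshev.Chebyshev.fit(t, x, deg=poly_order)
    return x - fit(t)


def bandpass(x: np.ndarray, fs: float, lo: float = 1.0, hi: float = 90.0,
             order: int = 2, zero_phase: bool = True) -> np.ndarray:
    """Butterworth IIR bandpass of the given order between ``lo`` and ``hi`` Hz."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid bandpass corners ({lo}, {hi}) at fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return _apply_sos(sos, np.asarray(x, dtype=float), zero_phase)


def preprocess_recording(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Condition every channel: downsample -> notch -> drift removal -> bandpass."""
    if rec.fs < cfg.target_fs:
        raise ValueError(f"recording rate {rec.fs} Hz below target {cfg.target_fs} Hz")
    channels = []
    for ch in rec.samples:
        y = downsample(ch, rec.fs, cfg.target_fs)
        y = notch_filter(y, cfg.target_fs, cfg.notch_freq, cfg.notch_bandwidth,
                         cfg.zero_phase)
        y = remove_baseline_drift(y, cfg.target_fs, cfg.drift_poly_order)
        y = bandpass(y, cfg.target_fs, cfg.band_lo, cfg.band_hi, cfg.iir_order,
                     cfg.zero_phase)
        channels.append(y)
    return rec.with_samples(np.vstack(channels), fs=cfg.target_fs)
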