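"""Phase-amplitude coupling: phase-binned amplitude distributions, the
KL-divergence modulation index, and cross-frequency comodulograms.

The estimator quantifies how strongly the phase of a slow oscillation (e.g.
theta, 4-8 Hz) modulates the amplitude envelope of a fast one (e.g. low gamma
30-50 Hz or high gamma 50-90 Hz):

1. zero-phase bandpass the signal to the phase band and take the
   instantaneous phase of the analytic signal (Hilbert transform), and to the
   amplitude band taking the analytic-signal modulus (envelope);
2. partition the phase circle into ``n_bins`` equal bins (default 18 bins of
   20 degrees) and average the envelope within each bin, giving mean
   amplitudes ``a_j``;
3. normalise ``p_j = a_j / sum_k a_k`` -- a probability-like distribution over
   phase bins;
4. the modulation index is the Kullback-Leibler divergence of ``p`` from the
   uniform distribution, normalised by its maximum: ``MI = KL(p, U) / log N``
   with ``KL = sum_j p_j log(p_j N)`` and ``0 log 0 := 0``.  MI = 0 for a flat
   distribution (no coupling), MI = 1 when all amplitude mass concentrates in
   a single phase bin.

MI is invariant to global amplitude scaling of the input and to the base of
the logarithm.  Phases are cosine-referenced: a pure cosine has phase 0 at
its peak.  Filter edge transients are excluded from binning (1 s at each end
by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "PhaseAmplitudeDistribution",
    "MIResult",
    "ComodulogramGrid",
    "extract_phase",
    "extract_amplitude",
    "phase_amplitude_distribution",
    "modulation_index",
    "compute_mi",
    "comodulogram",
    "phase_binned_amplitude_map",
]


def _bandpass_zero_phase(x: np.ndarray, fs: float, band: tuple[float, float],
                         order: int = 4) -> np.ndarray:
    # order 4 forward-backward (effective order 8): narrow PAC bands need
    # steep edges, or out-of-band carrier leakage beats against modulation
    # sidebands and smears the comodulogram
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at fs={fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def extract_phase(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous phase (radians in [-pi, pi)) of the band-limited analytic signal."""
    return np.angle(sps.hilbert(_bandpass_zero_phase(x, fs, band)))


def extract_amplitude(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Instantaneous amplitude envelope (analytic-signal modulus) in the band."""
    return np.abs(sps.hilbert(_bandpass_zero_phase(x, fs, band)))


@dataclass
class PhaseAmplitudeDistribution:
    """Mean fast-oscillation amplitude per phase bin, and its normalisation.

    ``bin_edges`` are in degrees over [0, 360]; bin ``j`` covers
    [edges[j], edges[j+1]).  ``p`` sums to one.
    """

    n_bins: int
    bin_edges: np.ndarray
    mean_amp: np.ndarray
    p: np.ndarray

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def phase_amplitude_distribution(phase: np.ndarray, amplitude: np.ndarray,
                                 n_bins: int = 18) -> PhaseAmplitudeDistribution:
    """Bin amplitudes by phase and normalise to a probability-like distribution.

    ``a_j`` is the mean of the amplitude samples whose phase falls in bin
    ``j`` (empty bins get 0); ``p_j = a_j / sum_k a_k``.  If every mean
    amplitude is zero the distribution is defined as uniform (no amplitude,
    hence no preferential phase).
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.size == 0 or amplitude.size == 0:
        raise ValueError("phase and amplitude series must be non-empty")
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    frac = np.mod(phase, 2.0 * np.pi) / (2.0 * np.pi)
    idx = np.minimum((frac * n_bins).astype(np.intp), n_bins - 1)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    mean_amp = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    total = mean_amp.sum()
    p = mean_amp / total if total > 0 else np.full(n_bins, 1.0 / n_bins)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    return PhaseAmplitudeDistribution(n_bins=n_bins, bin_edges=edges,
                                      mean_amp=mean_amp, p=p)


@dataclass
class MIResult:
    """Modulation index between one phase band and one amplitude band."""

    phase_band: tuple[float, float]
    amp_band: tuple[float, float]
    mi: float
    kl: float
    pad: PhaseAmplitudeDistribution


def modulation_index(pad: PhaseAmplitudeDistribution) -> tuple[float, float]:
    """KL divergence from uniform (nats) and the normalised modulation index.

    ``kl = sum_j p_j log(p_j N)`` with ``0 log 0 := 0``; ``mi = kl / log N``,
    bounded in [0, 1].
    """
    p = pad.p
    n = pad.n_bins
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n)))
    kl = max(kl, 0.0)  # guard round-off on near-uniform distributions
    mi = kl / np.log(n)
    return kl, min(mi, 1.0)


def compute_mi(x: np.ndarray, fs: float, phase_band: tuple[float, float],
               amp_band: tuple[float, float], n_bins: int = 18,
               edge_s: float = 1.0) -> MIResult:
    """Full MI estimate between two bands of one signal.

    ``edge_s`` seconds at each end of the record are excluded from binning
    (filter and Hilbert edge transients distort phase and envelope there).
    """
    if phase_band[1] > amp_band[0]:
        warnings.warn(f"phase band {phase_band} and amplitude band {amp_band} "
                      "overlap; MI may be inflated by filter leakage",
                      stacklevel=2)
    phase = extract_phase(x, fs, phase_band)
    amplitude = extract_amplitude(x, fs, amp_band)
    k = int(round(edge_s * fs))
    if 2 * k < phase.size and k > 0:
        phase, amplitude = phase[k:-k], amplitude[k:-k]
    pad = phase_amplitude_distribution(phase, amplitude, n_bins)
    kl, mi = modulation_index(pad)
    return MIResult(phase_band=tuple(phase_band), amp_band=tuple(amp_band),
                    mi=mi, kl=kl, pad=pad)


@dataclass
class ComodulogramGrid:
    """MI over a grid of (phase frequency, amplitude frequency) band pairs."""

    phase_centers: np.ndarray
    amp_centers: np.ndarray
    phase_bandwidth: float
    amp_bandwidth: float
    mi_matrix: np.ndarray  # shape (n_phase, n_amp)

    def argmax(self) -> tuple[float, float]:
        """(phase centre, amplitude centre) of the strongest coupling cell."""
        i, j = np.unravel_index(np.argmax(self.mi_matrix), self.mi_matrix.shape)
        return float(self.phase_centers[i]), float(self.amp_centers[j])


def comodulogram(x: np.ndarray, fs: float,
                 phase_lo: float = 2.0, phase_hi: float = 12.0,
                 phase_step: float = 1.0, phase_bw: float = 2.0,
                 amp_lo: float = 20.0, amp_hi: float = 100.0,
                 amp_step: float = 5.0, amp_bw: float = 10.0,
                 n_bins: int = 18, edge_s: float = 1.0) -> ComodulogramGrid:
    """MI matrix over narrow-filtered frequency pairs.

    Phase bands: centres ``phase_lo..phase_hi`` every ``phase_step`` Hz,
    ``phase_bw`` Hz wide; amplitude bands: centres ``amp_lo..amp_hi`` every
    ``amp_step`` Hz, ``amp_bw`` Hz wide.  Each phase and amplitude series is
    extracted once and reused across pairs.
    """
    x = np.asarray(x, dtype=float)
    phase_centers = np.arange(phase_lo, phase_hi + 0.5 * phase_step, phase_step)
    amp_centers = np.arange(amp_lo, amp_hi + 0.5 * amp_step, amp_step)
    if amp_centers[-1] + amp_bw / 2 >= fs / 2:
        raise ValueError("amplitude grid reaches the Nyquist rate")
    k = int(round(edge_s * fs))
    sl = slice(k, x.size - k) if (k > 0 and 2 * k < x.size) else slice(None)
    phases = [extract_phase(x, fs, (c - phase_bw / 2, c + phase_bw / 2))[sl]
              for c in phase_centers]
    amps = [extract_amplitude(x, fs, (c - amp_bw / 2, c + amp_bw / 2))[sl]
            for c in amp_centers]
    mi = np.empty((phase_centers.size, amp_centers.size))
    for i, ph in enumerate(phases):
        for j, am in enumerate(amps):
            pad = phase_amplitude_distribution(ph, am, n_bins)
            mi[i, j] = modulation_index(pad)[1]
    return ComodulogramGrid(phase_centers=phase_centers, amp_centers=amp_centers,
                            phase_bandwidth=phase_bw, amp_bandwidth=amp_bw,
                            mi_matrix=mi)


def phase_binned_amplitude_map(x: np.ndarray, fs: float,
                               phase_band: tuple[float, float],
                               amp_band: tuple[float, float],
                               cycles: int = 2, n_bins: int = 18,
                               edge_s: float = 1.0) -> np.ndarray:
    """Normalised amplitude per 20-degree phase bin tiled over ``cycles`` cycles.

    The 18-bin distribution repeated over (by default) 0-720 degrees, the
    standard display of phase preference.
    """
    res = compute_mi(x, fs, phase_band, amp_band, n_bins=n_bins, edge_s=edge_s)
    return np.tile(res.pad.p, cycles)
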