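"""Seeded synthetic LFP generator with known ground truth.

The generator produces signals with the statistical structure the analysis
pipeline assumes, so that every estimator in the package can be validated
against known parameters:

* a 1/f^alpha Gaussian background (white noise shaped in the frequency
  domain), the dominant broadband component of extracellular recordings;
* narrowband oscillations in the canonical bands, realised as band-limited
  filtered noise (so Welch band powers are realistically spread) except for
  the theta band, which is a coherent sinusoidal carrier;
* one or more phase-amplitude coupled components: a fast tone whose
  instantaneous amplitude follows ``amp_base * (1 - kappa + kappa *
  (1 + cos(phi_theta - preferred_phase)) / 2)`` where ``phi_theta`` is the
  carrier's cosine-convention phase and ``kappa`` in [0, 1] is the coupling
  depth (kappa = 0: constant envelope, no coupling; kappa = 1: envelope
  reaches zero at the anti-preferred phase);
* 50 Hz line contamination and a slow polynomial baseline drift
  (instrumental artefacts, targets of the preprocessing chain);
* cohort structure: groups x subjects x channels with per-group
  multiplicative attenuation of oscillatory power and of coupling depth, and
  log-normal per-subject gain jitter.

Reproducibility: every random draw comes from a substream derived by
``numpy.random.SeedSequence(seed, spawn_key=(group, subject, channel))``, so
identical spec + seed gives bit-identical output and channels are
statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Recording, write_recording
from .spectral import CANONICAL_BANDS

__all__ = [
    "CouplingSpec",
    "SyntheticCohortSpec",
    "CohortBundle",
    "generate_coupled_signal",
    "generate_subject_recording",
    "generate_cohort",
    "pink_noise",
    "write_cohort",
]


@dataclass(frozen=True)
class CouplingSpec:
    """Ground truth for one phase-amplitude coupled component.

    ``preferred_phase`` (radians, cosine convention) is the slow-carrier phase
    at which the fast component's envelope is maximal.
    """

    f_phase: float
    f_amp: float
    kappa: float
    amp_base: float = 1.0
    preferred_phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if not 0.0 < self.f_phase < self.f_amp:
            raise ValueError(
                f"need f_amp > f_phase > 0, got f_phase={self.f_phase}, f_amp={self.f_amp}")
        if self.amp_base < 0:
            raise ValueError("amp_base must be non-negative")


def _default_band_amplitudes() -> dict[str, float]:
    # Theta-dominated resting hippocampal profile, arbitrary voltage units.
    return {"delta": 0.6, "theta": 1.0, "alpha": 0.4, "beta": 0.3,
            "low_gamma": 0.25, "high_gamma": 0.2}


def _default_coupling() -> tuple[CouplingSpec, ...]:
    # Theta carrier at 6 Hz modulating a low-gamma and a high-gamma tone.
    return (CouplingSpec(f_phase=6.0, f_amp=40.0, kappa=0.6, amp_base=0.3,
                         preferred_phase=np.pi / 2),
            CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=0.6, amp_base=0.25,
                         preferred_phase=np.pi / 2))


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Full parameterisation of a synthetic cohort (the ground-truth manifest source).

    Defaults emulate the study design the pipeline is built for: three groups
    (control, a power-attenuated group, and a group with both power and
    coupling attenuation) of six subjects, eight channels each, 5 min at
    1 kHz.  ``group_power_factors`` scale all oscillatory components and the
    1/f background (diseased recordings show a globally reduced spectrum);
    ``group_kappa_factors`` scale only the coupling depth.  Line noise and
    drift are instrumental and are never scaled.
    """

    n_groups: int = 3
    n_subjects_per_group: int = 6
    n_channels: int = 8
    duration_s: float = 300.0
    fs: float = 1000.0
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    coupling: CouplingSpec | tuple[CouplingSpec, ...] = field(default_factory=_default_coupling)
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    line_noise_amp: float = 0.5
    drift_coeffs: tuple[float, ...] = (0.0, 2.0, -1.0, 0.5)
    group_power_factors: tuple[float, ...] = (1.0, 0.6, 0.5)
    group_kappa_factors: tuple[float, ...] = (1.0, 1.0, 0.3)
    subject_sigma: float = 0.1
    group_labels: tuple[str, ...] = ("control", "ad_mild", "ad_severe")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_power_factors) != self.n_groups:
            raise ValueError("group_power_factors must have one entry per group")
        if len(self.group_kappa_factors) != self.n_groups:
            raise ValueError("group_kappa_factors must have one entry per group")
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels must have one entry per group")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")
        if any(f < 0 for f in self.group_power_factors + self.group_kappa_factors):
            raise ValueError("group factors must be non-negative")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")
        for c in self.couplings:
            if c.f_amp >= self.fs / 2:
                raise ValueError(f"coupled tone at {c.f_amp} Hz is at or above "
                                 f"Nyquist ({self.fs / 2} Hz)")

    @property
    def couplings(self) -> tuple[CouplingSpec, ...]:
        c = self.coupling
        return (c,) if isinstance(c, CouplingSpec) else tuple(c)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent Gaussian noise (white noise shaped in frequency)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(n: int, fs: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Band-limited Gaussian noise with unit RMS, centred on [lo, hi]."""
    from scipy import signal as sps

    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _coupled_pair(spec: CouplingSpec, t: np.ndarray, carrier_phase: float,
                  tone_phase: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude slow carrier and the modulated fast tone.

    The carrier is cosine-referenced so its Hilbert (analytic-signal) phase is
    exactly the argument below; the fast tone's envelope peaks where that
    phase equals ``preferred_phase``.
    """
    phi = 2.0 * np.pi * spec.f_phase * t + carrier_phase
    slow = np.cos(phi)
    envelope = spec.amp_base * (1.0 - spec.kappa
                                + spec.kappa * (1.0 + np.cos(phi - spec.preferred_phase)) / 2.0)
    fast = envelope * np.cos(2.0 * np.pi * spec.f_amp * t + tone_phase)
    return slow, fast


def generate_coupled_signal(spec: CouplingSpec, duration_s: float, fs: float,
                            noise_amp: float = 0.0, seed: int = 0) -> np.ndarray:
    """Single-channel benchmark signal: slow carrier + coupled fast tone + 1/f noise.

    Returns the sum of a unit-amplitude carrier at ``f_phase``, a fast tone at
    ``f_amp`` whose envelope is ``amp_base * (1 - kappa + kappa *
    (1 + cos(phi - preferred_phase)) / 2)`` with ``phi`` the carrier phase,
    and 1/f-shaped Gaussian noise scaled by ``noise_amp``.  Deterministic
    given ``seed``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if spec.f_amp >= fs / 2:
        raise ValueError(f"f_amp={spec.f_amp} Hz is at or above Nyquist ({fs / 2} Hz)")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    slow, fast = _coupled_pair(spec, t, carrier_phase=0.0, tone_phase=0.0)
    x = slow + fast
    if noise_amp > 0:
        x = x + noise_amp * pink_noise(n, 1.0, _substream(seed, 0))
    return x


def _band_lookup(name: str):
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band name {name!r}; canonical bands are "
                   f"{[b.name for b in CANONICAL_BANDS]}")


def _subject_gain(spec: SyntheticCohortSpec, group_index: int,
                  subject_index: int) -> float:
    rng = _substream(spec.seed, group_index, subject_index)
    return float(np.exp(spec.subject_sigma * rng.standard_normal()))


def generate_subject_recording(spec: SyntheticCohortSpec, group_index: int,
                               subject_index: int) -> Recording:
    """One subject's multichannel recording under the cohort's group effects.

    Each channel is an independent realisation (own noise substream and own
    random gamma-tone phases) of: theta carrier + coupled fast tones +
    narrowband oscillations in the remaining canonical bands + 1/f background,
    all scaled by the group power factor and the subject gain, plus unscaled
    50 Hz line noise and polynomial baseline drift.
    """
    if not 0 <= group_index < spec.n_groups:
        raise IndexError(f"group_index {group_index} outside 0..{spec.n_groups - 1}")
    if not 0 <= subject_index < spec.n_subjects_per_group:
        raise IndexError(f"subject_index {subject_index} outside "
                         f"0..{spec.n_subjects_per_group - 1}")
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    g_pow = spec.group_power_factors[group_index]
    g_kap = spec.group_kappa_factors[group_index]
    gain = _subject_gain(spec, group_index, subject_index)
    scale = g_pow * gain

    u = 2.0 * t / spec.duration_s - 1.0  # normalized time in [-1, 1]
    drift = np.polynomial.polynomial.polyval(u, np.asarray(spec.drift_coeffs, dtype=float))
    line = spec.line_noise_amp * np.sin(2.0 * np.pi * 50.0 * t)

    theta_amp = spec.band_amplitudes.get("theta", 0.0)
    carrier_freqs = sorted({c.f_phase for c in spec.couplings})

    channels = np.empty((spec.n_channels, n), dtype=np.float32)
    for ch in range(spec.n_channels):
        rng = _substream(spec.seed, group_index, subject_index, ch)
        carrier_phases = {f: rng.uniform(0.0, 2.0 * np.pi) for f in carrier_freqs}
        x = np.zeros(n)
        # Shared theta carrier(s), coherent within the channel.
        for f in carrier_freqs:
            x += theta_amp * np.cos(2.0 * np.pi * f * t + carrier_phases[f])
        # Coupled fast tones, phase-incoherent across channels.
        for c in spec.couplings:
            eff = replace(c, kappa=min(c.kappa * g_kap, 1.0))
            _, fast = _coupled_pair(eff, t, carrier_phase=carrier_phases[c.f_phase],
                                    tone_phase=rng.uniform(0.0, 2.0 * np.pi))
            x += fast
        # Remaining bands as narrowband noise (RMS = amplitude / sqrt(2),
        # matching the RMS of a sinusoid of that amplitude).
        for name, amp in spec.band_amplitudes.items():
            if name == "theta" or amp <= 0:
                continue
            band = _band_lookup(name)
            x += (amp / np.sqrt(2.0)) * _narrowband_noise(n, spec.fs, band.lo,
                                                          band.hi, rng)
        x += spec.noise_amp * pink_noise(n, spec.noise_exponent, rng)
        channels[ch] = (scale * x + line + drift).astype(np.float32)

    label = spec.group_labels[group_index]
    return Recording(samples=channels, fs=spec.fs,
                     channel_labels=[f"ch{ch}" for ch in range(spec.n_channels)],
                     subject_id=f"g{group_index}s{subject_index}", group=label)


@dataclass
class CohortBundle:
    """All recordings of a cohort plus the ground-truth manifest (one row per subject)."""

    spec: SyntheticCohortSpec
    recordings: list[Recording]
    manifest: pd.DataFrame


def generate_cohort(spec: SyntheticCohortSpec) -> CohortBundle:
    """Generate every subject of the cohort and the manifest of true parameters."""
    recordings: list[Recording] = []
    rows = []
    for gi in range(spec.n_groups):
        for si in range(spec.n_subjects_per_group):
            rec = generate_subject_recording(spec, gi, si)
            recordings.append(rec)
            gain = _subject_gain(spec, gi, si)
            row = {
                "group": spec.group_labels[gi],
                "group_index": gi,
                "subject_id": rec.subject_id,
                "power_factor": spec.group_power_factors[gi],
                "kappa_factor": spec.group_kappa_factors[gi],
                "subject_gain": gain,
                "seed": spec.seed,
            }
            for name, amp in spec.band_amplitudes.items():
                row[f"amp_{name}"] = amp * spec.group_power_factors[gi] * gain
            for c in spec.couplings:
                row[f"kappa_{int(round(c.f_phase))}_{int(round(c.f_amp))}"] = \
                    min(c.kappa * spec.group_kappa_factors[gi], 1.0)
            rows.append(row)
    return CohortBundle(spec=spec, recordings=recordings,
                        manifest=pd.DataFrame(rows))


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write each recording to the native container plus ``manifest.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in bundle.recordings:
        write_recording(rec, outdir / f"{rec.subject_id}.dat")
    bundle.manifest.to_csv(outdir / "manifest.csv", index=False)
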