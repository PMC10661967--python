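# Methods

`lfpac` analyses continuous multichannel extracellular recordings (local
field potentials, LFPs) for oscillatory band power and theta–gamma
phase-amplitude coupling (PAC), and compares these metrics across
experimental groups. Because such studies rarely deposit raw recordings, the
package ships a seeded synthetic-cohort generator with analytically known
ground truth; every estimator is validated against it.

## Signal model of the generator

A synthetic channel is

```
x(t) = g · [ A_θ cos(2π f_p t + φ_c)                       (theta carrier)
           + Σ_k E_k(t) cos(2π f_a,k t + ψ_k)              (coupled fast tones)
           + Σ_b (A_b/√2) ν_b(t)                           (narrowband noise)
           + σ_n η_α(t) ]                                   (1/f^α background)
           + A_line sin(2π·50 t) + d(t)                     (line noise, drift)
```

* **Coupled tones.** Each fast tone's envelope follows the cosine law
  `E_k(t) = a_k [1 − κ + κ (1 + cos(φ(t) − φ_pref))/2]`, where `φ(t)` is the
  carrier's cosine-convention phase and `κ ∈ [0, 1]` is the coupling depth:
  `κ = 0` gives a constant envelope (no coupling), `κ = 1` an envelope that
  reaches zero at the anti-preferred phase. The carrier is written as a
  cosine so that the Hilbert-transform phase of the carrier equals the
  modulating phase exactly, making `φ_pref` directly the measured preferred
  phase. This construction's phase-amplitude distribution is known in closed
  form, which is what makes parameter-recovery tests possible.
* **Band noise.** Bands other than theta are realised as Butterworth-filtered
  Gaussian noise (order 4, zero-phase) normalised so its RMS equals
  `amplitude/√2` — the RMS of a sinusoid of that amplitude — so "amplitude"
  means the same thing for tonal and stochastic components. Filtered noise
  rather than tones spreads Welch band power realistically.
* **Background.** `η_α` is white Gaussian noise shaped to `1/f^α` in the
  frequency domain and rescaled to unit variance; `α = 1` by default, the
  typical LFP slope. Default `σ_n = 0.5` (half the theta carrier amplitude)
  puts the gamma-band noise floor at a level where default-κ coupling is
  clearly detectable but far from noise-free.
* **Cohort structure.** Groups × subjects × channels (default 3 × 6 × 8,
  300 s at 1 kHz, emulating a three-strain mouse study with six animals per
  strain and an eight-contact array). The group **power factor** multiplies
  every neural component *including the 1/f background* — diseased cohorts
  show a globally depressed spectrum, and because MI is scale-invariant this
  choice keeps coupling statistically identical between groups that differ
  only in power. The group **κ factor** multiplies only the coupling depth.
  Line noise and drift are instrumental and are never scaled. A per-subject
  log-normal gain `g` (σ = 0.1 by default) provides realistic
  between-subject variance; it scales signal and background together, so it
  moves band power but not MI.
* **Defaults as study conditions.** `group_power_factors = (1.0, 0.6, 0.5)`
  and `group_kappa_factors = (1.0, 1.0, 0.3)` encode the pattern the
  pipeline is designed to detect: power reduced in groups 2–3, coupling
  additionally broken only in group 3. Two coupled tones (6 → 40 Hz and
  6 → 70 Hz, κ = 0.6, preferred phase π/2) put coupling in both gamma bands.
* **Reproducibility.** Every draw comes from
  `SeedSequence(seed, spawn_key=(group, subject, channel))`; identical spec
  and seed give bit-identical cohorts, and channels are independent streams.

**What the generator does not emulate:** spikes and unit activity,
biophysical (conductance-based) LFP genesis, non-stationarity across the
recording, movement/chewing artefacts, volume conduction or inter-channel
correlation, and electrode impedance drift. Passing tests therefore
demonstrate estimator correctness under the assumed stationary additive
model, not robustness to every pathology of real recordings.

## Preprocessing

Per channel, in order: integer-ratio downsampling (order-8 Butterworth
anti-alias low-pass at 0.45·f_target, then decimation), a second-order IIR
notch at 50 Hz with quality factor Q = f0/bandwidth (default 50/3), removal
of a least-squares polynomial in time (default order 5 over the full record;
order 0 is mean subtraction; fitted on a Chebyshev basis for conditioning),
and an order-2 Butterworth bandpass at 1–90 Hz. All filters run
forward-backward (zero-phase) by default because downstream PAC depends on
undistorted phase; a causal single-pass mode exists. Note the order-2
bandpass is deliberately gentle and already attenuates the upper gamma range
(|H|² ≈ 0.75 at 70 Hz); band powers remain comparable across groups because
every group passes the same filter.

The polynomial order and per-record (rather than per-segment) drift fitting
are configurable choices; order 5 removes multi-second drift while leaving
≥ 1 Hz content intact (verified by the sine-plus-trend test).

## Spectral estimation

* **Welch PSD:** Hamming windows of 2 s with 50 % overlap, density
  normalisation (the integral of the PSD over [0, f_N] equals the signal
  variance). Frequency resolution 0.5 Hz.
* **Decibels:** `20·log10(power)` by default, with a conventional
  `10·log10` switch (`convention="power10"`). The 20·log10 form is retained
  as the pipeline's reference convention; since every group comparison is on
  linear power and dB is monotone, the choice does not affect inference.
  Zero power maps to a −120 dB floor.
* **Bands:** delta 1–4, theta 4–8, alpha 8–12, beta 15–30, low gamma 30–50,
  high gamma 50–90 Hz; half-open intervals so shared edges are unambiguous;
  the 12–15 Hz gap is part of the definition. Band power is the arithmetic
  mean of the linear PSD over in-band grid frequencies, converted to dB
  afterwards (never averaged in dB).
* **Spectrogram:** complex-Morlet CWT (PyWavelets `cmor6.0-1.0`) on a
  1–90 Hz grid at 1 Hz steps, computed per non-overlapping 5 s segment with
  power averaged within the segment. The time-bandwidth-6 wavelet is narrow
  enough in frequency that a pure tone peaks in its own 1 Hz row; shorter
  wavelets skew the peak one bin via the scale normalisation.
* **Channel averaging** applies to derived metrics (band power, MI) per
  subject, never to raw voltage: gamma is phase-incoherent across contacts,
  so averaging raw traces would cancel it and corrupt MI.

## Phase-amplitude coupling

Phase and envelope come from the analytic signal (Hilbert transform) after a
zero-phase order-4 Butterworth bandpass (effective order 8). The steep edges
matter: with an order-2 filter, carrier leakage into a neighbouring
comodulogram amplitude band beats against the modulation sideband and can
displace the comodulogram peak. One second at each record end is excluded
from binning (filter/Hilbert edge transients; configurable).

The phase circle is divided into 18 bins of 20°; the envelope is averaged
within each bin (`a_j`) and normalised, `p_j = a_j / Σ_k a_k`. The
modulation index is the KL divergence of `p` from uniform, normalised to
[0, 1]:

```
MI = KL(p, U) / log N,   KL = Σ_j p_j log(p_j N),   0·log 0 := 0,   N = 18.
```

MI = 0 for a flat distribution; MI = 1 when all mass is in one bin. MI is
invariant to global amplitude scaling and to the base of the logarithm. An
all-zero-amplitude input yields the uniform distribution (hence MI = 0)
rather than an error: no amplitude means no phase preference. Tiny negative
KL from round-off on near-uniform distributions is clamped to zero (KL ≥ 0
analytically).

Comodulograms evaluate MI over phase bands of 2 Hz width at 1 Hz steps
(centres 2–12 Hz) and amplitude bands of 10 Hz width at 5 Hz steps (centres
20–100 Hz); the centre ranges are a package default chosen to cover theta
and both gamma bands and are fully configurable. One practical caveat of the
10 Hz amplitude bandwidth: for a 6 Hz modulator the sidebands sit ±6 Hz from
the fast tone, at the very edge of the tone-centred band, so the peak cell
may land one 5 Hz step off-centre — within the estimator's stated recovery
tolerance. MI is computed on the full record by default; a segment-then-
average mode is available through the per-channel API.

## Group statistics

The experimental unit is the subject (channel-averaged metrics; default
n = 6 per group).

* **Band powers:** Shapiro–Wilk normality per group and Bartlett's
  chi-square variance-homogeneity check are logged, then one-way ANOVA, then
  Tamhane's T2 post hoc: per pair, a Welch t statistic with
  Welch–Satterthwaite df and a Šidák-type adjustment
  `p_adj = 1 − (1 − p)^k` over the k pairs. With one pair this reduces
  exactly to Welch's t-test. (The original studentised-maximum-modulus
  refinement of T2 is not implemented; the Šidák form is the standard
  textbook construction and is slightly conservative.)
* **MI:** one-tailed Wilcoxon rank-sum of each non-control group against
  control, default alternative "treatment less than control". The p-value is
  exact by full enumeration of rank assignments for tie-free pooled samples
  of n ≤ 12 (the n = 6 + 6 study case), otherwise a normal approximation
  with tie and continuity corrections.
* α = 0.05 throughout; no correction across bands (each band is reported as
  its own comparison).

## Numerical choices and degenerate inputs

dB floor −120 for zero power; hard errors for NaN samples, zero/negative
sampling rates, non-finite table values, constant samples in normality
testing, zero-variance groups in Bartlett/Tamhane, empty phase/amplitude
series, bands containing no PSD grid point, and bandpass corners outside
(0, f_N). Downsampling requires an integer rate ratio; arbitrary resampling
is out of scope. Ties in bin assignment at the 2π wrap are closed by the
half-open bin convention `[lo, hi)` with the top edge folded into the last
bin.

## Problem sizes

The shipped defaults analyse the full study scale (18 subjects × 8 channels
× 300 s at 1 kHz) in about a minute on one CPU. Unit and property tests use
4–120 s single-channel signals; the end-to-end cohort test runs the full
default scale. The reduced-scale example (`examples/05_cohort_pipeline.py`)
uses 4 subjects × 2 channels × 60 s to stay interactive.

## Known limitations

* The MI has a positive noise floor that shrinks with record length
  (~1e-4 at 60 s); comparisons between conditions should use equal-length
  records, as the pipeline does.
* The order-2 analysis bandpass attenuates the upper half of the high-gamma
  band; absolute high-gamma powers are comparable within the pipeline but
  not across differently filtered pipelines.
* Tamhane T2 at n = 6 per group is conservative; the omnibus ANOVA can be
  significant while no pair survives adjustment at smaller n.
* EDF reading requires the optional `mne` dependency and is read-only; the
  native container is the supported interchange format.
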