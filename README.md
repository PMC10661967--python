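# lfpac

Spectral band power and theta–gamma phase-amplitude coupling (PAC) analysis
for local field potential (LFP) recordings, with group-comparison statistics
and a ground-truth synthetic cohort generator.

Hippocampal LFPs carry rhythmic oscillations in canonical bands — delta
(1–4 Hz), theta (4–8 Hz), alpha (8–12 Hz), beta (15–30 Hz), low gamma
(30–50 Hz), high gamma (50–90 Hz) — and the phase of theta modulates the
amplitude of gamma. Both band power and the strength of that cross-frequency
coupling change in disease models, which makes them candidate
electrophysiological biomarkers. `lfpac` is for researchers who record
multichannel LFPs (e.g. chronically implanted arrays in rodents) and want a
tested, scriptable pipeline from raw voltage traces to group-level
statistics.

## What it computes

* **Preprocessing** — integer downsampling (e.g. 40 kHz → 1 kHz), 50 Hz
  notch (Q = f0/bandwidth), polynomial baseline-drift removal, order-2
  Butterworth 1–90 Hz bandpass; zero-phase by default.
* **Spectral power** — Welch PSD (2 s Hamming windows, 50 % overlap),
  complex-Morlet CWT spectrograms (5 s segments, 1–90 Hz at 1 Hz), band
  powers as mean linear PSD per band, dB via 20·log10.
* **Phase-amplitude coupling** — the KL-divergence modulation index: the
  fast-band envelope is averaged in 18 phase bins of 20° of the slow-band
  phase, normalised to a distribution `p`, and

  `MI = KL(p, U) / log 18`, with `KL = Σ p_j log(18 p_j)`,

  so MI = 0 for no coupling and MI = 1 when all amplitude concentrates in
  one bin. Comodulograms scan (phase × amplitude) band pairs (2 Hz/1 Hz and
  10 Hz/5 Hz grids).
* **Group statistics** — Shapiro–Wilk and Bartlett checks, one-way ANOVA,
  Tamhane T2 post hoc (Welch t + Šidák), and one-tailed Wilcoxon rank-sum
  (exact by enumeration for n ≤ 12) for MI.
* **Synthetic cohorts** — seeded generator with tunable coupling depth κ,
  1/f background, line noise, drift, and per-group power/κ attenuation, so
  every estimator can be checked against known truth.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Measure MI on a synthetic coupled signal (6 Hz carrier modulating a 70 Hz
tone) at increasing coupling depth (`examples/01_coupled_signal.py`):

```python
from lfpac import CouplingSpec, compute_mi, generate_coupled_signal

for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
    spec = CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=kappa)
    x = generate_coupled_signal(spec, duration_s=60.0, fs=1000.0,
                                noise_amp=0.1, seed=1)
    res = compute_mi(x, 1000.0, (4.0, 8.0), (50.0, 90.0))
    print(f"kappa={kappa:4.2f}  MI={res.mi:.5f}")
```

prints

```
kappa=0.00  MI=0.00000
kappa=0.25  MI=0.00174
kappa=0.50  MI=0.00961
kappa=0.75  MI=0.03222
kappa=1.00  MI=0.09804
```

MI grows monotonically with the generator's true coupling depth; at κ = 0 it
sits at the estimator's noise floor (~1e-4 for a 60 s record — MI of real
data is never exactly zero).

The full study-scale pipeline — 3 groups × 6 subjects × 8 channels × 300 s,
with power attenuated in groups 2–3 and coupling attenuated only in
group 3 — runs in about a minute:

```sh
lfp-pac run --demo --seed 1 --out demo_out
```

and finds every band power significantly reduced in both attenuated groups
(Tamhane T2, all p < 1e-5) while theta–low-gamma and theta–high-gamma MI are
significantly reduced only in the coupling-attenuated group (one-tailed
rank-sum, p = 0.0011 = 1/924, the exact floor for 6 vs 6). Other entry
points: `lfp-pac simulate|preprocess|spectrum|bandpower|pac|comodulogram|compare`,
each a thin wrapper over the library; `examples/` holds one short script per
capability.

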