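"""Condition a contaminated channel: notch, drift removal, bandpass.

The raw channel mixes a theta tone with 50 Hz line noise and a slow
polynomial drift; the chain removes the last two while keeping theta.
"""

import numpy as np

from lfpac import PreprocessConfig, Recording, preprocess_recording, welch_psd


def tone_amp(x, fs, f):
    t = np.arange(x.size) / fs
    return 2.0 * abs(np.mean(x * np.exp(-2j * np.pi * f * t)))


fs = 1000.0
t = np.arange(int(30 * fs)) / fs
raw = (np.sin(2 * np.pi * 6.0 * t)              # theta
       + 2.0 * np.sin(2 * np.pi * 50.0 * t)     # mains
       + 4.0 * (t / t[-1]) ** 2)                # drift
rec = Recording(samples=raw[np.newaxis, :], fs=fs)

out = preprocess_recording(rec, PreprocessConfig()).samples[0][2000:-2000]
print(f"50 Hz amplitude: raw 2.00 -> cleaned {tone_amp(out, fs, 50.0):.4f}")
print(f"6 Hz amplitude:  raw 1.00 -> cleaned {tone_amp(out, fs, 6.0):.4f}")
print(f"mean (drift residual): {np.mean(out):+.4f}")
ps = welch_psd(out, fs)
print(f"PSD peak after cleaning: {ps.freqs[np.argmax(ps.psd)]:.1f} Hz")
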