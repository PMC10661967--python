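import numpy as np
import pytest

from lfpac import CouplingSpec, Recording, SyntheticCohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """2 channels x 3 s of noise at 1 kHz, with metadata."""
    return Recording(samples=rng.standard_normal((2, 3000)).astype(np.float32),
                     fs=1000.0, channel_labels=["a", "b"],
                     subject_id="s0", group="control")


@pytest.fixture
def tiny_cohort_spec():
    """2 groups x 2 subjects x 2 channels x 4 s: fast enough for shape tests."""
    return SyntheticCohortSpec(
        n_groups=2, n_subjects_per_group=2, n_channels=2, duration_s=4.0,
        fs=1000.0,
        coupling=CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=0.6, amp_base=0.3),
        group_power_factors=(1.0, 0.5), group_kappa_factors=(1.0, 1.0),
        group_labels=("control", "treated"), seed=7)


@pytest.fixture
def coupled_60s():
    """60 s benchmark coupled signal (6 Hz carrier -> 70 Hz tone, kappa 0.8)."""
    from lfpac import generate_coupled_signal

    spec = CouplingSpec(f_phase=6.0, f_amp=70.0, kappa=0.8, amp_base=1.0,
                        preferred_phase=np.pi / 2)
    return generate_coupled_signal(spec, 60.0, 1000.0, noise_amp=0.1, seed=11), spec
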