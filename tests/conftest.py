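import numpy as np
import pytest

from erplat.containers import ERPWaveform, epoch_time_axis
from erplat.synth import ComponentSpec, Condition, NoiseSpec, SimulationConfig

TINY_MONTAGE = ("POz", "Oz", "M1", "M2")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_waveform(data, fs=500.0, montage=("POz",), level="subject", n=10):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    time_ms = epoch_time_axis(fs)[: data.shape[1]]
    return ERPWaveform(data=data, time_ms=time_ms, montage=montage, level=level, n=n)


@pytest.fixture
def tiny_config():
    """4 subjects x 8 trials, 4 posterior sites, light noise - fast everywhere."""
    c1 = ComponentSpec("C1", peak_latency_ms=80.0, onset_ms=50.0, amplitude_uV=-0.6,
                       site_weights={"POz": 1.0, "Oz": 0.8})
    effect = ComponentSpec("contrast_effect", peak_latency_ms=92.0, onset_ms=68.0,
                           amplitude_uV=0.6, site_weights={"POz": 1.0, "Oz": 0.85})
    return SimulationConfig(
        conditions=[
            Condition("homogeneous", [c1]),
            Condition("contrast", [c1, effect]),
        ],
        n_subjects=4,
        n_trials_per_condition=8,
        sampling_rate_hz=500.0,
        montage=TINY_MONTAGE,
        noise=NoiseSpec(white_sd_uV=1.0, pink_sd_uV=0.5, alpha_amp_uV=0.5,
                        subject_latency_jitter_sd_ms=1.0, subject_amp_sd_uV=0.05,
                        artifact_rate=0.0),
        seed=42,
    )


@pytest.fixture
def noiseless_config(tiny_config):
    cfg = tiny_config
    cfg.noise = NoiseSpec.silent()
    return cfg
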