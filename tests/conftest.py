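import numpy as np
import pytest

from fatigueeg.synthetic import SimConfig, generate_dataset, generate_recording


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast 2-subject configuration used throughout the unit tests."""
    return SimConfig(
        n_subjects=2, minutes_per_state=0.5, rate=200.0, n_channels=4, seed=42
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def one_recording(small_cfg):
    return generate_recording(small_cfg, "S01", "normal")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_epochs_100():
    """100 noise-free 10-s band-mixture signals for denoising benchmarks."""
    out = []
    s = 0
    while len(out) < 100:
        cfg = SimConfig(
            n_subjects=1, minutes_per_state=1.0, rate=200.0, n_channels=4,
            noise_sd=0.0, line_amp=0.0, artifact_rate=0.0, seed=1000 + s,
        )
        state = "fatigue" if s % 2 else "normal"
        rec = generate_recording(cfg, "S01", state)
        for ch in range(rec.n_channels):
            for k in range(rec.n_samples // 2000):
                out.append(rec.data[ch, k * 2000 : (k + 1) * 2000].copy())
        s += 1
    return out[:100]
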