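"""Synthetic multichannel EEG with a controllable fatigue/wakefulness contrast.

Real driving-fatigue recordings are rarely shareable, so the experiment is
emulated: each channel is a sum of band-limited oscillations (filtered white
noise in the five classical EEG bands), broadband sensor noise, 50 Hz mains
interference, and sporadic low-frequency high-amplitude transients mimicking
ocular artifacts.  The fatigue state raises delta/theta amplitudes and lowers
alpha/beta, the contrast a band-power classifier is expected to exploit.

Everything is deterministic in (seed, subject, state): a per-subject gain on
every band amplitude is drawn log-normally from a seed derived from the
subject id, which makes leave-one-subject-out evaluation genuinely harder
than a random split.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .recording import STATES, Recording

#: Frequency bands (Hz). The classical clinical conventions.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: 32-channel actiCAP-style montage in the international 10-20 system.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT9",
    "FC5", "FC1", "FC2", "FC6", "FT10", "T7", "C3", "Cz",
    "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
]

#: Band RMS amplitudes (microvolt) per state.  Wakefulness shows the alpha/beta
#: peaks; fatigue raises theta and delta.  Free parameters of the simulator,
#: not estimates from any particular dataset.
DEFAULT_BAND_POWERS: dict[str, dict[str, float]] = {
    "normal": {"delta": 3.0, "theta": 2.5, "alpha": 9.0, "beta": 5.0, "gamma": 1.5},
    "fatigue": {"delta": 8.0, "theta": 8.5, "alpha": 4.0, "beta": 2.5, "gamma": 1.5},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic-EEG generator.

    Attributes
    ----------
    n_subjects : int
        Number of simulated subjects.
    minutes_per_state : float
        Recording length per behavioural state, minutes.
    rate : float
        Sampling rate, Hz. Must exceed twice the highest band edge.
    n_channels : int
        Channel count (first ``n_channels`` labels of the 32-channel montage).
    band_powers : dict state -> dict band -> RMS amplitude (microvolt)
    bands : dict band -> (lo, hi) Hz
    noise_sd : float
        Standard deviation of the additive broadband Gaussian noise, microvolt.
    line_freq, line_amp : float
        Mains interference frequency (Hz) and amplitude (microvolt).
    artifact_rate : float
        Poisson rate of ocular-like transients, events per minute.
    subject_sd : float
        Sigma of the log-normal per-subject gain applied to band amplitudes.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_subjects: int = 6
    minutes_per_state: float = 20.0
    rate: float = 1000.0
    n_channels: int = 32
    band_powers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(v) for s, v in DEFAULT_BAND_POWERS.items()}
    )
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    noise_sd: float = 2.0
    line_freq: float = 50.0
    line_amp: float = 1.0
    artifact_rate: float = 4.0
    subject_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.minutes_per_state <= 0:
            raise ConfigurationError("minutes_per_state must be positive")
        if not 1 <= self.n_channels <= len(CHANNELS_32):
            raise ConfigurationError(
                f"n_channels must be in [1, {len(CHANNELS_32)}]"
            )
        top = max(hi for _, hi in self.bands.values())
        if self.rate <= 2 * top:
            raise ConfigurationError(
                f"rate {self.rate} Hz must exceed twice the highest band edge {top} Hz"
            )
        for name, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi:
                raise ConfigurationError(f"band {name}: need 0 <= lo < hi")
        for state in STATES:
            if state not in self.band_powers:
                raise ConfigurationError(f"band_powers missing state {state!r}")
            for band in self.bands:
                amp = self.band_powers[state].get(band)
                if amp is None or amp < 0:
                    raise ConfigurationError(
                        f"band_powers[{state!r}][{band!r}] must be >= 0"
                    )
        for val, name in [
            (self.noise_sd, "noise_sd"),
            (self.line_amp, "line_amp"),
            (self.artifact_rate, "artifact_rate"),
            (self.subject_sd, "subject_sd"),
        ]:
            if val < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        # the fatigue/wakefulness spectral contrast the classifiers rely on
        fat, nor = self.band_powers["fatigue"], self.band_powers["normal"]
        if not (fat["theta"] > nor["theta"] and fat["delta"] > nor["delta"]):
            raise ConfigurationError(
                "fatigue state must have strictly larger theta and delta amplitudes"
            )
        if not (nor["alpha"] > fat["alpha"] and nor["beta"] > fat["beta"]):
            raise ConfigurationError(
                "normal state must have strictly larger alpha and beta amplitudes"
            )

    @property
    def channel_names(self) -> list[str]:
        return CHANNELS_32[: self.n_channels]


def _subject_rng(cfg: SimConfig, subject_id: str, salt: str) -> np.random.Generator:
    """Deterministic generator keyed by (seed, subject, salt)."""
    h = zlib.crc32(f"{subject_id}|{salt}".encode())
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, h]))


def _subject_gains(cfg: SimConfig, subject_id: str) -> dict[str, float]:
    """Per-subject log-normal gain on every band amplitude."""
    rng = _subject_rng(cfg, subject_id, "gains")
    return {
        band: float(np.exp(rng.normal(0.0, cfg.subject_sd)))
        for band in sorted(cfg.bands)
    }


def _bandlimited_noise(
    rng: np.random.Generator, n: int, rate: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz (4th-order Butterworth)."""
    x = rng.standard_normal(n)
    hi = min(hi, 0.49 * rate)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(y**2))
    return y / rms if rms > 0 else y


def generate_recording(cfg: SimConfig, subject_id: str, state: str) -> Recording:
    """Generate one subject/state recording of ``minutes_per_state`` minutes.

    The signal model per channel is

    ``sum_b g_s(b) * A_state(b) * n_b(t)  +  noise  +  line  +  artifacts``

    where ``n_b`` is unit-RMS band-limited noise with an independent
    realisation (hence random phase) per channel, ``A_state(b)`` the state's
    band amplitude and ``g_s(b)`` the subject's log-normal gain.
    """
    cfg.validate()
    if state not in STATES:
        raise ConfigurationError(f"state must be one of {STATES}")
    n = int(round(cfg.minutes_per_state * 60 * cfg.rate))
    gains = _subject_gains(cfg, subject_id)
    rng = _subject_rng(cfg, subject_id, f"signal|{state}")
    t = np.arange(n) / cfg.rate
    data = np.empty((cfg.n_channels, n))
    for ch in range(cfg.n_channels):
        x = np.zeros(n)
        for band in sorted(cfg.bands):
            lo, hi = cfg.bands[band]
            amp = cfg.band_powers[state][band] * gains[band]
            if amp > 0:
                x += amp * _bandlimited_noise(rng, n, cfg.rate, lo, hi)
        x += rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
        if cfg.line_amp > 0:
            x += cfg.line_amp * np.sin(
                2 * np.pi * cfg.line_freq * t + rng.uniform(0, 2 * np.pi)
            )
        data[ch] = x
    _add_artifacts(cfg, rng, data)
    return Recording(
        data=data,
        rate=cfg.rate,
        channel_names=cfg.channel_names,
        subject_id=subject_id,
        state=state,
    )


def _add_artifacts(
    cfg: SimConfig, rng: np.random.Generator, data: np.ndarray
) -> None:
    """Add Poisson-arriving 1-3 Hz exponentially decaying transients in place.

    Amplitude is five times the background RMS; each event hits every channel
    with a random gain in [0.2, 1], largest at frontal sites by construction
    of the gain draw order being irrelevant -- simple and deterministic.
    """
    if cfg.artifact_rate <= 0:
        return
    n = data.shape[1]
    duration_min = n / cfg.rate / 60.0
    n_events = rng.poisson(cfg.artifact_rate * duration_min)
    if n_events == 0:
        return
    background = float(np.sqrt(np.mean(data**2)))
    amp = 5.0 * background
    tau = 0.3  # decay time constant, seconds
    width = int(5 * tau * cfg.rate)
    tt = np.arange(width) / cfg.rate
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - width))
        f = rng.uniform(1.0, 3.0)
        burst = amp * np.exp(-tt / tau) * np.sin(2 * np.pi * f * tt)
        ch_gain = rng.uniform(0.2, 1.0, data.shape[0])
        data[:, start : start + width] += np.outer(ch_gain, burst)


def generate_dataset(cfg: SimConfig) -> list[Recording]:
    """All ``n_subjects x 2`` recordings (one per state per subject)."""
    cfg.validate()
    recs = []
    for i in range(cfg.n_subjects):
        subject_id = f"S{i + 1:02d}"
        for state in STATES:
            recs.append(generate_recording(cfg, subject_id, state))
    return recs
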