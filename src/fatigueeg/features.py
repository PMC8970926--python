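"""Feature extraction: band power spectra, per-IMF energies, higher-order spectra.

Two extractors feed the classifiers:

* **Band power** -- Hann-windowed short-time Fourier transform, squared
  magnitude averaged over frames (one power spectrum per epoch), summed over
  the classical EEG bands: one feature per (channel, band).
* **EMD + energy spectrum** -- each channel is decomposed by EMD and the
  energy spectral density ``Phi(w) = |F(w)|^2 / 2pi`` of each of the first
  ``n_imfs`` IMFs is summed into one scalar energy: one feature per
  (channel, IMF).  32 channels x 3 IMFs = 96 features.

The segmented third-order cumulant estimator and the AR-model bispectrum are
exposed for completeness but are not on the default classification path.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .emd import SiftConfig, emd_decompose
from .errors import ParameterError
from .recording import Epoch, EpochSet
from .synthetic import DEFAULT_BANDS

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrogram",
    "FeatureVector",
    "FeatureMatrix",
    "CumulantEstimate",
    "hann_window",
    "stft",
    "psd",
    "band_energy",
    "psd_features",
    "esd",
    "emd_esd_features",
    "extract_features",
    "third_order_cumulant",
    "ar_bispectrum",
]


@dataclass
class Spectrogram:
    """Frames x full-DFT-bins complex STFT values."""

    values: np.ndarray  # (n_frames, N) complex
    rate: float
    window_len: int
    hop: int

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        """Bin frequencies k * rate / N, k = 0..N-1."""
        return np.arange(self.window_len) * self.rate / self.window_len


@dataclass
class FeatureVector:
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.feature_names):
            raise ParameterError("feature values and names disagree in length")


@dataclass
class FeatureMatrix:
    """Epochs x features, with names, class labels and subject ids."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ParameterError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ParameterError("feature count does not match names")
        if not (len(self.labels) == len(self.subject_ids) == self.values.shape[0]):
            raise ParameterError("labels/subject_ids must align with rows")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature matrix contains non-finite entries")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, row_mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            values=self.values[row_mask],
            feature_names=list(self.feature_names),
            labels=np.asarray(self.labels)[row_mask],
            subject_ids=np.asarray(self.subject_ids)[row_mask],
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df["subject"] = self.subject_ids
        return df


def hann_window(N: int) -> np.ndarray:
    """Hann window ``0.5 (1 - cos(2 pi n / (N-1))) = sin^2(pi n / (N-1))``."""
    if N < 2:
        raise ParameterError("window length must be >= 2")
    n = np.arange(N)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / (N - 1)))


def stft(
    x: np.ndarray,
    N: int,
    hop: int,
    rate: float = 1.0,
    window: str | None = "hann",
) -> Spectrogram:
    """Short-time Fourier transform with full-DFT bins.

    Frame m covers samples ``[m hop, m hop + N)``; each frame is windowed
    (Hann by default, ``window=None`` for rectangular) and DFT'd to N bins.
    """
    x = np.asarray(x, dtype=float)
    if N > len(x):
        raise ParameterError(f"window length {N} exceeds signal length {len(x)}")
    if hop < 1:
        raise ParameterError("hop must be >= 1")
    w = hann_window(N) if window == "hann" else np.ones(N)
    n_frames = (len(x) - N) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, N)[:: hop][:n_frames]
    return Spectrogram(
        values=np.fft.fft(frames * w, axis=1),
        rate=rate,
        window_len=N,
        hop=hop,
    )


def psd(spec: Spectrogram) -> np.ndarray:
    """Power spectrum: ``E(w_k) = |X|^2`` averaged over frames, divided by N."""
    if spec.n_frames == 0:
        raise ParameterError("empty spectrogram")
    E = np.mean(np.abs(spec.values) ** 2, axis=0)
    return E / spec.window_len


def band_energy(
    spectrum: np.ndarray, band: tuple[float, float], rate: float
) -> float:
    """Sum of spectrum bins with frequency in the half-open band [lo, hi).

    ``spectrum`` is any per-bin nonnegative vector over the full DFT axis
    (PSD or energy); bins are at ``k * rate / N``.
    """
    lo, hi = band
    if not 0 <= lo < hi <= rate / 2 + 1e-9:
        raise ParameterError(f"band [{lo}, {hi}] outside [0, Nyquist={rate / 2}]")
    N = len(spectrum)
    freqs = np.arange(N) * rate / N
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        logger.warning("band [%g, %g) Hz contains no DFT bins", lo, hi)
        return 0.0
    return float(np.sum(spectrum[mask]))


def psd_features(
    epoch: Epoch,
    bands: dict[str, tuple[float, float]] | None = None,
    window_seconds: float = 1.0,
    overlap: float = 0.5,
) -> FeatureVector:
    """One band-power feature per (channel, band).

    STFT window defaults to 1 s at the epoch's rate with 50% overlap.
    """
    bands = bands or DEFAULT_BANDS
    N = int(round(window_seconds * epoch.rate))
    hop = max(1, int(round(N * (1.0 - overlap))))
    values, names = [], []
    for ch in range(epoch.n_channels):
        spec = stft(epoch.data[ch], N, hop, rate=epoch.rate)
        p = psd(spec)
        for band_name, edges in bands.items():
            values.append(band_energy(p, edges, epoch.rate))
            names.append(f"ch{ch}:{band_name}")
    return FeatureVector(values=np.array(values), feature_names=names)


def esd(x: np.ndarray) -> np.ndarray:
    """Energy spectral density ``Phi(w_k) = |DFT(x)|^2 / (2 pi)`` over all bins."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("empty signal")
    X = np.fft.fft(x)
    return np.abs(X) ** 2 / (2.0 * np.pi)


def emd_esd_features(
    epoch: Epoch,
    n_imfs: int = 3,
    sift_config: SiftConfig | None = None,
) -> FeatureVector:
    """Per-channel EMD, then total energy-spectral-density per IMF.

    Channels yielding fewer than ``n_imfs`` IMFs contribute zero-energy
    features for the missing modes, keeping the vector length fixed at
    channels x n_imfs (96 for a 32-channel epoch at the default 3).
    """
    if n_imfs < 1:
        raise ParameterError("n_imfs must be >= 1")
    cfg = sift_config or SiftConfig(max_imfs=n_imfs)
    values, names = [], []
    for ch in range(epoch.n_channels):
        x = epoch.data[ch]
        if np.allclose(x, 0.0):
            imfs = []
        else:
            imfs = emd_decompose(x, cfg).imfs
        if len(imfs) < n_imfs:
            logger.debug(
                "channel %d yielded %d < %d IMFs; zero-padding features",
                ch, len(imfs), n_imfs,
            )
        for i in range(n_imfs):
            energy = float(np.sum(esd(imfs[i]))) if i < len(imfs) else 0.0
            values.append(energy)
            names.append(f"ch{ch}:imf{i + 1}_energy")
    return FeatureVector(values=np.array(values), feature_names=names)


def extract_features(
    epochs: EpochSet,
    method: str = "emd",
    **kwargs,
) -> FeatureMatrix:
    """Apply one extractor (``"emd"`` or ``"psd"``) to every epoch."""
    if method == "emd":
        fn = lambda ep: emd_esd_features(ep, **kwargs)  # noqa: E731
    elif method == "psd":
        fn = lambda ep: psd_features(ep, **kwargs)  # noqa: E731
    else:
        raise ParameterError(f"unknown feature method {method!r}")
    rows, names = [], None
    for ep in epochs:
        fv = fn(ep)
        if names is None:
            names = _rename(fv.feature_names, epochs.channel_names)
        rows.append(fv.values)
    if names is None:
        raise ParameterError("cannot extract features from an empty epoch set")
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names,
        labels=epochs.labels,
        subject_ids=epochs.subject_ids,
    )


def _rename(names: list[str], channel_names: list[str]) -> list[str]:
    """Replace positional ch<i> prefixes with electrode labels when known."""
    if not channel_names:
        return list(names)
    out = []
    for nm in names:
        prefix, _, rest = nm.partition(":")
        if prefix.startswith("ch") and prefix[2:].isdigit():
            i = int(prefix[2:])
            if i < len(channel_names):
                prefix = channel_names[i]
        out.append(f"{prefix}:{rest}")
    return out


# ------------------------------------------------ higher-order spectra (optional)

@dataclass
class CumulantEstimate:
    """Segment-averaged third-order cumulant over a symmetric lag grid."""

    r_hat: np.ndarray  # (2p+1, 2p+1), lag indices -p..p on both axes
    p_lags: int
    segment_len: int
    n_segments: int

    def value(self, m: int, n: int) -> float:
        return float(self.r_hat[m + self.p_lags, n + self.p_lags])


def third_order_cumulant(x: np.ndarray, M: int, p_lags: int) -> CumulantEstimate:
    """Segmented third-moment estimate averaged over K = len(x)/M segments.

    Per segment (1-indexed samples k), for lags m, n:
    ``r_i(m, n) = (1/M) sum_{k=s1..s2} x_i(k) x_i(k+m) x_i(k+n)`` with
    ``s1 = max(1, 1-m, 1-n)``, ``s2 = min(M, M-m, M-n)``; the overall
    estimate is the mean over segments.  Symmetric in (m, n).
    """
    x = np.asarray(x, dtype=float)
    if M < 1 or len(x) % M != 0:
        raise ParameterError(f"segment length {M} must divide signal length {len(x)}")
    if not 0 <= p_lags < M:
        raise ParameterError("need 0 <= p_lags < M")
    K = len(x) // M
    segs = x.reshape(K, M)
    size = 2 * p_lags + 1
    r = np.zeros((size, size))
    for m in range(-p_lags, p_lags + 1):
        for nlag in range(-p_lags, p_lags + 1):
            s1 = max(1, 1 - m, 1 - nlag)
            s2 = min(M, M - m, M - nlag)
            if s2 < s1:
                continue
            k = np.arange(s1 - 1, s2)  # 0-indexed
            vals = segs[:, k] * segs[:, k + m] * segs[:, k + nlag]
            r[m + p_lags, nlag + p_lags] = np.mean(np.sum(vals, axis=1) / M)
    return CumulantEstimate(r_hat=r, p_lags=p_lags, segment_len=M, n_segments=K)


def ar_bispectrum(
    cum: CumulantEstimate,
    p: int,
    grid: np.ndarray | None = None,
    convention: str = "as_printed",
) -> np.ndarray:
    """Bispectrum of an order-p AR model fitted to diagonal cumulant lags.

    Solves the (p+1)-equation diagonal-lag system ``R [1, a]^T = [beta, 0..0]^T``
    for the AR coefficients a and the driving-noise third moment beta, then
    evaluates ``B(w1, w2) = beta I(w1) I(w2) conj(I(w1 + w2))`` with
    ``I(w) = 1 + sum_n a_n exp(-j w (n-1))``; ``convention="standard"``
    uses the textbook exponent ``exp(-j w n)`` instead.
    """
    if p < 0:
        raise ParameterError("AR order p must be >= 0")
    if p > cum.p_lags:
        raise ParameterError(f"cumulant covers lags up to {cum.p_lags} < p={p}")
    if convention not in ("as_printed", "standard"):
        raise ParameterError(f"unknown convention {convention!r}")
    if grid is None:
        grid = np.linspace(-np.pi, np.pi, 64)
    grid = np.asarray(grid, dtype=float)
    # R[i, j] = r(j - i, j - i): diagonal cumulant slice, Toeplitz in j - i
    R = np.empty((p + 1, p + 1))
    for i in range(p + 1):
        for j in range(p + 1):
            R[i, j] = cum.value(j - i, j - i)
    if p == 0:
        a = np.zeros(0)
        beta = R[0, 0]
    else:
        try:
            a = np.linalg.solve(R[1:, 1:], -R[1:, 0])
        except np.linalg.LinAlgError as exc:
            cond = np.linalg.cond(R)
            raise ParameterError(
                f"singular AR system (condition number {cond:.3g})"
            ) from exc
        beta = R[0, 0] + R[0, 1:] @ a

    def transfer(w: np.ndarray) -> np.ndarray:
        acc = np.ones_like(w, dtype=complex)
        for n in range(1, p + 1):
            expo = (n - 1) if convention == "as_printed" else n
            acc = acc + a[n - 1] * np.exp(-1j * w * expo)
        return acc

    I1 = transfer(grid)
    W1, W2 = np.meshgrid(grid, grid, indexing="ij")
    return beta * np.outer(I1, I1) * np.conj(transfer(W1 + W2))
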