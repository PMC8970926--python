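"""Empirical mode decomposition (EMD) by envelope-mean sifting.

EMD splits a signal into intrinsic mode functions (IMFs), ordered from the
fastest oscillation to the slowest, plus a residual trend.  One sift
subtracts the mean of the cubic-spline upper and lower envelopes,
``m(t) = (e_up(t) + e_low(t)) / 2``; sifting repeats until the Cauchy
criterion ``sum (h_prev - h)^2 / sum h_prev^2 < sd_tol`` (or an iteration
cap) and the accepted IMF is subtracted from the running residual.  The
construction is telescoping, so IMFs plus residual reconstruct the input to
machine precision by identity.

Boundary behaviour dominates EMD quality in practice; extrema are mirrored
beyond both signal ends before spline fitting to suppress end swings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import DataError, ParameterError

__all__ = [
    "SiftConfig",
    "IMFSet",
    "find_extrema",
    "envelopes",
    "sift_once",
    "emd_decompose",
    "InsufficientExtrema",
]


class InsufficientExtrema(Exception):
    """Fewer than two maxima or two minima: envelopes undefined, sifting stops."""


@dataclass
class SiftConfig:
    """Stopping rules and boundary handling for the sifting loop.

    ``sd_tol`` is the Cauchy sifting tolerance (community default 0.2); a
    candidate is accepted only once it also satisfies the IMF criterion that
    extrema and zero-crossing counts differ by at most one.
    ``energy_tol`` stops extraction once the residual holds less than that
    fraction of the input energy; ``fixed_sift_count`` (if set) replaces the
    Cauchy rule by exactly k sifts per IMF.
    """

    max_imfs: int = 10
    max_sift_iters: int = 50
    sd_tol: float = 0.2
    energy_tol: float = 0.01
    boundary: str = "mirror"  # or "clamp": repeat end extrema without reflection
    fixed_sift_count: int | None = None

    def validate(self) -> None:
        if self.max_imfs < 1 or self.max_sift_iters < 1:
            raise ParameterError("max_imfs and max_sift_iters must be >= 1")
        if self.sd_tol <= 0 or self.energy_tol < 0:
            raise ParameterError("sd_tol must be > 0 and energy_tol >= 0")
        if self.boundary not in ("mirror", "clamp"):
            raise ParameterError(f"unknown boundary mode {self.boundary!r}")


@dataclass
class IMFSet:
    """Ordered IMFs (fast to slow) plus the residual trend."""

    imfs: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray | None = None
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.imfs:
            out += c
        return out


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior maxima and minima.

    A flat run that is a local extremum contributes a single index at its
    midpoint (the earlier index when the run length is even).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ParameterError("need at least 3 samples to find extrema")
    d = np.diff(x)
    if np.all(d != 0):  # no ties: fully vectorised strict comparison
        rising, falling = d > 0, d < 0
        maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
        minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
        return maxima, minima
    # run-length encode equal-value plateaus, compare run to its neighbours
    starts = np.flatnonzero(np.concatenate([[True], d != 0]))
    ends = np.concatenate([starts[1:] - 1, [n - 1]])
    vals = x[starts]
    maxima_l, minima_l = [], []
    for k in range(1, len(starts) - 1):
        v, left, right = vals[k], vals[k - 1], vals[k + 1]
        mid = (starts[k] + ends[k]) // 2
        if v > left and v > right:
            maxima_l.append(mid)
        elif v < left and v < right:
            minima_l.append(mid)
    return np.array(maxima_l, dtype=int), np.array(minima_l, dtype=int)


def _extend(idx: np.ndarray, val: np.ndarray, n: int, mode: str):
    """Mirror (or clamp) two extrema beyond each end for spline support."""
    if mode == "clamp":
        li = np.array([-1]); lv = val[:1]
        ri = np.array([n]); rv = val[-1:]
    else:
        k = min(2, len(idx))
        li = -idx[:k][::-1]
        lv = val[:k][::-1]
        ri = 2 * (n - 1) - idx[-k:][::-1]
        rv = val[-k:][::-1]
        # guard against coincident indices at the boundary
        if li[-1] >= idx[0]:
            li = li - (li[-1] - idx[0] + 1)
        if ri[0] <= idx[-1]:
            ri = ri + (idx[-1] - ri[0] + 1)
    return np.concatenate([li, idx, ri]), np.concatenate([lv, val, rv])


def envelopes(
    x: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
    boundary: str = "mirror",
) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-spline upper and lower envelopes through the extrema.

    Raises :class:`InsufficientExtrema` with fewer than two maxima or two
    minima; callers treat that as the natural end of sifting.
    """
    x = np.asarray(x, dtype=float)
    if len(maxima) < 2 or len(minima) < 2:
        raise InsufficientExtrema(
            f"{len(maxima)} maxima / {len(minima)} minima: envelopes undefined"
        )
    n = len(x)
    t = np.arange(n)
    mi, mv = _extend(maxima, x[maxima], n, boundary)
    upper = CubicSpline(mi, mv)(t)
    ni, nv = _extend(minima, x[minima], n, boundary)
    lower = CubicSpline(ni, nv)(t)
    return upper, lower


def sift_once(x: np.ndarray, boundary: str = "mirror") -> np.ndarray:
    """One sifting step: subtract the envelope mean from the signal."""
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    e_up, e_low = envelopes(x, maxima, minima, boundary)
    return x - (e_up + e_low) / 2.0


def _near_imf(h: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one (IMF criterion)."""
    try:
        maxima, minima = find_extrema(h)
    except ParameterError:
        return True
    s = np.sign(h)
    s = s[s != 0]
    crossings = int(np.sum(s[:-1] != s[1:]))
    return abs((len(maxima) + len(minima)) - crossings) <= 1


def emd_decompose(x: np.ndarray, cfg: SiftConfig | None = None) -> IMFSet:
    """Full decomposition into IMFs plus residual.

    Extraction stops when the residual has fewer than two maxima or minima
    (monotone trend), when ``max_imfs`` is reached, or when the residual
    energy drops below ``energy_tol`` of the input energy.
    """
    cfg = cfg or SiftConfig()
    cfg.validate()
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("input contains non-finite samples")
    if len(x) < 8:
        raise ParameterError("need at least 8 samples for EMD")
    total_energy = float(np.sum(x**2))
    result = IMFSet()
    residual = x.copy()
    while result.n_imfs < cfg.max_imfs:
        if total_energy > 0 and float(np.sum(residual**2)) < cfg.energy_tol * total_energy:
            break
        try:
            maxima, minima = find_extrema(residual)
        except ParameterError:
            break
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual
        count = 0
        for _ in range(cfg.max_sift_iters):
            try:
                h_new = sift_once(h, cfg.boundary)
            except (InsufficientExtrema, ParameterError):
                break
            count += 1
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if cfg.fixed_sift_count is not None:
                if count >= cfg.fixed_sift_count:
                    break
            elif sd < cfg.sd_tol and _near_imf(h):
                break
        if count == 0:
            break
        result.imfs.append(h)
        result.sift_counts.append(count)
        residual = residual - h
    # telescoping residual: exact by construction
    recon_resid = x.copy()
    for c in result.imfs:
        recon_resid -= c
    result.residual = recon_resid
    return result
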