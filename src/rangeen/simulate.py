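"""Seeded generators for the synthetic processes used throughout.

Covers Gaussian white noise, spectrally shaped pink (1/f) and brown
(1/f^2) noise, fractional Brownian motion (fBm, exact Cholesky method
with a covariance scale D), fractional Levy motion (fLm, moving-average
discretisation driven by alpha-stable innovations), and piecewise-
constant amplitude gains for nonstationarity tests.

Every generator is deterministic given its spec (parameters + seed).
Noise outputs are standardised to zero mean and unit variance where the
study protocol implies comparable amplitudes; raw fBm/fLm paths are NOT
standardised — their amplitude behaviour is part of what the entropy
measures are probed with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve

from .entropy import SignalLike, TimeSeries, as_values

__all__ = [
    "NoiseSpec",
    "FbmSpec",
    "FlmSpec",
    "GainProfile",
    "FBM_MAX_N",
    "gen_noise",
    "gen_fbm",
    "gen_flm",
    "sample_stable",
    "apply_gain",
    "blockwise_gain",
]

#: Hard cap on fBm length — the exact covariance factorisation is O(N^3).
FBM_MAX_N = 4096


@dataclass(frozen=True)
class NoiseSpec:
    """Coloured-noise parameters: ``kind`` in {white, pink, brown}."""

    kind: str
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in ("white", "pink", "brown"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.n < 8:
            raise ValueError(f"noise length must be >= 8, got {self.n}")


@dataclass(frozen=True)
class FbmSpec:
    """Fractional Brownian motion: Hurst exponent ``hurst`` in (0, 1),
    covariance scale ``d_scale`` (D; paths scale as sqrt(D))."""

    hurst: float
    n: int
    seed: int
    d_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"Hurst exponent must lie in (0, 1), got {self.hurst}")
        if not self.d_scale > 0:
            raise ValueError(f"covariance scale D must be > 0, got {self.d_scale}")
        if self.n < 2:
            raise ValueError("fBm length must be >= 2")
        if self.n > FBM_MAX_N:
            raise ValueError(
                f"fBm length {self.n} exceeds the exact-factorisation cap {FBM_MAX_N}"
            )


@dataclass(frozen=True)
class FlmSpec:
    """Fractional Levy motion: Levy index ``alpha`` in (0, 2], Hurst
    exponent ``hurst`` in (0, 1); the memory parameter is
    ``d = hurst - 1/alpha`` exactly. ``scale`` is the stable scale C;
    ``kernel_cutoff`` the moving-average truncation M."""

    alpha: float
    hurst: float
    n: int
    seed: int
    scale: float = 1.0
    kernel_cutoff: int = 600

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 2.0:
            raise ValueError(f"Levy index alpha must lie in (0, 2], got {self.alpha}")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"Hurst exponent must lie in (0, 1), got {self.hurst}")
        if self.scale <= 0:
            raise ValueError("scale C must be > 0")
        if self.kernel_cutoff < 1:
            raise ValueError("kernel cutoff M must be >= 1")
        if self.n < 1:
            raise ValueError("fLm length must be >= 1")

    @property
    def memory(self) -> float:
        """The moving-average memory parameter d = H - 1/alpha."""
        return self.hurst - 1.0 / self.alpha


@dataclass(frozen=True)
class GainProfile:
    """Piecewise-constant gain: ``edges`` are 0-based block boundaries
    ``[0, e1, ..., N]`` and ``gains`` the positive multiplier per block."""

    edges: tuple
    gains: tuple

    def __post_init__(self) -> None:
        edges = tuple(int(e) for e in self.edges)
        gains = tuple(float(g) for g in self.gains)
        if len(edges) != len(gains) + 1:
            raise ValueError("need exactly one more edge than gains")
        if edges[0] != 0 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must start at 0 and be strictly increasing")
        if any(g <= 0 for g in gains):
            raise ValueError("all gains must be > 0")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "gains", gains)


def blockwise_gain(n: int = 1000) -> GainProfile:
    """The default five-block gain (1, 3, 10, 4, 1) over equal blocks.

    For ``n = 1000`` this is the nonstationary test profile: samples
    201-400 scaled by 3, 401-600 by 10, 601-800 by 4 (1-based)."""
    if n % 5:
        raise ValueError("default five-block profile needs a length divisible by 5")
    b = n // 5
    return GainProfile(edges=(0, b, 2 * b, 3 * b, 4 * b, n), gains=(1, 3, 10, 4, 1))


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def gen_noise(spec: NoiseSpec) -> TimeSeries:
    """Generate white, pink (1/f) or brown (1/f^2) Gaussian noise.

    White noise is iid N(0, 1). Pink/brown noise are produced by scaling
    the one-sided spectrum of white noise by ``f**(-beta/2)`` (beta = 1
    or 2) with the zero-frequency bin set to 0, inverting, and
    standardising to zero mean and unit (population) variance.
    """
    rng = np.random.default_rng(spec.seed)
    w = rng.standard_normal(spec.n)
    if spec.kind == "white":
        return TimeSeries(w, label=f"white(n={spec.n},seed={spec.seed})")
    beta = 1.0 if spec.kind == "pink" else 2.0
    spectrum = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(spec.n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=spec.n)
    x = (x - x.mean()) / x.std()
    return TimeSeries(x, label=f"{spec.kind}(n={spec.n},seed={spec.seed})")


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

@lru_cache(maxsize=12)
def _fbm_cholesky(hurst: float, n: int) -> np.ndarray:
    """Lower-triangular factor of the unit-scale fBm covariance on t=1..n:
    cov(t, s) = (t^2H + s^2H - |t-s|^2H) / 2."""
    t = np.arange(1, n + 1, dtype=float)
    h2 = 2.0 * hurst
    cov = 0.5 * (t[:, None] ** h2 + t[None, :] ** h2 - np.abs(t[:, None] - t[None, :]) ** h2)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"fBm covariance factorisation failed for H={hurst}, N={n}: "
            "the matrix is numerically not positive definite; add diagonal "
            "jitter or reduce N"
        ) from exc


def gen_fbm(spec: FbmSpec) -> TimeSeries:
    """Exact fBm sample path via Cholesky factorisation of Eq.-(12)-type
    covariance ``D * (t^2H + s^2H - |t-s|^2H) / 2`` on integer times
    ``t = 1..N``. Matched seeds at different D give the same path up to
    the scalar factor sqrt(D)."""
    factor = _fbm_cholesky(float(spec.hurst), int(spec.n))
    rng = np.random.default_rng(spec.seed)
    path = factor @ rng.standard_normal(spec.n)
    if spec.d_scale != 1.0:
        path = np.sqrt(spec.d_scale) * path
    return TimeSeries(
        path, label=f"fbm(H={spec.hurst},D={spec.d_scale},n={spec.n},seed={spec.seed})"
    )


# ---------------------------------------------------------------------------
# fractional Levy motion
# ---------------------------------------------------------------------------

def sample_stable(alpha: float, size: int, rng: np.random.Generator,
                  scale: float = 1.0) -> np.ndarray:
    """Symmetric alpha-stable variates via the Chambers–Mallows–Stuck
    transform. ``alpha = 2`` gives Gaussians with variance ``2 * scale**2``;
    ``alpha = 1`` gives Cauchy variates."""
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    u = rng.uniform(-np.pi / 2.0, np.pi / 2.0, size)
    if alpha == 1.0:
        return scale * np.tan(u)
    w = rng.exponential(1.0, size)
    x = (
        np.sin(alpha * u)
        / np.cos(u) ** (1.0 / alpha)
        * (np.cos((1.0 - alpha) * u) / w) ** ((1.0 - alpha) / alpha)
    )
    return scale * x


def gen_flm(spec: FlmSpec) -> TimeSeries:
    """Fractional Levy motion by FFT moving average.

    Symmetric alpha-stable innovations are convolved with the truncated
    kernel ``a(k) = (k+1)^d - k^d`` (``k = 0..M-1``, ``d = H - 1/alpha``)
    to form correlated increments, which are cumulated into a motion
    starting at the first increment. ``alpha = 2`` yields Gaussian
    increments (an fBm-like path); ``d = 0`` degenerates to an ordinary
    stable Levy motion. The kernel is proportional to the discretised
    moving-average weights; the overall normalisation constant is
    immaterial for scale-invariant analyses.
    """
    rng = np.random.default_rng(spec.seed)
    m = int(spec.kernel_cutoff)
    innovations = sample_stable(spec.alpha, spec.n + m - 1, rng, scale=spec.scale)
    d = spec.memory
    if d == 0.0:
        increments = innovations[m - 1:]
    else:
        kernel = np.empty(m)
        kernel[0] = 1.0  # a(0) = 1^d - 0^d
        k = np.arange(1, m, dtype=float)
        kernel[1:] = (k + 1.0) ** d - k ** d
        full = fftconvolve(innovations, kernel, mode="full")
        increments = full[m - 1: m - 1 + spec.n]
    path = np.cumsum(increments)
    return TimeSeries(
        path,
        label=(
            f"flm(alpha={spec.alpha},H={spec.hurst},C={spec.scale},"
            f"M={m},n={spec.n},seed={spec.seed})"
        ),
    )


# ---------------------------------------------------------------------------
# amplitude gain
# ---------------------------------------------------------------------------

def apply_gain(x: SignalLike, profile: GainProfile) -> TimeSeries:
    """Multiply a signal by a piecewise-constant gain profile.

    The profile's edges must exactly cover ``[0, N]``.
    """
    v = as_values(x).copy()
    if profile.edges[-1] != v.size:
        raise ValueError(
            f"gain profile covers [0, {profile.edges[-1]}] but the signal has "
            f"{v.size} samples"
        )
    for a, b, g in zip(profile.edges, profile.edges[1:], profile.gains):
        v[a:b] *= g
    label = x.label if isinstance(x, TimeSeries) else ""
    return TimeSeries(v, label=f"{label}*gain" if label else "gained")
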