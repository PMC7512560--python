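"""Phase-space entropy estimators for univariate time series.

This module implements four template-matching entropy measures on the
delay-1 reconstructed phase space of a uniformly sampled signal:

* approximate entropy (ApEn) — mean negative log conditional probability
  that templates close at embedding dimension ``m`` remain close at
  ``m + 1``, with self-matching allowed (Pincus estimator);
* sample entropy (SampEn) — the Richman–Moorman variant that excludes
  self-matches and takes the log of aggregated match ratios;
* RangeEnA and RangeEnB — ApEn and SampEn with the Chebyshev distance
  replaced by the normalised *range distance*

      d_range(a, b) = (max_k|a_k - b_k| - min_k|a_k - b_k|)
                      / (max_k|a_k - b_k| + min_k|a_k - b_k|),

  which lies in [0, 1], is exactly invariant to a common additive offset
  and to joint rescaling by any non-zero scalar, and is *undefined* for
  element-wise identical templates (zero denominator).

SampEn, RangeEnA and RangeEnB can be undefined (no matching templates at
some dimension); this state is first-class and reported as ``value=None``
on :class:`EntropyValue`, never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TimeSeries",
    "EmbeddingConfig",
    "TemplateSet",
    "MatchCounts",
    "EntropyValue",
    "MEASURES",
    "embed",
    "chebyshev_distance",
    "range_distance",
    "pairwise_distance_matrix",
    "match_counts",
    "apen",
    "sampen",
    "rangeen_a",
    "rangeen_b",
]

#: The four measures computed by this module.
MEASURES = ("ApEn", "SampEn", "RangeEnA", "RangeEnB")


@dataclass
class TimeSeries:
    """A finite univariate real-valued signal.

    Parameters
    ----------
    values
        Ordered sequence of samples (dimensionless amplitude). Must be
        one-dimensional, non-empty and finite.
    label
        Free-text identifier carried through outputs.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError(f"signal must be one-dimensional, got shape {v.shape}")
        if v.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("signal contains non-finite samples")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


SignalLike = Union[TimeSeries, np.ndarray, list, tuple]


def as_values(x: SignalLike) -> np.ndarray:
    """Return the sample array of a signal-like input (validated)."""
    if isinstance(x, TimeSeries):
        return x.values
    return TimeSeries(np.asarray(x, dtype=float)).values


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the template-matching search.

    ``m`` is the embedding dimension (template length), ``r`` the
    similarity tolerance, ``delay`` the embedding delay (fixed at 1),
    and ``sd_correction`` requests division of the signal by its
    population standard deviation before matching — the classical
    amplitude correction for ApEn/SampEn, equivalent to using a
    tolerance of ``r * SD``. Range-entropy measures are
    amplitude-invariant by construction and never apply it.
    """

    m: int = 2
    r: float = 0.2
    delay: int = 1
    sd_correction: bool = False

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 1:
            raise ValueError(f"embedding dimension m must be an integer >= 1, got {self.m}")
        if self.r < 0:
            raise ValueError(f"tolerance r must be >= 0, got {self.r}")
        if self.delay != 1:
            raise ValueError("only delay (tau) = 1 is supported")


@dataclass
class TemplateSet:
    """The ``N - m + 1`` overlapping length-``m`` windows of a signal.

    Template ``i`` (0-based) covers samples ``[i, i + m)``; consecutive
    templates overlap in ``m - 1`` samples.
    """

    templates: np.ndarray  # shape (N - m + 1, m)
    m: int
    source_length: int

    def __len__(self) -> int:
        return self.templates.shape[0]


@dataclass
class MatchCounts:
    """Per-template neighbour counts ``B_i(r)`` under a distance function.

    ``mode`` is ``"include_self"`` (ApEn-style: the pair ``(i, i)`` counts
    as a match under the Chebyshev distance, but not under the range
    distance where it is undefined) or ``"exclude_self"`` (SampEn-style:
    ``j != i``). Pairs whose range distance is undefined are counted as
    non-matches and tallied in ``n_excluded_pairs``.
    """

    counts: np.ndarray  # integer, one entry per template
    distance: str
    mode: str
    r: float
    n_excluded_pairs: int = 0


@dataclass
class EntropyValue:
    """One entropy estimate with its parameters and provenance.

    ``value`` is ``None`` when the estimate is undefined (a log of zero
    would occur). Defined SampEn/RangeEnB values are always >= 0 because
    match counts are non-increasing in the embedding dimension.
    """

    measure: str
    value: Optional[float]
    config: EmbeddingConfig
    n_templates_m: int
    n_templates_m1: int
    n_excluded_pairs: int = 0
    label: str = ""

    @property
    def defined(self) -> bool:
        return self.value is not None


# ---------------------------------------------------------------------------
# embedding and distances
# ---------------------------------------------------------------------------

def embed(x: SignalLike, m: int) -> TemplateSet:
    """Slice a signal into its delay-1 phase-space templates.

    Returns the ``N - m + 1`` overlapping windows of length ``m``.
    Raises ``ValueError`` if the signal is shorter than ``m + 1`` samples.
    """
    v = as_values(x)
    n = v.size
    if int(m) != m or m < 1:
        raise ValueError(f"embedding dimension m must be an integer >= 1, got {m}")
    if n < m + 1:
        raise ValueError(
            f"signal too short to embed: N={n} but m={m} requires N >= m + 1"
        )
    return TemplateSet(templates=sliding_window_view(v, m), m=int(m), source_length=n)


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"template length mismatch: {a.shape} vs {b.shape}")
    return a, b


def chebyshev_distance(a, b) -> float:
    """Maximum element-wise absolute difference between two templates."""
    a, b = _check_pair(a, b)
    return float(np.max(np.abs(a - b)))


def range_distance(a, b) -> Optional[float]:
    """Normalised range distance between two equal-length templates.

    ``(max|a-b| - min|a-b|) / (max|a-b| + min|a-b|)`` over element-wise
    absolute differences. Lies in [0, 1] when defined; returns ``None``
    for element-wise identical templates, where the denominator is zero.
    """
    a, b = _check_pair(a, b)
    d = np.abs(a - b)
    hi = float(d.max())
    lo = float(d.min())
    den = hi + lo
    if den == 0.0:
        return None
    return (hi - lo) / den


def pairwise_distance_matrix(t: TemplateSet, distance: str = "chebyshev") -> np.ndarray:
    """All pairwise template distances as a dense symmetric matrix.

    Undefined range distances (identical templates, including the
    diagonal) are NaN. This is the shared fast path used by the entropy
    estimators and the profile sweeps: thresholding one matrix at many
    tolerances is arithmetically identical to recomputing each pair.
    """
    if distance not in ("chebyshev", "range"):
        raise ValueError(f"unknown distance {distance!r}")
    w = t.templates
    n, m = w.shape
    mx: np.ndarray | None = None
    mn: np.ndarray | None = None
    for k in range(m):
        col = w[:, k]
        d = np.abs(col[:, None] - col[None, :])
        if mx is None:
            mx, mn = d, d.copy()
        else:
            np.maximum(mx, d, out=mx)
            np.minimum(mn, d, out=mn)
    assert mx is not None and mn is not None
    if distance == "chebyshev":
        return mx
    den = mx + mn
    out = np.full_like(den, np.nan)
    np.divide(mx - mn, den, out=out, where=den > 0)
    return out


def match_counts(
    t: TemplateSet,
    r: float,
    distance: str = "chebyshev",
    mode: str = "include_self",
) -> MatchCounts:
    """Count, for every template, the templates within tolerance ``r``.

    The comparison is inclusive (``d <= r``). Undefined range-distance
    pairs never match and are tallied in ``n_excluded_pairs`` (the
    diagonal is in scope only for ``include_self``).
    """
    if r < 0:
        raise ValueError(f"tolerance r must be >= 0, got {r}")
    if mode not in ("include_self", "exclude_self"):
        raise ValueError(f"unknown mode {mode!r}")
    dm = pairwise_distance_matrix(t, distance)
    matched = dm <= r  # NaN compares False
    n = dm.shape[0]
    if mode == "exclude_self":
        np.fill_diagonal(matched, False)
        n_scope_excluded = int(np.isnan(dm).sum() - np.isnan(np.diag(dm)).sum())
    else:
        n_scope_excluded = int(np.isnan(dm).sum())
    counts = matched.sum(axis=1).astype(int)
    return MatchCounts(
        counts=counts,
        distance=distance,
        mode=mode,
        r=float(r),
        n_excluded_pairs=n_scope_excluded,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _prepare(x: SignalLike, cfg: EmbeddingConfig, correct: bool) -> np.ndarray:
    v = as_values(x)
    if v.size < cfg.m + 2:
        raise ValueError(
            f"signal too short: N={v.size} but templates are needed at both "
            f"m={cfg.m} and m+1={cfg.m + 1} (N >= m + 2)"
        )
    if correct and cfg.sd_correction:
        sd = v.std()  # population convention
        if sd == 0:
            raise ValueError("sd_correction requested but signal is constant (SD = 0)")
        v = v / sd
    return v


def _matrices(v: np.ndarray, m: int, distance: str) -> tuple[np.ndarray, np.ndarray]:
    n = v.size
    dm = pairwise_distance_matrix(
        TemplateSet(sliding_window_view(v, m), m, n), distance
    )
    dm1 = pairwise_distance_matrix(
        TemplateSet(sliding_window_view(v, m + 1), m + 1, n), distance
    )
    return dm, dm1


def _apen_from(dm: np.ndarray, dm1: np.ndarray, r: float) -> float:
    # Per-template probabilities over all templates, self included; the
    # Chebyshev diagonal is 0 <= r, so every count is positive and ApEn
    # is defined for any finite input.
    phis = []
    for d in (dm, dm1):
        c = np.count_nonzero(d <= r, axis=1) / d.shape[0]
        phis.append(float(np.mean(np.log(c))))
    return phis[0] - phis[1]


def _sampen_from(dm: np.ndarray, dm1: np.ndarray, r: float) -> Optional[float]:
    # Both i and j range over the first N - m templates (the set that
    # also exists at dimension m + 1); self-pairs excluded.
    n2 = dm1.shape[0]
    b = int(np.count_nonzero(dm[:n2, :n2] <= r)) - n2
    a = int(np.count_nonzero(dm1 <= r)) - n2
    if a == 0 or b == 0:
        return None
    return float(-np.log(a / b))


def _rangeen_a_from(dm: np.ndarray, dm1: np.ndarray, r: float) -> Optional[float]:
    # Self-pairs are undefined under the range distance (NaN diagonal),
    # so probabilities are normalised by the candidate count (template
    # count minus one); a zero count anywhere makes the estimate
    # undefined. All counts equal the candidate count for r >= 1 on a
    # duplicate-free signal, giving exactly 0.
    phis = []
    for d in (dm, dm1):
        cnt = np.count_nonzero(d <= r, axis=1)
        if np.any(cnt == 0):
            return None
        phis.append(float(np.mean(np.log(cnt / (d.shape[0] - 1)))))
    return phis[0] - phis[1]


def _rangeen_b_from(dm: np.ndarray, dm1: np.ndarray, r: float) -> Optional[float]:
    n2 = dm1.shape[0]
    b = int(np.count_nonzero(dm[:n2, :n2] <= r))  # diagonal is NaN: never matches
    a = int(np.count_nonzero(dm1 <= r))
    if a == 0 or b == 0:
        return None
    return float(-np.log(a / b))


_FROM_MATRICES = {
    "ApEn": ("chebyshev", _apen_from, True),
    "SampEn": ("chebyshev", _sampen_from, True),
    "RangeEnA": ("range", _rangeen_a_from, False),
    "RangeEnB": ("range", _rangeen_b_from, False),
}


def _estimate(measure: str, x: SignalLike, cfg: EmbeddingConfig) -> EntropyValue:
    distance, fn, correctable = _FROM_MATRICES[measure]
    v = _prepare(x, cfg, correct=correctable)
    dm, dm1 = _matrices(v, cfg.m, distance)
    value = fn(dm, dm1, cfg.r)
    excluded = int(np.isnan(dm).sum() + np.isnan(dm1).sum()) if distance == "range" else 0
    return EntropyValue(
        measure=measure,
        value=value,
        config=cfg,
        n_templates_m=dm.shape[0],
        n_templates_m1=dm1.shape[0],
        n_excluded_pairs=excluded,
        label=x.label if isinstance(x, TimeSeries) else "",
    )


def _make_cfg(cfg, m, r, sd_correction) -> EmbeddingConfig:
    if cfg is not None:
        return cfg
    return EmbeddingConfig(m=m, r=r, sd_correction=sd_correction)


def apen(x: SignalLike, cfg: EmbeddingConfig | None = None, *,
         m: int = 2, r: float = 0.2, sd_correction: bool = False) -> EntropyValue:
    """Approximate entropy with Chebyshev distance and self-matching.

    Always defined. With ``sd_correction`` the signal is divided by its
    population standard deviation before matching.
    """
    return _estimate("ApEn", x, _make_cfg(cfg, m, r, sd_correction))


def sampen(x: SignalLike, cfg: EmbeddingConfig | None = None, *,
           m: int = 2, r: float = 0.2, sd_correction: bool = False) -> EntropyValue:
    """Sample entropy: ``-ln(B_{m+1}/B_m)`` with self-matches excluded.

    Undefined (``value=None``) when either aggregated count is zero.
    Defined values are non-negative.
    """
    return _estimate("SampEn", x, _make_cfg(cfg, m, r, sd_correction))


def rangeen_a(x: SignalLike, cfg: EmbeddingConfig | None = None, *,
              m: int = 2, r: float = 0.2) -> EntropyValue:
    """ApEn-style range entropy (range distance, per-template log mean).

    Self-pairs never match (undefined distance), so the estimate is
    undefined whenever any template has no neighbour — the most
    undefined-prone of the four measures at small ``r``. Exactly 0 for
    ``r >= 1`` on duplicate-free signals, and exactly invariant to
    offsets and positive rescaling of the input. Never SD-corrected.
    """
    return _estimate("RangeEnA", x, _make_cfg(cfg, m, r, False))


def rangeen_b(x: SignalLike, cfg: EmbeddingConfig | None = None, *,
              m: int = 2, r: float = 0.2) -> EntropyValue:
    """SampEn-style range entropy (range distance, aggregated counts).

    Undefined when either aggregated count is zero; defined values are
    non-negative. Exactly 0 for ``r >= 1`` on duplicate-free signals,
    and exactly amplitude/offset invariant. Never SD-corrected.
    """
    return _estimate("RangeEnB", x, _make_cfg(cfg, m, r, False))
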