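"""Rescaled-range (R/S) analysis and Hurst-exponent estimation.

The signal is split into ``n = 1, 2, 4, ...`` equisized non-overlapping
segments while the segment length ``floor(N/n)`` exceeds four samples.
Each segment is mean-centred, cumulatively summed, and contributes the
rescaled range R/S where R is the range of the cumulative sum and S the
(population) standard deviation of the segment. The Hurst exponent is
the OLS slope of ``ln(mean R/S)`` against ``ln(segment length)``.

Input-kind convention
---------------------
Classical R/S analysis takes an increment-like ("noise") series: the
cumulative sum inside the procedure builds the walk whose range is
measured. Applied directly to a motion-like path (e.g. Brownian motion)
it saturates near 1 regardless of the true exponent. ``hurst_rs`` makes
the choice explicit: ``kind="noise"`` analyses the series as given;
``kind="motion"`` differences the path first, so a Brownian path
recovers H near 0.5 and an fBm path its generative H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .entropy import SignalLike, as_values

__all__ = ["RescaledRangePoint", "HurstEstimate", "rescaled_range_curve", "hurst_rs"]

#: Smallest usable segment length (segments must have *more* than four points).
MIN_SEGMENT_LENGTH = 5


@dataclass
class RescaledRangePoint:
    """Average rescaled range at one scale (number of segments ``n``)."""

    n_segments: int
    segment_length: int
    mean_rs: float
    n_segments_used: int  # segments surviving the zero-SD filter


@dataclass
class HurstEstimate:
    """Slope-based self-similarity estimate with fit diagnostics."""

    hurst: float
    intercept: float  # ln C of the power law
    r_squared: float
    points: list[RescaledRangePoint]
    kind: str = "noise"


def rescaled_range_curve(x: SignalLike) -> list[RescaledRangePoint]:
    """Mean rescaled range R/S at doubling segment counts.

    Scales where every segment has zero standard deviation are dropped;
    trailing samples beyond ``n * floor(N/n)`` are discarded. Raises
    ``ValueError`` for signals of 8 or fewer samples or when fewer than
    two scales survive (e.g. a constant signal).
    """
    v = as_values(x)
    n_samples = v.size
    if n_samples <= 8:
        raise ValueError(f"rescaled-range analysis needs N > 8 samples, got {n_samples}")
    points: list[RescaledRangePoint] = []
    n = 1
    while n_samples // n >= MIN_SEGMENT_LENGTH:
        length = n_samples // n
        seg = v[: n * length].reshape(n, length)
        seg = seg - seg.mean(axis=1, keepdims=True)
        z = np.cumsum(seg, axis=1)
        rng = z.max(axis=1) - z.min(axis=1)
        sd = seg.std(axis=1)  # population convention, matching the centring
        keep = sd > 0
        if keep.any():
            points.append(
                RescaledRangePoint(
                    n_segments=n,
                    segment_length=length,
                    mean_rs=float(np.mean(rng[keep] / sd[keep])),
                    n_segments_used=int(keep.sum()),
                )
            )
        n *= 2
    if len(points) < 2:
        raise ValueError(
            "rescaled-range curve degenerate: fewer than two usable scales "
            "(is the signal constant?)"
        )
    return points


def hurst_rs(x: SignalLike, kind: str = "noise") -> HurstEstimate:
    """Estimate the Hurst exponent from the rescaled-range scaling law.

    ``kind="noise"`` applies the procedure to the series as given;
    ``kind="motion"`` analyses the increments of a path-like input.
    The estimate is the OLS slope of ``ln(mean R/S)`` on ``ln(segment
    length)`` and is not clipped to (0, 1).
    """
    if kind not in ("noise", "motion"):
        raise ValueError(f"kind must be 'noise' or 'motion', got {kind!r}")
    v = as_values(x)
    if kind == "motion":
        v = np.diff(v)
    points = rescaled_range_curve(v)
    log_len = np.log([p.segment_length for p in points])
    log_rs = np.log([p.mean_rs for p in points])
    slope, intercept = np.polyfit(log_len, log_rs, 1)
    fitted = slope * log_len + intercept
    ss_res = float(np.sum((log_rs - fitted) ** 2))
    ss_tot = float(np.sum((log_rs - log_rs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HurstEstimate(
        hurst=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        points=points,
        kind=kind,
    )
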