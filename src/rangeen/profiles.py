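"""Entropy profiles over tolerance or embedding dimension, and the
log-slope ("exponent") fits that link entropy trajectories to the Hurst
exponent.

An r-profile holds one entropy estimate per tolerance on a grid (default
0.01..1.00 in steps of 0.01 at fixed m = 2); an m-profile one estimate
per embedding dimension (default m = 2..10 at fixed r = 0.2). Undefined
estimates are preserved as ``None`` slots. The r-exponent (m-exponent)
is the OLS slope of the entropy values against the natural log of the
grid; following the study protocol, no line is fitted when any grid
point is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .entropy import (
    EmbeddingConfig,
    SignalLike,
    TemplateSet,
    TimeSeries,
    _FROM_MATRICES,
    as_values,
    pairwise_distance_matrix,
)

__all__ = [
    "EntropyProfile",
    "ExponentFit",
    "DEFAULT_R_GRID",
    "DEFAULT_M_GRID",
    "entropy_profile",
    "fit_exponent",
]

#: Tolerance grid 0.01, 0.02, ..., 1.00.
DEFAULT_R_GRID = np.round(np.arange(1, 101) * 0.01, 2)
#: Embedding-dimension grid 2..10.
DEFAULT_M_GRID = np.arange(2, 11)


@dataclass
class EntropyProfile:
    """Entropy as a function of one swept parameter (r or m)."""

    measure: str
    sweep: str  # "r" or "m"
    grid: np.ndarray
    values: list  # float or None per grid point
    fixed: dict  # the parameter held constant, e.g. {"m": 2}
    sd_correction: bool = False
    label: str = ""

    @property
    def n_undefined(self) -> int:
        return sum(v is None for v in self.values)

    def defined(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid points and values at the defined slots."""
        mask = [v is not None for v in self.values]
        return (
            np.asarray(self.grid)[mask],
            np.array([v for v in self.values if v is not None], dtype=float),
        )


@dataclass
class ExponentFit:
    """OLS slope of an entropy profile against ln(grid value).

    ``skipped`` is True when the profile had any undefined point (the
    exclusion rule for the H-sweep scatter analyses) or fewer than two
    points; no slope is reported in that case.
    """

    measure: str
    sweep: str
    slope: Optional[float]
    intercept: Optional[float]
    n_points: int
    skipped: bool
    label: str = ""


def _validate_grid(grid: np.ndarray, sweep: str) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("sweep grid must be non-empty")
    if np.any(np.diff(grid.astype(float)) <= 0):
        raise ValueError("sweep grid must be strictly increasing")
    if sweep == "r" and np.any(grid < 0):
        raise ValueError("tolerances must be >= 0")
    if sweep == "m" and (np.any(grid < 1) or not np.issubdtype(grid.dtype, np.integer)):
        raise ValueError("embedding dimensions must be integers >= 1")
    return grid


def entropy_profile(
    x: SignalLike,
    measure: str,
    sweep: str = "r",
    grid: np.ndarray | None = None,
    *,
    m: int = 2,
    r: float = 0.2,
    sd_correction: bool = False,
) -> EntropyProfile:
    """Sweep one entropy measure over tolerances or dimensions.

    For an r-sweep the pairwise distance matrices at dimensions ``m``
    and ``m + 1`` are computed once and thresholded at every tolerance,
    which is arithmetically identical to independent per-point
    evaluation. ``sd_correction`` only affects ApEn and SampEn.
    """
    if measure not in _FROM_MATRICES:
        raise ValueError(f"unknown measure {measure!r}; choose from {tuple(_FROM_MATRICES)}")
    if sweep not in ("r", "m"):
        raise ValueError(f"sweep must be 'r' or 'm', got {sweep!r}")
    if grid is None:
        grid = DEFAULT_R_GRID if sweep == "r" else DEFAULT_M_GRID
    grid = _validate_grid(grid, sweep)

    distance, value_fn, correctable = _FROM_MATRICES[measure]
    v = as_values(x)
    correct = sd_correction and correctable
    if correct:
        sd = v.std()
        if sd == 0:
            raise ValueError("sd_correction requested but signal is constant (SD = 0)")
        v = v / sd

    max_m = int(m if sweep == "r" else grid[-1])
    if v.size < max_m + 2:
        raise ValueError(
            f"signal too short for the sweep: N={v.size} needs N >= {max_m + 2}"
        )

    def mats(mm: int) -> tuple[np.ndarray, np.ndarray]:
        n = v.size
        dm = pairwise_distance_matrix(
            TemplateSet(sliding_window_view(v, mm), mm, n), distance)
        dm1 = pairwise_distance_matrix(
            TemplateSet(sliding_window_view(v, mm + 1), mm + 1, n), distance)
        return dm, dm1

    values: list = []
    if sweep == "r":
        dm, dm1 = mats(int(m))
        for r_val in grid:
            values.append(value_fn(dm, dm1, float(r_val)))
        fixed = {"m": int(m)}
    else:
        for m_val in grid:
            dm, dm1 = mats(int(m_val))
            values.append(value_fn(dm, dm1, float(r)))
        fixed = {"r": float(r)}

    return EntropyProfile(
        measure=measure,
        sweep=sweep,
        grid=grid,
        values=values,
        fixed=fixed,
        sd_correction=correct,
        label=x.label if isinstance(x, TimeSeries) else "",
    )


def fit_exponent(profile: EntropyProfile) -> ExponentFit:
    """Least-squares slope of an entropy profile against ln(grid).

    Returns a skipped fit when any grid point is undefined or fewer
    than two points are available. Natural logarithms are used
    throughout; a base-10 fit would differ only by a constant factor.
    """
    n = len(profile.values)
    if profile.n_undefined > 0 or n < 2:
        return ExponentFit(
            measure=profile.measure,
            sweep=profile.sweep,
            slope=None,
            intercept=None,
            n_points=n - profile.n_undefined,
            skipped=True,
            label=profile.label,
        )
    log_grid = np.log(np.asarray(profile.grid, dtype=float))
    y = np.asarray(profile.values, dtype=float)
    slope, intercept = np.polyfit(log_grid, y, 1)
    return ExponentFit(
        measure=profile.measure,
        sweep=profile.sweep,
        slope=float(slope),
        intercept=float(intercept),
        n_points=n,
        skipped=False,
        label=profile.label,
    )
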