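"""Reading and writing single-column signal files and tidy result tables.

The native on-disk signal format is one numeric sample per line — the
dialect of the public Bonn epileptic EEG segments — with single-column
headerless CSV accepted as the same thing (a trailing comma per line is
tolerated). Undefined entropy values are serialised as blank cells.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .entropy import SignalLike, TimeSeries, as_values
from .profiles import EntropyProfile

__all__ = [
    "read_segment",
    "write_signal",
    "write_sidecar",
    "profiles_to_frame",
    "write_profiles",
]

PathLike = Union[str, Path]


def read_segment(path: PathLike, label: str | None = None) -> TimeSeries:
    """Read a single-column ASCII/CSV signal file.

    Blank lines are skipped; anything unparseable raises a ``ValueError``
    naming the offending line number.
    """
    path = Path(path)
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            token = raw.strip().rstrip(",").strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: could not parse {raw.strip()!r} as a number"
                ) from None
    if not values:
        raise ValueError(f"{path}: no numeric samples found")
    return TimeSeries(values, label=label if label is not None else path.stem)


def write_signal(x: SignalLike, path: PathLike) -> Path:
    """Write a signal as one sample per line at full float precision.

    A write-then-read round trip is lossless.
    """
    path = Path(path)
    v = as_values(x)
    with path.open("w") as fh:
        for sample in v:
            fh.write(f"{float(sample)!r}\n")  # shortest round-trip repr
    return path


def write_sidecar(spec, path: PathLike) -> Path:
    """Write a generator spec (or any mapping/dataclass) as a JSON sidecar."""
    path = Path(path)
    if dataclasses.is_dataclass(spec) and not isinstance(spec, type):
        payload = {"spec_type": type(spec).__name__, **dataclasses.asdict(spec)}
    else:
        payload = dict(spec)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def profiles_to_frame(profiles: Iterable[EntropyProfile]) -> pd.DataFrame:
    """Tidy table: one row per (signal, measure, fixed m or r, grid value).

    Columns: ``signal, measure, sweep, m, r, value, sd_correction``.
    Undefined values become NA (blank in CSV).
    """
    rows = []
    for p in profiles:
        for g, v in zip(p.grid, p.values):
            m_val = p.fixed.get("m") if p.sweep == "r" else int(g)
            r_val = float(g) if p.sweep == "r" else p.fixed.get("r")
            rows.append(
                {
                    "signal": p.label,
                    "measure": p.measure,
                    "sweep": p.sweep,
                    "m": m_val,
                    "r": r_val,
                    "value": v,
                    "sd_correction": p.sd_correction,
                }
            )
    return pd.DataFrame(rows)


def write_profiles(profiles: Iterable[EntropyProfile], path: PathLike) -> Path:
    """Write profiles as CSV with blank cells for undefined values."""
    path = Path(path)
    profiles_to_frame(profiles).to_csv(path, index=False)
    return path
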