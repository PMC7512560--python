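"""Config-driven replication experiments at full or reduced scale.

Each experiment generates its own seeded synthetic signals, runs the
entropy / self-similarity machinery, and writes tidy CSV tables plus a
JSON manifest to an output directory. Defaults mirror the study
protocol (100 realisations, N = 1000, r-grid 0.01..1.00 step 0.01,
H-grid 0.01..0.99 step 0.01, D-grid {0.001, 0.01, 1, 10, 100} at
H = 0.75); ``reduced=True`` switches to desk-scale grids (10 H levels,
10 tolerances, 10 realisations) with the same structure.

Summary tables average over *defined* values only and carry explicit
undefined counts, so no undefined estimate is ever folded into a mean.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .entropy import TimeSeries, apen, sampen, rangeen_a, rangeen_b, MEASURES
from .hurst import hurst_rs
from .io import read_segment, write_signal
from .profiles import DEFAULT_R_GRID, DEFAULT_M_GRID, entropy_profile, fit_exponent
from .simulate import (
    FbmSpec,
    FlmSpec,
    NoiseSpec,
    apply_gain,
    blockwise_gain,
    gen_fbm,
    gen_flm,
    gen_noise,
)

__all__ = ["ExperimentConfig", "EXPERIMENTS", "run_experiment", "make_fixtures"]

EXPERIMENTS = (
    "length_sweep",
    "r_sweep",
    "amplitude_test",
    "hurst_sweep_fbm",
    "hurst_sweep_flm",
    "cov_scaling",
    "eeg_profiles",
)

REDUCED_R_GRID = np.round(np.arange(1, 11) * 0.1, 1)
NOISE_KINDS = ("white", "pink", "brown")

_ESTIMATORS = {
    "ApEn": apen,
    "SampEn": sampen,
    "RangeEnA": lambda x, **kw: rangeen_a(x, m=kw["m"], r=kw["r"]),
    "RangeEnB": lambda x, **kw: rangeen_b(x, m=kw["m"], r=kw["r"]),
}


@dataclass
class ExperimentConfig:
    """Parameters of one experiment run.

    ``None`` fields fall back to the experiment's own defaults (full
    scale, or desk scale when ``reduced`` is set). ``input_dir`` is only
    used by ``eeg_profiles`` and must point at a directory of
    single-column segment files.
    """

    experiment: str
    outdir: Path
    seed: int = 0
    reduced: bool = False
    n_realisations: Optional[int] = None
    signal_length: Optional[int] = None
    m: int = 2
    r: float = 0.2
    sd_correction: bool = False
    r_grid: Optional[np.ndarray] = None
    h_grid: Optional[np.ndarray] = None
    d_grid: Optional[tuple] = None
    lengths: Optional[np.ndarray] = None
    include_m_sweep: bool = True
    m_grid: Optional[np.ndarray] = None
    input_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )
        self.outdir = Path(self.outdir)

    # resolved defaults -----------------------------------------------------
    @property
    def reps(self) -> int:
        if self.n_realisations is not None:
            return self.n_realisations
        return 10 if self.reduced else 100

    @property
    def n(self) -> int:
        return self.signal_length if self.signal_length is not None else 1000

    def resolved_r_grid(self) -> np.ndarray:
        if self.r_grid is not None:
            return np.asarray(self.r_grid)
        return REDUCED_R_GRID if self.reduced else DEFAULT_R_GRID

    def resolved_m_grid(self) -> np.ndarray:
        if self.m_grid is not None:
            return np.asarray(self.m_grid)
        return DEFAULT_M_GRID

    def resolved_h_grid(self) -> np.ndarray:
        if self.h_grid is not None:
            return np.asarray(self.h_grid)
        if self.reduced:
            return np.round(np.arange(1, 10) * 0.1, 1)
        return np.round(np.arange(1, 100) * 0.01, 2)

    def resolved_lengths(self) -> np.ndarray:
        if self.lengths is not None:
            return np.asarray(self.lengths)
        if self.reduced:
            return np.arange(100, 1001, 100)
        return np.arange(50, 1001, 10)


def _child_seeds(seed: int, k: int) -> np.ndarray:
    """Deterministic per-realisation seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(k, dtype=np.uint32) % (2**31)


def _point_estimates(x: TimeSeries, m: int, r: float, sd_correction: bool) -> dict:
    out = {}
    for name in MEASURES:
        if name in ("ApEn", "SampEn"):
            ev = _ESTIMATORS[name](x, m=m, r=r, sd_correction=sd_correction)
        else:
            ev = _ESTIMATORS[name](x, m=m, r=r)
        out[name] = ev.value
    return out


# ---------------------------------------------------------------------------
# individual experiments
# ---------------------------------------------------------------------------

def _length_sweep(cfg: ExperimentConfig):
    lengths = cfg.resolved_lengths()
    seeds = _child_seeds(cfg.seed, cfg.reps)
    rows = []
    for kind in NOISE_KINDS:
        for rep, s in enumerate(seeds):
            full = gen_noise(NoiseSpec(kind, int(lengths[-1]), int(s)))
            for n in lengths:
                x = TimeSeries(full.values[: int(n)], label=f"{kind}-{rep}")
                est = _point_estimates(x, cfg.m, cfg.r, cfg.sd_correction)
                for meas, val in est.items():
                    rows.append(
                        {"kind": kind, "n": int(n), "rep": rep, "measure": meas,
                         "value": val}
                    )
    raw = pd.DataFrame(rows)
    summary = _summarise(raw, ["kind", "n", "measure"])
    return raw, summary


def _summarise(raw: pd.DataFrame, keys: list) -> pd.DataFrame:
    raw = raw.assign(value=pd.to_numeric(raw["value"]))  # None -> NaN
    grp = raw.groupby(keys, sort=True)["value"]
    out = grp.agg(
        mean="mean", sd="std", n_defined="count", n_total="size"
    ).reset_index()
    out["n_undefined"] = out["n_total"] - out["n_defined"]
    return out


def _r_sweep(cfg: ExperimentConfig):
    grid = cfg.resolved_r_grid()
    seeds = _child_seeds(cfg.seed, cfg.reps)
    rows = []
    for kind in NOISE_KINDS:
        for rep, s in enumerate(seeds):
            x = gen_noise(NoiseSpec(kind, cfg.n, int(s)))
            for meas in MEASURES:
                p = entropy_profile(x, meas, "r", grid, m=cfg.m,
                                    sd_correction=cfg.sd_correction)
                for g, v in zip(p.grid, p.values):
                    rows.append({"kind": kind, "rep": rep, "measure": meas,
                                 "r": float(g), "value": v})
    raw = pd.DataFrame(rows)
    summary = _summarise(raw, ["kind", "measure", "r"])
    return raw, summary


def _amplitude_test(cfg: ExperimentConfig):
    grid = cfg.resolved_r_grid()
    seed = int(_child_seeds(cfg.seed, 1)[0])
    x1 = gen_noise(NoiseSpec("white", cfg.n, seed))
    x1.label = "x1"
    x2 = TimeSeries(5.0 * x1.values, label="x2")
    x3 = apply_gain(x1, blockwise_gain(cfg.n))
    x3.label = "x3"
    rows = []
    for x in (x1, x2, x3):
        for meas in MEASURES:
            arms = (False, True) if meas in ("ApEn", "SampEn") else (False,)
            for corrected in arms:
                p = entropy_profile(x, meas, "r", grid, m=cfg.m,
                                    sd_correction=corrected)
                for g, v in zip(p.grid, p.values):
                    rows.append({"signal": x.label, "measure": meas,
                                 "sd_correction": corrected, "r": float(g),
                                 "value": v})
    raw = pd.DataFrame(rows)
    summary = _summarise(raw, ["signal", "measure", "sd_correction"])
    return raw, summary


def _hurst_sweep(cfg: ExperimentConfig, family: str):
    grid = cfg.resolved_r_grid()
    m_grid = cfg.resolved_m_grid()
    h_levels = cfg.resolved_h_grid()
    reps = cfg.n_realisations if cfg.n_realisations is not None else (
        10 if cfg.reduced else 1)
    seeds = _child_seeds(cfg.seed, reps)
    prof_rows, exp_rows, hurst_rows = [], [], []
    for h in h_levels:
        for rep, s in enumerate(seeds):
            if family == "fbm":
                x = gen_fbm(FbmSpec(hurst=float(h), n=cfg.n, seed=int(s)))
            else:
                x = gen_flm(FlmSpec(alpha=1.0, hurst=float(h), n=cfg.n, seed=int(s)))
            est = hurst_rs(x, kind="motion")
            hurst_rows.append({"H": float(h), "rep": rep,
                               "hurst_rs": est.hurst, "r_squared": est.r_squared})
            sweeps = [("r", grid)]
            if cfg.include_m_sweep:
                sweeps.append(("m", m_grid))
            for meas in MEASURES:
                arms = (False, True) if meas in ("ApEn", "SampEn") else (False,)
                for corrected in arms:
                    for sweep, g in sweeps:
                        p = entropy_profile(x, meas, sweep, g, m=cfg.m, r=cfg.r,
                                            sd_correction=corrected)
                        fit = fit_exponent(p)
                        for gv, v in zip(p.grid, p.values):
                            prof_rows.append(
                                {"H": float(h), "rep": rep, "measure": meas,
                                 "sweep": sweep, "sd_correction": corrected,
                                 "grid_value": float(gv), "value": v})
                        exp_rows.append(
                            {"H": float(h), "rep": rep, "measure": meas,
                             "sweep": sweep, "sd_correction": corrected,
                             "slope": fit.slope, "skipped": fit.skipped,
                             "n_points": fit.n_points})
    raw = pd.DataFrame(prof_rows)
    extra = {"exponents": pd.DataFrame(exp_rows), "hurst": pd.DataFrame(hurst_rows)}
    summary = _summarise(raw, ["H", "measure", "sweep", "sd_correction", "grid_value"])
    return raw, summary, extra


def _cov_scaling(cfg: ExperimentConfig):
    grid = cfg.resolved_r_grid()
    d_grid = cfg.d_grid if cfg.d_grid is not None else (0.001, 0.01, 1.0, 10.0, 100.0)
    seed = int(_child_seeds(cfg.seed, 1)[0])
    rows = []
    for d in d_grid:
        # matched seed: all D share one underlying Gaussian draw
        x = gen_fbm(FbmSpec(hurst=0.75, n=cfg.n, seed=seed, d_scale=float(d)))
        for meas in MEASURES:
            # per the protocol, no amplitude correction for any measure here
            p = entropy_profile(x, meas, "r", grid, m=cfg.m, sd_correction=False)
            for g, v in zip(p.grid, p.values):
                rows.append({"D": float(d), "measure": meas, "r": float(g),
                             "value": v})
    raw = pd.DataFrame(rows)
    summary = _summarise(raw, ["D", "measure"])
    return raw, summary


def _eeg_profiles(cfg: ExperimentConfig):
    if cfg.input_dir is None:
        raise ValueError("eeg_profiles needs input_dir pointing at segment files")
    files = sorted(Path(cfg.input_dir).glob("*"))
    files = [f for f in files if f.is_file() and f.suffix.lower() in ("", ".txt", ".csv")]
    if not files:
        raise ValueError(f"no segment files found in {cfg.input_dir}")
    grid = cfg.resolved_r_grid()
    prof_rows, hurst_rows = [], []
    for f in files:
        x = read_segment(f)
        est = hurst_rs(x, kind="noise")
        hurst_rows.append({"segment": f.name, "hurst_rs": est.hurst,
                           "r_squared": est.r_squared})
        for meas in MEASURES:
            corrected = meas in ("ApEn", "SampEn")  # corrected amplitudes, fixed m
            p = entropy_profile(x, meas, "r", grid, m=cfg.m,
                                sd_correction=corrected)
            for g, v in zip(p.grid, p.values):
                prof_rows.append({"segment": f.name, "measure": meas,
                                  "r": float(g), "value": v})
    raw = pd.DataFrame(prof_rows)
    summary = _summarise(raw, ["measure", "r"])
    return raw, summary, {"hurst": pd.DataFrame(hurst_rows)}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment and write its tables and manifest to disk.

    Returns ``{"raw": DataFrame, "summary": DataFrame, "extra": {...},
    "manifest": dict, "outdir": Path}``. Deterministic given the seed.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    extra: dict = {}
    if cfg.experiment == "length_sweep":
        raw, summary = _length_sweep(cfg)
    elif cfg.experiment == "r_sweep":
        raw, summary = _r_sweep(cfg)
    elif cfg.experiment == "amplitude_test":
        raw, summary = _amplitude_test(cfg)
    elif cfg.experiment in ("hurst_sweep_fbm", "hurst_sweep_flm"):
        raw, summary, extra = _hurst_sweep(cfg, cfg.experiment.rsplit("_", 1)[-1])
    elif cfg.experiment == "cov_scaling":
        raw, summary = _cov_scaling(cfg)
    else:
        raw, summary, extra = _eeg_profiles(cfg)

    outputs = {}
    raw_path = cfg.outdir / f"{cfg.experiment}_raw.csv"
    raw.to_csv(raw_path, index=False)
    outputs["raw"] = raw_path.name
    summary_path = cfg.outdir / f"{cfg.experiment}_summary.csv"
    summary.to_csv(summary_path, index=False)
    outputs["summary"] = summary_path.name
    for name, df in extra.items():
        p = cfg.outdir / f"{cfg.experiment}_{name}.csv"
        df.to_csv(p, index=False)
        outputs[name] = p.name

    n_undefined = int(raw["value"].isna().sum()) if "value" in raw else 0
    manifest = {
        "experiment": cfg.experiment,
        "config": _jsonable_config(cfg),
        "seed": cfg.seed,
        "versions": {"rangeen": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "outputs": outputs,
        "n_rows": int(len(raw)),
        "n_undefined_values": n_undefined,
    }
    manifest_path = cfg.outdir / f"{cfg.experiment}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return {"raw": raw, "summary": summary, "extra": extra,
            "manifest": manifest, "outdir": cfg.outdir}


def _jsonable_config(cfg: ExperimentConfig) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, np.ndarray):
            v = v.tolist()
        elif isinstance(v, Path):
            v = str(v)
        out[f.name] = v
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write small deterministic instances of every signal family.

    Produces three coloured noises, three fBm paths (H = 0.2/0.5/0.8),
    one fLm path (alpha = 1), the white-noise amplitude-test triplet
    x1 / x2 = 5*x1 / x3 (five-block gain), and a synthetic segment in
    the one-sample-per-line EEG dialect (4097 integer samples, the
    nominal segment length of the public Bonn recordings). Identical
    seeds give byte-identical files. Returns the manifest (also written
    as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = 1000
    entries = []

    def emit(name: str, x: TimeSeries, spec) -> None:
        path = write_signal(x, outdir / name)
        entries.append({
            "file": name,
            "n": int(len(x)),
            "label": x.label,
            "spec": {"spec_type": type(spec).__name__, **dataclasses.asdict(spec)}
            if dataclasses.is_dataclass(spec) else spec,
        })
        _ = path

    seeds = _child_seeds(seed, 8)
    for i, kind in enumerate(NOISE_KINDS):
        spec = NoiseSpec(kind, n, int(seeds[i]))
        emit(f"{kind}.txt", gen_noise(spec), spec)
    for i, h in enumerate((0.2, 0.5, 0.8)):
        spec = FbmSpec(hurst=h, n=n, seed=int(seeds[3 + i]))
        emit(f"fbm_h{int(h * 10):02d}.txt", gen_fbm(spec), spec)
    flm_spec = FlmSpec(alpha=1.0, hurst=0.5, n=n, seed=int(seeds[6]))
    emit("flm_alpha1_h05.txt", gen_flm(flm_spec), flm_spec)

    x1 = gen_noise(NoiseSpec("white", n, int(seeds[7])))
    x1.label = "x1"
    emit("x1.txt", x1, NoiseSpec("white", n, int(seeds[7])))
    x2 = TimeSeries(5.0 * x1.values, label="x2")
    emit("x2.txt", x2, {"derived": "5 * x1"})
    x3 = apply_gain(x1, blockwise_gain(n))
    x3.label = "x3"
    emit("x3.txt", x3, {"derived": "x1 * five-block gain (1,3,10,4,1)"})

    # synthetic stand-in for a real EEG segment, in the same file dialect
    pink = gen_noise(NoiseSpec("pink", 4097, int(seeds[2])))
    eeg = TimeSeries(np.round(100.0 * pink.values), label="synthetic_eeg")
    emit("synthetic_eeg_segment.txt", eeg,
         {"derived": "pink noise x100 rounded to integers; synthetic stand-in "
                     "for a 4097-sample, 173.61 Hz EEG segment"})

    manifest = {"seed": seed, "n_files": len(entries), "files": entries,
                "versions": {"rangeen": __version__, "numpy": np.__version__}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
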