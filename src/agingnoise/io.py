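"""Config resolution, CSV readers/writers and the analysis orchestration.

CSV dialect everywhere: comma-separated, header row, UTF-8, '.' decimal,
times in minutes as floats, intensities as floats in arbitrary units.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import KineticRates, PromoterRates
from .pipeline import (
    CellTrace,
    PipelineConfig,
    aggregate_population,
    catastrophe_analysis,
    division_time_correlation,
    estimate_background,
    filter_cohort,
    generational_mean_profile,
    per_cell_windows,
    rls_summary,
    subtract_background,
)
from .synthetic import AgingSchedule

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "SweepConfig",
    "load_config",
    "save_config",
    "read_traces",
    "read_divisions",
    "read_pixels",
    "build_cell_traces",
    "frame_backgrounds",
    "run_analysis",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Unknown key, type mismatch or unreadable config file."""


@dataclass
class SimulationConfig:
    """Inputs for a single-trajectory or ensemble simulation run."""

    r_on: float = 0.0229
    r_off: float = 0.0348
    k_m: float = 1.0
    gamma_m: float = 0.05
    k_p: float = 2.0
    gamma_p: float = float(np.log(2.0) / 90.0)
    t_end: float | None = None
    sample_interval: float = 10.0
    n_reps: int = 2000
    seed: int = 0

    @property
    def rates(self) -> PromoterRates:
        return PromoterRates(self.r_on, self.r_off)

    @property
    def kin(self) -> KineticRates:
        return KineticRates(self.k_m, self.gamma_m, self.k_p, self.gamma_p)


@dataclass
class SweepConfig:
    """Inputs for the parameter sweeps (all kinds)."""

    r_on: float = 0.0229
    r_off: float = 0.0348
    k_m: float = 1.0
    gamma_m: float = 0.05
    k_p: float = 2.0
    gamma_p: float = float(np.log(2.0) / 90.0)
    engine: str = "oracle"
    n_reps: int = 2000
    seed: int = 0
    grid_points: int = 5
    grid_span: float = 8.0
    scale_factors: tuple = (1.0, 2.0, 4.0, 8.0)
    fold: float = 10.0
    nonchromatin_points: int = 9

    @property
    def rates(self) -> PromoterRates:
        return PromoterRates(self.r_on, self.r_off)

    @property
    def kin(self) -> KineticRates:
        return KineticRates(self.k_m, self.gamma_m, self.k_p, self.gamma_p)


_NESTED_FIELDS = {
    "rates": PromoterRates,
    "kin": KineticRates,
    "schedule": AgingSchedule,
}


def _build_dataclass(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)} for {cls.__name__}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED_FIELDS and isinstance(value, dict):
            value = _build_dataclass(_NESTED_FIELDS[key], value, f"{path}.{key}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path, cls=PipelineConfig):
    """Parse a YAML or JSON config into a validated dataclass.

    Unknown keys are rejected; missing keys fall back to the documented
    defaults of the dataclass.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return _build_dataclass(cls, data, str(path))


def save_config(config, path) -> None:
    """Serialize a config dataclass to YAML (nested dataclasses included)."""
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=True))


def _read_table(path, required: dict) -> pd.DataFrame:
    path = Path(path)
    # round_trip parsing: re-reading a written table reproduces floats exactly,
    # so downstream results are independent of row order and rewrite cycles
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col, dtype in required.items():
        try:
            df[col] = df[col].astype(dtype)
        except (TypeError, ValueError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()[:5]
            raise ValueError(
                f"{path}: column {col} not convertible to {dtype}; "
                f"first bad rows (0-based) {bad}"
            ) from exc
    log.info("%s: %d rows", path.name, len(df))
    return df


def read_traces(path) -> pd.DataFrame:
    """Snapshot table; rows canonically sorted by (cell_id, time_min).

    Duplicate (cell_id, time_min) pairs are an error: after sorting they are
    the only way per-cell times can fail to be strictly increasing.
    """
    df = _read_table(path, {
        "cell_id": str, "time_min": float, "frame_id": int, "raw_intensity": float,
    })
    df = df.sort_values(["cell_id", "time_min"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["cell_id", "time_min"])
    if dup.any():
        rows = df.loc[dup, ["cell_id", "time_min"]].head(5).to_dict("records")
        raise ValueError(f"duplicate (cell_id, time_min) pairs, e.g. {rows}")
    return df


def read_divisions(path) -> pd.DataFrame:
    df = _read_table(path, {"cell_id": str, "division_time_min": float})
    df = df.sort_values(["cell_id", "division_time_min"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["cell_id", "division_time_min"])
    if dup.any():
        raise ValueError("duplicate division times within a cell")
    return df


def read_pixels(path) -> pd.DataFrame:
    return _read_table(path, {"frame_id": int, "pixel_intensity": float})


def build_cell_traces(traces: pd.DataFrame, divisions: pd.DataFrame) -> list[CellTrace]:
    """Join the snapshot and division tables into CellTrace objects."""
    div_groups = {cid: grp["division_time_min"].to_numpy()
                  for cid, grp in divisions.groupby("cell_id")}
    out = []
    for cid, grp in traces.groupby("cell_id"):
        if cid not in div_groups:
            raise ValueError(f"cell {cid} present in traces but has no division rows")
        out.append(CellTrace(
            cell_id=str(cid),
            times=grp["time_min"].to_numpy(),
            frame_ids=grp["frame_id"].to_numpy(),
            intensities=grp["raw_intensity"].to_numpy(),
            division_times=div_groups[cid],
        ))
    return out


def frame_backgrounds(pixels: pd.DataFrame, percentile: float = 10.0) -> dict:
    """Per-frame nearest-rank bottom-percentile background estimates."""
    return {
        int(fid): estimate_background(grp["pixel_intensity"].to_numpy(), percentile)
        for fid, grp in pixels.groupby("frame_id")
    }


def run_analysis(
    traces_path,
    divisions_path,
    pixels_path,
    config: PipelineConfig | None = None,
    outdir=None,
) -> dict:
    """Full pipeline run from CSV inputs; optionally writes the output files.

    Returns a dict with the in-memory results: population (PopulationSummary),
    catastrophe (CatastropheResult), rls (RlsSummary), correlations
    (DataFrame), profile (DataFrame), report (FilterReport).
    """
    config = config or PipelineConfig()
    traces_df = read_traces(traces_path)
    divisions_df = read_divisions(divisions_path)
    pixels_df = read_pixels(pixels_path)
    backgrounds = frame_backgrounds(pixels_df, config.background_percentile)
    raw_cells = build_cell_traces(traces_df, divisions_df)
    corrected = [subtract_background(tr, backgrounds) for tr in raw_cells]

    rls = rls_summary([tr.lifespan for tr in corrected])
    kept, report = filter_cohort(corrected, config)
    windows = [ws for tr in kept for ws in per_cell_windows(tr, config)]
    population = aggregate_population(windows, config)
    profile = generational_mean_profile(kept)
    catastrophe = catastrophe_analysis(corrected, config)
    analyzed_untrimmed = [
        tr for tr in corrected
        if tr.cell_id in {k.cell_id for k in kept}
    ]
    correlations = division_time_correlation(analyzed_untrimmed)

    results = {
        "population": population,
        "catastrophe": catastrophe,
        "rls": rls,
        "correlations": correlations,
        "profile": profile,
        "report": report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        population.table.to_csv(outdir / "windowed_summary.csv", index=False)
        catastrophe.windows.to_csv(outdir / "catastrophe_summary.csv", index=False)
        catastrophe.durations.to_csv(outdir / "catastrophe_durations.csv", index=False)
        rls.viability.to_csv(outdir / "rls.csv", index=False)
        correlations.to_csv(outdir / "correlations.csv", index=False)
        profile.to_csv(outdir / "generation_profile.csv", index=False)
        exclusions = report.as_dict()
        exclusions["mean_rls"] = rls.mean_rls
        (outdir / "exclusions.json").write_text(json.dumps(exclusions, indent=1))
        resolved = dataclasses.asdict(config)
        resolved["agingnoise_version"] = __version__
        (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    return results
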