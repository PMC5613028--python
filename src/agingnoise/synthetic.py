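"""Synthetic aging-cohort generator with attached ground truth.

Emulates mother-cell fluorescence trajectories from a microfluidic
replicative-aging experiment: YFP sampled every 10 min (4-9 snapshots per
generation at baseline 40-90 min generation durations), replicative
lifespans averaging ~23 generations in [4, 53], promoter transition rates
that rise with age up to a plateau generation (the aging schedule), a
catastrophe phase over the final four generations with lengthened and more
variable generation durations plus ramped extrinsic intensity noise, a
minority of OFF cells, and per-frame background offsets recoverable from
emitted pixel samples.

Protein dilution is handled by explicit division: molecule counts are
partitioned binomially at each division and there is no continuous protein
removal between divisions. The reported intensity is a concentration proxy,
scale x count / volume, with cell volume doubling exponentially across each
generation and resetting at division (consistent with the binomial split),
times a mean-corrected lognormal measurement factor.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._ssa import ssa_segment
from .model import GAL1_RATES, KineticRates, PromoterRates
from .pipeline import CellTrace

__all__ = [
    "AgingSchedule",
    "CohortConfig",
    "Cohort",
    "rate_schedule",
    "generate_cohort",
    "scenario_preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class AgingSchedule:
    """How promoter transition rates change with generation number.

    proportional: both rates scaled by s(g) = 1 + (scale_at_plateau - 1) *
    min(g, plateau)/plateau — the mean-conserving aging path; r_on_only
    scales only the opening rate (mean rises); constant leaves rates fixed.
    """

    mode: str = "proportional"
    scale_at_plateau: float = 3.0
    plateau_generation: int = 16

    def __post_init__(self):
        if self.mode not in ("proportional", "r_on_only", "constant"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.scale_at_plateau < 1:
            raise ValueError("scale_at_plateau must be >= 1")
        if self.plateau_generation < 1:
            raise ValueError("plateau_generation must be >= 1")


def rate_schedule(base: PromoterRates, schedule: AgingSchedule, generation: int) -> PromoterRates:
    """Promoter rates in effect during a given (1-based) generation."""
    if generation < 1:
        raise ValueError("generation must be >= 1")
    if schedule.mode == "constant":
        return base
    s = 1.0 + (schedule.scale_at_plateau - 1.0) * min(
        generation, schedule.plateau_generation
    ) / schedule.plateau_generation
    if schedule.mode == "proportional":
        return PromoterRates(base.r_on * s, base.r_off * s)
    return PromoterRates(base.r_on * s, base.r_off)  # r_on_only


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    name: str = "custom"
    n_cells: int = 59
    lifespan_mean: float = 23.0
    lifespan_min: int = 4
    lifespan_max: int = 53
    lifespan_shape: float = 4.0  # gamma shape; scale = mean/shape
    rates: PromoterRates = field(default_factory=lambda: GAL1_RATES)
    kin: KineticRates = field(default_factory=KineticRates)
    schedule: AgingSchedule = field(default_factory=AgingSchedule)
    gen_duration_min: float = 40.0
    gen_duration_max: float = 90.0
    catastrophe_len: int = 4
    catastrophe_duration_mean_factor: float = 1.8
    catastrophe_duration_sd_factor: float = 2.5
    catastrophe_sigma: float = 0.35  # extrinsic lognormal sigma at the last generation
    snapshot_interval: float = 10.0
    intensity_scale: float = 2.0
    measurement_sigma: float = 0.05
    off_fraction: float = 0.1
    off_leak_k_m: float = 0.05  # transcription rate of silenced (OFF) cells
    background_level: float = 300.0
    background_frame_sd: float = 30.0
    pixel_spread: float = 500.0
    n_pixels_per_frame: int = 150
    burnin_generations: int = 3

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 <= self.off_fraction <= 1):
            raise ValueError("off_fraction must be in [0, 1]")
        if self.gen_duration_min < self.snapshot_interval:
            raise ValueError("generation durations shorter than the snapshot interval")
        if self.lifespan_min < 1 or self.lifespan_max < self.lifespan_min:
            raise ValueError("invalid lifespan bounds")


@dataclass
class Cohort:
    """Generated tables plus ground truth."""

    traces: pd.DataFrame      # cell_id, time_min, frame_id, raw_intensity
    divisions: pd.DataFrame   # cell_id, division_time_min
    pixels: pd.DataFrame      # frame_id, pixel_intensity
    truth: dict
    config: CohortConfig
    seed: int

    def cell_traces(self) -> list[CellTrace]:
        """Raw (not background-subtracted) CellTrace objects."""
        out = []
        div = self.divisions.groupby("cell_id")["division_time_min"]
        for cid, grp in self.traces.groupby("cell_id", sort=False):
            out.append(CellTrace(
                cell_id=str(cid),
                times=grp["time_min"].to_numpy(),
                frame_ids=grp["frame_id"].to_numpy(),
                intensities=grp["raw_intensity"].to_numpy(),
                division_times=div.get_group(cid).to_numpy(),
            ))
        return out

    def write(self, outdir) -> None:
        """Write traces.csv, divisions.csv, pixels.csv, truth.json, config.yaml."""
        import yaml

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(outdir / "traces.csv", index=False)
        self.divisions.to_csv(outdir / "divisions.csv", index=False)
        self.pixels.to_csv(outdir / "pixels.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))
        resolved = dataclasses.asdict(self.config)
        resolved["seed"] = self.seed
        (outdir / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))


def _draw_lifespan(rng: np.random.Generator, cfg: CohortConfig) -> int:
    scale = cfg.lifespan_mean / cfg.lifespan_shape
    for _ in range(10000):
        ls = int(round(rng.gamma(cfg.lifespan_shape, scale)))
        if cfg.lifespan_min <= ls <= cfg.lifespan_max:
            return ls
    raise RuntimeError("lifespan sampling failed to land in bounds")


def _draw_durations(rng: np.random.Generator, cfg: CohortConfig, lifespan: int) -> np.ndarray:
    """Generation durations; the final catastrophe generations are inflated
    with a linear ramp toward death."""
    base_mean = 0.5 * (cfg.gen_duration_min + cfg.gen_duration_max)
    base_sd = (cfg.gen_duration_max - cfg.gen_duration_min) / math.sqrt(12.0)
    out = np.empty(lifespan)
    for g in range(1, lifespan + 1):
        back = lifespan - g + 1  # 1 = last generation
        if back <= cfg.catastrophe_len:
            w = (cfg.catastrophe_len - back + 1) / cfg.catastrophe_len
            mu = base_mean * (1 + (cfg.catastrophe_duration_mean_factor - 1) * w)
            sd = base_sd * (1 + (cfg.catastrophe_duration_sd_factor - 1) * w)
            out[g - 1] = max(rng.normal(mu, sd), 1.5 * cfg.snapshot_interval)
        else:
            out[g - 1] = rng.uniform(cfg.gen_duration_min, cfg.gen_duration_max)
    return out


def _catastrophe_sigma(cfg: CohortConfig, back: int) -> float:
    """Extrinsic lognormal sigma for a generation counted back from death."""
    if back > cfg.catastrophe_len:
        return 0.0
    w = (cfg.catastrophe_len - back + 1) / cfg.catastrophe_len
    return cfg.catastrophe_sigma * w


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate a cohort of mother cells and emit pipeline-ready tables.

    Per cell: lifespan from the truncated discretized gamma; per-generation
    promoter rates from the aging schedule; exact SSA within each generation
    with binomial partition of mRNA and protein at divisions; burn-in
    generations (not emitted) to relax the initial state. Identical seeds
    yield byte-identical tables.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    kin = cfg.kin
    n_off = int(round(cfg.off_fraction * cfg.n_cells))
    off_flags = np.zeros(cfg.n_cells, dtype=bool)
    off_flags[:n_off] = True
    off_flags = off_flags[rng.permutation(cfg.n_cells)]

    trace_rows, division_rows = [], []
    truth_cells = {}
    max_time = 0.0
    dt = cfg.snapshot_interval

    for i in range(cfg.n_cells):
        cid = f"cell{i:04d}"
        is_off = bool(off_flags[i])
        lifespan = _draw_lifespan(rng, cfg)
        durations = _draw_durations(rng, cfg, lifespan)
        div_times = np.concatenate([[0.0], np.cumsum(durations)])
        total = div_times[-1]
        max_time = max(max_time, total)

        if is_off:
            base = PromoterRates(r_on=1.0, r_off=0.0)
            cell_kin = KineticRates(cfg.off_leak_k_m, kin.gamma_m, kin.k_p, 0.0)
            gen_rates = [base] * lifespan
        else:
            base = cfg.rates
            cell_kin = KineticRates(kin.k_m, kin.gamma_m, kin.k_p, 0.0)
            gen_rates = [rate_schedule(base, cfg.schedule, g) for g in range(1, lifespan + 1)]

        # initial state near its stationary point, then burn-in generations
        p_on0 = gen_rates[0].p_on
        mean_m0 = cell_kin.k_m * p_on0 / cell_kin.gamma_m
        mean_T = 0.5 * (cfg.gen_duration_min + cfg.gen_duration_max)
        g_state = 1 if rng.random() < p_on0 else 0
        m_state = int(round(mean_m0))
        p_state = int(round(cell_kin.k_p * mean_m0 * mean_T))
        empty = np.empty(0, dtype=float)
        for _ in range(cfg.burnin_generations):
            dur = rng.uniform(cfg.gen_duration_min, cfg.gen_duration_max)
            sseed = int(rng.integers(0, 2**31 - 1))
            _, _, _, g_state, m_state, p_state = ssa_segment(
                gen_rates[0].r_on, gen_rates[0].r_off,
                cell_kin.k_m, cell_kin.gamma_m, cell_kin.k_p, cell_kin.gamma_p,
                g_state, m_state, p_state, empty, dur, sseed,
            )
            m_state = int(rng.binomial(m_state, 0.5))
            p_state = int(rng.binomial(p_state, 0.5))

        for g in range(1, lifespan + 1):
            t0, t1 = div_times[g - 1], div_times[g]
            grid = np.arange(math.ceil(t0 / dt - 1e-9), math.ceil(t1 / dt - 1e-9)) * dt
            grid = grid[(grid >= t0) & (grid < t1)]
            offsets = grid - t0
            sseed = int(rng.integers(0, 2**31 - 1))
            r = gen_rates[g - 1]
            _, _, p_samp, g_state, m_state, p_state = ssa_segment(
                r.r_on, r.r_off,
                cell_kin.k_m, cell_kin.gamma_m, cell_kin.k_p, cell_kin.gamma_p,
                g_state, m_state, p_state, offsets, t1 - t0, sseed,
            )
            sigma = math.sqrt(
                cfg.measurement_sigma**2
                + _catastrophe_sigma(cfg, lifespan - g + 1) ** 2
            )
            duration = t1 - t0
            for t, p_val in zip(grid, p_samp):
                mult = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma > 0 else 1.0
                volume = 2.0 ** ((t - t0) / duration)  # doubles over the generation
                trace_rows.append({
                    "cell_id": cid,
                    "time_min": float(t),
                    "frame_id": int(round(t / dt)),
                    "true_intensity": cfg.intensity_scale * p_val / volume * mult,
                })
            m_state = int(rng.binomial(m_state, 0.5))
            p_state = int(rng.binomial(p_state, 0.5))

        for t in div_times:
            division_rows.append({"cell_id": cid, "division_time_min": float(t)})
        truth_cells[cid] = {
            "lifespan": lifespan,
            "on": not is_off,
            "division_times": [float(t) for t in div_times],
            "rates_per_generation": [
                {"r_on": r.r_on, "r_off": r.r_off} for r in gen_rates
            ],
        }

    # per-frame backgrounds and pixel samples; the nearest-rank bottom-percentile
    # pixel sits within pixel_spread/100 of the true background by construction
    n_frames = int(math.floor(max_time / dt)) + 1
    frame_bg = {}
    pixel_rows = []
    for f in range(n_frames):
        b = max(rng.normal(cfg.background_level, cfg.background_frame_sd), 0.0)
        frame_bg[f] = float(b)
        pix = b + cfg.pixel_spread * rng.random(cfg.n_pixels_per_frame) ** 2
        for v in pix:
            pixel_rows.append({"frame_id": f, "pixel_intensity": float(v)})

    traces = pd.DataFrame(trace_rows)
    traces["raw_intensity"] = traces["true_intensity"] + traces["frame_id"].map(frame_bg)
    traces = traces[["cell_id", "time_min", "frame_id", "raw_intensity"]]
    divisions = pd.DataFrame(division_rows)
    pixels = pd.DataFrame(pixel_rows)
    truth = {
        "cells": truth_cells,
        "frame_backgrounds": frame_bg,
        "seed": seed,
        "preset": cfg.name,
    }
    return Cohort(traces=traces, divisions=divisions, pixels=pixels,
                  truth=truth, config=cfg, seed=seed)


PRESET_NAMES = ("wt", "gal80del", "rpd3del", "synthetic_promoter", "synthetic_gal80del")


def scenario_preset(name: str) -> CohortConfig:
    """Cohort configuration qualitatively matching one of the five strains.

    wt: native promoter, mean-conserving aging (proportional x3 by gen 16).
    gal80del: constitutive network — slower young-cell switching (noisier,
    brighter), strong reduction. rpd3del: long-lived, weakest rate scaling
    and mildest catastrophe. synthetic_promoter: nucleosome-disfavoring
    edits raise the opening rate (brighter), reduction preserved.
    synthetic_gal80del: near the fast-switching noise floor already in young
    cells; rates constant with age.
    """
    if name == "wt":
        return CohortConfig(name="wt", n_cells=59)
    if name == "gal80del":
        return CohortConfig(
            name="gal80del", n_cells=102,
            rates=PromoterRates(GAL1_RATES.r_on * 0.5, GAL1_RATES.r_off * 0.5),
            kin=KineticRates(k_m=1.5),
        )
    if name == "rpd3del":
        return CohortConfig(
            name="rpd3del", n_cells=52,
            lifespan_mean=28.0,
            schedule=AgingSchedule(mode="proportional", scale_at_plateau=1.5),
            catastrophe_duration_mean_factor=1.4,
            catastrophe_duration_sd_factor=1.8,
            catastrophe_sigma=0.2,
        )
    if name == "synthetic_promoter":
        return CohortConfig(
            name="synthetic_promoter", n_cells=73,
            rates=PromoterRates(GAL1_RATES.r_on * 3.0, GAL1_RATES.r_off),
        )
    if name == "synthetic_gal80del":
        return CohortConfig(
            name="synthetic_gal80del", n_cells=82,
            rates=PromoterRates(GAL1_RATES.r_on * 20.0, GAL1_RATES.r_off * 20.0),
            kin=KineticRates(k_m=2.0),
            schedule=AgingSchedule(mode="constant"),
        )
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
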