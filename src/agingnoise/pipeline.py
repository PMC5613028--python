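"""Generation-windowed noise analysis of mother-cell fluorescence trajectories.

The pipeline starts from extracted per-cell intensity snapshots plus per-frame
background pixel samples and reproduces the trajectory-analysis procedure of
microfluidic replicative-aging experiments:

1. per-frame background = nearest-rank bottom-percentile pixel, subtracted
   from every snapshot taken in that frame;
2. ON/OFF classification by lifespan-average corrected intensity
   (>= 1000 a.u. is ON);
3. cohort filters: ON cells only, replicative lifespan >= 10 generations,
   snapshots of the final four ("catastrophe") generations removed;
4. snapshots assigned to generations by the division times (half-open
   intervals, 1-based), grouped into non-overlapping two-generation windows
   aligned from birth; a window needs both generations retained, >= 4
   snapshots per generation and >= 8 in total;
5. per-cell window statistics (mean, CV, Fano) computed first, then averaged
   across cells per window — the cell-intrinsic construction; windows with
   fewer than 10 cells are flagged and suppressed from the summary;
6. death-aligned catastrophe analysis, expression/division-time correlations
   and replicative-lifespan summaries on the side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import InsufficientDataError, SampleStats, UndefinedRatioError, compute_stats

__all__ = [
    "CellTrace",
    "GenerationRecord",
    "WindowStat",
    "PipelineConfig",
    "FilterReport",
    "PopulationSummary",
    "CatastropheResult",
    "RlsSummary",
    "estimate_background",
    "subtract_background",
    "classify_on",
    "assign_generations",
    "filter_cohort",
    "per_cell_windows",
    "aggregate_population",
    "generational_mean_profile",
    "catastrophe_analysis",
    "division_time_correlation",
    "rls_summary",
]

log = logging.getLogger(__name__)


@dataclass
class CellTrace:
    """One mother cell's time-stamped fluorescence snapshots.

    division_times mark generation boundaries: generation g (1-based) is the
    half-open interval [division_times[g-1], division_times[g]).
    """

    cell_id: str
    times: np.ndarray
    frame_ids: np.ndarray
    intensities: np.ndarray
    division_times: np.ndarray
    background_subtracted: bool = False
    total_lifespan: int | None = None  # set when catastrophe generations are trimmed

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.division_times = np.asarray(self.division_times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"cell {self.cell_id}: snapshot times not strictly increasing")
        if np.any(np.diff(self.division_times) <= 0):
            raise ValueError(f"cell {self.cell_id}: division times not strictly increasing")

    @property
    def lifespan(self) -> int:
        """Number of generation intervals covered by the division times."""
        return len(self.division_times) - 1

    @property
    def full_lifespan(self) -> int:
        """Replicative lifespan before any catastrophe trimming."""
        return self.total_lifespan if self.total_lifespan is not None else self.lifespan


@dataclass
class GenerationRecord:
    cell_id: str
    generation_index: int  # 1-based
    times: np.ndarray
    intensities: np.ndarray
    duration: float


@dataclass
class WindowStat:
    """Per-cell statistics over one two-generation window (1-based index;
    window w covers generations 2w-1 and 2w)."""

    cell_id: str
    window_index: int
    stats: SampleStats


@dataclass
class PipelineConfig:
    """Analysis defaults mirroring the experimental protocol."""

    on_threshold: float = 1000.0
    min_lifespan: int = 10
    catastrophe_len: int = 4
    window_size: int = 2
    min_snapshots_per_gen: int = 4
    min_snapshots_per_window: int = 8
    background_percentile: float = 10.0
    min_cells_per_window: int = 10

    def __post_init__(self):
        for name in (
            "on_threshold", "min_lifespan", "catastrophe_len", "window_size",
            "min_snapshots_per_gen", "min_snapshots_per_window",
            "background_percentile", "min_cells_per_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.background_percentile > 100:
            raise ValueError("background_percentile must be in (0, 100]")


@dataclass
class FilterReport:
    """Exclusion bookkeeping from filter_cohort."""

    n_input: int
    n_off: int
    n_short_lifespan: int
    n_kept: int
    off_cells: list = field(default_factory=list)
    short_cells: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_off": self.n_off,
            "n_short_lifespan": self.n_short_lifespan,
            "n_kept": self.n_kept,
            "off_cells": list(self.off_cells),
            "short_cells": list(self.short_cells),
        }


def estimate_background(pixel_intensities, percentile: float = 10.0) -> float:
    """Nearest-rank percentile of a frame's pixel intensities.

    The value at (1-based) index ceil(q/100 * n) of the ascending sort; for
    q = 10 and n = 100 this is the 10th-lowest pixel.
    """
    x = np.sort(np.asarray(pixel_intensities, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty pixel vector")
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(x[rank - 1])


def subtract_background(trace: CellTrace, backgrounds) -> CellTrace:
    """Subtract the per-frame background from each snapshot.

    backgrounds maps frame_id -> background intensity. Negative corrected
    values are retained (clamping would bias window means upward).
    """
    corrected = np.empty_like(trace.intensities)
    for i, fid in enumerate(trace.frame_ids):
        if fid not in backgrounds:
            raise KeyError(f"no background for frame {fid} (cell {trace.cell_id})")
        corrected[i] = trace.intensities[i] - backgrounds[fid]
    out = replace(trace, intensities=corrected)
    out.background_subtracted = True
    return out


def classify_on(trace: CellTrace, on_threshold: float = 1000.0) -> bool:
    """True (ON) iff the lifespan-average corrected intensity >= threshold."""
    if trace.times.size < 1:
        raise ValueError(f"cell {trace.cell_id} has no snapshots")
    return bool(trace.intensities.mean() >= on_threshold)


def assign_generations(trace: CellTrace) -> tuple[list[GenerationRecord], int]:
    """Assign snapshots to generations; returns (records, n_dropped).

    Snapshot at time t belongs to generation g iff
    division_times[g-1] <= t < division_times[g]. Snapshots outside all
    generation intervals are dropped and counted.
    """
    div = trace.division_times
    idx = np.searchsorted(div, trace.times, side="right")  # == generation index
    in_range = (idx >= 1) & (idx <= trace.lifespan)
    n_dropped = int((~in_range).sum())
    if n_dropped:
        log.info("cell %s: dropped %d snapshots outside generation bounds",
                 trace.cell_id, n_dropped)
    records = []
    for g in range(1, trace.lifespan + 1):
        mask = in_range & (idx == g)
        records.append(GenerationRecord(
            cell_id=trace.cell_id,
            generation_index=g,
            times=trace.times[mask],
            intensities=trace.intensities[mask],
            duration=float(div[g] - div[g - 1]),
        ))
    return records, n_dropped


def _trim_catastrophe(trace: CellTrace, catastrophe_len: int) -> CellTrace:
    """Remove all snapshots from the final catastrophe_len generations."""
    L = trace.lifespan
    keep_gens = max(L - catastrophe_len, 0)
    cutoff = trace.division_times[keep_gens]
    mask = trace.times < cutoff
    out = replace(
        trace,
        times=trace.times[mask],
        frame_ids=trace.frame_ids[mask],
        intensities=trace.intensities[mask],
        division_times=trace.division_times[: keep_gens + 1],
    )
    out.total_lifespan = L
    return out


def filter_cohort(
    traces, config: PipelineConfig | None = None, drop_catastrophe: bool = True
) -> tuple[list[CellTrace], FilterReport]:
    """Keep ON cells with lifespan >= min_lifespan; trim catastrophe snapshots.

    Raises if nothing survives (there would be nothing to analyze).
    """
    config = config or PipelineConfig()
    traces = list(traces)
    kept: list[CellTrace] = []
    off_cells, short_cells = [], []
    for tr in traces:
        if not classify_on(tr, config.on_threshold):
            off_cells.append(tr.cell_id)
            continue
        if tr.lifespan < config.min_lifespan:
            short_cells.append(tr.cell_id)
            continue
        kept.append(_trim_catastrophe(tr, config.catastrophe_len) if drop_catastrophe else tr)
    report = FilterReport(
        n_input=len(traces),
        n_off=len(off_cells),
        n_short_lifespan=len(short_cells),
        n_kept=len(kept),
        off_cells=off_cells,
        short_cells=short_cells,
    )
    if not kept:
        raise ValueError("no cells survive the cohort filters; nothing to analyze")
    log.info("cohort filter: %d in, %d OFF, %d short-lived, %d kept",
             report.n_input, report.n_off, report.n_short_lifespan, report.n_kept)
    return kept, report


def per_cell_windows(trace: CellTrace, config: PipelineConfig | None = None) -> list[WindowStat]:
    """Two-generation window statistics for one (filtered) cell.

    Windows are aligned from generation 1; a window is emitted only if both
    its generations are retained, each carries >= min_snapshots_per_gen
    snapshots, and the pooled window total is >= min_snapshots_per_window.
    The trailing incomplete window is discarded.
    """
    config = config or PipelineConfig()
    gens, _ = assign_generations(trace)
    w = config.window_size
    out: list[WindowStat] = []
    for win in range(1, len(gens) // w + 1):
        block = gens[(win - 1) * w: win * w]
        if any(g.times.size < config.min_snapshots_per_gen for g in block):
            continue
        pooled = np.concatenate([g.intensities for g in block])
        if pooled.size < config.min_snapshots_per_window:
            continue
        try:
            stats = compute_stats(pooled)
        except (InsufficientDataError, UndefinedRatioError):
            continue
        out.append(WindowStat(cell_id=trace.cell_id, window_index=win, stats=stats))
    return out


@dataclass
class PopulationSummary:
    """Cross-cell aggregates per two-generation window.

    table holds every window with its cell count and a below-min-cells flag;
    summary exposes only the windows meeting the minimum cell count.
    """

    table: pd.DataFrame
    min_cells: int

    @property
    def summary(self) -> pd.DataFrame:
        return self.table[self.table["included"]].drop(columns=["included"])


def aggregate_population(
    window_stats, config: PipelineConfig | None = None
) -> PopulationSummary:
    """Average per-cell window statistics across cells, window by window.

    Per window: n_cells; mean and SD of the per-cell window means; mean and
    SEM of the per-cell CVs and Fano factors. Windows with fewer than
    min_cells_per_window cells are flagged (included=False), not silently
    dropped.
    """
    config = config or PipelineConfig()
    rows = []
    by_window: dict[int, list[WindowStat]] = {}
    for ws in window_stats:
        by_window.setdefault(ws.window_index, []).append(ws)
    for win in sorted(by_window):
        group = by_window[win]
        means = np.array([g.stats.mean for g in group])
        cvs = np.array([g.stats.cv for g in group])
        fanos = np.array([g.stats.fano for g in group])
        n = len(group)
        sd = float(means.std(ddof=1)) if n > 1 else 0.0
        sem_cv = float(cvs.std(ddof=1)) / math.sqrt(n) if n > 1 else 0.0
        sem_fano = float(fanos.std(ddof=1)) / math.sqrt(n) if n > 1 else 0.0
        rows.append({
            "window_index": win,
            "n_cells": n,
            "mean_intensity": float(means.mean()),
            "sd_intensity": sd,
            "mean_cv": float(cvs.mean()),
            "sem_cv": sem_cv,
            "mean_fano": float(fanos.mean()),
            "sem_fano": sem_fano,
            "included": n >= config.min_cells_per_window,
        })
    table = pd.DataFrame(rows, columns=[
        "window_index", "n_cells", "mean_intensity", "sd_intensity",
        "mean_cv", "sem_cv", "mean_fano", "sem_fano", "included",
    ])
    return PopulationSummary(table=table, min_cells=config.min_cells_per_window)


def generational_mean_profile(traces) -> pd.DataFrame:
    """Per-generation average of per-cell generation means."""
    acc: dict[int, list[float]] = {}
    for tr in traces:
        gens, _ = assign_generations(tr)
        for g in gens:
            if g.times.size:
                acc.setdefault(g.generation_index, []).append(float(g.intensities.mean()))
    rows = [
        {"generation": g, "mean_intensity": float(np.mean(v)), "n_cells": len(v)}
        for g, v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["generation", "mean_intensity", "n_cells"])


@dataclass
class CatastropheResult:
    """Death-aligned window noise and generation-duration statistics.

    windows: indexed by windows_before_death (1 = the final two generations,
    2 = the two before those, ...). durations: indexed by
    generations_before_death (1 = the last generation).
    """

    windows: pd.DataFrame
    durations: pd.DataFrame


def catastrophe_analysis(
    traces, config: PipelineConfig | None = None
) -> CatastropheResult:
    """Death-aligned two-generation-window analysis keeping the final generations.

    Takes untrimmed traces (background-corrected), applies the ON and
    minimum-lifespan filters but NOT the last-four-generation exclusion,
    aligns cells by their last generation, forms two-generation windows
    counting backwards from death, and aggregates per-cell statistics across
    cells. Also returns generation-duration mean/SD by generations before
    death.
    """
    config = config or PipelineConfig()
    kept = [
        tr for tr in traces
        if classify_on(tr, config.on_threshold) and tr.lifespan >= config.min_lifespan
    ]
    win_acc: dict[int, list[SampleStats]] = {}
    dur_acc: dict[int, list[float]] = {}
    for tr in kept:
        gens, _ = assign_generations(tr)
        L = len(gens)
        for g in gens:
            back = L - g.generation_index + 1  # 1 = last generation
            dur_acc.setdefault(back, []).append(g.duration)
        for k in range(1, L // 2 + 1):  # window k = generations L-2k+1 .. L-2k+2
            block = gens[L - 2 * k: L - 2 * k + 2]
            if any(b.times.size < config.min_snapshots_per_gen for b in block):
                continue
            pooled = np.concatenate([b.intensities for b in block])
            if pooled.size < config.min_snapshots_per_window:
                continue
            try:
                win_acc.setdefault(k, []).append(compute_stats(pooled))
            except (InsufficientDataError, UndefinedRatioError):
                continue
    wrows = []
    for k in sorted(win_acc):
        group = win_acc[k]
        cvs = np.array([s.cv for s in group])
        fanos = np.array([s.fano for s in group])
        n = len(group)
        wrows.append({
            "windows_before_death": k,
            "n_cells": n,
            "mean_cv": float(cvs.mean()),
            "sem_cv": float(cvs.std(ddof=1)) / math.sqrt(n) if n > 1 else 0.0,
            "mean_fano": float(fanos.mean()),
            "sem_fano": float(fanos.std(ddof=1)) / math.sqrt(n) if n > 1 else 0.0,
        })
    drows = []
    for k in sorted(dur_acc):
        d = np.asarray(dur_acc[k])
        drows.append({
            "generations_before_death": k,
            "n_cells": d.size,
            "mean_duration": float(d.mean()),
            "sd_duration": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        })
    return CatastropheResult(
        windows=pd.DataFrame(wrows, columns=[
            "windows_before_death", "n_cells", "mean_cv", "sem_cv",
            "mean_fano", "sem_fano",
        ]),
        durations=pd.DataFrame(drows, columns=[
            "generations_before_death", "n_cells", "mean_duration", "sd_duration",
        ]),
    )


def division_time_correlation(traces, min_cells: int = 3) -> pd.DataFrame:
    """Per-generation Pearson correlation between expression and division time.

    For each generation index, correlates (across cells) the generation-mean
    intensity with the generation duration. Generations with fewer than
    min_cells cells or zero variance in either variable are omitted (with a
    reason in the 'omitted' frame attribute).
    """
    from scipy.stats import pearsonr

    acc: dict[int, list[tuple[float, float]]] = {}
    for tr in traces:
        gens, _ = assign_generations(tr)
        for g in gens:
            if g.times.size:
                acc.setdefault(g.generation_index, []).append(
                    (float(g.intensities.mean()), g.duration)
                )
    rows, omitted = [], {}
    for g in sorted(acc):
        pairs = acc[g]
        if len(pairs) < min_cells:
            omitted[g] = f"only {len(pairs)} cells (< {min_cells})"
            continue
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if x.std() == 0 or y.std() == 0:
            omitted[g] = "zero variance"
            continue
        r, _p = pearsonr(x, y)
        rows.append({"generation": g, "pearson_r": float(r), "n_cells": len(pairs)})
    out = pd.DataFrame(rows, columns=["generation", "pearson_r", "n_cells"])
    out.attrs["omitted"] = omitted
    return out


@dataclass
class RlsSummary:
    mean_rls: float
    viability: pd.DataFrame  # generation, fraction_alive


def rls_summary(lifespans) -> RlsSummary:
    """Viability curve and mean replicative lifespan (short-lived cells included)."""
    ls = np.asarray(list(lifespans), dtype=float)
    if ls.size == 0:
        raise ValueError("need at least one lifespan")
    gens = np.arange(0, int(ls.max()) + 2)
    frac = np.array([(ls >= g).mean() for g in gens])
    viability = pd.DataFrame({"generation": gens, "fraction_alive": frac})
    return RlsSummary(mean_rls=float(ls.mean()), viability=viability)
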