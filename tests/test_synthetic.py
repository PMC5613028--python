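"""Synthetic cohort generator: schedules, presets, ground-truth round trips."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import linregress, spearmanr

from agingnoise.io import frame_backgrounds
from agingnoise.model import GAL1_RATES, KineticRates, moment_oracle
from agingnoise.pipeline import (
    aggregate_population,
    assign_generations,
    classify_on,
    filter_cohort,
    per_cell_windows,
    subtract_background,
)
from agingnoise.synthetic import (
    PRESET_NAMES,
    AgingSchedule,
    CohortConfig,
    generate_cohort,
    rate_schedule,
    scenario_preset,
)


def analyzed_population(cohort, min_cells=10):
    bgs = frame_backgrounds(cohort.pixels)
    corrected = [subtract_background(t, bgs) for t in cohort.cell_traces()]
    kept, report = filter_cohort(corrected)
    windows = [w for t in kept for w in per_cell_windows(t)]
    return aggregate_population(windows), report


class TestRateSchedule:
    def test_constant_mode_returns_base(self):
        sched = AgingSchedule(mode="constant")
        for g in (1, 5, 40):
            assert rate_schedule(GAL1_RATES, sched, g) == GAL1_RATES

    def test_plateau_scaling(self):
        sched = AgingSchedule(mode="proportional", scale_at_plateau=3.0,
                              plateau_generation=16)
        for g in (16, 20, 50):
            r = rate_schedule(GAL1_RATES, sched, g)
            assert r.r_on == pytest.approx(3 * GAL1_RATES.r_on)
            assert r.r_off == pytest.approx(3 * GAL1_RATES.r_off)
        mid = rate_schedule(GAL1_RATES, sched, 8)
        assert mid.r_on == pytest.approx(2 * GAL1_RATES.r_on)

    def test_mean_conserved_only_in_proportional_mode(self):
        kin = KineticRates()
        prop = AgingSchedule(mode="proportional", scale_at_plateau=3.0)
        ron = AgingSchedule(mode="r_on_only", scale_at_plateau=3.0)
        base_mean = moment_oracle(GAL1_RATES, kin).mean_p
        prop_means = [
            moment_oracle(rate_schedule(GAL1_RATES, prop, g), kin).mean_p
            for g in (1, 8, 16, 30)
        ]
        ron_means = [
            moment_oracle(rate_schedule(GAL1_RATES, ron, g), kin).mean_p
            for g in (1, 8, 16, 30)
        ]
        assert np.allclose(prop_means, base_mean, rtol=1e-10)
        assert ron_means[0] < ron_means[1] < ron_means[2]
        assert ron_means[3] == pytest.approx(ron_means[2])  # plateau

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            AgingSchedule(mode="sideways")


class TestGenerateCohort:
    def test_all_off_cohort(self):
        cfg = CohortConfig(n_cells=6, off_fraction=1.0)
        cohort = generate_cohort(cfg, seed=1)
        bgs = frame_backgrounds(cohort.pixels)
        corrected = [subtract_background(t, bgs) for t in cohort.cell_traces()]
        assert not any(classify_on(t) for t in corrected)

    def test_tables_satisfy_pipeline_preconditions(self, wt_cohort):
        assert set(wt_cohort.traces.columns) == {
            "cell_id", "time_min", "frame_id", "raw_intensity"}
        for cid, grp in wt_cohort.traces.groupby("cell_id"):
            assert np.all(np.diff(grp.time_min.values) > 0)
        cells = wt_cohort.cell_traces()
        assert {t.cell_id for t in cells} == set(wt_cohort.truth["cells"])
        for tr in cells:
            truth = wt_cohort.truth["cells"][tr.cell_id]
            assert tr.lifespan == truth["lifespan"]
            gens, dropped = assign_generations(tr)
            assert dropped == 0
            # baseline generations carry 4-9 snapshots at the 10-min interval
            for g in gens[: max(tr.lifespan - 4, 0)]:
                assert 4 <= g.times.size <= 9

    def test_lifespans_within_bounds(self, wt_cohort):
        ls = [c["lifespan"] for c in wt_cohort.truth["cells"].values()]
        assert min(ls) >= 4 and max(ls) <= 53

    def test_background_recoverable_from_pixels(self, wt_cohort):
        bgs = frame_backgrounds(wt_cohort.pixels)
        truth = wt_cohort.truth["frame_backgrounds"]
        err = max(abs(bgs[f] - truth[f]) for f in bgs)
        # nearest-rank 10th pct of the quadratic pixel tail sits within a few
        # percent of the spread above the true background
        assert err < 0.05 * wt_cohort.config.pixel_spread

    def test_same_seed_byte_identical(self, tmp_path):
        cfg = CohortConfig(n_cells=4)
        for sub in ("a", "b"):
            generate_cohort(cfg, seed=9).write(tmp_path / sub)
        for name in ("traces.csv", "divisions.csv", "pixels.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_catastrophe_durations_lengthened(self):
        cfg = CohortConfig(n_cells=30, off_fraction=0.0)
        cohort = generate_cohort(cfg, seed=3)
        early, late = [], []
        for c in cohort.truth["cells"].values():
            div = np.asarray(c["division_times"])
            durs = np.diff(div)
            late.extend(durs[-2:])
            early.extend(durs[: max(len(durs) - 4, 0)])
        assert np.mean(late) > 1.3 * np.mean(early)


class TestPresets:
    def test_cohort_sizes_match_study_design(self):
        sizes = {name: scenario_preset(name).n_cells for name in PRESET_NAMES}
        assert sizes == {
            "wt": 59, "gal80del": 102, "rpd3del": 52,
            "synthetic_promoter": 73, "synthetic_gal80del": 82,
        }

    def test_unknown_preset_lists_names(self):
        with pytest.raises(ValueError, match="wt"):
            scenario_preset("nope")

    def test_gal80del_young_cells_noisier_than_wt(self):
        wt = dataclasses.replace(scenario_preset("wt"), n_cells=40)
        g80 = dataclasses.replace(scenario_preset("gal80del"), n_cells=40)
        pop_wt, _ = analyzed_population(generate_cohort(wt, seed=11))
        pop_g80, _ = analyzed_population(generate_cohort(g80, seed=11))
        young_wt = pop_wt.table.set_index("window_index").loc[1:2, "mean_cv"].mean()
        young_g80 = pop_g80.table.set_index("window_index").loc[1:2, "mean_cv"].mean()
        assert young_g80 > young_wt

    def test_constant_mode_preset_has_no_cv_trend(self):
        cfg = dataclasses.replace(scenario_preset("synthetic_gal80del"), n_cells=50)
        pop, _ = analyzed_population(generate_cohort(cfg, seed=13))
        sub = pop.summary
        res = linregress(sub.window_index.astype(float), sub.mean_cv)
        assert abs(res.slope) < 2.5 * res.stderr


class TestRoundTrip:
    def test_proportional_cohort_cv_decreases(self):
        cfg = dataclasses.replace(scenario_preset("wt"), n_cells=40, off_fraction=0.0)
        pop, _ = analyzed_population(generate_cohort(cfg, seed=5))
        cv = pop.table.set_index("window_index").loc[1:8, "mean_cv"]
        rho, _ = spearmanr(cv.index, cv.values)
        assert rho < 0
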