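# Methods

## The model

The core object is the telegraph (two-state promoter) model of eukaryotic
gene expression, as a continuous-time Markov jump process over
(promoter state g ∈ {OFF, ON}, mRNA count m, protein count p):

| reaction | propensity |
|---|---|
| OFF → ON | r_ON |
| ON → OFF | r_OFF |
| ON → ON + M | k_m |
| M → ∅ | γ_m · m |
| M → M + P | k_p · m |
| P → ∅ | γ_p · p |

Assumptions: transcription only while the chromatin is open; first-order
mRNA decay; protein loss is pure dilution by growth and division (the
fluorescent reporter is stable), reduced to a continuous first-order rate
γ_p for steady-state work. No upstream regulatory species are modelled:
the constitutive-network data motivating the fitted rates make promoter
chromatin dynamics the only slow input, and extrinsic variability enters
only through the synthetic-data generator.

`simulate_ssa` is an exact direct-method Gillespie sampler (numba-compiled;
one RNG stream per replicate derived from a master seed via
`SeedSequence`, so identical inputs give bit-identical trajectories and
replicates are uncorrelated). Zero total propensity freezes the state —
a valid absorbing condition, not an error.

## Exact moments and the noise metrics

All six propensities are linear in the state, so first and second moments
close exactly: the eight stationary unknowns
(E[g], E[m], E[p], E[gm], E[m²], E[gp], E[mp], E[p²]) satisfy a linear
system solved by `moment_oracle` with a dense solve (8×8; conditioning is
benign over the 64-fold rate ranges swept here, agreeing with the textbook
telegraph closed forms to ≲1e-10 relative). This oracle is the independent
reference for every simulation-based statistic in the package, and the two
routes are never collapsed: tests always compare SSA ensembles against the
oracle, not against themselves.

Noise is quantified as CV = σ/μ and Fano = σ²/μ. Sample statistics use the
unbiased (n−1) variance convention everywhere, including SD error bars and
SEM = σ/√n: per-window samples hold only 8–18 snapshots, where the n/(n−1)
distinction is material. CV is reported as a ratio, not a percentage.

## Default parameters

Only the promoter rates are experimentally anchored
(r_OFF = 0.0348 min⁻¹, r_ON = 0.0229 min⁻¹ for the native GAL1 promoter).
The non-promoter defaults are this package's choices, all overridable:

* k_m = 1 transcript·min⁻¹ while ON — a moderate burst intensity giving
  ~8 transcripts at steady state;
* γ_m = 0.05 min⁻¹ (~14 min half-life), a typical yeast mRNA;
* k_p = 2 proteins·transcript⁻¹·min⁻¹;
* γ_p = ln2/90 min⁻¹ — pure dilution at a 90-min generation time.

Ensembles measure p at a single horizon t_end = 10/min(γ_m, γ_p, r_ON+r_OFF)
(≥ 10 times the slowest relaxation timescale), not time-averaged, because
the sweeps report per-parameter-point steady-state noise. The default
initial condition draws the promoter from its stationary law with copy
numbers at their state-conditional means, which shortens burn-in; the
horizon rule makes any fixed choice acceptable.

## Rate inversion

`fit_promoter_rates` inverts the moment map: the target mean fixes the ON
occupancy p_on = mean·γ_mγ_p/(k_mk_p); the target CV then fixes
s = r_ON + r_OFF by Brent root-finding on log s against the oracle (CV is
strictly decreasing in s at fixed occupancy). The fast-switching floor
CV² = (1 + k_p/(γ_m+γ_p))/mean is reported when a target is infeasible.
At the p_on = 1 boundary the ON state is absorbing, r_OFF = 0 is returned
and r_ON (unidentifiable) is set to 1 min⁻¹ by convention.

## Trajectory pipeline

Numerical and procedural choices, where the protocol leaves room:

* background = nearest-rank (ceil) bottom-10th-percentile pixel per frame;
  corrected intensities may go negative and are retained (clamping would
  bias window means upward);
* ON means lifespan-average ≥ 1000 a.u. (boundary inclusive);
* generations are 1-based half-open intervals [division g−1, division g);
  a snapshot on a boundary belongs to the later generation;
* two-generation windows are aligned from each cell's first generation;
  window w covers generations 2w−1 and 2w; a window needs both generations
  retained, ≥ 4 snapshots in each and ≥ 8 pooled; the trailing odd
  generation is discarded;
* the last-four-generation exclusion removes snapshots, not windows: a
  window straddling the cutoff loses one generation and is dropped by the
  both-generations rule;
* noise is computed per cell first and averaged across cells afterwards —
  the cell-intrinsic construction. Pooling snapshots across cells first
  would fold cell-to-cell mean differences into the variance; a test
  verifies the two orders disagree on heterogeneous cohorts;
* windows with < 10 contributing cells are flagged and suppressed from the
  population summary, not silently dropped;
* the catastrophe analysis aligns cells by death on a
  generations-before-death axis and pools all cells (rather than grouping
  by exact last-generation value), forming two-generation windows backwards
  from the final generation with the same snapshot rules;
* window boundaries are not re-aligned after the last-four exclusion;
  alignment from birth is kept throughout;
* division-time correlations use Pearson's r across cells per generation,
  omitted when fewer than 3 cells or either variable has zero variance.

CSV readers parse floats in round-trip mode and canonically sort rows, so
results are independent of row order and of write/read cycles; duplicate
(cell, time) pairs are rejected.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
10-min snapshot grid shared across cells (frames indexed by time);
generation durations uniform on [40, 90] min, yielding 4–9 snapshots per
generation; lifespans from a discretized gamma (shape 4, mean 23) truncated
to [4, 53]; promoter rates updated at each division according to an aging
schedule s(g) = 1 + (scale−1)·min(g, plateau)/plateau with defaults
scale = 3, plateau = 16. The proportional default is chosen to produce a
clearly detectable CV decrease at cohort sizes near 60 cells; it is an
assumption, not an estimate of the biological magnitude, which is not
identifiable from published summary trends.

Dilution is explicit here (unlike the steady-state core): no continuous
protein removal within a generation, binomial halving of m and p at each
division, and three unrecorded burn-in generations. The emitted intensity
is a concentration proxy, scale·p/v(t) with cell volume v doubling
exponentially across each generation and resetting at division — consistent
with the binomial split and with what fluorescence-per-area measurements
report. A raw count proxy would carry a deterministic within-generation
doubling ramp (CV ≈ 0.19) that is age-independent and would mask the
promoter-noise trend.

The catastrophe phase inflates the final four generations with a linear
ramp toward death (duration mean ×1.8 and SD ×2.5 at the last generation;
extrinsic mean-corrected lognormal intensity noise up to σ = 0.35). The
ramp reflects noise and duration spread being highest at the last
generation; a flat inflation would make the last two death-aligned windows
indistinguishable. OFF cells are simulated as a silenced promoter
(constitutive leak k_m = 0.05) so their lifespan-average stays below the
1000 a.u. threshold. Frame backgrounds are Gaussian per frame
(300 ± 30 a.u.) with pixel samples constructed so the nearest-rank 10th
percentile sits within a few percent of the spread above the truth.

What the generator does **not** emulate: cell-cycle phase structure within
a generation, photobleaching, segmentation artifacts, upstream-network
extrinsic noise shared across generations, or mother-size trends. Passing
round-trip tests therefore demonstrates that the pipeline detects (and,
under null schedules, does not invent) aging trends of the modelled kind —
not that real microfluidic data are free of other confounders.

Scenario presets (`wt`, `gal80del`, `rpd3del`, `synthetic_promoter`,
`synthetic_gal80del`) reproduce the five study designs' cohort sizes
(59/102/52/73/82) and their qualitative orderings: slower young-cell
switching and higher expression for the constitutive deletion (noisier
young cells, strong reduction), weakest scaling and mildest catastrophe
with longer lifespans for the remodeling-regulator deletion, a raised
opening rate for the nucleosome-disfavoring edit, and near-floor,
age-constant switching for the edited constitutive strain.

## Problem sizes and determinism

Ensembles default to N = 2000 replicates (the sweep error-bar convention);
sweep tests use the exact oracle except for spot checks, and the
non-chromatin grid runs 9×9 over [1/10, 10]² by default with the same code
path supporting denser grids. Round-trip analyses use cohorts of ~60 cells
and 10-seed repetitions for majority-vote properties. Every stochastic
entry point takes a seed; identical seeds give byte-identical outputs.

## Known limitations

* The moment oracle requires γ_m, γ_p > 0 and r_ON + r_OFF > 0; degenerate
  cases are simulator-only.
* The reduction of division to a continuous dilution rate in the core model
  slightly understates protein noise relative to explicit partitioning; the
  generator exists precisely to exercise the explicit mechanism.
* `fit_promoter_rates` assumes the supplied kinetic rates are correct;
  errors in k_p/γ_p propagate directly into the recovered occupancy.
* Near the constitutive floor the CV→s inversion becomes ill-conditioned;
  recovery tolerances hold in the 4-fold neighbourhood of the anchored
  rates, not arbitrarily close to the floor.
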