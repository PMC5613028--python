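"""Two-state (telegraph) promoter model of stochastic gene expression.

The promoter switches between a transcriptionally silent OFF state and an
active ON state with chromatin transition rates ``r_on`` (OFF->ON) and
``r_off`` (ON->OFF). While ON, mRNA is transcribed at ``k_m``; mRNA decays at
``gamma_m``, is translated at ``k_p`` per transcript, and protein is removed
at ``gamma_p`` (for a stable fluorescent reporter this is dilution by growth,
not active degradation).

Three routes into the same model live here:

* :func:`simulate_ssa` — exact event-driven (Gillespie) sampling;
* :func:`moment_oracle` — exact steady-state moments from the linear
  moment equations (no simulation);
* :func:`fit_promoter_rates` — inversion of the moment equations to recover
  (r_on, r_off) from a target protein mean and CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._ssa import ssa_ensemble_final, ssa_segment

__all__ = [
    "PromoterRates",
    "KineticRates",
    "ModelState",
    "SsaTrajectory",
    "Moments",
    "EnsembleStats",
    "GAL1_RATES",
    "ParameterError",
    "InfeasibleNoiseError",
    "simulate_ssa",
    "moment_oracle",
    "telegraph_closed_forms",
    "constitutive_cv_floor",
    "ensemble_stats",
    "fit_promoter_rates",
    "default_t_end",
    "stationary_init",
]


class ParameterError(ValueError):
    """A rate or simulation parameter violates its constraints."""


class InfeasibleNoiseError(ValueError):
    """The requested (mean, CV) pair lies below the constitutive noise floor."""

    def __init__(self, message: str, floor: float):
        super().__init__(message)
        self.floor = floor


@dataclass(frozen=True)
class PromoterRates:
    """Chromatin-state transition rates, per minute.

    r_on: OFF -> ON opening rate; r_off: ON -> OFF closing rate.
    """

    r_on: float
    r_off: float

    def __post_init__(self):
        if self.r_on < 0 or self.r_off < 0:
            raise ParameterError(
                f"promoter rates must be non-negative, got r_on={self.r_on}, "
                f"r_off={self.r_off}"
            )

    def scaled(self, c: float) -> "PromoterRates":
        """Both rates multiplied by c; leaves ON occupancy unchanged."""
        return PromoterRates(self.r_on * c, self.r_off * c)

    @property
    def p_on(self) -> float:
        """Stationary ON-state occupancy r_on / (r_on + r_off)."""
        s = self.r_on + self.r_off
        if s == 0:
            raise ParameterError("p_on undefined when r_on = r_off = 0")
        return self.r_on / s


#: Promoter transition rates fitted for the native GAL1 promoter.
GAL1_RATES = PromoterRates(r_on=0.0229, r_off=0.0348)


@dataclass(frozen=True)
class KineticRates:
    """Non-promoter reaction rates (per minute).

    Defaults: k_m = 1 transcript/min while ON; gamma_m = 0.05/min (~14 min
    mRNA half-life); k_p = 2 proteins/transcript/min; gamma_p = ln2/90 /min,
    pure dilution at a 90-min generation time.
    """

    k_m: float = 1.0
    gamma_m: float = 0.05
    k_p: float = 2.0
    gamma_p: float = math.log(2.0) / 90.0

    def __post_init__(self):
        for name in ("k_m", "gamma_m", "k_p", "gamma_p"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class ModelState:
    """Instantaneous system state: time, promoter (0=OFF/1=ON), copy numbers."""

    t: float = 0.0
    promoter: int = 1
    m: int = 0
    p: int = 0

    def __post_init__(self):
        if self.promoter not in (0, 1):
            raise ParameterError("promoter must be 0 (OFF) or 1 (ON)")
        if self.m < 0 or self.p < 0:
            raise ParameterError("copy numbers must be non-negative")


@dataclass
class SsaTrajectory:
    """One exact trajectory sampled on a regular grid."""

    t: np.ndarray
    promoter: np.ndarray
    m: np.ndarray
    p: np.ndarray
    seed: int


@dataclass
class Moments:
    """Exact steady-state moments of the telegraph model."""

    p_on: float
    mean_m: float
    var_m: float
    mean_p: float
    var_p: float
    cov_mp: float

    @property
    def fano_m(self) -> float:
        return self.var_m / self.mean_m

    @property
    def fano_p(self) -> float:
        return self.var_p / self.mean_p

    @property
    def cv_m(self) -> float:
        return math.sqrt(self.var_m) / self.mean_m

    @property
    def cv_p(self) -> float:
        return math.sqrt(self.var_p) / self.mean_p


@dataclass
class EnsembleStats:
    """Cross-replicate protein statistics at t_end with Monte-Carlo SEMs."""

    mean_p: float
    cv_p: float
    fano_p: float
    sem_mean: float
    sem_cv: float
    sem_fano: float
    n_reps: int
    seed: int
    degenerate: bool = False  # True when mean_p == 0 and CV/Fano are undefined


def _check_rates(rates: PromoterRates, kin: KineticRates) -> None:
    # dataclass validation already enforces non-negativity; nothing extra yet
    _ = rates, kin


def simulate_ssa(
    rates: PromoterRates,
    kin: KineticRates,
    t_end: float,
    sample_interval: float,
    init: ModelState | None = None,
    seed: int = 0,
) -> SsaTrajectory:
    """Exact stochastic simulation sampled on the grid 0, d, 2d, ..., t_end.

    Zero total propensity is not an error: the state is simply held constant
    for the remainder of the trajectory. Identical inputs (including seed)
    produce bit-identical trajectories.
    """
    if t_end <= 0:
        raise ParameterError("t_end must be positive")
    if sample_interval <= 0:
        raise ParameterError("sample_interval must be positive")
    _check_rates(rates, kin)
    if init is None:
        init = stationary_init(rates, kin)
    n = int(math.floor(t_end / sample_interval + 1e-9)) + 1
    grid = np.arange(n) * sample_interval
    g, m, p, *_ = ssa_segment(
        rates.r_on, rates.r_off, kin.k_m, kin.gamma_m, kin.k_p, kin.gamma_p,
        init.promoter, init.m, init.p, grid, t_end, seed,
    )
    return SsaTrajectory(t=grid, promoter=g, m=m, p=p, seed=seed)


def moment_oracle(rates: PromoterRates, kin: KineticRates) -> Moments:
    """Exact steady-state first and second moments via the linear moment system.

    Every propensity is linear in state, so the moment hierarchy closes at
    second order. The eight stationary unknowns
    (E[g], E[m], E[p], E[gm], E[m^2], E[gp], E[mp], E[p^2]) satisfy a linear
    system solved here exactly; no simulation and no approximation.
    """
    r_on, r_off = rates.r_on, rates.r_off
    km, gm, kp, gp = kin.k_m, kin.gamma_m, kin.k_p, kin.gamma_p
    if gm <= 0 or gp <= 0:
        raise ParameterError("steady-state moments require gamma_m > 0 and gamma_p > 0")
    if r_on + r_off <= 0:
        raise ParameterError("steady-state moments require r_on + r_off > 0")
    s = r_on + r_off
    # unknowns: [Eg, Em, Ep, Egm, Em2, Egp, Emp, Ep2]
    A = np.zeros((8, 8))
    b = np.zeros(8)
    A[0, 0] = -s;                       b[0] = -r_on
    A[1, 0] = km;   A[1, 1] = -gm
    A[2, 1] = kp;   A[2, 2] = -gp
    A[3, 1] = r_on; A[3, 0] = km;       A[3, 3] = -(s + gm)
    A[4, 3] = 2 * km; A[4, 0] = km; A[4, 1] = gm; A[4, 4] = -2 * gm
    A[5, 2] = r_on; A[5, 3] = kp;       A[5, 5] = -(s + gp)
    A[6, 5] = km;   A[6, 4] = kp;       A[6, 6] = -(gm + gp)
    A[7, 6] = 2 * kp; A[7, 1] = kp; A[7, 2] = gp; A[7, 7] = -2 * gp
    x = np.linalg.solve(A, b)
    eg, em, ep, _egm, em2, _egp, emp, ep2 = x
    return Moments(
        p_on=eg,
        mean_m=em,
        var_m=em2 - em**2,
        mean_p=ep,
        var_p=ep2 - ep**2,
        cov_mp=emp - em * ep,
    )


def telegraph_closed_forms(rates: PromoterRates, kin: KineticRates) -> dict:
    """Textbook closed forms for the telegraph model (used as cross-checks).

    p_on = r_on/(r_on+r_off); mean_m = k_m p_on / gamma_m;
    Fano_m = 1 + k_m r_off / ((r_on+r_off)(r_on+r_off+gamma_m));
    mean_p = k_p mean_m / gamma_p.
    """
    s = rates.r_on + rates.r_off
    p_on = rates.r_on / s
    mean_m = kin.k_m * p_on / kin.gamma_m
    fano_m = 1.0 + kin.k_m * rates.r_off / (s * (s + kin.gamma_m))
    mean_p = kin.k_p * mean_m / kin.gamma_p
    return {"p_on": p_on, "mean_m": mean_m, "fano_m": fano_m, "mean_p": mean_p}


def constitutive_cv_floor(mean_p: float, kin: KineticRates) -> float:
    """CV floor at fixed protein mean in the fast-switching limit.

    As r_on + r_off -> infinity at fixed occupancy, promoter noise averages
    out and the system behaves as a constitutive two-stage birth-death
    process, for which Fano_p = 1 + k_p/(gamma_m + gamma_p).
    """
    fano_floor = 1.0 + kin.k_p / (kin.gamma_m + kin.gamma_p)
    return math.sqrt(fano_floor / mean_p)


def default_t_end(rates: PromoterRates, kin: KineticRates) -> float:
    """Relaxation horizon: ten times the slowest timescale in the system."""
    slowest = min(kin.gamma_m, kin.gamma_p, rates.r_on + rates.r_off)
    if slowest <= 0:
        raise ParameterError("cannot choose a relaxation horizon: zero slowest rate")
    return 10.0 / slowest


def stationary_init(rates: PromoterRates, kin: KineticRates) -> ModelState:
    """Deterministic burn-in-shortening initial condition.

    Promoter set to its more likely stationary state; m and p at their
    stationary means rounded to integers. (Ensemble runs randomise the
    promoter state per replicate instead; see ensemble_stats.)
    """
    mom = moment_oracle(rates, kin)
    return ModelState(
        t=0.0,
        promoter=1 if mom.p_on >= 0.5 else 0,
        m=int(round(mom.mean_m)),
        p=int(round(mom.mean_p)),
    )


def _conditional_init(rates: PromoterRates, kin: KineticRates):
    """Promoter-state-conditional means of m and p for per-replicate inits."""
    r_on, r_off = rates.r_on, rates.r_off
    km, gm, kp, gp = kin.k_m, kin.gamma_m, kin.k_p, kin.gamma_p
    mom = moment_oracle(rates, kin)
    s = r_on + r_off
    # E[gm] from the stationary moment equation for the g*m cross moment
    egm = (r_on * mom.mean_m + km * mom.p_on) / (s + gm)
    egp_num = r_on * mom.mean_p + kp * egm
    egp = egp_num / (s + gp)
    p_on = mom.p_on
    if p_on in (0.0, 1.0):
        m_on = m_off = mom.mean_m
        p_on_state = p_off_state = mom.mean_p
    else:
        m_on = egm / p_on
        m_off = (mom.mean_m - egm) / (1 - p_on)
        p_on_state = egp / p_on
        p_off_state = (mom.mean_p - egp) / (1 - p_on)
    return p_on, int(round(m_on)), int(round(p_on_state)), int(round(m_off)), int(round(p_off_state))


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate streams from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n).astype(np.int64) % (2**31 - 1)


def ensemble_stats(
    rates: PromoterRates,
    kin: KineticRates,
    n_reps: int = 2000,
    t_end: float | None = None,
    seed: int = 0,
    n_boot: int = 200,
    init: ModelState | None = None,
) -> EnsembleStats:
    """Cross-replicate mean/CV/Fano of protein copy number at t_end.

    Runs n_reps independent exact simulations (replicate RNG streams derived
    deterministically from the master seed), records p at t_end, and attaches
    bootstrap SEMs for CV and Fano and the analytic SEM for the mean. By
    default each replicate starts with the promoter drawn from its stationary
    distribution and copy numbers at their state-conditional means; passing
    init pins every replicate to that exact state instead.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be at least 2")
    if t_end is None:
        t_end = default_t_end(rates, kin)
    if init is not None:
        p_on = float(init.promoter)
        m_on = m_off = init.m
        p_on_state = p_off_state = init.p
    else:
        p_on, m_on, p_on_state, m_off, p_off_state = _conditional_init(rates, kin)
    seeds = _replicate_seeds(seed, n_reps)
    _, p_fin = ssa_ensemble_final(
        rates.r_on, rates.r_off, kin.k_m, kin.gamma_m, kin.k_p, kin.gamma_p,
        p_on, m_on, p_on_state, m_off, p_off_state, t_end, seeds,
    )
    return _stats_from_sample(p_fin.astype(float), seed, n_boot)


def _stats_from_sample(p: np.ndarray, seed: int, n_boot: int) -> EnsembleStats:
    n = p.size
    mean = float(p.mean())
    sd = float(p.std(ddof=1))
    sem_mean = sd / math.sqrt(n)
    if mean == 0.0:
        return EnsembleStats(
            mean_p=0.0, cv_p=float("nan"), fano_p=float("nan"),
            sem_mean=sem_mean, sem_cv=float("nan"), sem_fano=float("nan"),
            n_reps=n, seed=seed, degenerate=True,
        )
    cv = sd / mean
    fano = sd**2 / mean
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = p[idx]
    bmean = boots.mean(axis=1)
    bsd = boots.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bcv = bsd / bmean
        bfano = bsd**2 / bmean
    return EnsembleStats(
        mean_p=mean, cv_p=cv, fano_p=fano,
        sem_mean=sem_mean,
        sem_cv=float(np.nanstd(bcv, ddof=1)),
        sem_fano=float(np.nanstd(bfano, ddof=1)),
        n_reps=n, seed=seed,
    )


def fit_promoter_rates(
    target_mean_p: float,
    target_cv_p: float,
    kin: KineticRates,
    s_bounds: tuple[float, float] = (1e-8, 1e8),
) -> PromoterRates:
    """Recover (r_on, r_off) from a target protein mean and CV.

    The mean fixes the ON occupancy p_on = mean_p gamma_m gamma_p/(k_m k_p);
    the CV then fixes the total switching rate s = r_on + r_off, which is
    solved by bracketed root finding on log(s) against the exact moment
    oracle (CV is strictly decreasing in s at fixed occupancy).

    Raises InfeasibleNoiseError (carrying the floor value) when the target CV
    lies at or below the fast-switching constitutive floor for this mean.
    """
    from scipy.optimize import brentq

    if target_mean_p <= 0:
        raise ParameterError("target_mean_p must be positive")
    if target_cv_p <= 0:
        raise ParameterError("target_cv_p must be positive")
    p_on = target_mean_p * kin.gamma_m * kin.gamma_p / (kin.k_m * kin.k_p)
    if p_on > 1 + 1e-12:
        raise InfeasibleNoiseError(
            f"target mean {target_mean_p} exceeds the fully-ON mean "
            f"{kin.k_m * kin.k_p / (kin.gamma_m * kin.gamma_p)}",
            floor=float("nan"),
        )
    floor = constitutive_cv_floor(target_mean_p, kin)
    if p_on >= 1 - 1e-12:
        # promoter effectively always ON: r_off = 0 boundary; r_on is
        # unidentifiable (the ON state is absorbing) and set to 1.0 by convention
        if target_cv_p < floor * (1 - 1e-9):
            raise InfeasibleNoiseError(
                f"target CV {target_cv_p} below constitutive floor {floor}", floor
            )
        return PromoterRates(r_on=1.0, r_off=0.0)
    if target_cv_p <= floor:
        raise InfeasibleNoiseError(
            f"target CV {target_cv_p} at or below the constitutive floor {floor} "
            f"achievable at mean {target_mean_p}",
            floor,
        )

    def cv_at_log_s(log_s: float) -> float:
        s = math.exp(log_s)
        r = PromoterRates(r_on=p_on * s, r_off=(1 - p_on) * s)
        return moment_oracle(r, kin).cv_p

    lo, hi = math.log(s_bounds[0]), math.log(s_bounds[1])
    f_lo = cv_at_log_s(lo) - target_cv_p
    f_hi = cv_at_log_s(hi) - target_cv_p
    if f_lo < 0:
        raise InfeasibleNoiseError(
            f"target CV {target_cv_p} exceeds the slow-switching maximum "
            f"{f_lo + target_cv_p} at this mean",
            floor,
        )
    if f_hi > 0:
        raise InfeasibleNoiseError(
            f"target CV {target_cv_p} below what the bracket reaches; floor {floor}",
            floor,
        )
    log_s = brentq(lambda x: cv_at_log_s(x) - target_cv_p, lo, hi, xtol=1e-13, rtol=1e-15)
    s = math.exp(log_s)
    return PromoterRates(r_on=p_on * s, r_off=(1 - p_on) * s)
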