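"""Noise statistics: coefficient of variation (sigma/mu) and Fano factor (sigma^2/mu).

Sample statistics use the unbiased (n-1) variance convention throughout,
which matters at the small per-window sample sizes (8-18 snapshots) this
package works with. SEM = sigma/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampleStats",
    "InsufficientDataError",
    "UndefinedRatioError",
    "compute_stats",
    "scaling_residuals",
]


class InsufficientDataError(ValueError):
    """Fewer than two observations: no variance estimate."""


class UndefinedRatioError(ValueError):
    """Zero mean: CV and Fano are undefined ratios."""

    def __init__(self, message: str, mean: float):
        super().__init__(message)
        self.mean = mean


@dataclass(frozen=True)
class SampleStats:
    n: int
    mean: float
    sd: float
    cv: float
    fano: float

    @property
    def sem(self) -> float:
        return self.sd / self.n**0.5


def compute_stats(values) -> SampleStats:
    """Mean, sample SD, CV = sd/mean, Fano = var/mean of one sample vector."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 values, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        raise UndefinedRatioError("mean is zero; CV and Fano undefined", mean)
    return SampleStats(n=n, mean=mean, sd=sd, cv=sd / mean, fano=sd**2 / mean)


def scaling_residuals(values, c: float) -> dict:
    """Metric sanity check: deviations from the exact scaling laws.

    For any c > 0, CV(c*x) = CV(x) and Fano(c*x) = c*Fano(x). Returns the
    absolute residuals of both identities (zero up to rounding).
    """
    if c <= 0:
        raise ValueError("scale factor must be positive")
    base = compute_stats(values)
    scaled = compute_stats(np.asarray(values, dtype=float) * c)
    return {
        "cv_residual": abs(scaled.cv - base.cv),
        "fano_residual": abs(scaled.fano - c * base.fano),
    }
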