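"""Sensitivity power analysis for a single-df predictor in a linear model.

Rather than computing power at an assumed effect, a sensitivity analysis asks:
given the sample size n, test size alpha, and a target power, what is the
smallest Cohen's f-squared a single-degree-of-freedom predictor could have and
still be detected?  The test statistic is F(1, n - n_params) and the effect
enters through the noncentrality lambda = f2 * n; the detectable f2 is found
by bisection on the noncentral-F power curve.  Partial R-squared is the
companion scale f2 / (1 + f2).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from scipy.optimize import brentq

__all__ = ["PowerQuery", "PowerResult", "sensitivity_f2", "power_at"]


@dataclass(frozen=True)
class PowerQuery:
    n: int
    alpha: float = 0.05
    power: float = 0.80
    df_num: int = 1
    n_params: int = 28  # full interacted design: 2 x (const + pgs + age + age2 + sex + 10 PCs)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.n_params >= self.n:
            raise ValueError("model parameter count must be below the sample size")
        if self.df_num < 1:
            raise ValueError("numerator df must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    f2: float
    partial_r2: float
    ncp: float
    f_crit: float
    df_denom: int


def power_at(q: PowerQuery, f2: float) -> float:
    """Power of the F test at a given Cohen's f-squared (lambda = f2 * n)."""
    dfd = q.n - q.n_params
    fcrit = stats.f.isf(q.alpha, q.df_num, dfd)
    return _ncf_power(fcrit, q.df_num, dfd, f2 * q.n)


def _ncf_power(fcrit: float, dfn: int, dfd: int, ncp: float) -> float:
    # the noncentral survival function is unreliable at ncp exactly 0
    if ncp == 0.0:
        return float(stats.f.sf(fcrit, dfn, dfd))
    return float(stats.ncf.sf(fcrit, dfn, dfd, ncp))


def sensitivity_f2(q: PowerQuery, tol: float = 1e-10) -> PowerResult:
    """Smallest f-squared detectable with the requested power.

    Bisection on f2 between 0 (power = alpha) and an upper limit; monotone
    because the noncentral-F survival function increases in the
    noncentrality.
    """
    dfd = q.n - q.n_params
    fcrit = stats.f.isf(q.alpha, q.df_num, dfd)

    def gap(f2: float) -> float:
        return _ncf_power(fcrit, q.df_num, dfd, f2 * q.n) - q.power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("requested power unattainable at any effect size")
    f2 = brentq(gap, 0.0, hi, xtol=tol)
    return PowerResult(
        f2=float(f2),
        partial_r2=float(f2 / (1.0 + f2)),
        ncp=float(f2 * q.n),
        f_crit=float(fcrit),
        df_denom=dfd,
    )
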