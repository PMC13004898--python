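"""Invert observed instrument choices into interval-valued preference parameters.

Under expected-utility theory with constant relative risk aversion (CRRA),
utility of a positive payoff x is u(x; r) = x^(1-r) / (1-r), with the log
limit at r = 1.  A choice from an ordered lottery menu then brackets r between
the indifference points of adjacent lotteries.  Analogously, under exponential
discounting PV = FV / (1+d)^t, the switching row of a multiple price list
brackets the weekly discount rate d.  Both inversions yield intervals, possibly
half-infinite for respondents who never switch; the interval-censored
regression downstream consumes the bounds directly, so no imputation happens
here.

The module also houses the simple binary collapses used alongside the interval
measures: the loss-avoidance indicator (picked a lottery with no negative
payoff), the long-planning-horizon indicator (plans beyond the next year), and
the childhood-disadvantage index (two or more of four adverse dimensions, with
a configurable missing-data policy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .instruments import InstrumentSet, Lottery, LotteryMenu, MplPanel

__all__ = [
    "CrraInterval",
    "DiscountInterval",
    "MomentPair",
    "DisadvantageProfile",
    "crra_value",
    "lottery_eu",
    "indifference_r",
    "menu_crra_intervals",
    "lottery_moments",
    "weekly_discount_bound",
    "panel_discount_bounds",
    "mpl_interval",
    "la_binary",
    "planning_binary",
    "disadvantage_index",
    "elicit_responses",
]

MISSING_POLICIES = ("missing_as_zero", "missing_indicator", "complete_case")


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CrraInterval:
    """Bounds on the CRRA coefficient implied by one menu choice.

    Intervals are closed on the left: a respondent exactly at an indifference
    point is assigned to the safer choice's interval.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, r: float) -> bool:
        return self.lower <= r < self.upper or (r == self.upper == math.inf)


@dataclass(frozen=True)
class DiscountInterval:
    """Bounds on the weekly discount rate implied by an MPL response pattern.

    ``consistent`` is False when the pattern switches between the sooner and
    future option more than once; the first switch still defines the interval
    but downstream models must carry the inconsistency flag as a covariate.
    ``switch_row`` is the 0-based index of the first future-option row, or
    None when the respondent always took the sooner option.
    """

    lower: float
    upper: float
    consistent: bool = True
    switch_row: int | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, d: float) -> bool:
        return self.lower <= d <= self.upper


@dataclass(frozen=True)
class MomentPair:
    expected_value: float
    std_dev: float


@dataclass(frozen=True)
class DisadvantageProfile:
    """Count and binary collapse of the four childhood-disadvantage dimensions."""

    dims: tuple[float | None, ...]
    count: int
    binary: int
    any_missing: bool
    excluded: bool = False


# ---------------------------------------------------------------------------
# CRRA utility and lottery inversion


def crra_value(x: float, r: float) -> float:
    """CRRA utility x^(1-r)/(1-r), with the log limit at r = 1.

    Defined for strictly positive payoffs only; menus containing losses must
    be analysed ordinally (see :func:`la_binary`) because the power function
    is undefined for negative arguments.
    """
    if x <= 0:
        raise ValueError(f"CRRA utility undefined for non-positive payoff {x!r}")
    if abs(r - 1.0) < 1e-10:
        return math.log(x)
    return x ** (1.0 - r) / (1.0 - r)


def _crra_shifted(x: float, r: float) -> float:
    # (x^(1-r) - 1)/(1-r): same preferences as crra_value but continuous in r
    # across r = 1, which keeps the indifference objective smooth for brentq.
    if x <= 0:
        raise ValueError(f"CRRA utility undefined for non-positive payoff {x!r}")
    if abs(r - 1.0) < 1e-10:
        return math.log(x)
    return (x ** (1.0 - r) - 1.0) / (1.0 - r)


def lottery_eu(lot: Lottery, r: float) -> float:
    """Expected CRRA utility of a 50/50 lottery."""
    try:
        return 0.5 * (crra_value(lot.low, r) + crra_value(lot.high, r))
    except ValueError as err:
        raise ValueError(f"lottery {lot} has a non-positive payoff: {err}") from err


def _eu_shifted(lot: Lottery, r: float) -> float:
    return 0.5 * (_crra_shifted(lot.low, r) + _crra_shifted(lot.high, r))


def indifference_r(
    lot_a: Lottery,
    lot_b: Lottery,
    bracket: tuple[float, float] = (-10.0, 10.0),
    tol: float = 1e-10,
) -> float:
    """CRRA coefficient at which two lotteries have equal expected utility.

    The objective uses the affine-shifted utility (x^(1-r)-1)/(1-r), which
    represents the same preferences at every r but is continuous across r = 1,
    so a single bracketing solve covers roots on either side of (or at) the
    log-utility point.  The default bracket is deliberately moderate: far
    outside it the shifted utilities of all payoffs converge to 1/(r-1) and
    their differences fall below float resolution.
    """
    if lot_a == lot_b:
        raise ValueError("identical lotteries have no unique indifference point")

    def gap(r: float) -> float:
        return _eu_shifted(lot_a, r) - _eu_shifted(lot_b, r)

    lo, hi = bracket
    glo, ghi = gap(lo), gap(hi)
    if glo == 0.0:
        return lo
    if ghi == 0.0:
        return hi
    if glo * ghi > 0:
        raise ValueError(
            f"expected-utility gap does not change sign on bracket {bracket} "
            f"for lotteries {lot_a} vs {lot_b}"
        )
    return brentq(gap, lo, hi, xtol=tol)


def menu_crra_intervals(menu: LotteryMenu, tol: float = 1e-10) -> list[CrraInterval]:
    """CRRA interval implied by each choice from an ordered menu.

    Choice k's interval runs from the indifference point with the next riskier
    lottery up to the indifference point with the next safer one; the safest
    choice is right-unbounded and the riskiest left-unbounded, so the
    intervals partition the real line.
    """
    if menu.has_loss:
        raise ValueError(
            f"menu {menu.name!r} contains losses; CRRA inversion needs positive payoffs"
        )
    roots = [
        indifference_r(menu[k], menu[k + 1], tol=tol) for k in range(len(menu) - 1)
    ]
    if any(b >= a for a, b in zip(roots, roots[1:])):
        raise ValueError(
            f"indifference points {roots} are not strictly decreasing; "
            f"menu {menu.name!r} is not ordered safe-to-risky"
        )
    bounds = [math.inf] + roots + [-math.inf]
    return [CrraInterval(bounds[k + 1], bounds[k]) for k in range(len(menu))]


def lottery_moments(lot: Lottery) -> MomentPair:
    """Expected value and spread of a 50/50 lottery.

    The spread uses the two-point sample convention with divisor n-1 = 1,
    i.e. SD = |high - low| / sqrt(2).
    """
    ev = 0.5 * (lot.low + lot.high)
    sd = abs(lot.high - lot.low) / math.sqrt(2.0)
    return MomentPair(ev, sd)


# ---------------------------------------------------------------------------
# MPL discounting inversion


def weekly_discount_bound(pv: float, fv: float, t: float) -> float:
    """Weekly discount rate at which PV = FV/(1+d)^t holds with equality."""
    if pv <= 0 or fv <= 0:
        raise ValueError(f"amounts must be positive, got pv={pv}, fv={fv}")
    if t <= 0:
        raise ValueError(f"delay must be positive, got t={t}")
    return (fv / pv) ** (1.0 / t) - 1.0


def panel_discount_bounds(panel: MplPanel) -> list[float]:
    """Per-row indifference discount rates of an MPL panel (increasing)."""
    return [
        weekly_discount_bound(panel.sooner_amount, fv, panel.delay_weeks)
        for fv in panel.future_amounts
    ]


def _normalise_choice(c) -> int:
    # accept 'A'/'B' (case-insensitive) or 0/1
    if isinstance(c, str):
        cu = c.strip().upper()
        if cu in ("A", "B"):
            return 0 if cu == "A" else 1
        raise ValueError(f"MPL choice must be 'A' or 'B', got {c!r}")
    ci = int(c)
    if ci not in (0, 1):
        raise ValueError(f"MPL choice must be 0 (sooner) or 1 (future), got {c!r}")
    return ci


def mpl_interval(choices: Sequence, panel: MplPanel) -> DiscountInterval:
    """Discount-rate interval implied by one MPL response pattern.

    The first row on which the respondent takes the future option defines the
    switch: the rate lies between that row's bound and the previous row's.
    Always-sooner responders get a right-open interval above the last bound;
    an immediate future choice gives a left-open interval.  Patterns with more
    than one switch are coded by their first switch and flagged inconsistent.
    """
    if len(choices) == 0:
        raise ValueError("empty MPL choice vector")
    if len(choices) != panel.n_rows:
        raise ValueError(
            f"{len(choices)} choices for a {panel.n_rows}-row panel {panel.name!r}"
        )
    picks = [_normalise_choice(c) for c in choices]
    bounds = panel_discount_bounds(panel)
    if 1 not in picks:  # always sooner: extremely impatient
        return DiscountInterval(bounds[-1], math.inf, consistent=True, switch_row=None)
    first_b = picks.index(1)
    monotone = all(p == 1 for p in picks[first_b:])
    lower = -math.inf if first_b == 0 else bounds[first_b - 1]
    return DiscountInterval(lower, bounds[first_b], consistent=monotone, switch_row=first_b)


# ---------------------------------------------------------------------------
# binary collapses


def la_binary(choice) -> int:
    """1 if the chosen lottery from the loss menu is loss-free (A, B or C).

    Accepts a label 'A'..'F' or a 1-based index 1..6.
    """
    if isinstance(choice, str):
        cu = choice.strip().upper()
        if cu not in "ABCDEF" or len(cu) != 1:
            raise ValueError(f"lottery label must be A..F, got {choice!r}")
        idx = ord(cu) - ord("A") + 1
    else:
        idx = int(choice)
        if not 1 <= idx <= 6:
            raise ValueError(f"lottery index must be 1..6, got {choice!r}")
    return 1 if idx <= 3 else 0


def planning_binary(level: int) -> int:
    """1 if the reported planning horizon extends beyond the next year.

    Levels 0..6 run from "does not plan / plans day to day" (0) through "the
    next year" (3) to "longer than 10 years" (6); levels 4-6 count as long.
    """
    lv = int(level)
    if not 0 <= lv <= 6:
        raise ValueError(f"planning-horizon level must be 0..6, got {level!r}")
    return 1 if lv >= 4 else 0


def disadvantage_index(
    dims: Sequence,
    policy: str = "missing_as_zero",
    threshold: int = 2,
) -> DisadvantageProfile:
    """Collapse four binary disadvantage dimensions into a count and indicator.

    ``dims`` holds 0/1 values with None/NaN for missing.  Under
    ``missing_as_zero`` missing dimensions count as unexposed; under
    ``missing_indicator`` the same imputation applies but ``any_missing`` is
    meant to enter downstream models as a control; under ``complete_case`` a
    subject with any missing dimension is flagged ``excluded``.
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {policy!r}; use one of {MISSING_POLICIES}")
    clean: list[float | None] = []
    for v in dims:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            clean.append(None)
        else:
            iv = int(v)
            if iv not in (0, 1):
                raise ValueError(f"disadvantage dimensions must be 0/1, got {v!r}")
            clean.append(iv)
    any_missing = any(v is None for v in clean)
    count = sum(v for v in clean if v is not None)
    excluded = policy == "complete_case" and any_missing
    return DisadvantageProfile(
        dims=tuple(clean),
        count=int(count),
        binary=int(count >= threshold),
        any_missing=any_missing,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# table-level driver


def elicit_responses(
    data: pd.DataFrame,
    instruments: InstrumentSet,
    missing_policy: str = "missing_as_zero",
    disadvantage_threshold: int = 2,
) -> pd.DataFrame:
    """Turn a table of raw instrument responses into tidy preference measures.

    Expected columns (missing ones are simply skipped): ``beg_choice`` and
    ``la_choice`` (1-based menu index), per-panel MPL choices in columns
    ``mpl_<panel>_r1`` .. ``mpl_<panel>_rK`` holding 'A'/'B' (or 0/1),
    ``planning_horizon`` (0..6), and ``disadv_1`` .. ``disadv_4`` with blanks
    for missing.  Returns one row per input row with interval bounds, flags
    and binary collapses; infinite bounds are kept as +/-inf so downstream
    interval likelihoods see the censoring directly.
    """
    out = pd.DataFrame(index=data.index)
    if "beg_choice" in data.columns:
        intervals = menu_crra_intervals(instruments.beg_menu)
        idx = data["beg_choice"].astype(int) - 1
        if (idx < 0).any() or (idx >= len(intervals)).any():
            raise ValueError("beg_choice outside the menu range")
        out["beg_choice"] = data["beg_choice"].astype(int)
        out["crra_lower"] = [intervals[i].lower for i in idx]
        out["crra_upper"] = [intervals[i].upper for i in idx]
        # 6-point risk-aversion scale, 1 = riskiest choice .. 6 = safest
        out["risk_aversion_beg"] = len(instruments.beg_menu) + 1 - out["beg_choice"]
    if "la_choice" in data.columns:
        out["la_choice"] = data["la_choice"].astype(int)
        out["risk_aversion_la"] = len(instruments.la_menu) + 1 - out["la_choice"]
        out["la_binary"] = [la_binary(c) for c in data["la_choice"]]
    for key, panel in instruments.mpl_panels.items():
        cols = [f"mpl_{key}_r{i + 1}" for i in range(panel.n_rows)]
        if not all(c in data.columns for c in cols):
            continue
        ivs = [mpl_interval(row, panel) for row in data[cols].to_numpy()]
        out[f"d_{key}_lower"] = [iv.lower for iv in ivs]
        out[f"d_{key}_upper"] = [iv.upper for iv in ivs]
        out[f"d_{key}_consistent"] = [int(iv.consistent) for iv in ivs]
        out[f"d_{key}_switch_row"] = [
            -1 if iv.switch_row is None else iv.switch_row for iv in ivs
        ]
        # 7-point impatience scale: switch row 0..K-1 -> 1..K, never-switch -> K+1
        out[f"impatience_{key}"] = [
            panel.n_rows + 1 if iv.switch_row is None else iv.switch_row + 1 for iv in ivs
        ]
    if "planning_horizon" in data.columns:
        out["planning_horizon"] = data["planning_horizon"].astype(int)
        out["planning_binary"] = [planning_binary(v) for v in data["planning_horizon"]]
    dim_cols = [c for c in ("disadv_1", "disadv_2", "disadv_3", "disadv_4") if c in data.columns]
    if dim_cols:
        profiles = [
            disadvantage_index(row, policy=missing_policy, threshold=disadvantage_threshold)
            for row in data[dim_cols].to_numpy()
        ]
        out["disadv_count"] = [p.count for p in profiles]
        out["disadvantage"] = [p.binary for p in profiles]
        out["disadv_missing"] = [int(p.any_missing) for p in profiles]
        if missing_policy == "complete_case":
            out["disadv_excluded"] = [int(p.excluded) for p in profiles]
    return out
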