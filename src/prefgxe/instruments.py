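"""Instrument definitions: lottery menus and multiple-price-list panels.

A risk instrument is an ordered menu of 50/50 lotteries running from a safe
option (A) to increasingly risky ones; the chosen lottery brackets the
respondent's relative risk-aversion coefficient.  A time instrument is a
multiple price list (MPL): a column of choices between a fixed sooner amount
and a growing future amount at a fixed delay; the switching row brackets the
respondent's weekly discount rate under exponential discounting.

Instruments are configuration, not code: the default battery ships as a YAML
document (``data/instruments.yaml``) and any structurally identical file can
be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "Lottery",
    "LotteryMenu",
    "MplPanel",
    "InstrumentSet",
    "load_instruments",
    "default_instruments",
]


@dataclass(frozen=True)
class Lottery:
    """A two-outcome lottery paying ``low`` or ``high`` with probability 1/2 each."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("lottery payoffs must be finite")
        if self.low > self.high:
            raise ValueError(f"lottery low payoff {self.low} exceeds high payoff {self.high}")

    @property
    def has_loss(self) -> bool:
        return self.low < 0 or self.high < 0


@dataclass(frozen=True)
class LotteryMenu:
    """An ordered menu of lotteries, safest first.

    For the default menus expected value and spread are non-decreasing from the
    first (safe) lottery to the last (riskiest); this ordering is what makes a
    single choice informative about risk aversion.
    """

    lotteries: tuple[Lottery, ...]
    labels: tuple[str, ...] = ()
    name: str = "menu"

    def __post_init__(self) -> None:
        if len(self.lotteries) < 2:
            raise ValueError("a lottery menu needs at least two lotteries")
        if self.labels and len(self.labels) != len(self.lotteries):
            raise ValueError("labels and lotteries length mismatch")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(chr(ord("A") + i) for i in range(len(self.lotteries)))
            )

    def __len__(self) -> int:
        return len(self.lotteries)

    def __iter__(self):
        return iter(self.lotteries)

    def __getitem__(self, i: int) -> Lottery:
        return self.lotteries[i]

    @property
    def has_loss(self) -> bool:
        return any(lot.has_loss for lot in self.lotteries)


@dataclass(frozen=True)
class MplPanel:
    """One multiple-price-list panel: sooner amount vs a rising future amount.

    ``delay_weeks`` is the effective delay between the sooner and future
    payment dates, in weeks; the discount-rate bounds the panel implies are
    computed from it under PV = FV / (1 + d)^t.
    """

    sooner_amount: float
    future_amounts: tuple[float, ...]
    delay_weeks: float
    name: str = "mpl"

    def __post_init__(self) -> None:
        if self.delay_weeks <= 0:
            raise ValueError("delay_weeks must be positive")
        if self.sooner_amount <= 0:
            raise ValueError("sooner_amount must be positive")
        fa = self.future_amounts
        if any(b <= a for a, b in zip(fa, fa[1:])):
            raise ValueError("future_amounts must be strictly increasing")
        if any(f <= self.sooner_amount for f in fa):
            raise ValueError("every future amount must exceed the sooner amount")

    @property
    def n_rows(self) -> int:
        return len(self.future_amounts)


@dataclass(frozen=True)
class InstrumentSet:
    """The full battery: two risk menus, a dict of MPL panels, horizon labels."""

    beg_menu: LotteryMenu
    la_menu: LotteryMenu
    mpl_panels: dict[str, MplPanel] = field(default_factory=dict)
    planning_levels: tuple[str, ...] = ()


def _menu_from_dict(d: dict) -> LotteryMenu:
    lots = tuple(Lottery(float(x["low"]), float(x["high"])) for x in d["lotteries"])
    return LotteryMenu(lots, tuple(d.get("labels", ())), name=d.get("name", "menu"))


def load_instruments(path: str | Path) -> InstrumentSet:
    """Read an instrument battery from a YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    panels = {
        key: MplPanel(
            sooner_amount=float(p["sooner_amount"]),
            future_amounts=tuple(float(x) for x in p["future_amounts"]),
            delay_weeks=float(p["delay_weeks"]),
            name=key,
        )
        for key, p in doc.get("mpl_panels", {}).items()
    }
    return InstrumentSet(
        beg_menu=_menu_from_dict(doc["beg_menu"]),
        la_menu=_menu_from_dict(doc["la_menu"]),
        mpl_panels=panels,
        planning_levels=tuple(doc.get("planning_horizon_levels", ())),
    )


def default_instruments() -> InstrumentSet:
    """The packaged default battery (six-lottery menus, 1- and 2-month MPLs)."""
    ref = resources.files("prefgxe").joinpath("data/instruments.yaml")
    with resources.as_file(ref) as path:
        return load_instruments(path)
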