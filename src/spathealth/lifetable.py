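"""Abridged (current-method) life tables.

Builds period life tables over multi-year age intervals from cross-sectional
exposures ``P_x`` and deaths ``D_x``.  The conventions are the classical
current life-table ones:

* central death rate ``m_x = D_x / P_x``;
* age-0 interval probability ``q_0 = m_0`` (the infant convention used by
  the Chinese census life tables this module mirrors);
* interior intervals ``q_x = n·m_x / (1 + (n/2)·m_x)`` (deaths spread
  uniformly over the interval);
* person-years by the trapezoid rule ``L_x = n·(l_x + l_{x+n})/2`` for all
  closed intervals, and ``L = l/m`` for the open terminal interval
  (exponential tail, so ``e`` at the terminal age equals ``1/m``).

A schedule normally starts at age 0; a partial schedule starting at a later
exact age is accepted so that the tail of a published table can be rebuilt
from its printed survivor count (pass that count as ``radix``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateTerminalError, InvalidScheduleError

__all__ = [
    "AgeSchedule",
    "AbridgedLifeTable",
    "build_life_table",
    "life_expectancy_at",
    "validate_schedule",
    "read_schedule_csv",
]

DEFAULT_RADIX = 100_000.0


@dataclass(frozen=True)
class AgeSchedule:
    """Age-interval exposures and deaths.

    Parameters
    ----------
    start_ages
        Exact starting age of each interval, strictly increasing. The last
        interval is open (terminal).
    exposures
        Mid-period population exposed to risk in each interval (``P_x``).
    deaths
        Deaths observed in each interval over the period (``D_x``).
    """

    start_ages: np.ndarray
    exposures: np.ndarray
    deaths: np.ndarray

    def __init__(self, start_ages: Sequence[float], exposures: Sequence[float],
                 deaths: Sequence[float]):
        object.__setattr__(self, "start_ages", np.asarray(start_ages, dtype=float))
        object.__setattr__(self, "exposures", np.asarray(exposures, dtype=float))
        object.__setattr__(self, "deaths", np.asarray(deaths, dtype=float))

    @property
    def n_intervals(self) -> int:
        return len(self.start_ages)

    @property
    def widths(self) -> np.ndarray:
        """Interval widths; the terminal (open) interval has width NaN."""
        w = np.diff(self.start_ages)
        return np.append(w, np.nan)


@dataclass(frozen=True)
class AbridgedLifeTable:
    """Full abridged life table with the standard column set."""

    start_ages: np.ndarray
    widths: np.ndarray          # NaN for the open terminal interval
    P: np.ndarray
    D: np.ndarray
    m: np.ndarray               # central death rate
    q: np.ndarray               # probability of dying within the interval
    l: np.ndarray               # survivors at exact start age
    d: np.ndarray               # radix-scaled deaths in the interval
    L: np.ndarray               # person-years lived in the interval
    T: np.ndarray               # person-years lived at and above start age
    e: np.ndarray               # life expectancy at exact start age
    radix: float = field(default=DEFAULT_RADIX)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view in the conventional x P D m q l d L T e order."""
        return pd.DataFrame({
            "x": self.start_ages.astype(int),
            "P": self.P, "D": self.D, "m": self.m, "q": self.q,
            "l": self.l, "d": self.d, "L": self.L, "T": self.T, "e": self.e,
        })


def validate_schedule(schedule: AgeSchedule, *, require_zero_start: bool = True) -> list[str]:
    """Return a list of invariant violations (empty when the schedule is valid).

    Reports rather than raises so callers can surface every problem at once.
    """
    v: list[str] = []
    x, P, D = schedule.start_ages, schedule.exposures, schedule.deaths
    if len(x) == 0:
        return ["schedule is empty"]
    if not (len(x) == len(P) == len(D)):
        v.append("start_ages, exposures and deaths have unequal lengths")
        return v
    if require_zero_start and x[0] != 0:
        v.append("first interval does not start at age 0")
    if np.any(np.diff(x) <= 0):
        v.append("start ages are not strictly increasing")
    if np.any(P <= 0):
        v.append("exposures must be positive")
    if np.any(D < 0):
        v.append("deaths must be nonnegative")
    bad = np.where(D > P)[0]
    for i in bad:
        v.append(f"deaths exceed exposure in interval starting at age {x[i]:g}")
    return v


def build_life_table(schedule: AgeSchedule, radix: float = DEFAULT_RADIX) -> AbridgedLifeTable:
    """Build an abridged life table from exposures and deaths.

    ``radix`` is the survivor count at the first start age (100,000 by
    convention when the schedule starts at birth).
    """
    problems = validate_schedule(schedule, require_zero_start=False)
    if problems:
        raise InvalidScheduleError("; ".join(problems))
    if radix <= 0:
        raise InvalidScheduleError("radix must be positive")

    x = schedule.start_ages
    P = schedule.exposures
    D = schedule.deaths
    k = len(x)
    widths = schedule.widths

    m = D / P
    q = np.empty(k)
    for i in range(k):
        n = widths[i]
        if i == k - 1:          # open terminal interval
            q[i] = 1.0
        elif x[i] == 0:
            q[i] = m[i]         # infant convention: q_0 = m_0
        else:
            q[i] = n * m[i] / (1.0 + (n / 2.0) * m[i])
    if np.any(q[:-1] >= 1.0):
        raise InvalidScheduleError("interval death probability reached 1 before the terminal interval")

    l = np.empty(k)
    l[0] = radix
    for i in range(k - 1):
        l[i + 1] = l[i] * (1.0 - q[i])
    d = l * q

    L = np.empty(k)
    for i in range(k - 1):
        L[i] = widths[i] * (l[i] + l[i + 1]) / 2.0
    if m[-1] <= 0:
        if l[-1] > 0:
            raise DegenerateTerminalError(
                "terminal interval has zero mortality but surviving population")
        L[-1] = 0.0
    else:
        L[-1] = l[-1] / m[-1]

    T = np.cumsum(L[::-1])[::-1]
    e = T / l
    return AbridgedLifeTable(start_ages=x.copy(), widths=widths, P=P.copy(), D=D.copy(),
                             m=m, q=q, l=l, d=d, L=L, T=T, e=e, radix=radix)


def life_expectancy_at(table: AbridgedLifeTable, age: float) -> float:
    """Life expectancy ``e_x = T_x / l_x`` at an exact interval start age."""
    idx = np.where(table.start_ages == age)[0]
    if len(idx) == 0:
        raise KeyError(f"age {age:g} is not an interval start of this table")
    i = int(idx[0])
    return float(table.T[i] / table.l[i])


def read_schedule_csv(path) -> AgeSchedule:
    """Read an age schedule from a CSV with columns ``x``, ``P``, ``D``."""
    df = pd.read_csv(path)
    missing = {"x", "P", "D"} - set(df.columns)
    if missing:
        raise InvalidScheduleError(f"schedule CSV missing columns: {sorted(missing)}")
    df = df.sort_values("x")
    return AgeSchedule(df["x"].to_numpy(), df["P"].to_numpy(), df["D"].to_numpy())
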