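"""Synthetic all-cause mortality life table.

The cohort model needs age-specific six-month probabilities of death from any
cause.  This module generates a *synthetic* sex-weighted life table from a
Gompertz hazard h(a) = A exp(B (a - 60)) per sex, mixed at the cohort's male
proportion.  The default level/slope are UK-plausible for 2014 (annual q at 60
of about 0.0088 for men and 0.0056 for women, hazard doubling roughly every
7.4 years); they are a stand-in fixture, not national-statistics data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["GompertzParams", "LifeTable", "make_life_table"]


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard h(a) = level * exp(slope * (a - anchor_age))."""

    level: float  # annual hazard at the anchor age
    slope: float  # per-year log-hazard slope
    anchor_age: float = 60.0


# Synthetic defaults calibrated so q(60) per six months ~ 0.004 (sex-weighted).
DEFAULT_MALE = GompertzParams(level=0.0088, slope=0.094)
DEFAULT_FEMALE = GompertzParams(level=0.0056, slope=0.099)


@dataclass(frozen=True)
class LifeTable:
    """Six-month all-cause death probabilities on a half-year age grid."""

    ages: np.ndarray       # start ages of each half-year interval
    q6: np.ndarray         # P(die within 6 months | alive at age)
    male_fraction: float

    def death_prob(self, age: float) -> float:
        """Six-month death probability at ``age`` (nearest grid point)."""
        if age <= self.ages[0]:
            return float(self.q6[0])
        if age >= self.ages[-1]:
            return float(self.q6[-1])
        idx = int(round((age - self.ages[0]) * 2))
        return float(self.q6[idx])


def _q6_gompertz(age: np.ndarray, p: GompertzParams) -> np.ndarray:
    """Exact six-month death probability under the Gompertz hazard."""
    # integral of h over [age, age+0.5]
    b = p.slope
    h0 = p.level * np.exp(b * (age - p.anchor_age))
    cum = h0 * (math.exp(b * 0.5) - 1.0) / b
    return 1.0 - np.exp(-cum)


def make_life_table(start_age: float = 60.0, end_age: float = 110.0,
                    male_fraction: float = 0.796,
                    male: GompertzParams = DEFAULT_MALE,
                    female: GompertzParams = DEFAULT_FEMALE) -> LifeTable:
    """Build the sex-weighted synthetic life table.

    The mixture weight is the cohort male proportion and is held fixed over
    the horizon (differential survival by sex is negligible over 5 years).
    """
    if not start_age < end_age:
        raise ValueError("start_age must be below end_age")
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must lie in [0, 1]")
    ages = np.arange(start_age, end_age + 1e-9, 0.5)
    q6 = (male_fraction * _q6_gompertz(ages, male)
          + (1.0 - male_fraction) * _q6_gompertz(ages, female))
    return LifeTable(ages=ages, q6=q6, male_fraction=male_fraction)
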