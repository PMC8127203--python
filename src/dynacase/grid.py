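"""Measurement-occasion grid for the birth-to-16th-birthday observation window.

Healthcare use is aggregated into 15 occasions: the first spans birth to the
second birthday (utilization specific to the disease is too sparse in the
first year of life to support a separate period), and each later occasion
covers a single year of age, up to but excluding the 16th birthday.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

DAYS_PER_YEAR = 365.25
#: Exclusive upper bound on claim days (16 years of age).
MAX_DAY = int(16 * DAYS_PER_YEAR)  # 5844


@dataclass(frozen=True)
class Occasion:
    """One measurement occasion: an age span [age_lo, age_hi) in years."""

    index: int
    age_lo: float
    age_hi: float

    @property
    def day_lo(self) -> int:
        """First day-since-birth inside the span (inclusive)."""
        return int(math.ceil(self.age_lo * DAYS_PER_YEAR))

    @property
    def day_hi(self) -> int:
        """One past the last day inside the span (exclusive)."""
        return int(math.ceil(self.age_hi * DAYS_PER_YEAR))

    @property
    def covariate_age(self) -> float:
        """Age value used as the model covariate for this occasion.

        A single representative year: 1 for the two-year first occasion,
        otherwise the year of age the occasion covers.
        """
        return 1.0 if self.index == 1 else float(self.index)


@dataclass(frozen=True)
class OccasionGrid:
    """Ordered, disjoint occasions whose union is [0, 16) years of age."""

    occasions: tuple[Occasion, ...]

    @staticmethod
    def default() -> "OccasionGrid":
        occ = [Occasion(1, 0.0, 2.0)]
        occ += [Occasion(j, float(j), float(j + 1)) for j in range(2, 16)]
        return OccasionGrid(tuple(occ))

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def covariate_ages(self) -> np.ndarray:
        return np.array([o.covariate_age for o in self.occasions])

    def occasion_of_day(self, day: int) -> int:
        """Map a day since birth onto its occasion index (1-based).

        Days in [0, 730.5) fall in occasion 1; after that the occasion index
        equals floor(day / 365.25), the year of age.
        """
        if day < 0 or day >= MAX_DAY:
            raise ValueError(f"day {day} outside the [0, {MAX_DAY}) follow-up window")
        year = int(day // DAYS_PER_YEAR)
        return 1 if year < 2 else year

    def occasion(self, index: int) -> Occasion:
        occ = self.occasions[index - 1]
        if occ.index != index:
            raise ValueError(f"grid occasions are not contiguous at index {index}")
        return occ


DEFAULT_GRID = OccasionGrid.default()
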