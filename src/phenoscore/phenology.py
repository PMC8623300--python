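"""Core data types and the Phenological Index.

The Phenological Index (PI) summarises how far a herbarium specimen has
progressed through its reproductive cycle.  Each reproductive organ on the
sheet belongs to one of four ordered classes — flower buds (index value 1),
open flowers (2), immature fruits (3), mature fruits (4) — and the PI is the
count-proportion-weighted mean of those index values:

    PI = sum_i p_i * i,    p_i = count_i / total

A sheet bearing only buds scores exactly 1; a sheet bearing only mature
fruits scores exactly 4; mixtures fall strictly in between.  The PI depends
only on the *composition* of the counts, never on their absolute magnitude,
which is why systematically undercounting detectors can still recover it
accurately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered organ-class names; position k corresponds to index value k + 1.
ORGAN_CLASSES = ("buds", "flowers", "immature_fruits", "mature_fruits")

#: Index value assigned to each class (buds = 1 ... mature fruits = 4).
CLASS_INDEX = {name: i + 1 for i, name in enumerate(ORGAN_CLASSES)}


class UndefinedPIError(ValueError):
    """Raised when the PI is requested for a specimen with no organs."""


@dataclass(frozen=True)
class OrganCounts:
    """Per-specimen counts of the four reproductive organ classes.

    All counts are non-negative integers.  ``total()`` is the number of
    reproductive structures on the sheet.
    """

    buds: int = 0
    flowers: int = 0
    immature_fruits: int = 0
    mature_fruits: int = 0

    def __post_init__(self) -> None:
        for name in ORGAN_CLASSES:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def total(self) -> int:
        return self.buds + self.flowers + self.immature_fruits + self.mature_fruits

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.buds, self.flowers, self.immature_fruits, self.mature_fruits)

    def scaled(self, factor: int) -> "OrganCounts":
        """Multiply every count by a positive integer (composition-preserving)."""
        if factor < 1:
            raise ValueError("scale factor must be a positive integer")
        return OrganCounts(*(factor * c for c in self.as_tuple()))


@dataclass(frozen=True)
class PhenologicalIndex:
    """A computed PI value; always in [1, 4] when defined."""

    value: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.value <= 4.0):
            raise ValueError(f"PI must lie in [1, 4], got {self.value}")

    def __float__(self) -> float:
        return self.value


@dataclass
class SpecimenRecord:
    """One herbarium sheet: collection metadata plus organ counts.

    ``doy`` is the day of year of collection (1 = Jan 1); 366 is admitted
    for Dec-31 records in leap years.  ``spring_tmax`` is the spring mean
    maximum daily temperature (degC) and ``winter_ppt`` the cumulative winter
    precipitation (mm) at the collection site in the collection year.
    ``predicted_counts`` holds detector output when available.
    """

    id: str
    year: int
    doy: int
    latitude: float
    longitude: float
    elevation: float
    spring_tmax: float
    winter_ppt: float
    manual_counts: OrganCounts
    predicted_counts: Optional[OrganCounts] = None

    YEAR_WINDOW = (1800, 2100)

    def __post_init__(self) -> None:
        if not (1 <= self.doy <= 366):
            raise ValueError(f"specimen {self.id}: doy must be in [1, 366], got {self.doy}")
        lo, hi = self.YEAR_WINDOW
        if not (lo <= self.year <= hi):
            raise ValueError(
                f"specimen {self.id}: year {self.year} outside plausible window [{lo}, {hi}]"
            )

    def counts(self, source: Literal["manual", "predicted"]) -> OrganCounts:
        if source == "manual":
            return self.manual_counts
        if source == "predicted":
            if self.predicted_counts is None:
                raise ValueError(f"specimen {self.id} has no predicted counts")
            return self.predicted_counts
        raise ValueError(f"unknown count source {source!r}")


def phenological_index(counts: OrganCounts, specimen_id: str | None = None) -> PhenologicalIndex:
    """Compute the Phenological Index of one set of organ counts.

    Raises :class:`UndefinedPIError` when the sheet bears no reproductive
    structures (the PI is a composition statistic and has no value there).
    """
    total = counts.total()
    if total == 0:
        who = f" for specimen {specimen_id!r}" if specimen_id else ""
        raise UndefinedPIError(f"PI undefined{who}: zero reproductive structures")
    value = sum(i * c for i, c in enumerate(counts.as_tuple(), start=1)) / total
    return PhenologicalIndex(value)


def pi_table(
    records: Sequence[SpecimenRecord],
    source: Literal["manual", "predicted"] = "manual",
    on_zero_total: Literal["error", "skip"] = "skip",
) -> pd.DataFrame:
    """PI of every specimen in a collection, as a two-column table.

    Parameters
    ----------
    records
        Specimens to score.
    source
        Which counts to score, ``"manual"`` or ``"predicted"``.  Requesting
        predicted counts when any record lacks them is an error listing the
        offending ids.
    on_zero_total
        ``"skip"`` (default) drops zero-total specimens with a logged
        warning, mirroring a pipeline that only ever scores fertile sheets;
        ``"error"`` raises on the first such specimen.

    Returns
    -------
    DataFrame with columns ``id`` and ``pi``, one row per retained specimen.
    """
    if source == "predicted":
        missing = [r.id for r in records if r.predicted_counts is None]
        if missing:
            raise ValueError(f"records without predicted counts: {missing}")

    rows: list[tuple[str, float]] = []
    skipped: list[str] = []
    for rec in records:
        counts = rec.counts(source)
        try:
            pi = phenological_index(counts, specimen_id=rec.id)
        except UndefinedPIError:
            if on_zero_total == "error":
                raise
            skipped.append(rec.id)
            continue
        rows.append((rec.id, pi.value))
    if skipped:
        logger.warning(
            "skipped %d specimen(s) with zero %s counts: %s",
            len(skipped), source, ", ".join(skipped),
        )
    table = pd.DataFrame(rows, columns=["id", "pi"])
    logger.info("scored %d of %d specimens (%s counts)", len(table), len(records), source)
    return table
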