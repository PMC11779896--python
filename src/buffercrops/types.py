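"""Shared data model for the crop–climate analysis pipeline.

Five "buffer" crops are analysed throughout: rye, oat, millet, buckwheat
and hemp.  Wheat and barley are deliberately outside the crop set because
their species/variety identification is too coarse in both archaeobotanical
and archival sources to carry a climatic signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The five admissible crop labels, in canonical order.
CROPS: tuple[str, ...] = ("rye", "oat", "millet", "buckwheat", "hemp")

PERCENT_TOL = 1e-6


def validate_crop(name: str) -> str:
    """Return *name* if it is one of the five analysed crops, else raise."""
    if name not in CROPS:
        raise ValueError(f"unknown crop {name!r}; admissible crops are {CROPS}")
    return name


@dataclass
class ArchContext:
    """One archaeobotanical sampling context.

    A context is a discrete sampling unit at an archaeological site from
    which identifiable plant remains were recovered, dated to an interval
    ``[date_early, date_late]`` of calendar years AD.  ``counts`` holds
    either raw counts of identified remains (``value_kind="count"``) or
    pre-computed percentages (``value_kind="percent"``); percentage rows
    are renormalised so the five crops sum to 100.
    """

    site_id: str
    context_id: str
    date_early: int
    date_late: int
    counts: dict[str, float]
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.date_early > self.date_late:
            raise ValueError(
                f"date_early > date_late ({self.date_early} > {self.date_late})"
            )
        if self.value_kind not in ("count", "percent"):
            raise ValueError(f"value_kind must be count|percent, got {self.value_kind!r}")
        clean: dict[str, float] = {}
        for crop in CROPS:
            v = float(self.counts.get(crop, 0.0))
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"negative or non-finite value for {crop}: {v}")
            clean[crop] = v
        extra = set(self.counts) - set(CROPS)
        if extra:
            raise ValueError(f"unknown crop labels {sorted(extra)}")
        total = sum(clean.values())
        if total <= 0:
            raise ValueError("context has no crop remains (all values zero)")
        if self.value_kind == "percent":
            # renormalise so the composition sums to exactly 100
            clean = {c: 100.0 * v / total for c, v in clean.items()}
            assert abs(sum(clean.values()) - 100.0) < PERCENT_TOL
        self.counts = clean

    @property
    def span(self) -> int:
        """Width of the dating interval in years."""
        return self.date_late - self.date_early

    def percentages(self) -> dict[str, float]:
        """Five-crop composition of this context, in percent (sums to 100)."""
        if self.value_kind == "percent":
            return dict(self.counts)
        total = sum(self.counts.values())
        return {c: 100.0 * v / total for c, v in self.counts.items()}


@dataclass
class ProxySeries:
    """A (year, value) climate proxy series, e.g. varve thickness or
    chironomid-inferred summer temperature (CIT).

    Years are strictly increasing; use :meth:`from_pairs` to build a series
    from possibly unsorted data with duplicate years (duplicates averaged).
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape or self.years.ndim != 1:
            raise ValueError("years and values must be 1-D arrays of equal length")
        if self.years.size == 0:
            raise ValueError("empty proxy series")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing; use from_pairs()")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite proxy values")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[int, float]],
        name: str = "",
        units: str = "",
    ) -> "ProxySeries":
        """Build a series from (year, value) pairs: sorts by year and
        averages duplicate years."""
        pairs = list(pairs)
        if not pairs:
            raise ValueError("empty proxy series")
        acc: dict[int, list[float]] = {}
        for year, value in pairs:
            acc.setdefault(int(year), []).append(float(value))
        years = np.array(sorted(acc), dtype=int)
        values = np.array([float(np.mean(acc[y])) for y in years])
        return cls(name=name, years=years, values=values, units=units)

    def __len__(self) -> int:
        return int(self.years.size)

    def pairs(self) -> list[tuple[int, float]]:
        return [(int(y), float(v)) for y, v in zip(self.years, self.values)]


def century_of(year: int) -> int:
    """Century label for an Early Modern year: 16 for 1500-1599, 17 for
    1600-1699, 18 for 1700-1800.

    The closing year 1800 belongs to the 18th century because the study
    window is 1500-1800 AD inclusive.
    """
    if year == 1800:
        return 18
    if not 1500 <= year < 1800:
        raise ValueError(f"year {year} outside the 1500-1800 study window")
    return year // 100 + 1


def in_study_window(year: int) -> bool:
    return 1500 <= year <= 1800


@dataclass
class ManorRecord:
    """One manor-inventory description of crops sown in a given year.

    ``sown`` holds amounts (source units such as barrels) for crops the
    inventory records; ``present`` flags which crops were recorded at all,
    so an explicit zero is distinguishable from "not mentioned" — the
    mention counts require that distinction.
    """

    manor_id: str
    year: int
    sown: dict[str, float]
    present: dict[str, bool] = field(default_factory=dict)
    region_tag: str | None = None

    def __post_init__(self) -> None:
        sown: dict[str, float] = {}
        present: dict[str, bool] = {}
        for crop in CROPS:
            if crop in self.sown and self.sown[crop] is not None:
                v = float(self.sown[crop])
                if not math.isfinite(v) or v < 0:
                    raise ValueError(f"negative or non-finite sown amount for {crop}")
                sown[crop] = v
                present[crop] = self.present.get(crop, True)
            else:
                sown[crop] = 0.0
                present[crop] = self.present.get(crop, False)
        extra = set(self.sown) - set(CROPS)
        if extra:
            raise ValueError(f"unknown crop labels {sorted(extra)}")
        self.sown = sown
        self.present = present

    @property
    def in_study(self) -> bool:
        return in_study_window(self.year)

    @property
    def century(self) -> int:
        return century_of(self.year)

    def total_sown(self) -> float:
        return sum(self.sown.values())


@dataclass
class StationSeries:
    """Annual precipitation record of one meteorological station.

    ``region`` distinguishes the proxy (varve-lake) region from the study
    region for the two-region consistency check; ``data`` maps year to
    annual precipitation in mm, with missing years simply absent.
    """

    station_id: str
    region: str
    data: dict[int, float]

    def __post_init__(self) -> None:
        if self.region not in ("proxy_region", "study_region"):
            raise ValueError(
                "region must be 'proxy_region' or 'study_region', "
                f"got {self.region!r}"
            )
        for year, v in self.data.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"invalid precipitation {v} in year {year}")

    def years(self) -> list[int]:
        return sorted(self.data)


def crop_vector(values: Mapping[str, float]) -> np.ndarray:
    """Map a crop→value mapping to a vector in canonical CROPS order."""
    return np.array([float(values.get(c, 0.0)) for c in CROPS])


def crop_dict(values: Sequence[float]) -> dict[str, float]:
    """Inverse of :func:`crop_vector`."""
    if len(values) != len(CROPS):
        raise ValueError(f"expected {len(CROPS)} values, got {len(values)}")
    return {c: float(v) for c, v in zip(CROPS, values)}
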