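"""Temporal binning and aggregation of archaeobotanical contexts.

Contexts are assigned to 100-year bins by the midpoint of their dating
interval; contexts whose interval is wider than ``max_span`` are excluded
as chronologically unreliable.  Within each bin the five-crop composition
is summarised as the unweighted mean of per-context percentages ("mean
presence"); a pooled-count mode is available for sensitivity analysis.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .types import CROPS, ArchContext, validate_crop

logger = logging.getLogger(__name__)


class BinOutcome(enum.Enum):
    """Non-bin assignment outcomes."""

    EXCLUDED = "excluded"        # dating interval wider than max_span
    OUT_OF_RANGE = "out_of_range"  # midpoint outside the bin grid


EXCLUDED = BinOutcome.EXCLUDED
OUT_OF_RANGE = BinOutcome.OUT_OF_RANGE


@dataclass(frozen=True)
class BinSpec:
    """Grid of half-open temporal bins [b, b+width) covering
    [start_year, end_year), with a wide-interval exclusion threshold."""

    start_year: int = 100
    end_year: int = 1800
    width: int = 100
    max_span: int = 200

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bin width must be positive")
        if (self.end_year - self.start_year) % self.width != 0:
            raise ValueError("(end_year - start_year) must be divisible by width")
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")
        if self.max_span < 0:
            raise ValueError("max_span must be non-negative")

    @property
    def bin_starts(self) -> list[int]:
        return list(range(self.start_year, self.end_year, self.width))


@dataclass
class BinStat:
    """Summary of one populated temporal bin."""

    bin_start: int
    mean_percent: dict[str, float]
    n_contexts: int


@dataclass
class BinSeries:
    """Per-bin mean crop percentages with context counts.

    Only populated bins are stored: a bin with no contexts is *missing*,
    not zero — absence of evidence is not evidence of absent crops, and
    downstream correlation drops missing bins pairwise.
    """

    bins: list[BinStat] = field(default_factory=list)
    spec: BinSpec | None = None

    def __post_init__(self) -> None:
        self.bins = sorted(self.bins, key=lambda b: b.bin_start)

    def __len__(self) -> int:
        return len(self.bins)

    def bin_starts(self) -> list[int]:
        return [b.bin_start for b in self.bins]

    def get(self, bin_start: int) -> BinStat | None:
        for b in self.bins:
            if b.bin_start == bin_start:
                return b
        return None


def midpoint(context: ArchContext) -> float:
    """Chronological midpoint of a context's dating interval, in years AD."""
    return (context.date_early + context.date_late) / 2.0


def assign_bin(context: ArchContext, spec: BinSpec) -> int | BinOutcome:
    """Assign a context to a bin start year, or report why it cannot be.

    Returns ``EXCLUDED`` when the dating interval is wider than
    ``spec.max_span``, ``OUT_OF_RANGE`` when the midpoint falls outside
    the grid, else the start year of the half-open bin containing the
    midpoint (a midpoint exactly on a boundary goes to the upper bin).
    """
    if context.span > spec.max_span:
        return EXCLUDED
    m = midpoint(context)
    if m < spec.start_year or m >= spec.end_year:
        return OUT_OF_RANGE
    k = int(np.floor((m - spec.start_year) / spec.width))
    return spec.start_year + spec.width * k


def aggregate_bins(
    contexts: list[ArchContext],
    spec: BinSpec,
    mode: str = "mean",
    unit: str = "context",
) -> BinSeries:
    """Aggregate contexts into a :class:`BinSeries`.

    mode="mean" (default): each context is converted to a five-crop
    percentage composition and the bin value is the unweighted mean of
    those compositions — the "mean presence" statistic.  mode="pooled"
    sums raw counts within the bin before converting to percentages
    (percent-typed contexts contribute their percentages as pseudo-counts).

    unit="site" first collapses the contexts of each site within a bin to
    the site's mean composition, then averages sites.
    """
    if mode not in ("mean", "pooled"):
        raise ValueError(f"mode must be mean|pooled, got {mode!r}")
    if unit not in ("context", "site"):
        raise ValueError(f"unit must be context|site, got {unit!r}")

    assigned: dict[int, list[ArchContext]] = {}
    n_excluded = 0
    n_out = 0
    for ctx in contexts:
        where = assign_bin(ctx, spec)
        if where is EXCLUDED:
            n_excluded += 1
        elif where is OUT_OF_RANGE:
            n_out += 1
        else:
            assigned.setdefault(int(where), []).append(ctx)
    logger.info(
        "binning: %d contexts assigned, %d excluded (span > %d), %d out of range",
        sum(len(v) for v in assigned.values()), n_excluded, spec.max_span, n_out,
    )
    if not assigned:
        raise ValueError("empty bin series: no context could be assigned to a bin")

    bins: list[BinStat] = []
    for b in sorted(assigned):
        group = assigned[b]
        if mode == "pooled":
            pooled = {c: sum(ctx.counts[c] for ctx in group) for c in CROPS}
            total = sum(pooled.values())
            mean_pct = {c: 100.0 * pooled[c] / total for c in CROPS}
        else:
            comps = [ctx.percentages() for ctx in group]
            if unit == "site":
                by_site: dict[str, list[dict[str, float]]] = {}
                for ctx, comp in zip(group, comps):
                    by_site.setdefault(ctx.site_id, []).append(comp)
                comps = [
                    {c: float(np.mean([p[c] for p in ps])) for c in CROPS}
                    for ps in by_site.values()
                ]
            mean_pct = {c: float(np.mean([p[c] for p in comps])) for c in CROPS}
        bins.append(BinStat(bin_start=b, mean_percent=mean_pct, n_contexts=len(group)))
    return BinSeries(bins=bins, spec=spec)


def crop_trajectory(series: BinSeries, crop: str) -> list[tuple[int, float]]:
    """One crop's (bin_start, mean_percent) trajectory over populated bins.

    A crop absent from every context still yields explicit zeros in
    populated bins; only bins without any context are omitted.
    """
    validate_crop(crop)
    if not series.bins:
        raise ValueError("empty bin series")
    return [(b.bin_start, b.mean_percent[crop]) for b in series.bins]
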