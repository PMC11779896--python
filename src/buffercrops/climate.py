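"""Climate-proxy preprocessing.

The varve-thickness wetness record is smoothed with a rolling 50-year
average before being binned to the same 100-year grid as the crop data;
the chironomid-inferred summer temperature (CIT) record is binned
directly.  A two-region station-precipitation check verifies that the
proxy region's precipitation co-varies with the study region's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .binning import BinSpec
from .types import ProxySeries, StationSeries

logger = logging.getLogger(__name__)


@dataclass
class BinnedProxy:
    """A proxy series reduced to the 100-year bin grid.

    Only bins containing at least one sample are stored; empty bins are
    missing and handled downstream by pairwise deletion.
    """

    name: str
    bins: list[tuple[int, float, int]] = field(default_factory=list)  # (start, mean, n)

    def bin_starts(self) -> list[int]:
        return [b for b, _, _ in self.bins]

    def value(self, bin_start: int) -> float | None:
        for b, v, _ in self.bins:
            if b == bin_start:
                return v
        return None


def rolling_mean(series: ProxySeries, window_years: int = 50) -> ProxySeries:
    """Centred rolling mean in calendar years, truncated at the edges.

    At each sample year *t* the mean is taken over samples with year in
    [t - w/2, t + w/2).  The window is defined in calendar years, not in
    sample counts, so unevenly spaced series (e.g. varve chronologies
    with gaps) are handled correctly.  Edge windows are truncated rather
    than padded, so the whole span of the record is used.
    """
    if window_years <= 0:
        raise ValueError("window_years must be positive")
    years = series.years.astype(float)
    half = window_years / 2.0
    lo = np.searchsorted(years, years - half, side="left")
    hi = np.searchsorted(years, years + half, side="left")
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return ProxySeries(
        name=f"{series.name}_rm{window_years}", years=series.years.copy(),
        values=out, units=series.units,
    )


def bin_proxy(series: ProxySeries, spec: BinSpec) -> BinnedProxy:
    """Average proxy samples within each half-open 100-year bin [b, b+w)."""
    bins: list[tuple[int, float, int]] = []
    for b in spec.bin_starts:
        mask = (series.years >= b) & (series.years < b + spec.width)
        n = int(mask.sum())
        if n:
            bins.append((b, float(series.values[mask].mean()), n))
    return BinnedProxy(name=series.name, bins=bins)


def regional_mean_precip(stations: list[StationSeries], region: str) -> ProxySeries:
    """Mean annual precipitation over the stations of one region.

    Per year, the mean is over the stations that report that year;
    stations missing the year are skipped, which is what makes the
    regional mean robust to individual-station gaps (e.g. wartime
    interruptions).  Years no station reports are omitted.
    """
    group = [s for s in stations if s.region == region]
    if not group:
        raise ValueError(f"no stations in region {region!r}")
    years = sorted({y for s in group for y in s.data})
    pairs = []
    for y in years:
        vals = [s.data[y] for s in group if y in s.data]
        pairs.append((y, float(np.mean(vals))))
    return ProxySeries.from_pairs(pairs, name=f"mean_precip_{region}", units="mm")


def cross_region_correlation(
    a: ProxySeries, b: ProxySeries, from_year: int | None = None
) -> tuple[float, int]:
    """Pearson correlation of two annual series over their common years.

    ``from_year`` restricts the comparison to years >= from_year (the
    station records only become mutually consistent once both networks
    are dense).  Returns (r, number of overlapping years).
    """
    da = dict(a.pairs())
    db = dict(b.pairs())
    common = sorted(set(da) & set(db))
    if from_year is not None:
        common = [y for y in common if y >= from_year]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping years; need >= 3")
    xa = np.array([da[y] for y in common])
    xb = np.array([db[y] for y in common])
    r = float(np.corrcoef(xa, xb)[0, 1])
    return r, len(common)


def cubic_spline_smooth(series: ProxySeries, smooth_param: float) -> ProxySeries:
    """Cubic smoothing-spline fit evaluated at the sample years.

    ``smooth_param`` is the roughness penalty: 0 interpolates the data,
    large values approach the ordinary least-squares line, and ``inf``
    returns that limit exactly.  The penalty is defined on the year axis
    rescaled to [0, 1], so smooth_param is independent of the record's
    calendar span (and the solver stays well conditioned).
    """
    if len(series) < 4:
        raise ValueError("need at least 4 samples for a cubic smoothing spline")
    if smooth_param < 0:
        raise ValueError("smooth_param must be non-negative")
    x = series.years.astype(float)
    t = (x - x[0]) / (x[-1] - x[0])
    # the roughness penalty annihilates linear trends, so fitting the
    # spline to OLS residuals is mathematically identical and keeps the
    # solver well conditioned for near-collinear data
    coef = np.polyfit(t, series.values, 1)
    line = np.polyval(coef, t)
    if np.isinf(smooth_param):
        fitted = line
    else:
        fitted = line + make_smoothing_spline(t, series.values - line, lam=smooth_param)(t)
    return ProxySeries(
        name=f"{series.name}_spline", years=series.years.copy(),
        values=fitted, units=series.units,
    )


def annual_from_monthly(
    monthly: dict[int, list[float]], min_months: int = 12
) -> dict[int, float]:
    """Annual precipitation totals from per-year monthly values.

    Years with fewer than ``min_months`` reported months are dropped
    (conservative default: any missing month invalidates the year).
    When months are missing but the year is kept, the total is scaled
    by 12/n_months to remain an annual estimate.
    """
    if not 1 <= min_months <= 12:
        raise ValueError("min_months must be in 1..12")
    out: dict[int, float] = {}
    for year, months in monthly.items():
        vals = [m for m in months if m is not None and np.isfinite(m)]
        if len(vals) >= min_months:
            out[year] = float(np.sum(vals) * 12.0 / len(vals))
    return out
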