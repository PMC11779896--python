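"""Early Modern manor-inventory statistics (1500-1800 AD).

Each inventory record lists amounts sown per crop; the analysis works on
per-record *shares* of the five analysed crops, summarised per century
(16th/17th/18th) together with mention counts.  Stability over the three
centuries is tested per crop: one-way ANOVA for rye (whose shares are
close to normal) and tie-corrected Kruskal-Wallis for oat, millet,
buckwheat and hemp (sparse, skewed, many exact zeros).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import average_ranks
from .types import CROPS, ManorRecord

logger = logging.getLogger(__name__)

#: Test assignment fixed a priori: rye is tested parametrically, the rest
#: non-parametrically.
ANOVA_CROPS = ("rye",)
KRUSKAL_CROPS = ("oat", "millet", "buckwheat", "hemp")


@dataclass
class CenturySummary:
    century: int
    n_records: int
    mean_share: dict[str, float]
    mention_count: dict[str, int]


@dataclass
class StabilityTest:
    crop: str
    test: str  # "anova" | "kruskal_wallis"
    statistic: float
    df: tuple[int, ...]
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "crop": self.crop, "test": self.test, "statistic": self.statistic,
            "df": "/".join(str(d) for d in self.df), "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def record_shares(record: ManorRecord) -> dict[str, float]:
    """Per-crop share of the total amount sown across the five analysed
    crops in one record.  Unrecorded crops contribute zero."""
    total = record.total_sown()
    if total <= 0:
        raise ValueError(
            f"no analyzed crops sown in record {record.manor_id}/{record.year}"
        )
    return {c: record.sown[c] / total for c in CROPS}


def century_summary(records: list[ManorRecord]) -> list[CenturySummary]:
    """Mean per-record shares and mention counts per century.

    A mention is a record in which the crop was recorded at all (presence
    flag), regardless of the amount — an explicit zero still counts as a
    mention, a blank does not.
    """
    in_study = [r for r in records if r.in_study and r.total_sown() > 0]
    if not in_study:
        raise ValueError("no usable in-study manor records")
    out: list[CenturySummary] = []
    for century in (16, 17, 18):
        group = [r for r in in_study if r.century == century]
        if not group:
            logger.info("century %d has no records; omitted", century)
            continue
        shares = [record_shares(r) for r in group]
        out.append(
            CenturySummary(
                century=century,
                n_records=len(group),
                mean_share={c: float(np.mean([s[c] for s in shares])) for c in CROPS},
                mention_count={c: sum(r.present[c] for r in group) for c in CROPS},
            )
        )
    return out


def one_way_anova(groups: list[np.ndarray]) -> StabilityTest:
    """One-way fixed-effects ANOVA.

    F = between-group mean square / within-group mean square with
    (k-1, N-k) degrees of freedom.  Zero within-group variance with
    unequal means yields an infinite F (p = 0, flagged degenerate);
    all-identical data is an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    all_vals = np.concatenate(groups)
    n_total = all_vals.size
    k = len(groups)
    if n_total <= k:
        raise ValueError("total N must exceed number of groups")
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df1, df2 = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            raise ValueError("degenerate ANOVA: all values identical")
        return StabilityTest(
            crop="", test="anova", statistic=math.inf, df=(df1, df2),
            p_value=0.0, degenerate=True,
        )
    f = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(f, df1, df2))
    return StabilityTest(crop="", test="anova", statistic=float(f), df=(df1, df2), p_value=p)


def kruskal_wallis(groups: list[np.ndarray]) -> StabilityTest:
    """Kruskal-Wallis rank test with tie correction.

    H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1), divided by the tie factor
    1 - sum(t^3 - t)/(N^3 - N); p from the chi-square upper tail with
    k-1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("each group needs >= 1 observation")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need >= 3 observations in total")
    if np.ptp(pooled) == 0:
        raise ValueError("zero rank variance: all values tied")
    ranks = average_ranks(pooled)
    h = 0.0
    offset = 0
    for g in groups:
        rj = float(ranks[offset : offset + g.size].sum())
        h += rj * rj / g.size
        offset += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_factor = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    h /= tie_factor
    df = len(groups) - 1
    p = float(stats.chi2.sf(h, df))
    return StabilityTest(crop="", test="kruskal_wallis", statistic=float(h), df=(df,), p_value=p)


def stability_suite(records: list[ManorRecord]) -> list[StabilityTest]:
    """Per-crop test of whether sown shares changed across centuries.

    Groups are individual records' shares grouped by century: the study
    asks whether practice changed over time, and the record is the unit
    of replication.  Rye goes through ANOVA, the other four crops through
    Kruskal-Wallis.
    """
    in_study = [r for r in records if r.in_study and r.total_sown() > 0]
    by_century: dict[int, list[dict[str, float]]] = {}
    for r in in_study:
        by_century.setdefault(r.century, []).append(record_shares(r))
    if len(by_century) < 2:
        raise ValueError("need records in >= 2 centuries for stability tests")
    centuries = sorted(by_century)
    results: list[StabilityTest] = []
    for crop in CROPS:
        groups = [
            np.array([s[crop] for s in by_century[c]]) for c in centuries
        ]
        try:
            if crop in ANOVA_CROPS:
                res = one_way_anova(groups)
            else:
                res = kruskal_wallis(groups)
        except ValueError as exc:
            logger.warning("stability test for %s skipped: %s", crop, exc)
            continue
        res.crop = crop
        results.append(res)
    return results


def normality_report(records: list[ManorRecord]) -> dict[str, float]:
    """Advisory Shapiro-Wilk p-value per crop on pooled record shares.

    Emitted for documentation only: the ANOVA/Kruskal-Wallis assignment
    is fixed a priori, not re-derived from this report.
    """
    in_study = [r for r in records if r.in_study and r.total_sown() > 0]
    shares = [record_shares(r) for r in in_study]
    out: dict[str, float] = {}
    for crop in CROPS:
        vals = np.array([s[crop] for s in shares])
        if np.ptp(vals) == 0 or vals.size < 3:
            out[crop] = float("nan")
        else:
            out[crop] = float(stats.shapiro(vals).pvalue)
    return out
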