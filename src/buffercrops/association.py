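"""Permutation-calibrated Spearman correlation between crop and climate.

The per-bin crop percentages and the binned climate proxies are short
(≈17 bins), tied, and non-Gaussian, so association is measured with the
tie-aware Spearman rank correlation and its significance with a
Monte-Carlo permutation null: the climate vector is shuffled, rho is
recomputed for each shuffle, and the p-value is the add-one-smoothed
fraction of shuffles at least as extreme as the observation.  For n ≤ 8
an exact enumeration over all n! permutations is available as an oracle.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import false_discovery_control, rankdata

from .binning import BinSeries, crop_trajectory
from .climate import BinnedProxy
from .types import CROPS

logger = logging.getLogger(__name__)

ALTERNATIVES = ("two_sided", "greater", "less")
_TIE_EPS = 1e-12


@dataclass
class AssocResult:
    """Observed Spearman rho for one crop–proxy pair with its
    permutation-null summary."""

    crop: str
    proxy: str
    rho_obs: float
    n_bins: int
    n_perm: int
    p_value: float
    alternative: str
    seed: int
    null_quantiles: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "crop": self.crop, "proxy": self.proxy, "rho_obs": self.rho_obs,
            "n_bins": self.n_bins, "n_perm": self.n_perm, "p_value": self.p_value,
            "alternative": self.alternative, "seed": self.seed,
        }
        d.update({f"null_{k}": v for k, v in self.null_quantiles.items()})
        return d


def average_ranks(x) -> np.ndarray:
    """Midranks 1..n, ties receiving the mean of their occupied positions."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rank an empty vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values cannot be ranked")
    return rankdata(x, method="average")


def _drop_missing(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero rank variance: one input is constant")


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rank correlation: the Pearson correlation of
    the midranks of *x* and *y*.  Pairs with a missing value on either
    side are deleted first."""
    x, y = _drop_missing(x, y)
    _check_pair(x, y)
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _null_rhos(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Spearman rho for n_perm uniform shuffles of y against fixed x.

    Ranking commutes with permutation, so shuffling y's midranks is
    equivalent to (and much cheaper than) re-ranking each shuffle.
    """
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    denom = math.sqrt(float(rx @ rx))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(ryc @ ryc))
    perms = rng.permuted(np.tile(ryc, (n_perm, 1)), axis=1)
    return (perms @ rx) / (denom * sy)


def _tail_count(null: np.ndarray, obs: float, alternative: str) -> int:
    if alternative == "two_sided":
        return int(np.sum(np.abs(null) >= abs(obs) - _TIE_EPS))
    if alternative == "greater":
        return int(np.sum(null >= obs - _TIE_EPS))
    if alternative == "less":
        return int(np.sum(null <= obs + _TIE_EPS))
    raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def permutation_test(
    x,
    y,
    n_perm: int = 10_000,
    alternative: str = "two_sided",
    seed: int = 0,
    crop: str = "",
    proxy: str = "",
) -> AssocResult:
    """Monte-Carlo permutation test of Spearman association.

    *y* (the climate vector) is shuffled uniformly ``n_perm`` times with
    a generator seeded by ``seed``; the p-value uses the add-one
    convention p = (k + 1)/(n_perm + 1), which can never report an
    impossible p of zero from a finite Monte-Carlo sample.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x, y = _drop_missing(x, y)
    _check_pair(x, y)
    rho_obs = spearman_rho(x, y)
    rng = np.random.default_rng(seed)
    null = _null_rhos(x, y, n_perm, rng)
    k = _tail_count(null, rho_obs, alternative)
    p = (k + 1) / (n_perm + 1)
    q05, q50, q95 = np.quantile(null, [0.05, 0.50, 0.95])
    return AssocResult(
        crop=crop, proxy=proxy, rho_obs=rho_obs, n_bins=int(x.size),
        n_perm=int(n_perm), p_value=float(p), alternative=alternative,
        seed=int(seed),
        null_quantiles={"q05": float(q05), "q50": float(q50), "q95": float(q95)},
    )


def exact_permutation_p(x, y, alternative: str = "two_sided") -> float:
    """Exact permutation p-value by enumerating all n! shuffles of y.

    Returns the plain proportion of permutations at least as extreme as
    the observed rho (no add-one smoothing: this is the exact reference
    distribution used to validate the Monte-Carlo path).  Limited to
    n <= 8 (8! = 40,320 permutations).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    x, y = _drop_missing(x, y)
    _check_pair(x, y)
    n = x.size
    if n > 8:
        raise ValueError("exact enumeration limited to n <= 8; use Monte-Carlo")
    rho_obs = spearman_rho(x, y)
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ryc @ ryc))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = float(ryc[list(perm)] @ rx) / denom
        total += 1
        if alternative == "two_sided":
            hits += abs(rho) >= abs(rho_obs) - _TIE_EPS
        elif alternative == "greater":
            hits += rho >= rho_obs - _TIE_EPS
        else:
            hits += rho <= rho_obs + _TIE_EPS
    return hits / total


def run_association_suite(
    series: BinSeries,
    proxies: list[BinnedProxy],
    n_perm: int = 10_000,
    alternative: str = "two_sided",
    seed: int = 0,
    min_bins: int = 3,
) -> list[AssocResult]:
    """Permutation-tested Spearman rho for every (crop, proxy) pair.

    Bins missing on either side of a pair are dropped pairwise, never
    imputed.  Pairs left with fewer than ``min_bins`` joint bins, or with
    a constant crop vector (a crop absent from every joint bin), are
    skipped with a log entry.  Each pair gets its own child seed derived
    from ``seed`` so single pairs can be replayed in isolation.
    """
    results: list[AssocResult] = []
    pair_index = 0
    for crop in CROPS:
        traj = dict(crop_trajectory(series, crop))
        for proxy in proxies:
            pvals = {b: v for b, v, _ in proxy.bins}
            joint = sorted(set(traj) & set(pvals))
            pair_seed = int(np.random.SeedSequence([seed, pair_index]).generate_state(1)[0] % (2**31))
            pair_index += 1
            if len(joint) < min_bins:
                logger.warning(
                    "skipping %s vs %s: only %d joint bins", crop, proxy.name, len(joint)
                )
                continue
            xv = np.array([traj[b] for b in joint])
            yv = np.array([pvals[b] for b in joint])
            if np.ptp(xv) == 0 or np.ptp(yv) == 0:
                logger.warning("skipping %s vs %s: constant vector", crop, proxy.name)
                continue
            results.append(
                permutation_test(
                    xv, yv, n_perm=n_perm, alternative=alternative,
                    seed=pair_seed, crop=crop, proxy=proxy.name,
                )
            )
    return results


def summary_table(results: list[AssocResult]):
    """Suite results as a DataFrame with rho rounded to two decimals (the
    conventional reporting precision) and a Benjamini–Hochberg column as
    an advisory multiple-testing summary."""
    import pandas as pd

    if not results:
        raise ValueError("no association results to summarise")
    df = pd.DataFrame([r.to_dict() for r in results])
    df["rho_2dp"] = df["rho_obs"].round(2)
    df["p_bh"] = false_discovery_control(df["p_value"].to_numpy(), method="bh")
    return df
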