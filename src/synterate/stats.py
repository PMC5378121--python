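"""Permutation tests, Tukey–Kramer comparisons, and BCa bootstrap.

The group comparisons of the analysis avoid distributional assumptions:
two-sample contrasts use the Fisher–Pitman permutation test on raw
values (exact enumeration when feasible, Monte Carlo otherwise), and
multi-group stability-index contrasts use the Tukey–Kramer HSD
procedure.  Bootstrap confidence intervals for fitted parameters are
bias-corrected and accelerated (BCa), with the acceleration constant
from a leave-one-out jackknife.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "fisher_pitman_test",
    "tukey_kramer_hsd",
    "bca_interval",
    "bca_from_samples",
]

EXACT_ENUMERATION_CAP = 2_000_000
DEFAULT_MC_DRAWS = 100_000
_TIE_EPS = 1e-12


def fisher_pitman_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    mode: str = "auto",
    rng: np.random.Generator | int | None = None,
    enumeration_cap: int = EXACT_ENUMERATION_CAP,
    n_monte_carlo: int = DEFAULT_MC_DRAWS,
) -> float:
    """Two-sample Fisher–Pitman permutation test, two-tailed.

    The statistic is the sum of group A; the two-tailed p-value is the
    fraction of relabellings whose statistic deviates from the null mean
    at least as much as observed.  ``mode`` is "exact", "monte_carlo" or
    "auto" (exact when the number of assignments fits the enumeration
    cap).  Monte Carlo includes the observed assignment, so p >= 1/(B+1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = a.sum()
    null_mean = na * pooled.mean()
    dev = abs(observed - null_mean)

    n_exact = comb(n, na)
    if mode == "auto":
        mode = "exact" if n_exact <= enumeration_cap else "monte_carlo"
    if mode == "exact":
        if n_exact > enumeration_cap:
            raise ValueError(f"{n_exact} assignments exceed the enumeration cap")
        idx = np.fromiter(
            (i for c in combinations(range(n), na) for i in c),
            dtype=np.int64, count=n_exact * na,
        ).reshape(n_exact, na)
        stats = pooled[idx].sum(axis=1)
        return float(np.mean(np.abs(stats - null_mean) >= dev - _TIE_EPS))
    if mode != "monte_carlo":
        raise ValueError("mode must be 'auto', 'exact' or 'monte_carlo'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # vectorized random relabellings via argpartition of random keys
    keys = rng.random((n_monte_carlo, n))
    take = np.argpartition(keys, na - 1, axis=1)[:, :na]
    stats = pooled[take].sum(axis=1)
    hits = int(np.sum(np.abs(stats - null_mean) >= dev - _TIE_EPS))
    return (hits + 1) / (n_monte_carlo + 1)


def tukey_kramer_hsd(groups: Mapping[str, Sequence[float]],
                     alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs Tukey–Kramer HSD comparison of group means.

    Handles unequal group sizes through the studentized-range procedure
    (statsmodels implementation).  Returns one row per group pair with
    the mean difference, adjusted interval, adjusted p-value and a
    significance flag at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels, values = [], []
    for name, vals in groups.items():
        vals = list(vals)
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
        labels += [name] * len(vals)
        values += vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(labels),
                            alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=res.summary().data[0])
    frame["reject"] = frame["reject"].astype(bool)
    return frame


def bca_interval(
    data: np.ndarray | pd.DataFrame,
    statistic: Callable[[np.ndarray], float],
    n_boot: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    boot_stats: np.ndarray | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap interval for a statistic
    of rows of ``data``.

    The bias term z0 comes from the fraction of bootstrap statistics
    below the point estimate; the acceleration from the jackknife
    skewness.  Precomputed ``boot_stats`` (resampled with replacement
    from rows of ``data``) may be supplied to share one set of resamples
    across several statistics.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = np.asarray(data) if not isinstance(data, pd.DataFrame) else data
    n = len(rows)
    if n < 3:
        raise ValueError("need at least 3 observations")
    take = (lambda idx: rows.iloc[idx]) if isinstance(rows, pd.DataFrame) \
        else (lambda idx: rows[idx])
    theta_hat = float(statistic(rows))

    if boot_stats is None:
        boot_stats = np.array([
            float(statistic(take(rng.integers(0, n, size=n))))
            for _ in range(n_boot)
        ])
    boot_stats = boot_stats[np.isfinite(boot_stats)]
    if boot_stats.size == 0:
        raise RuntimeError("all bootstrap refits failed")
    if np.ptp(boot_stats) == 0:  # degenerate: zero-noise data
        return theta_hat, theta_hat

    prop = np.clip(np.mean(boot_stats < theta_hat), 1e-12, 1 - 1e-12)
    z0 = norm.ppf(prop)
    jack = np.array([
        float(statistic(take(np.delete(np.arange(n), i)))) for i in range(n)
    ])
    dev = jack.mean() - jack
    denom = 6.0 * (np.sum(dev ** 2) ** 1.5)
    a = float(np.sum(dev ** 3) / denom) if denom > 0 else 0.0

    def adjusted(q: float) -> float:
        z = norm.ppf(q)
        return float(norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z))))

    lo = np.quantile(boot_stats, adjusted(alpha / 2))
    hi = np.quantile(boot_stats, adjusted(1 - alpha / 2))
    return float(lo), float(hi)


def bca_from_samples(
    theta_hat: float,
    boot_stats: np.ndarray,
    jack_stats: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """BCa interval from precomputed bootstrap and jackknife statistics.

    Lets one set of resample refits feed intervals for several
    parameters at once (the refit, not the resampling, dominates cost).
    """
    boot = np.asarray(boot_stats, float)
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        raise RuntimeError("all bootstrap refits failed")
    if np.ptp(boot) == 0:
        return float(theta_hat), float(theta_hat)
    prop = np.clip(np.mean(boot < theta_hat), 1e-12, 1 - 1e-12)
    z0 = norm.ppf(prop)
    jack = np.asarray(jack_stats, float)
    dev = jack.mean() - jack
    denom = 6.0 * (np.sum(dev ** 2) ** 1.5)
    a = float(np.sum(dev ** 3) / denom) if denom > 0 else 0.0

    def adjusted(q: float) -> float:
        z = norm.ppf(q)
        return float(norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z))))

    return (float(np.quantile(boot, adjusted(alpha / 2))),
            float(np.quantile(boot, adjusted(1 - alpha / 2))))
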