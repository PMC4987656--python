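"""Dual differential-expression testing with FDR-corrected intersection.

Two independent tests are run per transcript — a mean-based Welch-type test
on log2(RPKM + 1) and a count-based exact conditional binomial test on read
units — each Benjamini–Hochberg adjusted; a transcript is called only when it
passes BOTH at the chosen FDR level ("common for both" statistics).  Called
transcripts are split into unique-to-one-group versus up-regulated categories
using a presence floor on the other group's mean RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError

CATEGORIES = ("unique_A", "unique_B", "up_A", "up_B", "ns")


@dataclass
class DiffParams:
    alpha: float = 0.01
    presence_floor: float = 0.5   # RPKM below which a group counts as absent


def mean_test(rpkm_a: np.ndarray, rpkm_b: np.ndarray) -> np.ndarray:
    """Welch t-test on log2(RPKM + 1), two-sided, per transcript (rows).

    Degenerate zero-variance rows return p = 1 when the group means are equal
    and p = 0 when they differ (the difference is then certain under the
    location model).
    """
    a = np.log2(np.asarray(rpkm_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(rpkm_b, dtype=float) + 1.0)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ConfigError("mean_test needs >= 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & equal] = 1.0
    p[degenerate & ~equal] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def count_test(
    units_a: np.ndarray,
    units_b: np.ndarray,
    norm_factors: tuple[float, float] | None = None,
) -> np.ndarray:
    """Exact conditional binomial test on group unit totals, per transcript.

    Conditional on the combined total n = kA + kB, kA ~ Binomial(n, piA)
    under the null, where piA is group A's share of the normalized library.
    Two-sided p doubles the smaller tail, capped at 1; a zero total gives
    p = 1.
    """
    ka = np.rint(np.asarray(units_a, dtype=float).sum(axis=1)).astype(np.int64)
    kb = np.rint(np.asarray(units_b, dtype=float).sum(axis=1)).astype(np.int64)
    if (ka < 0).any() or (kb < 0).any():
        raise ConfigError("unit totals must be non-negative")
    if norm_factors is None:
        la, lb = float(ka.sum()), float(kb.sum())
    else:
        la, lb = map(float, norm_factors)
    if la <= 0 or lb <= 0:
        raise ConfigError("library sizes must be positive")
    pi_a = la / (la + lb)
    n = ka + kb
    lower = stats.binom.cdf(ka, n, pi_a)
    upper = stats.binom.sf(ka - 1, n, pi_a)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    p[n == 0] = 1.0
    return p


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def categorize(
    transcripts,
    p_mean: np.ndarray,
    p_count: np.ndarray,
    rpkm_a: np.ndarray,
    rpkm_b: np.ndarray,
    params: DiffParams = DiffParams(),
) -> pd.DataFrame:
    """Build the per-transcript result table with the four-way category split.

    Significant transcripts (both adjusted p-values at or below alpha) are
    ``unique_A`` when the group-B mean RPKM falls below the presence floor
    (symmetrically ``unique_B``), otherwise ``up_A``/``up_B`` by fold
    direction; everything else is ``ns``.
    """
    q_mean = bh_fdr(p_mean)
    q_count = bh_fdr(p_count)
    mean_a = np.asarray(rpkm_a, dtype=float).mean(axis=1)
    mean_b = np.asarray(rpkm_b, dtype=float).mean(axis=1)
    log2fc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)
    sig = (q_mean <= params.alpha) & (q_count <= params.alpha)
    category = np.full(len(mean_a), "ns", dtype=object)
    unique_a = sig & (mean_b < params.presence_floor) & (mean_a >= params.presence_floor)
    unique_b = sig & (mean_a < params.presence_floor) & (mean_b >= params.presence_floor)
    up_a = sig & ~unique_a & ~unique_b & (log2fc > 0)
    up_b = sig & ~unique_a & ~unique_b & (log2fc < 0)
    category[unique_a] = "unique_A"
    category[unique_b] = "unique_B"
    category[up_a] = "up_A"
    category[up_b] = "up_B"
    return pd.DataFrame(
        {
            "transcript": list(transcripts),
            "log2fc": log2fc,
            "p_mean": p_mean,
            "p_count": p_count,
            "q_mean": q_mean,
            "q_count": q_count,
            "mean_rpkm_A": mean_a,
            "mean_rpkm_B": mean_b,
            "significant": sig,
            "category": category,
        }
    ).set_index("transcript")


def run_two_group(
    rpkm: pd.DataFrame,
    units: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    params: DiffParams = DiffParams(),
) -> pd.DataFrame:
    """Convenience wrapper: both tests plus categories for two sample groups."""
    ra, rb = rpkm[samples_a].values, rpkm[samples_b].values
    ua, ub = units[samples_a].values, units[samples_b].values
    p_m = mean_test(ra, rb)
    p_c = count_test(ua, ub)
    return categorize(rpkm.index, p_m, p_c, ra, rb, params)
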