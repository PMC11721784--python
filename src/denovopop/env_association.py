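"""Environmental association of gene presence: per-factor t-tests, the
subsampling permutation test, and the collinearity pre-filter used before
ordination.

The permutation test addresses the imbalance between a large present group
and a handful of absent accessions: it draws subsamples of the absent-group
size from the present group to build a null distribution of subsample means,
and asks whether the observed absent-group mean falls outside the empirical
95 % interval of that null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "ttest_env",
    "permutation_test",
    "filter_collinear",
    "BIO_FACTORS",
]

BIO_FACTORS = [f"bio{i}" for i in range(1, 20)]


@dataclass
class PermutationResult:
    observed_mean: float
    null_means: np.ndarray
    ci_low: float
    ci_high: float
    p_empirical: float
    significant: bool
    seed: int

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")
        if not (0 < self.p_empirical <= 1):
            raise ValueError("p_empirical must lie in (0, 1]")


def ttest_env(
    env: pd.DataFrame,
    present_ids: Sequence[str],
    absent_ids: Sequence[str],
    factors: Sequence[str] = BIO_FACTORS,
    accession_column: str = "accession",
) -> pd.DataFrame:
    """Two-sided equal-variance Student's t-test per climate factor.

    Reports group means, the mean difference (absent minus present), the raw
    p-value and a Benjamini-Hochberg adjusted column.  Factors with fewer
    than 2 non-missing values in either group are skipped with a warning.
    """
    df = env.set_index(accession_column)
    rows = []
    for factor in factors:
        if factor not in df.columns:
            logger.warning("factor %s absent from table; skipped", factor)
            continue
        a = df.loc[df.index.intersection(present_ids), factor].dropna().to_numpy(float)
        b = df.loc[df.index.intersection(absent_ids), factor].dropna().to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("factor %s has <2 values in a group; skipped", factor)
            continue
        if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append(
            {
                "factor": factor,
                "mean_present": float(a.mean()),
                "mean_absent": float(b.mean()),
                "mean_diff": float(b.mean() - a.mean()),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def permutation_test(
    present: Sequence[float],
    absent: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
    replace: bool = False,
    statistic: str = "mean",
) -> PermutationResult:
    """Subsampling permutation test of the absent-group mean.

    Draws ``k = len(absent)`` values from the present group (without
    replacement by default), ``n_perm`` times; the null is the distribution
    of subsample means.  ``significant`` is true when the observed
    absent-group mean falls outside the empirical [2.5, 97.5] percentile
    interval.  The empirical p uses the add-one rule
    ``(1 + 2 * min(#null <= obs, #null >= obs)) / (n_perm + 1)`` so it is
    never exactly zero.  ``statistic="diff"`` centres both the null and the
    observed value on the present-group mean (the equivalent
    difference-of-means formulation).
    """
    present = np.asarray(present, dtype=float)
    absent = np.asarray(absent, dtype=float)
    k = len(absent)
    if k < 1:
        raise ValueError("absent group is empty")
    if not replace and k > len(present):
        raise ValueError("cannot subsample more values than the present group has")
    if len(present) <= k:
        raise ValueError("present group must be larger than the absent group")
    if statistic not in {"mean", "diff"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    if replace:
        idx = rng.integers(0, len(present), size=(n_perm, k))
    else:
        keys = rng.random((n_perm, len(present)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_means = present[idx].mean(axis=1)
    observed = float(absent.mean())
    if statistic == "diff":
        null_means = null_means - present.mean()
        observed -= float(present.mean())
    ci_low, ci_high = np.percentile(null_means, [2.5, 97.5])
    n_le = int(np.sum(null_means <= observed))
    n_ge = int(np.sum(null_means >= observed))
    p = min(1.0, (1 + 2 * min(n_le, n_ge)) / (n_perm + 1))
    return PermutationResult(
        observed_mean=observed,
        null_means=null_means,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_empirical=p,
        significant=not (ci_low <= observed <= ci_high),
        seed=seed,
    )


def filter_collinear(
    env: pd.DataFrame,
    factors: Sequence[str] = BIO_FACTORS,
    threshold: float = 0.7,
) -> list[str]:
    """Greedy elimination of collinear climate factors (|Pearson r| > 0.7).

    Constant factors are dropped first with a warning.  While any remaining
    pair exceeds the threshold, the factor with the largest mean absolute
    correlation to the other remaining factors is dropped; ties break
    deterministically towards the earliest factor in the given order.
    """
    factors = [f for f in factors if f in env.columns]
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    values = env[factors].to_numpy(float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 accessions")
    keep = list(factors)
    for f in factors:
        if np.nanstd(env[f].to_numpy(float)) == 0:
            logger.warning("factor %s is constant; dropped before filtering", f)
            keep.remove(f)
    while len(keep) >= 2:
        corr = np.abs(np.corrcoef(env[keep].to_numpy(float), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= threshold:
            break
        mean_abs = corr.sum(axis=1) / (len(keep) - 1)
        drop = keep[int(np.argmax(mean_abs))]
        logger.info("dropping collinear factor %s (mean |r| = %.3f)", drop, mean_abs.max())
        keep.remove(drop)
    return keep
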