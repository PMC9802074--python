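"""The statistical battery for dark/light comparisons.

Test-to-quantity mapping follows standard practice for this kind of
dataset: Mann–Whitney U for pooled per-instance distributions (volumes,
sphericity, MCI, lengths) and per-site proximity areas; Welch's unequal-
variance t for per-cell totals (n = cells per condition); Fisher's exact
test for category counts (alone vs engaged); Pearson correlation for
volume-volume and volume-area relationships. All tests are two-sided and
uncorrected.

Implementations delegate to scipy.stats; this module fixes the exact
conventions (exact vs approximate Mann-Whitney path, Fisher's
probability-mass two-sided rule, sample odds ratio) so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration when min(n) <= 8 and there are no ties, else
    the tie-corrected normal approximation (no continuity correction, so
    perfectly symmetric inputs give p = 1 exactly). Identical constant
    samples give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Mann-Whitney p set to 1")
        return MannWhitneyResult(U=len(x) * len(y) / 2.0, p=1.0,
                                 method="degenerate")
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(x), len(y)) <= 8 and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return MannWhitneyResult(U=float(res.statistic), p=float(res.pvalue),
                                 method="exact")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="asymptotic", use_continuity=False)
    return MannWhitneyResult(U=float(res.statistic),
                             p=float(min(res.pvalue, 1.0)),
                             method="asymptotic")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables (at
    fixed margins) no more probable than the observed one — the common
    probability-mass convention. Returns (sample odds ratio, p); a zero
    margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative counts")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch's t needs at least 2 values per sample")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both samples")
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient r with its two-sided p.

    Pearson by default (``method="spearman"`` available). Zero variance in
    either input yields (nan, nan) with a warning — reported as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan"), float("nan")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def median_percent_change(dark, light) -> float:
    """(median_light - median_dark) / median_dark * 100."""
    md = float(np.median(np.asarray(dark, dtype=float)))
    ml = float(np.median(np.asarray(light, dtype=float)))
    if md == 0:
        return float("nan")
    return (ml - md) / md * 100.0


def median_iqr(values) -> tuple[float, float, float]:
    """(median, 25th, 75th percentile)."""
    v = np.asarray(values, dtype=float)
    return (float(np.median(v)), float(np.percentile(v, 25)),
            float(np.percentile(v, 75)))
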