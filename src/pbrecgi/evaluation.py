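"""Reconstruction-quality statistics.

Morphology agreement is quantified per epicardial recording site by
Pearson's correlation coefficient (CC) between the recorded and the
reconstructed electrogram at the closest mesh node; timing agreement by the
correlation R across sites of activation (or recovery) times; paired method
comparisons by Wilcoxon signed-rank and unpaired ones by rank-sum tests.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats


def pearson_cc(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (undefined) for constant input."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


class TimingCorrelation(NamedTuple):
    r: float
    n_pairs: int
    n_dropped: int


def timing_correlation(recorded: np.ndarray,
                       reconstructed: np.ndarray) -> TimingCorrelation:
    """Pearson R over paired defined (non-NaN) timings; undefined pairs are
    dropped and counted."""
    a = np.asarray(recorded, float).ravel()
    b = np.asarray(reconstructed, float).ravel()
    if len(a) != len(b):
        raise ValueError("paired series must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 defined timing pairs")
    return TimingCorrelation(r=pearson_cc(a[ok], b[ok]),
                             n_pairs=int(ok.sum()),
                             n_dropped=int(len(a) - ok.sum()))


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided signed-rank p for paired measurements: exact distribution
    for n <= 25 untied nonzero differences, normal approximation with tie
    correction otherwise. NaN when every difference is zero."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) != len(b):
        raise ValueError("paired series must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return np.nan
    if len(d) < 5:
        raise ValueError("need at least 5 nonzero differences")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.pvalue)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney) p for unpaired measurements; exact
    for small untied samples, tie-corrected normal approximation otherwise."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need at least 3 values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0  # identical constants: no evidence of a shift
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not ties) else \
        "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
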