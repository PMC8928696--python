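"""Bulk deconvolution by fragment size.

Peaks (called externally on the mixed signal) are classified into a
"small" fragment-size class (Pol2S5p) and a "large" class (H3K27me3) by
fitting a two-component Gaussian mixture to the per-peak average fragment
size and thresholding at the intersection point of the two weighted
component densities.

The EM fit is deterministic: components start at the 25th/75th percentiles
with the pooled standard deviation and equal weights, and iterate until
the absolute log-likelihood change falls below 1e-8 (at most 1,000
iterations).  Component standard deviations are floored at 1 bp; a fit
that hits the floor is flagged degenerate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

SD_FLOOR = 1.0  # bp


@dataclass
class TwoGaussianFit:
    weights: np.ndarray  # 2-simplex
    means: np.ndarray  # bp, means[0] < means[1]
    sds: np.ndarray
    loglik_trace: np.ndarray  # per-iteration values, non-decreasing
    threshold: float = math.nan  # filled by intersection_threshold
    degenerate: bool = False
    n_iter: int = 0


def mean_fragment_size_per_peak(frags: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Weighted mean fragment length per peak.

    A fragment overlaps a peak if their half-open intervals intersect by
    at least 1 bp.  Peaks within a class must be sorted and
    non-overlapping.  Peaks with no overlapping fragment are dropped (a
    count is logged).

    Returns a DataFrame ``chrom, start, end, n_fragments, mean_fraglen``.
    """
    rows = []
    n_empty = 0
    for chrom, pk in peaks.groupby("chrom", sort=True):
        starts = pk["start"].to_numpy()
        ends = pk["end"].to_numpy()
        if np.any(np.diff(starts) < 0) or np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"peaks on {chrom} must be sorted and non-overlapping")
        sub = frags[frags["chrom"] == chrom]
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        cnt = sub["count"].to_numpy().astype(float)
        flen = (fe - fs).astype(float)
        lo = np.searchsorted(ends, fs, side="right")
        hi = np.searchsorted(starts, fe, side="left")
        sum_w = np.zeros(len(pk))
        sum_lw = np.zeros(len(pk))
        simple = hi == lo + 1
        np.add.at(sum_w, lo[simple], cnt[simple])
        np.add.at(sum_lw, lo[simple], cnt[simple] * flen[simple])
        for j in np.flatnonzero(hi > lo + 1):  # fragment spanning several peaks
            sum_w[lo[j]:hi[j]] += cnt[j]
            sum_lw[lo[j]:hi[j]] += cnt[j] * flen[j]
        for i in range(len(pk)):
            if sum_w[i] == 0:
                n_empty += 1
                continue
            rows.append(
                (chrom, int(starts[i]), int(ends[i]), sum_w[i], sum_lw[i] / sum_w[i])
            )
    if n_empty:
        logger.info("dropped %d peaks with no overlapping fragments", n_empty)
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_fragments", "mean_fraglen"]
    )


def fit_two_gaussian_em(sizes, tol: float = 1e-8, max_iter: int = 1000) -> TwoGaussianFit:
    """Two-component Gaussian mixture by EM with deterministic start."""
    x = np.asarray(sizes, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: all observations identical")

    means = np.percentile(x, [25.0, 75.0]).astype(float)
    if means[0] == means[1]:
        means[1] = means[0] + 1.0
    sds = np.full(2, max(x.std(), SD_FLOOR))
    weights = np.array([0.5, 0.5])

    trace = []
    prev = -np.inf
    degenerate = False
    for it in range(1, max_iter + 1):
        logp = norm.logpdf(x[:, None], means[None, :], sds[None, :]) + np.log(weights)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        trace.append(loglik)
        resp = np.exp(logp - lse[:, None])
        nk = resp.sum(axis=0)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(var)
        if np.any(sds < SD_FLOOR):
            sds = np.maximum(sds, SD_FLOOR)
            degenerate = True
        if abs(loglik - prev) < tol:
            break
        prev = loglik

    order = np.argsort(means)
    fit = TwoGaussianFit(
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik_trace=np.asarray(trace),
        degenerate=degenerate,
        n_iter=len(trace),
    )
    if degenerate:
        logger.warning("EM fit hit the 1 bp sd floor; flagged degenerate")
    return fit


def intersection_threshold(fit: TwoGaussianFit) -> float:
    """Fragment size where the two weighted component densities intersect.

    Solves w0·N(x; m0, s0) = w1·N(x; m1, s1) as a quadratic in x on the
    log scale and returns the root between the two means (if both roots
    fall between them, the one where the responsibility of component 0
    crosses 0.5 from above).  Without a crossing between the means the
    midpoint is returned and a warning logged.
    """
    (w0, w1), (m0, m1), (s0, s1) = fit.weights, fit.means, fit.sds
    if m0 == m1:
        raise ValueError("component means must be distinct")
    # log w0 - log s0 - (x-m0)^2/2s0^2 = log w1 - log s1 - (x-m1)^2/2s1^2
    a = 0.5 * (1.0 / s1**2 - 1.0 / s0**2)
    b = m0 / s0**2 - m1 / s1**2
    c = (
        0.5 * (m1**2 / s1**2 - m0**2 / s0**2)
        + math.log(w0 / w1)
        + math.log(s1 / s0)
    )
    if a == 0.0:
        roots = [] if b == 0.0 else [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0:
            roots = []
        else:
            sq = math.sqrt(disc)
            roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    between = sorted(r for r in roots if m0 < r < m1)
    if not between:
        logger.warning("no density crossing between the means; using midpoint")
        threshold = 0.5 * (m0 + m1)
    elif len(between) == 1:
        threshold = between[0]
    else:
        # pick the root where component-0 responsibility crosses 0.5
        # downwards (density difference changes sign from + to -)
        def diff(x):
            return (
                math.log(w0) - math.log(s0) - (x - m0) ** 2 / (2 * s0**2)
                - math.log(w1) + math.log(s1) + (x - m1) ** 2 / (2 * s1**2)
            )

        threshold = between[0]
        for r in between:
            if diff(r - 1e-6) > 0 > diff(r + 1e-6):
                threshold = r
                break
    fit.threshold = float(threshold)
    return fit.threshold


def partition_peaks(profiles: pd.DataFrame, threshold: float):
    """Split peak profiles at the threshold: ``mean_fraglen < threshold``
    goes to the small (Pol2S5p) class, ``>= threshold`` to the large
    (H3K27me3) class.  Exhaustive and disjoint."""
    small = profiles[profiles["mean_fraglen"] < threshold].reset_index(drop=True)
    large = profiles[profiles["mean_fraglen"] >= threshold].reset_index(drop=True)
    return small, large
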