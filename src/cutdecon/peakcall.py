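"""Peak and domain calling on deconvolved cut-site density tracks.

Narrow Pol2S5p peaks and broad H3K27me3 domains are called by
thresholding each target's deconvolved density.  The threshold is the
weighted upper quantile of the density at cut positions: with r the
expected fraction of cuts falling in that target's peaks, the threshold
sits at cumulative probability (1 - r) so that approximately an r
fraction of cut weight lies above it.  r derives from the integral share
of the target, robustified with a Beta(0.5, 0.5) prior on the ratio and
the conservative assumption that half of a target's cuts fall into
reproducible peaks:

    r_hat = (I_target + 1/2) / (I_pol + I_k27 + 1)
    r     = (1 + 2 r_hat) / 8          # in [1/8, 3/8]

Pol2S5p peaks keep supra-threshold runs wider than 100 bp that contain at
least one cut; the summit is the position of maximal density (leftmost on
ties).  H3K27me3 domains are additionally called on the average of the
raw and a Gaussian-smoothed signal (bridging the discontinuous blocks
large domains decompose into), the two call sets are merged by interval
union, and only domains wider than 400 bp are kept.  Peaks of one class
overlapped on at least 50% of their span by the other class are
re-labelled "overlap".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from cutdecon.gpdeconv import DeconvResult

TARGET_LABEL = {"pol": "Pol2S5p", "k27": "H3K27me3"}
MIN_WIDTH = {"pol": 100, "k27": 400}
DEFAULT_SMOOTH_SIGMA = 2000.0  # bp; matches the broad-target GP length scale


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    target: str  # Pol2S5p / H3K27me3 / overlap
    score: float  # max deconvolved density in the peak
    summit: Optional[int] = None  # Pol2S5p only

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class ThresholdEstimate:
    r_hat: float
    r: float
    threshold_value: float = float("nan")


def estimate_target_fraction(result: DeconvResult, target: str = "pol") -> ThresholdEstimate:
    """Expected fraction of cuts in the target's peaks, from the
    deconvolved integrals with Beta(0.5, 0.5) pseudo-counts."""
    i_pol = sum(t.integral_pol for t in result.tracks)
    i_k27 = sum(t.integral_k27 for t in result.tracks)
    if i_pol + i_k27 <= 0:
        raise ValueError("zero combined integral")
    i_target = i_pol if target == "pol" else i_k27
    r_hat = (i_target + 0.5) / (i_pol + i_k27 + 1.0)
    return ThresholdEstimate(r_hat=r_hat, r=(1.0 + 2.0 * r_hat) / 8.0)


def weighted_quantile(values, weights, q: float) -> float:
    """Quantile of a weighted empirical distribution (step CDF)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    cum = np.cumsum(weights[order]) / weights.sum()
    i = int(np.searchsorted(cum, q, side="left"))
    return float(values[order][min(i, values.size - 1)])


def _runs_above(grid_pos, dens, step, threshold, cut_pos, min_width):
    """Supra-threshold runs containing at least one cut and wider than
    min_width (strict); returns (start, end, score, summit) tuples."""
    above = dens >= threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    out = []
    for i0, i1 in zip(edges[::2], edges[1::2]):
        start = int(grid_pos[i0])
        end = int(grid_pos[i1 - 1]) + step
        if end - start <= min_width:
            continue
        lo = np.searchsorted(cut_pos, start, side="left")
        hi = np.searchsorted(cut_pos, end, side="left")
        if hi == lo:  # no cut inside the candidate
            continue
        seg = dens[i0:i1]
        k = int(np.argmax(seg))  # leftmost maximum
        out.append((start, end, float(seg[k]), int(grid_pos[i0 + k])))
    return out


def call_pol_peaks(result: DeconvResult, est: Optional[ThresholdEstimate] = None):
    """Call narrow Pol2S5p peaks on the deconvolved pol signal."""
    if est is None:
        est = estimate_target_fraction(result, "pol")
    return _call_target(result, est, "pol")


def call_k27_domains(result: DeconvResult, est: Optional[ThresholdEstimate] = None,
                     smooth_sigma: float = DEFAULT_SMOOTH_SIGMA):
    """Call broad H3K27me3 domains: union of calls on the raw signal and
    on the average of raw and Gaussian-smoothed signal."""
    if est is None:
        est = estimate_target_fraction(result, "k27")
    raw = _call_target(result, est, "k27")
    smoothed = _call_target(result, est, "k27", smooth_sigma=smooth_sigma)
    return _union_domains(raw, smoothed, min_width=MIN_WIDTH["k27"])


def _call_target(result: DeconvResult, est: ThresholdEstimate, target: str,
                 smooth_sigma: Optional[float] = None):
    segments = list(result.segments())
    vals, wts, signals = [], [], []
    for seg in segments:
        dens = seg.dens_pol if target == "pol" else seg.dens_k27
        if smooth_sigma is not None:
            dens = 0.5 * (dens + gaussian_filter1d(dens, smooth_sigma / seg.grid_step))
        signals.append(dens)
        vals.append(np.interp(seg.cut_pos, seg.grid_pos, dens))
        wts.append(seg.cut_weight)
    if not segments:
        return []
    threshold = weighted_quantile(np.concatenate(vals), np.concatenate(wts), 1.0 - est.r)
    est.threshold_value = threshold
    min_width = 0 if target == "k27" else MIN_WIDTH["pol"]
    peaks = []
    for seg, dens in zip(segments, signals):
        for start, end, score, summit in _runs_above(
            seg.grid_pos, dens, seg.grid_step, threshold, seg.cut_pos, min_width
        ):
            peaks.append(
                Peak(
                    chrom=seg.chrom,
                    start=start,
                    end=end,
                    target=TARGET_LABEL[target],
                    score=score,
                    summit=summit if target == "pol" else None,
                )
            )
    return peaks


def _union_domains(calls_a, calls_b, min_width: int):
    """Interval union of two domain call sets, merging overlapping or
    touching intervals; the width filter applies to the merged result."""
    by_chrom = {}
    for pk in list(calls_a) + list(calls_b):
        by_chrom.setdefault(pk.chrom, []).append(pk)
    out = []
    for chrom in sorted(by_chrom):
        pks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur = pks[0]
        merged = [[cur.start, cur.end, cur.score]]
        for pk in pks[1:]:
            if pk.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], pk.end)
                merged[-1][2] = max(merged[-1][2], pk.score)
            else:
                merged.append([pk.start, pk.end, pk.score])
        for start, end, score in merged:
            if end - start > min_width:
                out.append(
                    Peak(chrom=chrom, start=start, end=end,
                         target=TARGET_LABEL["k27"], score=score)
                )
    return out


def _overlap_bp(peak: Peak, others) -> int:
    total = 0
    for o in others:
        if o.chrom != peak.chrom:
            continue
        total += max(0, min(peak.end, o.end) - max(peak.start, o.start))
    return total


def resolve_overlaps(pol_peaks, k27_peaks):
    """Re-label peaks overlapped on >= 50% of their span by the other
    class as "overlap"; all peaks are retained (labels partition into
    three classes)."""
    out = []
    for pk in pol_peaks:
        frac = _overlap_bp(pk, k27_peaks) / pk.width if pk.width else 0.0
        label = pk.target if frac < 0.5 else "overlap"
        out.append(Peak(pk.chrom, pk.start, pk.end, label, pk.score, pk.summit))
    for pk in k27_peaks:
        frac = _overlap_bp(pk, pol_peaks) / pk.width if pk.width else 0.0
        label = pk.target if frac < 0.5 else "overlap"
        out.append(Peak(pk.chrom, pk.start, pk.end, label, pk.score, pk.summit))
    out.sort(key=lambda p: (p.chrom, p.start, p.end))
    return out


def call_peaks(result: DeconvResult, smooth_sigma: float = DEFAULT_SMOOTH_SIGMA):
    """Full peak-calling stage: pol peaks, k27 domains, overlap resolution.

    Returns ``(peaks, est_pol, est_k27)``.
    """
    est_pol = estimate_target_fraction(result, "pol")
    est_k27 = estimate_target_fraction(result, "k27")
    pol = call_pol_peaks(result, est_pol)
    k27 = call_k27_domains(result, est_k27, smooth_sigma=smooth_sigma)
    return resolve_overlaps(pol, k27), est_pol, est_k27
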