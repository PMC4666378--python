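"""Evaluation metrics and baseline methods for simulation benchmarks.

Provides the true-discovery-rate machinery for ranked sites and ranked
regions, the two no-replicate baselines (per-site Fisher's exact test on
the pooled 2x2 count table, and the absolute difference of smoothed
means), and parameter-recovery summaries (Pearson correlation, MSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dmr import DmrRegion, assemble_regions, rank_regions
from .errors import ValidationError
from .io import CountPair
from .simulate import SimTruth
from .smoothing import SmoothedMeans

__all__ = [
    "TdrCurve",
    "true_dml_mask",
    "site_tdr",
    "region_tdr",
    "fisher_baseline",
    "meandiff_baseline",
    "recovery_metrics",
    "regions_from_scores",
]

#: minimum |mu1 - mu2| for a site inside a truth interval to count as truly
#: differential (re-smoothing tapers interval edges toward zero effect)
MIN_TRUE_EFFECT = 0.01


@dataclass
class TdrCurve:
    """True discovery rate along a ranking: fraction true at each cutoff."""

    axis: np.ndarray  # ranked cutoff: site count k, or cumulative bp
    tdr: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.axis) <= 0):
            raise ValidationError("TDR axis must be strictly increasing")
        if np.any((self.tdr < 0) | (self.tdr > 1)):
            raise ValidationError("TDR values must lie in [0, 1]")

    def at(self, cutoff) -> float:
        """TDR at the largest axis value <= cutoff.

        Falls back to the first (smallest) prefix when even that exceeds
        the cutoff, and to the last when the cutoff lies beyond the curve.
        """
        if len(self.axis) == 0:
            return float("nan")
        idx = np.searchsorted(self.axis, cutoff, side="right") - 1
        idx = int(np.clip(idx, 0, len(self.tdr) - 1))
        return float(self.tdr[idx])


def true_dml_mask(truth: SimTruth, min_effect: float = MIN_TRUE_EFFECT) -> np.ndarray:
    """Sites that are truly differential: inside a truth interval with
    |mu_true_1 - mu_true_2| above ``min_effect``."""
    return truth.in_dmr() & (
        np.abs(truth.mu_true_1 - truth.mu_true_2) > min_effect
    )


def _k_grid(n: int) -> np.ndarray:
    ks = np.unique(np.round(np.geomspace(10, n, 40)).astype(int))
    return ks[ks >= 1]


def site_tdr(ranked_idx: np.ndarray, truth_mask: np.ndarray, k_grid=None) -> TdrCurve:
    """TDR(k) = |top-k intersect truth| / k along a site ranking.

    ``ranked_idx`` holds site indexes, best first; every index must map to
    a truth label.
    """
    ranked_idx = np.asarray(ranked_idx)
    if len(ranked_idx) == 0:
        return TdrCurve(np.empty(0, dtype=int), np.empty(0))
    if ranked_idx.min() < 0 or ranked_idx.max() >= len(truth_mask):
        raise ValidationError("ranked site index outside the truth labelling")
    hits = np.cumsum(truth_mask[ranked_idx])
    if k_grid is None:
        k_grid = _k_grid(len(ranked_idx))
    k_grid = np.asarray(k_grid, dtype=int)
    k_grid = k_grid[k_grid <= len(ranked_idx)]
    return TdrCurve(k_grid, hits[k_grid - 1] / k_grid)


def _interval_overlap_bp(start: int, end: int, intervals) -> int:
    """bp overlap of [start, end] (1-based inclusive) with truth intervals."""
    total = 0
    for s, e, _ in intervals:
        o = min(end, e) - max(start, s) + 1
        if o > 0:
            total += o
    return total


def region_tdr(
    ranked_regions: list[DmrRegion],
    truth: SimTruth,
    min_effect: float | None = None,
) -> TdrCurve:
    """Cumulative bp-level TDR walking down a region ranking.

    At each prefix of the ranking, TDR = (bp of called regions overlapping
    truth intervals) / (total called bp).  Regions must be disjoint.
    With ``min_effect`` set, truth is taken as the intervals where the
    true mean curves differ by more than that amount
    (:meth:`SimTruth.effective_intervals`) rather than the recorded
    target spans — the appropriate reference when callers legitimately
    track the tapered effect boundaries.
    """
    by_chrom: dict[str, list[DmrRegion]] = {}
    for r in ranked_regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for rs in by_chrom.values():
        ordered = sorted(rs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValidationError("ranked regions overlap")
    if not ranked_regions:
        return TdrCurve(np.empty(0), np.empty(0))
    intervals = (
        truth.dmr_intervals
        if min_effect is None
        else truth.effective_intervals(min_effect)
    )
    cum_bp = 0
    cum_hit = 0
    axis, tdr = [], []
    for r in ranked_regions:
        cum_bp += r.length_bp
        cum_hit += _interval_overlap_bp(r.start, r.end, intervals)
        axis.append(cum_bp)
        tdr.append(cum_hit / cum_bp)
    return TdrCurve(np.asarray(axis, dtype=float), np.asarray(tdr))


def fisher_baseline(pair: CountPair) -> np.ndarray:
    """Two-sided Fisher exact p-value per site on [[X1, N1-X1], [X2, N2-X2]].

    The straightforward no-replicate baseline: it uses the raw counts only
    and ignores biological variance.  Sites with zero coverage in either
    group get NaN.
    """
    x1 = pair.group1.n_meth
    n1 = pair.group1.n_total
    x2 = pair.group2.n_meth
    n2 = pair.group2.n_total
    out = np.full(len(pair), np.nan)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(len(pair)):
        if n1[i] == 0 or n2[i] == 0:
            continue
        key = (int(x1[i]), int(n1[i]), int(x2[i]), int(n2[i]))
        p = cache.get(key)
        if p is None:
            table = [[key[0], key[1] - key[0]], [key[2], key[3] - key[2]]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            cache[key] = p
        out[i] = p
    return out


def meandiff_baseline(means1: SmoothedMeans, means2: SmoothedMeans) -> np.ndarray:
    """Absolute difference of smoothed means, the simplest ranking score."""
    return np.abs(means1.mu_hat - means2.mu_hat)


def recovery_metrics(estimates, truth) -> tuple[float, float]:
    """(Pearson r, MSE) between estimate and truth over defined entries."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if est.shape != tru.shape:
        raise ValidationError("estimate and truth fields differ in length")
    ok = np.isfinite(est) & np.isfinite(tru)
    if ok.sum() < 2:
        return float("nan"), float("nan")
    r = float(stats.pearsonr(est[ok], tru[ok])[0])
    mse = float(np.mean((est[ok] - tru[ok]) ** 2))
    return r, mse


def regions_from_scores(
    chrom,
    pos,
    flagged,
    score,
    mu1,
    mu2,
    depth=None,
    **region_kwargs,
) -> list[DmrRegion]:
    """Region calling for baseline methods that bring their own site rule.

    Applies the shared region-assembly machinery (grouping, merging,
    filtering) to an arbitrary flagging rule and per-site score, then
    ranks by |area| as usual — used to put baselines on the same footing
    as the Wald-test caller in region-level comparisons.
    """
    if depth is None:
        depth = np.ones(len(pos))
    regions = assemble_regions(
        np.asarray(chrom),
        np.asarray(pos),
        np.asarray(flagged, dtype=bool),
        np.asarray(score, dtype=float),
        np.asarray(mu1, dtype=float),
        np.asarray(mu2, dtype=float),
        np.asarray(depth, dtype=float),
        **region_kwargs,
    )
    return rank_regions(regions)
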