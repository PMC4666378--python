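"""Moving-average estimation of the smooth mean-methylation curve.

Methylation levels are spatially correlated, so the mean of the beta
distribution at site i is modelled as a smooth function f(l_i) of genomic
position.  f is estimated by collapsing counts inside a window around each
site:

    mu_hat_i = sum_{l in S_i} X_l / sum_{l in S_i} N_l,
    S_i = { m : |l_m - l_i| < w }

with half-width w (500 bp by default).  Collapsing weights each window
site by its read depth, and the site's own counts always belong to its
window.  Windows never cross chromosome boundaries.  Sites whose window
holds no covered CpG (or fewer than ``min_sites`` of them) are flagged
unsmoothable and skipped downstream — this is what confines the method to
CpG-dense regions on sparse (RRBS-like) inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import SiteCounts

__all__ = ["SmoothedMeans", "smooth_moving_average", "window_bounds", "window_mean"]


def window_bounds(pos: np.ndarray, half_width: int):
    """Index bounds (lo, hi) of each site's window, strict |l_m - l_i| < w.

    ``pos`` must be sorted ascending (one chromosome).  Site i's window is
    ``pos[lo[i]:hi[i]]``; a site at distance exactly ``half_width`` is
    outside the window.
    """
    pos = np.asarray(pos)
    if len(pos) > 1 and np.any(np.diff(pos) <= 0):
        raise ValidationError("positions must be strictly increasing")
    lo = np.searchsorted(pos, pos - half_width, side="right")
    hi = np.searchsorted(pos, pos + half_width, side="left")
    return lo, hi


def _window_sums(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(values, dtype=float)))
    return csum[hi] - csum[lo]


def window_mean(pos, values, half_width):
    """Unweighted moving average of ``values`` over the +/- half_width window."""
    lo, hi = window_bounds(pos, half_width)
    return _window_sums(np.asarray(values, dtype=float), lo, hi) / (hi - lo)


@dataclass
class SmoothedMeans:
    """Per-site smoothed means with their window totals.

    ``mu_hat`` is win_x / win_n wherever win_n > 0 and NaN at unsmoothable
    sites; ``lo``/``hi`` are global index bounds of each site's window
    (windows never span chromosomes), kept so downstream variance and
    pseudo-replicate pooling reuse exactly the smoothing windows.
    """

    mu_hat: np.ndarray
    win_n: np.ndarray
    win_x: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    usable: np.ndarray
    half_width: int
    min_sites: int
    sites: SiteCounts = field(repr=False)

    def __len__(self) -> int:
        return len(self.mu_hat)


def smooth_moving_average(
    counts: SiteCounts, half_width: int = 500, min_sites: int = 1
) -> SmoothedMeans:
    """Estimate per-site means by a moving average of collapsed counts.

    Windows are resolved per chromosome with a sorted two-sided sweep
    (searchsorted + cumulative sums), O(n log n) overall.  A site is usable
    when its window contains at least ``min_sites`` covered CpGs and a
    positive total depth.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    n_sites = len(counts)
    mu = np.full(n_sites, np.nan)
    win_n = np.zeros(n_sites)
    win_x = np.zeros(n_sites)
    lo_all = np.zeros(n_sites, dtype=np.int64)
    hi_all = np.zeros(n_sites, dtype=np.int64)
    covered = counts.n_total > 0
    for _, sl in counts.chrom_slices():
        lo, hi = window_bounds(counts.pos[sl], half_width)
        lo_all[sl] = lo + sl.start
        hi_all[sl] = hi + sl.start
        win_n[sl] = _window_sums(counts.n_total[sl], lo, hi)
        win_x[sl] = _window_sums(counts.n_meth[sl], lo, hi)
    n_covered = np.concatenate(([0], np.cumsum(covered)))
    n_cov_win = n_covered[hi_all] - n_covered[lo_all]
    usable = (win_n > 0) & (n_cov_win >= min_sites)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(usable, win_x / np.where(win_n > 0, win_n, 1.0), np.nan)
    return SmoothedMeans(
        mu_hat=mu,
        win_n=win_n,
        win_x=win_x,
        lo=lo_all,
        hi=hi_all,
        usable=usable,
        half_width=half_width,
        min_sites=min_sites,
        sites=counts,
    )
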