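"""Per-CpG Wald test of equal mean methylation between two conditions.

The test statistic is (mu_hat_1 - mu_hat_2) / sqrt(V1 + V2), referred to
the standard normal.  Because the means are window-collapsed ratios, their
variance is the ratio-estimator variance of a sum of independent
beta-binomial counts sharing the local mean:

    Var(mu_hat) = sum_l n_l mu (1-mu) (1 + (n_l - 1) phi_l) / (sum_l n_l)^2

with the per-site shrunken dispersions phi_l plugged in.  This is where
both read depth (through n_l) and biological variance (through phi_l)
enter the test; smoothing over the window is what shrinks the variance
below the single-site binomial value.  When the smoothed mean sits on the
boundary {0, 1} a continuity-corrected mean (sum X + 0.5)/(sum N + 1) is
used inside the variance only, keeping the standard error positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dispersion import DispersionField
from .errors import ValidationError
from .io import CountPair
from .smoothing import SmoothedMeans

__all__ = ["smoothed_mean_variance", "wald_test"]


def smoothed_mean_variance(xs, ns, mu_hat, phis) -> float:
    """Ratio-estimator variance of one window-collapsed mean (scalar form).

    ``xs``/``ns``/``phis`` list the window sites' methylated counts, depths
    and dispersions; ``mu_hat`` is the collapsed mean.  Returns NaN when
    the window carries no reads (site untestable).
    """
    ns = np.asarray(ns, dtype=float)
    xs = np.asarray(xs, dtype=float)
    phis = np.asarray(phis, dtype=float)
    tot = ns.sum()
    if tot <= 0:
        return float("nan")
    mu = float(mu_hat)
    if mu <= 0.0 or mu >= 1.0:
        mu = (xs.sum() + 0.5) / (tot + 1.0)
    num = np.sum(ns * mu * (1.0 - mu) * (1.0 + (ns - 1.0) * phis))
    return float(num / tot**2)


def _field_variance(counts, means: SmoothedMeans, phi: np.ndarray) -> np.ndarray:
    """Vectorized window variance for every site of one sample."""
    n = counts.n_total.astype(float)
    mu = means.mu_hat.copy()
    # continuity correction inside the variance only
    boundary = (mu <= 0.0) | (mu >= 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_cc = (means.win_x + 0.5) / (means.win_n + 1.0)
    mu = np.where(boundary | ~np.isfinite(mu), mu_cc, mu)
    contrib = n * (1.0 + (n - 1.0) * phi)  # per-site n(1+(n-1)phi)
    csum = np.concatenate(([0.0], np.cumsum(contrib)))
    win_contrib = csum[means.hi] - csum[means.lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        var = mu * (1.0 - mu) * win_contrib / means.win_n**2
    var[means.win_n <= 0] = np.nan
    return var


def wald_test(
    pair: CountPair,
    means1: SmoothedMeans,
    means2: SmoothedMeans,
    phis1: DispersionField,
    phis2: DispersionField,
) -> pd.DataFrame:
    """Site-level Wald tests; one output row per input site.

    Sites untestable in either group (no reads in the window) are emitted
    with NaN statistic and p-value so rows stay aligned with the input;
    they are excluded from any downstream ranking.  Columns: chrom, pos,
    mu1, mu2, diff, se, stat, pval, plus the raw per-site depths n1, n2.
    """
    n_sites = len(pair)
    for name, obj in (("means1", means1), ("means2", means2),
                      ("phis1", phis1), ("phis2", phis2)):
        if len(obj) != n_sites:
            raise ValidationError(f"{name} does not share the joined site index")
    v1 = _field_variance(pair.group1, means1, phis1.phi_hat)
    v2 = _field_variance(pair.group2, means2, phis2.phi_hat)
    mu1 = means1.mu_hat
    mu2 = means2.mu_hat
    diff = mu1 - mu2
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(v1 + v2)
        stat = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.nan))
    testable = (means1.win_n > 0) & (means2.win_n > 0) & np.isfinite(stat)
    stat = np.where(testable, stat, np.nan)
    pval = np.where(testable, 2.0 * norm.sf(np.abs(stat)), np.nan)
    return pd.DataFrame(
        {
            "chrom": pair.group1.chrom,
            "pos": pair.group1.pos,
            "mu1": mu1,
            "mu2": mu2,
            "diff": diff,
            "se": se,
            "stat": stat,
            "pval": pval,
            "n1": pair.group1.n_total,
            "n2": pair.group2.n_total,
        }
    )
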