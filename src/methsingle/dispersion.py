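"""Empirical-Bayes dispersion estimation without biological replicates.

The beta-binomial dispersion phi quantifies biological variance between
hypothetical replicates.  With no replicates the per-site likelihood is
nearly flat, but two sources of information remain:

* the smoothed mean mu_hat is a good plug-in for the beta mean, and with
  the mean fixed even a single observation carries variance information;
* dispersions genome-wide follow a common log-normal(m0, r0^2) prior, so
  hyperparameters fitted from all sites shrink each noisy per-site
  estimate toward the genome-wide distribution.

Hyperparameters are fitted by maximizing the marginal likelihood of the
counts — integrating the beta-binomial likelihood over the log-normal
prior on a dispersion grid — which is robust where simple log-moment
fitting of single-observation estimates is not: a one-observation moment
estimate of log phi carries chi-square noise of variance ~pi^2/2 and a
large point mass at the clamp floor, so its sample moments say little
about (m0, r0^2).  The moment fit (:func:`fit_prior`) remains available
as initializer and fallback.

Genome-wide fields report the posterior mean E[phi | data] per site (the
MSE-optimal point estimate); :func:`shrink_phi` exposes the per-site MAP
of the penalized likelihood for single-site work.  Neighboring sites can
be pooled into the per-site likelihood as pseudo-replicates
(``mode="window"``), and true replicates enter the same machinery by
summing their log-likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .betabinom import PHI_MAX, PHI_MIN, bb_loglik
from .errors import ValidationError
from .io import SiteCounts
from .smoothing import SmoothedMeans

logger = logging.getLogger(__name__)

__all__ = [
    "PriorHyper",
    "DispersionField",
    "naive_dispersion",
    "fit_prior",
    "fit_prior_marginal",
    "shrink_phi",
    "estimate_dispersion_field",
    "estimate_dispersion_multi",
]

#: fallback hyperparameters when too few sites support a fit
PRIOR_FALLBACK = (-3.0, 1.0)
#: minimum number of defined naive estimates required to fit the prior
MIN_FIT_SITES = 1000
#: floor on the fitted prior log-variance
R0_SQ_FLOOR = 0.1


@dataclass(frozen=True)
class PriorHyper:
    """Log-normal prior on phi: log phi ~ Normal(m0, r0_sq)."""

    m0: float
    r0_sq: float

    def __post_init__(self) -> None:
        if self.r0_sq <= 0:
            raise ValueError("r0_sq must be positive")

    @property
    def mode(self) -> float:
        """Mode of the log-normal density, clamped to the phi domain."""
        return float(np.clip(np.exp(self.m0 - self.r0_sq), PHI_MIN, PHI_MAX))

    @property
    def mean(self) -> float:
        """Prior mean E[phi], clamped to the phi domain."""
        return float(np.clip(np.exp(self.m0 + self.r0_sq / 2.0), PHI_MIN, PHI_MAX))

    def logpdf(self, phi):
        """Log density of phi itself (includes the 1/phi Jacobian)."""
        phi = np.asarray(phi, dtype=float)
        z = np.log(phi) - self.m0
        return -np.log(phi) - 0.5 * np.log(2 * np.pi * self.r0_sq) - z * z / (
            2.0 * self.r0_sq
        )

    def logpdf_log(self, log_phi):
        """Log density of z = log phi (a plain normal)."""
        z = np.asarray(log_phi, dtype=float) - self.m0
        return -0.5 * np.log(2 * np.pi * self.r0_sq) - z * z / (2.0 * self.r0_sq)


@dataclass
class DispersionField:
    """Per-site shrunken dispersions plus the prior they were shrunk to."""

    phi_hat: np.ndarray
    prior: PriorHyper
    n_pseudo: np.ndarray

    def __len__(self) -> int:
        return len(self.phi_hat)


def naive_dispersion(x, n, mu_hat):
    """Method-of-moments dispersion from a single observation.

    With the mean treated as known, E[(X - n mu)^2] = n mu (1-mu)
    (1 + (n-1) phi) gives

        phi_tilde = ((x - n mu)^2 / (n mu (1-mu)) - 1) / (n - 1)

    clamped to [1e-4, 0.99].  Undefined (NaN) when n < 2 or mu_hat is not
    strictly inside (0, 1); domain violations never raise, so the
    estimator is safe to broadcast genome-wide.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu_hat, dtype=float)
    x, n, mu = np.broadcast_arrays(x, n, mu)
    ok = (n >= 2) & (mu > 0.0) & (mu < 1.0)
    out = np.full(x.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (x - n * mu) ** 2 / (n * mu * (1.0 - mu))
        phi = (resid - 1.0) / (n - 1.0)
    out[ok] = np.clip(phi[ok], PHI_MIN, PHI_MAX)
    if out.ndim == 0:
        return float(out)
    return out


def fit_prior(naive, kappa: float = 0.0) -> PriorHyper:
    """Moment fit of (m0, r0_sq) from defined naive dispersion estimates.

    m0 is the mean of log phi_tilde; r0_sq the variance minus a noise
    allowance ``kappa`` (default 0), floored at 0.1.  Fewer than 1,000
    defined estimates fall back to the documented defaults (-3, 1).
    Adequate when the inputs are low-noise dispersion estimates; for
    single-observation estimates prefer :func:`fit_prior_marginal`.
    """
    naive = np.asarray(naive, dtype=float)
    naive = naive[np.isfinite(naive)]
    if len(naive) < MIN_FIT_SITES:
        logger.warning(
            "only %d defined naive dispersion estimates (< %d); "
            "falling back to prior (m0=%s, r0_sq=%s)",
            len(naive),
            MIN_FIT_SITES,
            *PRIOR_FALLBACK,
        )
        return PriorHyper(*PRIOR_FALLBACK)
    logs = np.log(naive)
    m0 = float(np.mean(logs))
    r0_sq = float(max(np.var(logs) - kappa, R0_SQ_FLOOR))
    return PriorHyper(m0, r0_sq)


# ---------------------------------------------------------------------------
# grid machinery shared by the marginal fit, posterior means and the MAP
# ---------------------------------------------------------------------------

_N_GRID = 80
_PHI_GRID = np.geomspace(PHI_MIN, PHI_MAX, _N_GRID)
_LOG_GRID = np.log(_PHI_GRID)
# trapezoid quadrature weights over z = log phi
_QUAD = np.zeros(_N_GRID)
_QUAD[1:] += np.diff(_LOG_GRID) / 2.0
_QUAD[:-1] += np.diff(_LOG_GRID) / 2.0
_LOG_QUAD = np.log(_QUAD)


def _loglik_grid(x_m, n_m, mu_m, owner, n_sites) -> np.ndarray:
    """Per-site log-likelihood evaluated on the dispersion grid.

    Returns an (n_sites, n_grid) array: row i sums bb_loglik over the
    member observations owned by site i, at each grid dispersion.  The
    binomial-coefficient term is constant in phi, hence factored out of
    the grid loop.
    """
    from scipy.special import betaln, gammaln

    choose = gammaln(n_m + 1.0) - gammaln(x_m + 1.0) - gammaln(n_m - x_m + 1.0)
    choose_site = np.bincount(owner, weights=choose, minlength=n_sites)
    L = np.empty((n_sites, _N_GRID))
    for g, phi in enumerate(_PHI_GRID):
        a = mu_m * (1.0 - phi) / phi
        b = (1.0 - mu_m) * (1.0 - phi) / phi
        ll = betaln(x_m + a, n_m - x_m + b) - betaln(a, b)
        L[:, g] = np.bincount(owner, weights=ll, minlength=n_sites)
    return L + choose_site[:, None]


def fit_prior_marginal(L: np.ndarray, init: PriorHyper | None = None) -> PriorHyper:
    """Empirical-Bayes hyperparameters by marginal-likelihood maximization.

    ``L`` is the per-site grid log-likelihood from :func:`_loglik_grid`.
    Maximizes sum_i log integral BB(x_i | phi) dLogNormal(phi; m0, r0^2)
    over (m0, log r0^2) by Nelder-Mead, the integral evaluated by
    trapezoid quadrature in log-phi.
    """
    if init is None:
        init = PriorHyper(*PRIOR_FALLBACK)

    def nll(theta):
        m0, log_r0 = theta
        r0_sq = float(np.exp(log_r0))
        lp = -0.5 * np.log(2 * np.pi * r0_sq) - (_LOG_GRID - m0) ** 2 / (2.0 * r0_sq)
        return -float(np.sum(logsumexp(L + lp[None, :] + _LOG_QUAD[None, :], axis=1)))

    x0 = [
        float(np.clip(init.m0, np.log(PHI_MIN), np.log(PHI_MAX))),
        float(np.clip(np.log(init.r0_sq), np.log(R0_SQ_FLOOR), np.log(16.0))),
    ]
    res = minimize(nll, x0=x0, method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-3})
    m0, r0_sq = float(res.x[0]), float(np.exp(res.x[1]))
    r0_sq = max(r0_sq, R0_SQ_FLOOR)
    return PriorHyper(m0, r0_sq)


def _posterior_mean(L: np.ndarray, prior: PriorHyper) -> np.ndarray:
    """E[phi | data] per site on the grid under the log-normal prior."""
    lw = L + prior.logpdf_log(_LOG_GRID)[None, :] + _LOG_QUAD[None, :]
    log_norm = logsumexp(lw, axis=1)
    return np.exp(logsumexp(lw + _LOG_GRID[None, :], axis=1) - log_norm)


_N_GOLDEN = 34  # (0.99 - 1e-4) * 0.618^34 < 1e-7 < the 1e-6 target tolerance


def _map_phi(x_m, n_m, mu_m, owner, n_sites, prior: PriorHyper) -> np.ndarray:
    """Vectorized MAP of phi per site from flattened member observations.

    The objective per site is the summed member beta-binomial
    log-likelihood plus the log-normal log-density of phi, maximized on
    [PHI_MIN, PHI_MAX] by coarse log-grid bracketing followed by
    golden-section refinement (absolute tolerance below 1e-6).  Sites
    with no members return the prior mode.
    """

    def objective(phi_sites):
        ll = bb_loglik(x_m, n_m, mu_m, phi_sites[owner])
        return np.bincount(owner, weights=ll, minlength=n_sites) + prior.logpdf(
            phi_sites
        )

    vals = np.stack([objective(np.full(n_sites, g)) for g in _PHI_GRID])
    best = np.argmax(vals, axis=0)
    a = _PHI_GRID[np.maximum(best - 1, 0)]
    b = _PHI_GRID[np.minimum(best + 1, _N_GRID - 1)]

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1 = objective(x1)
    f2 = objective(x2)
    for _ in range(_N_GOLDEN):
        take_right = f1 < f2
        a = np.where(take_right, x1, a)
        b = np.where(take_right, b, x2)
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1 = objective(x1)
        f2 = objective(x2)
    phi = 0.5 * (a + b)
    phi[np.bincount(owner, minlength=n_sites) == 0] = prior.mode
    return np.clip(phi, PHI_MIN, PHI_MAX)


def shrink_phi(x, n, mu_hat, prior: PriorHyper, pseudo=None) -> float:
    """MAP dispersion for one site under the log-normal penalty.

    ``pseudo`` is an optional list of (x, n, mu_hat) neighbor observations
    pooled into the likelihood as pseudo-replicates.  With no usable data
    (n = 0 everywhere, or mean on the boundary) the prior mode
    exp(m0 - r0_sq) is returned.
    """
    obs = [(x, n, mu_hat)] + (list(pseudo) if pseudo else [])
    obs = [
        (xi, ni, mi)
        for xi, ni, mi in obs
        if ni > 0 and np.isfinite(mi) and 0.0 < mi < 1.0
    ]
    if not obs:
        return prior.mode
    x_m = np.array([o[0] for o in obs], dtype=float)
    n_m = np.array([o[1] for o in obs], dtype=float)
    mu_m = np.array([o[2] for o in obs], dtype=float)
    owner = np.zeros(len(obs), dtype=np.int64)
    return float(_map_phi(x_m, n_m, mu_m, owner, 1, prior)[0])


def _usable_mu(means: SmoothedMeans) -> np.ndarray:
    mu = means.mu_hat
    return means.usable & np.isfinite(mu) & (mu > 0.0) & (mu < 1.0)


def _check_index(counts: SiteCounts, means: SmoothedMeans) -> None:
    if len(counts) != len(means) or (
        means.sites is not counts and not np.array_equal(means.sites.pos, counts.pos)
    ):
        raise ValidationError("counts and smoothed means use different site indexes")


def _field_from_members(x_m, n_m, mu_m, owner, n_sites, prior) -> DispersionField:
    L = _loglik_grid(x_m, n_m, mu_m, owner, n_sites)
    if prior is None:
        prior = fit_prior_marginal(L)
    phi = _posterior_mean(L, prior)
    n_pseudo = np.bincount(owner, minlength=n_sites)
    # sites with no usable data revert to the prior mean
    phi = np.where(n_pseudo == 0, prior.mean, phi)
    return DispersionField(
        phi_hat=np.clip(phi, PHI_MIN, PHI_MAX), prior=prior, n_pseudo=n_pseudo
    )


def estimate_dispersion_field(
    counts: SiteCounts,
    means: SmoothedMeans,
    mode: str = "single",
    prior: PriorHyper | None = None,
) -> DispersionField:
    """Genome-wide EB dispersion field for one sample.

    ``mode="single"`` (default) uses each site's own observation with its
    smoothed mean; ``mode="window"`` additionally pools the covered sites
    of the smoothing window into the likelihood as pseudo-replicates.
    When ``prior`` is None the hyperparameters are fitted from this
    sample by marginal-likelihood maximization (per-group fit); the
    returned per-site values are posterior means under that prior.
    """
    if mode not in ("single", "window"):
        raise ValueError(f"unknown dispersion mode {mode!r}")
    _check_index(counts, means)
    n_sites = len(counts)
    mu = means.mu_hat
    ok_mu = _usable_mu(means)
    covered = counts.n_total > 0

    if mode == "single":
        member_site = np.flatnonzero(covered & ok_mu)
        owner = member_site
    else:
        lens = means.hi - means.lo
        owner = np.repeat(np.arange(n_sites), lens)
        member_site = _window_members(means.lo, means.hi)
        keep = covered[member_site] & ok_mu[owner]
        owner = owner[keep]
        member_site = member_site[keep]

    x_m = counts.n_meth[member_site].astype(float)
    n_m = counts.n_total[member_site].astype(float)
    mu_m = mu[member_site]
    if mode == "window":
        # a pooled neighbor whose own mean is undefined borrows the owner's
        bad = ~(np.isfinite(mu_m) & (mu_m > 0) & (mu_m < 1))
        mu_m = np.where(bad, mu[owner], mu_m)
    return _field_from_members(x_m, n_m, mu_m, owner, n_sites, prior)


def _window_members(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    if len(lo) == 0:
        return np.empty(0, dtype=np.int64)
    lens = hi - lo
    offsets = np.repeat(np.cumsum(lens) - lens, lens)
    return np.arange(lens.sum()) - offsets + np.repeat(lo, lens)


def estimate_dispersion_multi(
    reps: list[SiteCounts],
    means: SmoothedMeans,
    prior: PriorHyper | None = None,
) -> DispersionField:
    """EB dispersion field from replicated data (shared site index).

    The per-site likelihood sums ``bb_loglik`` over replicates at the
    common smoothed mean (estimate the means from the pooled counts); the
    prior, when not supplied, is again fitted by marginal likelihood.
    """
    n_sites = len(means)
    for r in reps:
        if len(r) != n_sites:
            raise ValidationError("replicates are not on a common site index")
    mu = means.mu_hat
    ok_mu = _usable_mu(means)
    owners, xs, ns = [], [], []
    for r in reps:
        idx = np.flatnonzero((r.n_total > 0) & ok_mu)
        owners.append(idx)
        xs.append(r.n_meth[idx].astype(float))
        ns.append(r.n_total[idx].astype(float))
    owner = np.concatenate(owners)
    x_m = np.concatenate(xs)
    n_m = np.concatenate(ns)
    mu_m = mu[owner]
    return _field_from_members(x_m, n_m, mu_m, owner, n_sites, prior)
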