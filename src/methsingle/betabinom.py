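"""Beta-binomial distribution in the mean/dispersion parameterization.

Methylated read counts X at a CpG site are modelled hierarchically:

    X | N, p ~ Binomial(N, p)
    p | mu, phi ~ Beta(mu, phi)

where the beta distribution is parameterized by its mean ``mu`` in (0, 1)
and dispersion ``phi`` in [0, 1), so that Var(p) = mu (1 - mu) phi.  The
classical shape parameters are

    alpha = mu (1 - phi) / phi,   beta = (1 - mu) (1 - phi) / phi.

``phi`` captures biological variability between hypothetical replicates;
``phi = 0`` degenerates to a plain binomial.  All functions broadcast over
numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

from .errors import DegenerateBinomialError

__all__ = [
    "BBParams",
    "bb_shapes",
    "bb_variance",
    "bb_loglik",
    "bb_sample",
]

#: dispersion bounds used by all estimation code; keeps alpha, beta finite
PHI_MIN = 1e-4
PHI_MAX = 0.99


@dataclass(frozen=True)
class BBParams:
    """Mean/dispersion parameter pair of one beta-binomial."""

    mu: float
    phi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"phi must lie in [0, 1), got {self.phi}")


def bb_shapes(mu, phi):
    """Convert (mean, dispersion) to beta shape parameters (alpha, beta).

    Raises
    ------
    DegenerateBinomialError
        if any ``phi`` is 0, where the beta collapses to a point mass and
        the count model is an exact binomial.
    """
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any((mu <= 0.0) | (mu >= 1.0)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0.0):
        raise DegenerateBinomialError("phi = 0: model degenerates to Binomial(n, mu)")
    if np.any(phi >= 1.0):
        raise ValueError("phi must be < 1")
    alpha = mu * (1.0 - phi) / phi
    beta = (1.0 - mu) * (1.0 - phi) / phi
    return alpha, beta


def bb_variance(n, mu, phi):
    """Marginal count variance Var(X) = n mu (1-mu) (1 + (n-1) phi)."""
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(n < 0):
        raise ValueError("n must be non-negative")
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi must lie in [0, 1]")
    return n * mu * (1.0 - mu) * (1.0 + (n - 1.0) * phi)


def bb_loglik(x, n, mu, phi):
    """Log pmf of the beta-binomial marginal, log P(X = x | n, mu, phi).

    Computed with log-gamma arithmetic so arbitrary depths do not overflow.
    ``phi = 0`` entries take the exact binomial branch.  ``n = 0`` returns 0
    (the empty-data likelihood).  Broadcasts over all arguments.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(x > n) or np.any(x < 0):
        raise ValueError("require 0 <= x <= n")
    x, n, mu, phi = np.broadcast_arrays(x, n, mu, phi)

    out = np.empty(x.shape, dtype=float)
    choose = gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)

    over = phi > 0.0
    if np.any(over):
        a = mu * (1.0 - phi) / phi
        b = (1.0 - mu) * (1.0 - phi) / phi
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = choose + betaln(x + a, n - x + b) - betaln(a, b)
        out[over] = ll[over]
    if np.any(~over):
        # exact binomial: x log mu + (n-x) log(1-mu)
        with np.errstate(invalid="ignore", divide="ignore"):
            ll0 = choose + x * np.log(mu) + (n - x) * np.log1p(-mu)
        # 0 * log 0 -> 0 convention
        ll0 = np.where((x == 0) & (mu <= 0), choose, ll0)
        out[~over] = ll0[~over]
    out = np.where(n == 0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def bb_sample(n, mu, phi, rng):
    """Draw counts X by p ~ Beta(alpha, beta), X ~ Binomial(n, p).

    ``rng`` must be a seeded :class:`numpy.random.Generator`; the phi = 0
    entries bypass the beta draw and sample a plain binomial.
    """
    n, mu, phi = np.broadcast_arrays(
        np.asarray(n), np.asarray(mu, dtype=float), np.asarray(phi, dtype=float)
    )
    p = np.array(mu, dtype=float, copy=True)
    over = phi > 0.0
    if np.any(over):
        a = mu[over] * (1.0 - phi[over]) / phi[over]
        b = (1.0 - mu[over]) * (1.0 - phi[over]) / phi[over]
        p[over] = rng.beta(a, b)
    return rng.binomial(n, p)
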