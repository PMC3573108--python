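"""General time-reversible nucleotide model with discrete-gamma rates (GTR+G).

The rate matrix Q is built from six exchangeabilities (AC, AG, AT, CG,
CT, GT) and four base frequencies, normalised so the expected
substitution rate at stationarity is one; branch lengths are then in
expected substitutions per site.  Among-site rate variation uses the
discrete gamma approximation with equal-probability categories and the
category mean as the representative rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

NUC = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUC)}
# pairs in the conventional order of the six exchangeabilities
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


@dataclass
class GTRGammaParams:
    """Parameters of the GTR+G model.

    exchangeabilities are in the order AC, AG, AT, CG, CT, GT and are
    only identified up to a scale factor; base_freqs must sum to one.
    """

    exchangeabilities: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 0.5
    n_categories: int = 4

    def __post_init__(self) -> None:
        if len(self.exchangeabilities) != 6 or any(x < 0 for x in self.exchangeabilities):
            raise ValueError("need 6 non-negative exchangeabilities")
        if len(self.base_freqs) != 4 or abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must be 4 values summing to 1")
        if any(f <= 0 for f in self.base_freqs):
            raise ValueError("base frequencies must be positive")
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @classmethod
    def jc(cls, n_categories: int = 1, alpha: float = 1.0) -> "GTRGammaParams":
        """Jukes-Cantor limit: equal frequencies and exchangeabilities."""
        return cls((1.0,) * 6, (0.25,) * 4, alpha, n_categories)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Category mean rates for k equal-probability gamma bins (mean 1)."""
    if k == 1:
        return np.ones(1)
    # bin boundaries at quantiles i/k of Gamma(alpha, scale=1/alpha)
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], edges * alpha, [np.inf]])
    # mean of Gamma(alpha) within each bin via the incomplete gamma of alpha+1
    upper = gammainc(alpha + 1.0, cuts[1:])
    lower = gammainc(alpha + 1.0, cuts[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


class GTRModel:
    """Precomputed spectral form of a GTR+G model for fast P(t)."""

    def __init__(self, params: GTRGammaParams):
        self.params = params
        pi = np.asarray(params.base_freqs, dtype=float)
        R = np.zeros((4, 4))
        for (i, j), x in zip(_PAIRS, params.exchangeabilities):
            R[i, j] = R[j, i] = x
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise mean rate to 1 substitution/site
        mu = -np.sum(pi * np.diag(Q))
        if mu <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= mu
        self.Q = Q
        self.pi = pi
        # symmetrise: B = diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sqrt_pi = np.sqrt(pi)
        B = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
        self._lam = eigval
        self._U = (1.0 / sqrt_pi)[:, None] * eigvec
        self._Uinv = eigvec.T * sqrt_pi[None, :]
        self.rates = discrete_gamma_rates(params.alpha, params.n_categories)
        self.n_cat = params.n_categories
        self._cache: dict[float, np.ndarray] = {}

    def pmats(self, t: float) -> np.ndarray:
        """Transition matrices P(t * r_c), shape (n_cat, 4, 4)."""
        P = self._cache.get(t)
        if P is not None:
            return P
        # exp(lam * t * r) for each category
        expd = np.exp(self._lam[None, :] * (t * self.rates)[:, None])
        P = np.matmul(self._U[None, :, :] * expd[:, None, :], self._Uinv)
        np.maximum(P, 0.0, out=P)
        if len(self._cache) > 4096:
            self._cache.clear()
        self._cache[t] = P
        return P
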