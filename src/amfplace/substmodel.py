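"""General time-reversible (GTR) nucleotide substitution models with
discrete-gamma rate variation.

The model is parameterized by stationary frequencies ``pi`` (A, C, G, T),
six symmetric exchangeabilities (AC, AG, AT, CG, CT, GT) and, optionally, a
gamma shape ``alpha`` discretized into ``n_categories`` equal-probability
rate classes (category means, Yang 1994).  The rate matrix is normalized to
one expected substitution per site per unit branch length, so all branch
lengths are in expected substitutions/site.

Transition matrices are computed through the eigendecomposition of the
pi-symmetrized rate matrix, which is exact for reversible models and cheap
to evaluate for many branch lengths at once.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, 1/alpha).

    The discretization of Yang (1994): category boundaries at the i/k
    quantiles, category rate = conditional mean, so the mixture has mean 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], edges * alpha, [np.inf]])
    # E[X 1{X<c}] for X ~ Gamma(a, scale=1/a) equals P(a+1, c*a) (regularized).
    cum = gammainc(alpha + 1.0, bounds)
    rates = k * np.diff(cum)
    return rates / rates.mean()


class SubstModel:
    """GTR(+Gamma) substitution model.

    Parameters
    ----------
    pi : stationary frequencies, length 4, strictly positive, sum 1.
    exchangeabilities : six symmetric rates in order AC, AG, AT, CG, CT, GT.
    gamma_shape : shape of the gamma rate distribution (ignored when
        ``rate_variation`` is False).
    n_categories : number of discrete rate categories.
    rate_variation : toggle gamma rate heterogeneity.
    """

    def __init__(
        self,
        pi=None,
        exchangeabilities=None,
        gamma_shape: float = 1.0,
        n_categories: int = 4,
        rate_variation: bool = True,
    ):
        self.pi = np.asarray(pi if pi is not None else np.full(4, 0.25), dtype=float)
        self.exchangeabilities = np.asarray(
            exchangeabilities if exchangeabilities is not None else np.ones(6),
            dtype=float,
        )
        if self.pi.shape != (4,) or np.any(self.pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self.gamma_shape = float(gamma_shape)
        self.n_categories = int(n_categories)
        self.rate_variation = bool(rate_variation)
        self._build()

    def _build(self) -> None:
        S = np.zeros((4, 4))
        for s, (i, j) in zip(self.exchangeabilities, _PAIRS):
            S[i, j] = S[j, i] = s
        Q = S * self.pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(self.pi, np.diag(Q))  # expected rate, normalize to 1
        Q /= mu
        self.Q = Q
        d = np.sqrt(self.pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)  # enforce exact symmetry
        w, V = np.linalg.eigh(B)
        self._eigval = w
        self._left = V / d[:, None]
        self._right = V.T * d[None, :]
        if self.rate_variation:
            self.rates = discrete_gamma_rates(self.gamma_shape, self.n_categories)
        else:
            self.rates = np.ones(1)

    @classmethod
    def jc69(cls, rate_variation: bool = False, **kw) -> "SubstModel":
        """Jukes-Cantor: uniform frequencies, equal exchangeabilities."""
        return cls(rate_variation=rate_variation, **kw)

    @classmethod
    def from_alignment(cls, sequences, **kw) -> "SubstModel":
        """Empirical base frequencies from sequences; exchangeabilities all 1."""
        counts = np.zeros(4)
        from ._seq import encode

        for s in sequences:
            codes = encode(s) if isinstance(s, str) else np.asarray(s)
            for b in range(4):
                counts[b] += int(np.sum(codes == b))
        if counts.sum() == 0:
            raise ValueError("no unambiguous bases in alignment")
        pi = np.clip(counts / counts.sum(), 1e-6, None)
        pi = pi / pi.sum()
        return cls(pi=pi, **kw)

    # -- transition probabilities ------------------------------------------

    def transition_matrix(self, t) -> np.ndarray:
        """P(t) for scalar or array ``t``; shape (..., 4, 4)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("branch lengths must be non-negative")
        E = np.exp(np.multiply.outer(t, self._eigval))  # (..., 4)
        P = np.einsum("ij,...j,jk->...ik", self._left, E, self._right)
        return np.clip(P, 0.0, None)

    def category_matrices(self, t: float) -> np.ndarray:
        """P(r_c * t) stacked over rate categories; shape (k, 4, 4)."""
        return self.transition_matrix(self.rates * float(t))

    def expected_p_distance(self, t: float) -> float:
        """Closed-form expected proportion of differing sites at divergence t."""
        P = self.category_matrices(t)
        same = np.einsum("i,kii->k", self.pi, P)
        return float(1.0 - same.mean())
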