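"""Amino-acid substitution models: Poisson and LG, with +G and +I rate mixing.

Both models are time-reversible.  Rate heterogeneity across sites uses the
discrete-gamma construction (equal-probability quantile bins, each bin
represented by its conditional mean rate) with five categories by default,
optionally combined with a proportion of invariant sites; the site-rate
mixture always has mean 1, so branch lengths stay in expected substitutions
per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammainc, gammaincinv

from ._lg import AA_ORDER, LG_EXCHANGE_LOWER, LG_FREQS

N_STATES = 20


def _lg_exchange_matrix() -> np.ndarray:
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = LG_EXCHANGE_LOWER[k]
            k += 1
    return s


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rate of each of k equal-probability bins of Gamma(alpha, mean 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    # quantile boundaries of Gamma(shape=alpha, rate=alpha)
    probs = np.arange(1, k) / k
    bounds = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X | bin] * P(bin) = I(alpha+1, alpha*b) increments for rate-alpha gamma
    inc = gammainc(alpha + 1, np.where(np.isinf(upper), np.inf, alpha * upper)) \
        - gammainc(alpha + 1, alpha * lower)
    return k * inc


@dataclass
class SubstitutionModel:
    """Poisson or LG replacement model with optional +G(k) and +I.

    ``alpha=None`` disables gamma rate variation; ``p_inv=0`` disables the
    invariant class.  ``freqs=None`` uses the model's own equilibrium
    frequencies (uniform for Poisson, the published LG frequencies);
    pass empirical frequencies for +F.
    """

    matrix: str = "LG"  # 'Poisson' | 'LG'
    gamma_categories: int = 5
    alpha: float | None = None
    p_inv: float = 0.0
    freqs: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.matrix not in ("Poisson", "LG"):
            raise ValueError(f"unknown model matrix {self.matrix!r}")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")
        if self.freqs is not None:
            self.freqs = np.asarray(self.freqs, float)
            if self.freqs.shape != (N_STATES,) or not np.isclose(self.freqs.sum(), 1.0):
                raise ValueError("frequencies must be a 20-vector summing to 1")

    def with_params(self, **kw) -> "SubstitutionModel":
        m = replace(self, **kw)
        m._cache = {}
        return m

    @property
    def frequencies(self) -> np.ndarray:
        if self.freqs is not None:
            return self.freqs
        if self.matrix == "Poisson":
            return np.full(N_STATES, 1.0 / N_STATES)
        return np.asarray(LG_FREQS)

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to 0, scaled to mean rate 1 at equilibrium."""
        if "Q" in self._cache:
            return self._cache["Q"]
        pi = self.frequencies
        if self.matrix == "Poisson":
            s = np.ones((N_STATES, N_STATES))
        else:
            s = _lg_exchange_matrix()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        q /= scale
        self._cache["Q"] = q
        return q

    def _eigen(self):
        """Symmetrized eigendecomposition of Q (valid for reversible models)."""
        if "eig" not in self._cache:
            pi = self.frequencies
            sqrt_pi = np.sqrt(pi)
            # C = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
            b = self.rate_matrix() * sqrt_pi[:, None] / sqrt_pi[None, :]
            lam, u = np.linalg.eigh((b + b.T) / 2.0)
            left = u.T * sqrt_pi[None, :]        # U^T D^{1/2}
            right = u / sqrt_pi[:, None]          # D^{-1/2} U
            self._cache["eig"] = (lam, right, left)
        return self._cache["eig"]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0 or not np.isfinite(t):
            raise ValueError(f"invalid branch length {t}")
        lam, right, left = self._eigen()
        p = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def rate_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the positive-rate classes (invariant excluded).

        With +I the gamma rates are rescaled by 1/(1 - p_inv) so that the
        full site-rate mixture (including the zero-rate invariant class with
        weight p_inv) has mean exactly 1.
        """
        if self.alpha is None:
            rates = np.ones(1)
        else:
            rates = discrete_gamma_rates(self.alpha, self.gamma_categories)
        k = rates.size
        scale = 1.0 / (1.0 - self.p_inv)
        return rates * scale, np.full(k, (1.0 - self.p_inv) / k)

    def describe(self) -> str:
        parts = [self.matrix]
        if self.alpha is not None:
            parts.append(f"+G{self.gamma_categories}(a={self.alpha:.4g})")
        if self.p_inv > 0:
            parts.append(f"+I({self.p_inv:.4g})")
        if self.freqs is not None:
            parts.append("+F")
        return "".join(parts)


def empirical_frequencies(msa, pseudocount: float = 0.1) -> np.ndarray:
    """Amino-acid frequencies observed in an alignment (+F option)."""
    counts = np.full(N_STATES, pseudocount)
    index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for row in msa.rows:
        for ch in row.upper():
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()
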