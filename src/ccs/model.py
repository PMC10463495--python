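"""Amino-acid substitution model: JTT + discrete-gamma rate heterogeneity.

The model is the standard general time-reversible amino-acid CTMC built
from an empirical exchangeability matrix S and stationary frequencies
pi: Q_ij = s_ij * pi_j (i != j), with the generator rescaled so that the
expected substitution rate at equilibrium, -sum_i pi_i Q_ii, equals 1.
Branch lengths therefore stay in expected substitutions per site.

Among-site rate variation uses Yang's discrete gamma: K equal-probability
categories of a Gamma(alpha, alpha) distribution (mean 1), each category
represented by the conditional mean of its quantile bin, so the category
rates average to exactly 1 without renormalisation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc, gammaincinv

from .alphabet import N_STATES

#: sha256 of the embedded JTT constants file (Jones, Taylor & Thornton 1992,
#: exchangeabilities and frequencies as distributed with standard phylogenetics
#: software in PAML residue order)
JTT_SHA256 = "726a2f3c8e3e24885c4a56a1a1de2dfcc6ad20a56609ee63ba7b076706e154b1"


class ModelError(ValueError):
    pass


def _load_jtt() -> tuple[np.ndarray, np.ndarray]:
    data = resources.files("ccs.data").joinpath("jtt.dat").read_bytes()
    if hashlib.sha256(data).hexdigest() != JTT_SHA256:
        raise ModelError("embedded JTT data file failed its checksum")
    tokens = [
        float(tok)
        for line in data.decode().splitlines()
        if line.strip() and not line.startswith("#")
        for tok in line.split()
    ]
    if len(tokens) != 190 + N_STATES:
        raise ModelError("malformed JTT data file")
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = tokens[k]
            k += 1
    freqs = np.array(tokens[190:])
    return s, freqs / freqs.sum()


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-of-bin discrete-gamma category rates (ascending, mean exactly 1).

    The rate of category k is the conditional mean of Gamma(alpha, alpha)
    on its equal-probability quantile bin:
    r_k = K * [F_{alpha+1}(b_k) - F_{alpha+1}(b_{k-1})] where F is the
    regularised incomplete gamma of shape alpha+1 evaluated at alpha*x.
    """
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    K = int(n_categories)
    if K < 1:
        raise ModelError(f"need at least one rate category, got {K}")
    if K == 1:
        return np.ones(1)
    probs = np.arange(1, K) / K
    # bin boundaries of Gamma(alpha, rate=alpha): ppf at k/K
    bounds = gammaincinv(alpha, probs) / alpha
    upper = np.concatenate([gammainc(alpha + 1.0, alpha * bounds), [1.0]])
    lower = np.concatenate([[0.0], upper[:-1]])
    rates = K * (upper - lower)
    rates /= rates.mean()  # analytic mean is 1; remove residual rounding
    return rates


@dataclass
class SubstitutionModel:
    """Exchangeabilities, stationary frequencies and gamma rate model."""

    exchangeabilities: np.ndarray
    freqs: np.ndarray
    alpha: float = 1.0
    n_categories: int = 4
    name: str = "custom"

    def __post_init__(self) -> None:
        s = np.asarray(self.exchangeabilities, dtype=float)
        p = np.asarray(self.freqs, dtype=float)
        if s.shape != (N_STATES, N_STATES) and s.shape[0] != s.shape[1]:
            raise ModelError("exchangeability matrix must be square")
        if not np.allclose(s, s.T):
            raise ModelError("exchangeability matrix must be symmetric")
        if np.any(s < 0):
            raise ModelError("exchangeabilities must be non-negative")
        if p.shape[0] != s.shape[0]:
            raise ModelError("frequency vector length does not match matrix")
        if np.any(p <= 0):
            raise ModelError("degenerate stationary distribution (zero frequency)")
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ModelError("frequencies must sum to 1")
        if self.alpha <= 0:
            raise ModelError("gamma shape alpha must be positive")
        self.exchangeabilities = s
        self.freqs = p / p.sum()

    @property
    def n_states(self) -> int:
        return self.freqs.shape[0]

    @property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.n_categories)

    def with_(self, **kw) -> "SubstitutionModel":
        args = dict(
            exchangeabilities=self.exchangeabilities, freqs=self.freqs,
            alpha=self.alpha, n_categories=self.n_categories, name=self.name,
        )
        args.update(kw)
        return SubstitutionModel(**args)

    @classmethod
    def jtt(cls, freqs: np.ndarray | str = "model", alpha: float = 1.0,
            n_categories: int = 4) -> "SubstitutionModel":
        """JTT model; ``freqs`` may be "model" or an empirical (+F) vector."""
        s, model_freqs = _load_jtt()
        if isinstance(freqs, str):
            if freqs != "model":
                raise ModelError(f"unknown frequency option {freqs!r}")
            p = model_freqs
        else:
            p = np.asarray(freqs, dtype=float)
        return cls(s, p, alpha=alpha, n_categories=n_categories, name="JTT")


@dataclass
class RateMatrix:
    """Scaled reversible generator Q with its symmetric eigendecomposition.

    Satisfies detailed balance pi_i Q_ij = pi_j Q_ji; rows sum to zero;
    -sum_i pi_i Q_ii = 1 so t is substitutions per site.
    """

    Q: np.ndarray
    freqs: np.ndarray
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{-1/2} U
    _right: np.ndarray = field(repr=False, default=None)  # U^T D^{1/2}

    def __post_init__(self) -> None:
        if self._eigvals is None:
            d = np.sqrt(self.freqs)
            B = (self.Q / d[None, :]) * d[:, None]
            B = 0.5 * (B + B.T)  # enforce exact symmetry before eigh
            w, U = np.linalg.eigh(B)
            self._eigvals = w
            self._left = U / d[:, None]
            self._right = U.T * d[None, :]

    def expm(self, scaled_time: float) -> np.ndarray:
        """P = exp(Q * scaled_time) via the symmetric eigendecomposition."""
        if scaled_time < 0:
            raise ModelError(f"negative evolutionary time {scaled_time}")
        if scaled_time == 0:
            return np.eye(len(self.freqs))
        P = (self._left * np.exp(self._eigvals * scaled_time)) @ self._right
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ModelError("transition matrix rows failed to normalise")
        np.clip(P, 0.0, 1.0, out=P)
        return P


def build_rate_matrix(model: SubstitutionModel) -> RateMatrix:
    """Q_ij = s_ij * pi_j, diagonal = -row sum, rescaled to mean rate 1."""
    s, p = model.exchangeabilities, model.freqs
    Q = s * p[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(p * np.diag(Q)).sum()
    if mu <= 0:
        raise ModelError("rate matrix has zero total rate")
    return RateMatrix(Q / mu, p)


def transition_matrix(ratematrix: RateMatrix, t: float, rate: float = 1.0
                      ) -> np.ndarray:
    """P(r*t) for one branch and one rate category."""
    if t < 0:
        raise ModelError(f"negative branch length {t}")
    if rate < 0:
        raise ModelError(f"negative category rate {rate}")
    return ratematrix.expm(t * rate)
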