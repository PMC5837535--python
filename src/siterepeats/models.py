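"""GTR substitution models with discrete-Γ rate heterogeneity.

The generator Q is the standard time-reversible DNA rate matrix
``q_ij = s_ij * pi_j`` (i != j) normalised so that one unit of branch
length corresponds to one expected substitution at stationarity.
Transition probabilities ``P(t, r) = exp(Q t r)`` are computed by
eigendecomposition of the symmetrised generator, which is numerically
stable and exact for reversible Q.  Among-site rate variation uses Yang's
discrete gamma with equal-probability categories represented by their
category means (mean discretisation), so the category rates always average
to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

STATES = "ACGT"
#: exchangeability parameter order
RATE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ModelError(ValueError):
    pass


def discretize_gamma(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of ``k`` equal-probability categories of Gamma(alpha, alpha).

    The distribution has mean 1, so the returned rates average to 1 exactly
    (up to floating point).  ``k = 1`` returns ``[1.0]``.
    """
    if not np.isfinite(alpha) or alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if k < 1:
        raise ModelError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    cuts = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    # E[X; X <= c] for X ~ Gamma(alpha, rate alpha) is gammainc(alpha+1, alpha*c)
    cum = np.concatenate([[0.0], gammainc(alpha + 1.0, alpha * cuts), [1.0]])
    return np.diff(cum) * k


@dataclass
class SubstModel:
    """A GTR(+Γ) model: base frequencies, exchangeabilities, rate categories."""

    frequencies: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    alpha: float | None = None
    n_categories: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if self.frequencies.shape != (4,) or (self.frequencies <= 0).any():
            raise ModelError("need 4 strictly positive base frequencies")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ModelError("base frequencies must sum to 1")
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ModelError("need 6 nonnegative exchangeabilities (AC AG AT CG CT GT)")
        if self.alpha is None:
            if self.n_categories != 1:
                raise ModelError("rate heterogeneity requires a gamma shape alpha")
        elif self.alpha <= 0:
            raise ModelError("gamma shape alpha must be positive")
        self._eigen = None

    # -- constructors ------------------------------------------------------
    @classmethod
    def jc(cls, alpha: float | None = None, n_categories: int = 1) -> "SubstModel":
        """Jukes-Cantor: equal frequencies, equal exchangeabilities."""
        return cls(alpha=alpha, n_categories=n_categories)

    @classmethod
    def gtr(cls, frequencies, exchangeabilities,
            alpha: float | None = None, n_categories: int = 1) -> "SubstModel":
        return cls(np.asarray(frequencies), np.asarray(exchangeabilities),
                   alpha, n_categories)

    @classmethod
    def from_string(cls, spec: str, frequencies=None, exchangeabilities=None,
                    alpha: float | None = None) -> "SubstModel":
        """Build a model from a string like ``"JC"``, ``"JC+G4"``, ``"GTR+G4"``.

        ``+G`` takes an optional category count (default 4) and uses
        ``alpha`` (default 1.0).  GTR parameters default to equal values
        unless given explicitly.
        """
        parts = spec.strip().upper().split("+")
        name = parts[0]
        ncat, shape = 1, None
        for p in parts[1:]:
            if p.startswith("G"):
                ncat = int(p[1:]) if len(p) > 1 else 4
                shape = 1.0 if alpha is None else alpha
            else:
                raise ModelError(f"unknown model component {p!r}")
        if name not in ("JC", "GTR"):
            raise ModelError(f"unknown model {name!r}")
        freqs = np.full(4, 0.25) if frequencies is None else np.asarray(frequencies)
        rates = np.ones(6) if exchangeabilities is None else np.asarray(exchangeabilities)
        if name == "JC":
            freqs, rates = np.full(4, 0.25), np.ones(6)
        return cls(freqs, rates, shape, ncat)

    # -- derived quantities ------------------------------------------------
    @property
    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.ones(self.n_categories)
        return discretize_gamma(self.alpha, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        """The normalised reversible generator Q (rows sum to 0)."""
        pi = self.frequencies
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(self.exchangeabilities, _PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ModelError("degenerate rate matrix (all exchangeabilities zero)")
        return Q / mu

    def _eigensystem(self):
        if self._eigen is None:
            pi = self.frequencies
            sqrt_pi = np.sqrt(pi)
            Q = self.rate_matrix()
            B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
            eigvals, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U.T * sqrt_pi[None, :]      # U^T diag(sqrt pi)
            right = (1.0 / sqrt_pi)[:, None] * U
            self._eigen = (eigvals, right, left)
        return self._eigen

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t, rate) = exp(Q * t * rate); rows sum to 1."""
        if not np.isfinite(t) or t < 0:
            raise ModelError(f"branch length must be finite and nonnegative, got {t}")
        if rate < 0:
            raise ModelError("rate multiplier must be nonnegative")
        if t * rate == 0.0:
            return np.eye(4)
        eigvals, right, left = self._eigensystem()
        P = (right * np.exp(eigvals * t * rate)[None, :]) @ left
        np.maximum(P, 0.0, out=P)
        return P

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t, r) for every rate category, shape (k, 4, 4)."""
        return np.stack([self.transition_matrix(t, r) for r in self.category_rates])


def transition_matrix(model: SubstModel, t: float, rate: float = 1.0) -> np.ndarray:
    """Functional alias for :meth:`SubstModel.transition_matrix`."""
    return model.transition_matrix(t, rate)
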