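"""Amino-acid substitution models for simulation and likelihood.

A :class:`SubstitutionModel` is a time-reversible 20-state CTMC specified by
symmetric exchangeabilities ``S`` and equilibrium frequencies ``pi``; the
rate matrix is ``Q[i, j] = S[i, j] * pi[j]`` (off-diagonal), scaled so the
expected number of substitutions per site per unit branch length is 1.
Across-site rate variation uses the discrete-gamma approximation with
equal-probability categories, each represented by its category mean, so
category rates always average 1.

Two canonical models are provided: ``lg_model`` (the LG empirical matrix,
with either its published frequencies or observed "+F" frequencies) and
``poisson_model`` (all exchangeabilities equal, uniform frequencies), the
latter because several closed-form results exist for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import gammainc, gammaincinv

from ._lg_data import LG_FREQS, LG_LOWER_TRIANGLE

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _lower_triangle_to_matrix(values) -> np.ndarray:
    mat = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            mat[i, j] = mat[j, i] = values[k]
            k += 1
    if k != len(values):
        raise ValueError("expected 190 lower-triangle entries")
    return mat


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability discrete-gamma bins.

    The underlying gamma has mean 1 (shape = rate = ``shape``); each
    category's rate is the conditional mean within its probability bin, so
    the returned rates have mean exactly 1 (up to renormalisation).
    """
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    if n_categories == 1:
        return np.ones(1)
    k = n_categories
    # bin edges as quantiles of Gamma(shape, rate=shape)
    edges = gammaincinv(shape, np.arange(1, k) / k) / shape
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | a < X <= b] * P(bin) = I(shape+1, b*shape) - I(shape+1, a*shape)
    upper = gammainc(shape + 1.0, np.where(np.isinf(edges[1:]), 1e300, edges[1:] * shape))
    lower = gammainc(shape + 1.0, edges[:-1] * shape)
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid substitution model with discrete-gamma rates."""

    exchangeabilities: np.ndarray
    equilibrium_freqs: np.ndarray
    gamma_shape: float = 1.0
    n_rate_categories: int = 4
    name: str = "custom"

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.equilibrium_freqs, dtype=float)
        if ex.shape != (20, 20) or not np.allclose(ex, ex.T):
            raise ValueError("exchangeabilities must be a symmetric 20x20 matrix")
        if pi.shape != (20,) or np.any(pi <= 0):
            raise ValueError("equilibrium_freqs must be 20 positive values")
        pi = pi / pi.sum()
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "equilibrium_freqs", pi)
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("n_rate_categories must be >= 1")

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Scaled generator Q with expected rate 1 at equilibrium."""
        pi = self.equilibrium_freqs
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(pi * np.diag(q)).sum()
        return q / scale

    @cached_property
    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)

    @cached_property
    def _eigensystem(self):
        # symmetrise: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        pi = self.equilibrium_freqs
        sq = np.sqrt(pi)
        b = self.rate_matrix * (sq[:, None] / sq[None, :])
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        # P(t) = left @ diag(exp(eigval t)) @ right
        left = eigvec / sq[:, None]
        right = eigvec.T * sq[None, :]
        return eigval, left, right

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t): row-stochastic transition probabilities after time ``t``."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        eigval, left, right = self._eigensystem
        p = (left * np.exp(eigval * t)[None, :]) @ right
        return np.clip(p, 0.0, None)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Per-rate-category transition matrices, shape (n_cat, 20, 20)."""
        return np.stack([self.transition_matrix(t * r) for r in self.category_rates])

    def with_frequencies(self, freqs: np.ndarray) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities, np.asarray(freqs, float),
            self.gamma_shape, self.n_rate_categories, name=self.name + "+F",
        )

    def with_gamma(self, shape: float, n_categories: int | None = None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities, self.equilibrium_freqs, shape,
            n_categories if n_categories is not None else self.n_rate_categories,
            name=self.name,
        )


def lg_model(gamma_shape: float = 1.0, n_rate_categories: int = 4,
             frequencies: np.ndarray | None = None) -> SubstitutionModel:
    """LG model; pass ``frequencies`` (e.g. observed counts) for the +F variant."""
    ex = _lower_triangle_to_matrix(LG_LOWER_TRIANGLE)
    pi = np.asarray(LG_FREQS if frequencies is None else frequencies, float)
    return SubstitutionModel(ex, pi, gamma_shape, n_rate_categories, name="LG")


def poisson_model(gamma_shape: float = 1.0, n_rate_categories: int = 1) -> SubstitutionModel:
    """Equal-rates, equal-frequency (Poisson/JC-like) 20-state model."""
    ex = np.ones((20, 20))
    np.fill_diagonal(ex, 0.0)
    return SubstitutionModel(ex, np.full(20, 0.05), gamma_shape, n_rate_categories,
                             name="Poisson")


def observed_frequencies(sequences, pseudocount: float = 1.0) -> np.ndarray:
    """Amino-acid frequencies observed in ``sequences`` (gaps/X ignored)."""
    counts = np.full(20, pseudocount, dtype=float)
    for seq in sequences:
        for ch in seq:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1.0
    return counts / counts.sum()
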