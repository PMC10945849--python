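"""Disordered interaction matrices for Lotka-Volterra communities.

The community model couples ``S`` species through a fixed random matrix of
pairwise interaction coefficients ``alpha[i, j] = mu + sigma * z[i, j]``,
where the standardized residuals ``z[i, j]`` have zero mean and unit
variance.  An optional correlation ``gamma`` between diagonally opposed
elements biases the ensemble toward symmetric competition (``gamma = 1``)
or predator-prey pairs (``gamma = -1``).  Self-interaction is handled by
the logistic term of the dynamics, so the diagonal of ``alpha`` is not part
of the model; it is stored as zero and must never be read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "EcologicalParams",
    "InteractionMatrix",
    "sample_interactions",
    "net_interaction_bias",
]


@dataclass(frozen=True)
class EcologicalParams:
    """Control parameters of the disordered Lotka-Volterra model.

    Parameters
    ----------
    S : int
        Number of species in the pool (>= 2).
    mu : float
        Mean of the interaction coefficients.  In the strong-interaction
        regime ``mu`` is of order one and does not scale with ``S``.
    sigma : float
        Standard deviation of the interaction coefficients (>= 0).
    gamma : float, default 0
        Correlation between ``alpha[i, j]`` and ``alpha[j, i]``; must lie
        in ``[-1, 1]``.
    lam : float, default 1e-8
        Immigration rate: a constant, equal abundance influx per species
        that sets the rarity floor and prevents extinction.  Must satisfy
        ``0 < lam < 1``.

    Notes
    -----
    The intrinsic growth rate and carrying capacity are fixed to 1 for all
    species; time is measured in units of the inverse growth rate and
    abundance in units of the carrying capacity.
    """

    S: int
    mu: float
    sigma: float
    gamma: float = 0.0
    lam: float = 1e-8

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError(f"S must be >= 2, got {self.S}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [-1, 1], got {self.gamma}")
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lam must lie in (0, 1), got {self.lam}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EcologicalParams":
        return cls(**d)


@dataclass
class InteractionMatrix:
    """One realization of the disordered couplings.

    Attributes
    ----------
    alpha : ndarray of shape (S, S)
        Coupling table with the (unused) diagonal stored as zero.  When
        `poison_diagonal` has been called the diagonal holds NaN instead,
        so that any consumer that accidentally reads it fails loudly.
    params : EcologicalParams
    seed : int
        Seed of the RNG stream that produced this realization.
    """

    alpha: np.ndarray
    params: EcologicalParams
    seed: int
    _poisoned: bool = field(default=False, repr=False)

    @property
    def S(self) -> int:
        return self.params.S

    def coupling(self) -> np.ndarray:
        """Off-diagonal coupling matrix with the diagonal exactly zero.

        This is the only sanctioned way to feed ``alpha`` into a matrix
        product: with a zero diagonal, ``coupling() @ x`` equals the sum
        over ``j != i`` regardless of poisoning.
        """
        if not self._poisoned:
            return self.alpha
        a = self.alpha.copy()
        np.fill_diagonal(a, 0.0)
        return a

    def poison_diagonal(self) -> "InteractionMatrix":
        """Set the diagonal to NaN (in place) to trap accidental reads."""
        np.fill_diagonal(self.alpha, np.nan)
        self._poisoned = True
        return self

    @property
    def z(self) -> np.ndarray:
        """Standardized residuals ``(alpha - mu) / sigma`` (diagonal zero)."""
        if self.params.sigma == 0:
            raise ValueError("standardized residuals are undefined for sigma = 0")
        z = (self.coupling() - self.params.mu) / self.params.sigma
        np.fill_diagonal(z, 0.0)
        return z

    @property
    def z_bias(self) -> np.ndarray:
        """Per-species net interaction bias; see `net_interaction_bias`."""
        return net_interaction_bias(self)

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> Path:
        """Write the matrix as ``<path>.npz`` plus a JSON metadata sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), alpha=self.coupling())
        meta = {"params": self.params.to_dict(), "seed": int(self.seed)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "InteractionMatrix":
        path = Path(path)
        alpha = np.load(path.with_suffix(".npz"))["alpha"]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(alpha=alpha, params=EcologicalParams.from_dict(meta["params"]),
                   seed=meta["seed"])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.coupling(), delimiter=",")


def sample_interactions(params: EcologicalParams, seed: int) -> InteractionMatrix:
    """Draw one interaction-matrix realization.

    For every unordered pair ``i < j`` the residuals ``(z[i, j], z[j, i])``
    are a standard bivariate Gaussian with correlation ``gamma``, built by
    a Cholesky construction from two independent N(0, 1) draws:
    ``z[j, i] = gamma * z[i, j] + sqrt(1 - gamma**2) * e2``.  This makes
    ``gamma = 1`` produce a bit-exact symmetric matrix and ``gamma = -1``
    a bit-exact antisymmetric residual matrix.

    Parameters
    ----------
    params : EcologicalParams
    seed : int
        Any integer; identical (params, seed) yield bit-identical matrices.
    """
    S = params.S
    rng = np.random.default_rng(seed)
    e1 = rng.standard_normal((S, S))
    e2 = rng.standard_normal((S, S))
    z = np.zeros((S, S))
    iu = np.triu_indices(S, k=1)
    z[iu] = e1[iu]
    zt = z.T
    zt[iu] = params.gamma * e1[iu] + np.sqrt(1.0 - params.gamma**2) * e2[iu]
    alpha = params.mu + params.sigma * z
    np.fill_diagonal(alpha, 0.0)
    return InteractionMatrix(alpha=alpha, params=params, seed=int(seed))


def net_interaction_bias(M: InteractionMatrix) -> np.ndarray:
    """Net interaction bias ``z_i = S**-0.5 * sum_{j != i} z[i, j]``.

    The ``1/sqrt(S)`` normalization makes ``z_i`` unit-variance in the
    large-``S`` limit, so the net competition felt by species ``i`` near
    carrying capacity decomposes as ``S*mu + sqrt(S)*sigma*z_i``.  Species
    with lower ``z_i`` feel less net competition.

    Raises
    ------
    ValueError
        If ``sigma = 0`` (residuals undefined).
    """
    z = M.z  # raises for sigma == 0
    return z.sum(axis=1) / np.sqrt(M.S)
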