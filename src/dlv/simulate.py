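"""Integration of the disordered Lotka-Volterra equations.

The dynamics of species abundances x_i(t) is

    dx_i/dt = x_i * (1 - x_i - sum_{j != i} alpha_ij x_j) + lam,

with unit growth rate and carrying capacity and a constant immigration
rate ``lam`` per species.  Integration uses a fixed-step Euler scheme
applied to the logarithm of abundances (dt = 0.01 by default), which
guarantees positivity of all abundances at all times regardless of the
immigration rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .interactions import EcologicalParams, InteractionMatrix, sample_interactions

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "initial_condition",
    "growth_rates",
    "integrate",
    "simulate_community",
    "reference_run",
    "REFERENCE_PARAMS",
    "split_seed",
]

#: Reference configuration: chaotic turnover of ~9 dominant species.
REFERENCE_PARAMS = EcologicalParams(S=500, mu=0.5, sigma=0.3, gamma=0.0, lam=1e-8)


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass(frozen=True)
class IntegrationSettings:
    """Fixed-step log-Euler integration settings.

    Attributes
    ----------
    dt : float
        Euler step in time units (default 0.01).
    t_burn : float
        Discarded transient duration.  The default (2,000) covers well
        over 10 turnover times of the reference dynamics (tau_dom ~ 30).
    t_run : float
        Recorded duration after burn-in.
    store_stride : float
        Recording interval in time units; must be an integer multiple of
        ``dt``.  Stride 1.0 resolves individual booms (tens of time
        units) while keeping trajectory containers small.
    divergence_threshold : float
        Abundance ceiling; crossing it stops integration with a
        divergence flag (abundances are O(1) at carrying capacity, so
        1e3 cleanly separates the divergent phase).
    seed_x0 : int
        Seed of the initial-condition RNG stream, independent from the
        interaction-matrix stream so ensembles can vary either alone.
    """

    dt: float = 0.01
    t_burn: float = 2000.0
    t_run: float = 10000.0
    store_stride: float = 1.0
    divergence_threshold: float = 1e3
    seed_x0: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_run <= 0:
            raise ValueError("t_run must be positive")
        if self.t_burn < 0:
            raise ValueError("t_burn must be non-negative")
        ratio = self.store_stride / self.dt
        if self.store_stride < self.dt or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("store_stride must be an integer multiple of dt")

    @property
    def stride_steps(self) -> int:
        return int(round(self.store_stride / self.dt))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IntegrationSettings":
        return cls(**d)


@dataclass
class Trajectory:
    """Recorded abundance time series with full provenance.

    ``x`` has shape (S, n_times) and is strictly positive; ``times`` are
    uniformly spaced by ``settings.store_stride`` starting after burn-in.
    """

    times: np.ndarray
    x: np.ndarray
    params: EcologicalParams
    matrix_seed: int
    x0_seed: int
    settings: IntegrationSettings
    diverged: bool = False
    t_diverged: float | None = None

    @property
    def S(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        return self.x.shape[1]

    def total_abundance(self) -> np.ndarray:
        """X(t) = sum_i x_i(t)."""
        return self.x.sum(axis=0)

    def relative_abundances(self) -> np.ndarray:
        """p_i(t) = x_i(t) / X(t), shape (S, n_times)."""
        return self.x / self.total_abundance()

    # -- persistence ---------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), times=self.times, x=self.x)
        meta = {
            "params": self.params.to_dict(),
            "matrix_seed": int(self.matrix_seed),
            "x0_seed": int(self.x0_seed),
            "settings": self.settings.to_dict(),
            "diverged": bool(self.diverged),
            "t_diverged": self.t_diverged,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            times=arrs["times"],
            x=arrs["x"],
            params=EcologicalParams.from_dict(meta["params"]),
            matrix_seed=meta["matrix_seed"],
            x0_seed=meta["x0_seed"],
            settings=IntegrationSettings.from_dict(meta["settings"]),
            diverged=meta["diverged"],
            t_diverged=meta["t_diverged"],
        )

    def to_csv(self, path: str | Path) -> None:
        """Wide CSV: a time column followed by one column per species."""
        df = pd.DataFrame(self.x.T, columns=[f"sp{i}" for i in range(self.S)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    def interaction_matrix(self) -> InteractionMatrix:
        """Re-sample the interaction matrix from the stored seed."""
        return sample_interactions(self.params, self.matrix_seed)


def initial_condition(params: EcologicalParams,
                      settings: IntegrationSettings) -> np.ndarray:
    """Random initial abundances x_i ~ U(lam, 2/S).

    The support places every species between the immigration floor and
    twice the even-split abundance.
    """
    if params.lam >= 2.0 / params.S:
        raise ValueError(
            f"empty support: lam = {params.lam} >= 2/S = {2.0 / params.S}")
    rng = np.random.default_rng(settings.seed_x0)
    return rng.uniform(params.lam, 2.0 / params.S, size=params.S)


def growth_rates(x: np.ndarray, M: InteractionMatrix) -> np.ndarray:
    """Per-capita growth rates g_i = 1 - sum_{j != i} alpha_ij x_j.

    These are the growth rates a species would have at vanishing own
    abundance; the diagonal is excluded exactly because the coupling
    matrix carries a zero diagonal.
    """
    x = np.asarray(x)
    if x.shape[-1] != M.S and x.shape[0] != M.S:
        raise ValueError(f"abundance vector length {x.shape} does not match S={M.S}")
    return 1.0 - M.coupling() @ x


def integrate(M: InteractionMatrix, x0: np.ndarray,
              settings: IntegrationSettings) -> Trajectory:
    """Advance the community with the log-domain Euler scheme.

    The update is ``y <- y + dt * (1 - x - A @ x + lam / x)`` with
    ``y = ln x``, i.e. the immigration term is kept inside the log-domain
    derivative rather than operator-split.  Recording starts after
    ``t_burn`` at intervals of ``store_stride``.  If any abundance
    exceeds ``divergence_threshold`` the run stops early and the
    trajectory is flagged as diverged.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial abundances must be strictly positive")
    if x0.shape != (M.S,):
        raise ValueError(f"x0 has shape {x0.shape}, expected ({M.S},)")
    n_burn = int(round(settings.t_burn / settings.dt))
    n_run = int(round(settings.t_run / settings.dt))
    stride = settings.stride_steps
    A = np.ascontiguousarray(M.coupling())
    stored, k, status, t_stop = _kernels.integrate_lv(
        A, np.log(x0), settings.dt, n_burn, n_run, stride,
        M.params.lam, settings.divergence_threshold)
    if status == _kernels.NONFINITE:
        raise IntegrationError(f"non-finite state at t = {t_stop:.2f}")
    times = settings.t_burn + settings.store_stride * np.arange(1, k + 1)
    return Trajectory(
        times=times,
        x=stored[:k].T.copy(),
        params=M.params,
        matrix_seed=M.seed,
        x0_seed=settings.seed_x0,
        settings=settings,
        diverged=(status == _kernels.DIVERGED),
        t_diverged=t_stop if status == _kernels.DIVERGED else None,
    )


def split_seed(seed: int, n: int = 2) -> list[int]:
    """Derive `n` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n)]


def simulate_community(params: EcologicalParams, matrix_seed: int,
                       settings: IntegrationSettings) -> Trajectory:
    """Sample a matrix, draw the initial condition, and integrate."""
    M = sample_interactions(params, matrix_seed)
    x0 = initial_condition(params, settings)
    return integrate(M, x0, settings)


def reference_run(seed: int = 0, t_run: float = 10000.0,
                  **overrides) -> Trajectory:
    """Convenience wrapper for the reference chaotic configuration.

    Parameters (S, mu, sigma, lam) = (500, 0.5, 0.3, 1e-8): representative
    of chaotic turnover with about nine dominant species.  ``seed`` is
    split into independent matrix and initial-condition streams.
    """
    if t_run <= 0:
        raise ValueError("t_run must be positive")
    m_seed, x0_seed = split_seed(seed)
    settings = IntegrationSettings(t_run=t_run, seed_x0=x0_seed, **overrides)
    return simulate_community(REFERENCE_PARAMS, m_seed, settings)
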