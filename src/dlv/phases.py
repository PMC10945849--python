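"""Dynamical-phase classification and (mu, sigma) phase scanning.

Long-run community trajectories fall into four classes: equilibrium (all
abundances settle), cycle (periodic return of the abundance vector),
chaos (aperiodic turnover), and divergence (mutualistic positive feedback
drives abundances beyond any bound, where the model is biologically
unsound).  Classification uses a recurrence-counting heuristic on the
log-abundance state, cross-validated by a two-trajectory maximal-Lyapunov
estimator; scanning a (mu, sigma) grid with replicated random matrices
and initial conditions maps the probability of chaos.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernels
from .interactions import EcologicalParams, InteractionMatrix, sample_interactions
from .simulate import (IntegrationSettings, Trajectory, initial_condition,
                       integrate)

__all__ = [
    "PhaseLabel",
    "PhaseScan",
    "ClassifierSettings",
    "classify",
    "lyapunov_max",
    "phase_scan",
]

LABELS = ("equilibrium", "cycle", "chaos", "divergence")


@dataclass(frozen=True)
class ClassifierSettings:
    """Constants of the recurrence-counting heuristic.

    eps_eq : equilibrium if the largest per-species SD of ln x over the
        classification window falls below this.
    eps_rec : a frame "recurs" if it returns within this distance of a
        reference frame, in max-norm on ln x restricted to species above
        `rare_cut` relative abundance in the reference frame.
    min_separation : minimum spacing (time units) between counted
        recurrences, so one slow passage is not counted repeatedly.
    cv_cycle : recurrences with inter-recurrence-interval coefficient of
        variation below this are called periodic (cycle).
    window_fraction : trailing fraction of the recorded run classified
        (transients near phase boundaries can hold metastable episodes).
    """

    eps_eq: float = 1e-4
    eps_rec: float = 0.5
    rare_cut: float = 1e-4
    min_separation: float = 5.0
    cv_cycle: float = 0.1
    window_fraction: float = 0.5
    n_references: int = 3


@dataclass
class PhaseLabel:
    label: str
    n_recurrences: int = 0
    interval_cv: float = np.nan
    amplitude: float = np.nan
    lyapunov: float = np.nan

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _recurrences(lx: np.ndarray, times: np.ndarray, ref: int,
                 cs: ClassifierSettings):
    """Recurrence analysis of the window against reference frame `ref`.

    A recurrence is a return to within `eps_rec` of the reference state
    (max-norm on ln relative abundance, restricted to species that are
    not rare in the reference frame) after an excursion away from it of
    at least `min_separation` time units.  Returns ``(hit_times,
    always_close)``; the flag marks a window that never leaves the
    neighborhood at all — a stationary state, not a turnover.
    """
    sel = lx[:, ref] > np.log(cs.rare_cut)   # lx holds ln(relative abundance)
    if not np.any(sel):
        sel = np.ones(lx.shape[0], dtype=bool)
    d = np.max(np.abs(lx[sel] - lx[sel, ref][:, None]), axis=0)
    close = d < cs.eps_rec
    if np.all(close):
        return np.empty(0), True
    hits = []
    far_since = None
    for j in range(close.size):
        if close[j]:
            if far_since is not None and times[j] - far_since >= cs.min_separation:
                hits.append(times[j])
            far_since = None
        elif far_since is None:
            far_since = times[j]
    return np.asarray(hits), False


def classify(traj: Trajectory,
             settings: ClassifierSettings = ClassifierSettings()) -> PhaseLabel:
    """Label a trajectory as equilibrium / cycle / chaos / divergence.

    Divergence honors the integrator's flag.  Equilibrium requires every
    species' ln-abundance to be static over the trailing window.
    Otherwise near-recurrences of the log-relative-abundance state are
    counted from a few reference frames: regularly spaced recurrences
    (CV of intervals < `cv_cycle`, at least 3 recurrences) indicate a
    cycle; irregular or absent recurrences indicate chaos.
    """
    if traj.diverged:
        return PhaseLabel("divergence")
    n = traj.n_times
    start = int(n * (1.0 - settings.window_fraction))
    if n - start < 10:
        raise ValueError("trajectory too short to classify")
    x = traj.x[:, start:]
    times = traj.times[start:]
    lx_abs = np.log(x)
    sd = lx_abs.std(axis=1)
    amplitude = float(sd.max())
    if amplitude < settings.eps_eq:
        return PhaseLabel("equilibrium", amplitude=amplitude)

    p = x / x.sum(axis=0)
    lx = np.log(p)
    n_win = lx.shape[1]
    refs = np.linspace(0, n_win // 4, settings.n_references, dtype=int)
    best_cv = np.inf
    n_rec_total = 0
    n_stationary = 0
    for ref in refs:
        hits, always_close = _recurrences(lx, times, int(ref), settings)
        if always_close:
            n_stationary += 1
            continue
        n_rec_total += hits.size
        if hits.size >= 3:
            iv = np.diff(np.sort(np.concatenate([[times[int(ref)]], hits])))
            cv = iv.std() / iv.mean()
            best_cv = min(best_cv, cv)
    if n_stationary == len(refs):
        # the state never leaves any reference neighborhood: a (possibly
        # slowly relaxing) stationary composition, not turnover
        return PhaseLabel("equilibrium", amplitude=amplitude)
    if best_cv < settings.cv_cycle:
        return PhaseLabel("cycle", n_recurrences=n_rec_total,
                          interval_cv=best_cv, amplitude=amplitude)
    return PhaseLabel("chaos", n_recurrences=n_rec_total,
                      interval_cv=best_cv, amplitude=amplitude)


@dataclass
class LyapunovEstimate:
    rate: float
    stderr: float
    n_episodes: int

    @property
    def positive(self) -> bool:
        """Significantly positive at two standard errors."""
        return self.rate - 2 * self.stderr > 0


def lyapunov_max(M: InteractionMatrix, x0: np.ndarray,
                 settings: IntegrationSettings, eps: float = 1e-6,
                 renorm_every: float = 1.0) -> LyapunovEstimate:
    """Benettin-style maximal Lyapunov exponent in log-abundance space.

    A companion trajectory offset by ``eps`` (Euclidean norm on ln x) is
    integrated alongside the reference; every ``renorm_every`` time units
    the log separation growth rate is recorded and the companion is
    rescaled back onto the eps-sphere.  Returns the mean rate (1/time)
    with its standard error over renormalization episodes.
    """
    n_burn = int(round(settings.t_burn / settings.dt))
    n_total = int(round(settings.t_run / settings.dt))
    every = max(1, int(round(renorm_every / settings.dt)))
    A = np.ascontiguousarray(M.coupling())
    rates, k, status = _kernels.lyapunov_benettin(
        A, np.log(np.asarray(x0, dtype=float)), settings.dt,
        n_burn, n_total, eps, every, M.params.lam)
    if status == _kernels.DIVERGED:
        raise RuntimeError("trajectory diverged during Lyapunov estimation")
    rates = rates[:k]
    if k < 2:
        raise RuntimeError("too few renormalization episodes")
    return LyapunovEstimate(rate=float(rates.mean()),
                            stderr=float(rates.std(ddof=1) / np.sqrt(k)),
                            n_episodes=int(k))


@dataclass
class PhaseScan:
    """Replicated classification over a (mu, sigma) grid."""

    results: pd.DataFrame        # columns: mu, sigma, replicate, label
    replicates: int

    def counts(self) -> pd.DataFrame:
        tab = (self.results.groupby(["mu", "sigma"])["label"]
               .value_counts().unstack(fill_value=0))
        for lab in LABELS:
            if lab not in tab.columns:
                tab[lab] = 0
        return tab[list(LABELS)].reset_index()

    def probability(self, label: str = "chaos") -> pd.DataFrame:
        tab = self.counts()
        tab[f"p_{label}"] = tab[label] / self.replicates
        return tab[["mu", "sigma", f"p_{label}"]]

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


def phase_scan(mu_values, sigma_values, replicates: int = 30,
               S: int = 500, lam: float = 1e-8, gamma: float = 0.0,
               settings: IntegrationSettings | None = None,
               classifier: ClassifierSettings = ClassifierSettings(),
               seed: int = 0,
               out: str | Path | None = None) -> PhaseScan:
    """Classify replicated runs on every (mu, sigma) grid cell.

    Each replicate draws an independent interaction matrix and initial
    condition from seeds spawned off ``seed``.  Scan replicate runs are
    shorter than analysis runs by default (labels need far less data than
    converged statistics).  If ``out`` is given, per-cell results are
    appended to a CSV as they complete, making long scans resumable.
    """
    if settings is None:
        settings = IntegrationSettings(t_burn=500.0, t_run=2000.0)
    out = Path(out) if out is not None else None
    done = set()
    rows = []
    if out is not None and out.exists():
        prev = pd.read_csv(out)
        rows = prev.to_dict("records")
        done = {(r["mu"], r["sigma"], r["replicate"]) for r in rows}
    for mu in mu_values:
        for sigma in sigma_values:
            cell_ss = np.random.SeedSequence((seed, int(round(mu * 1e6)),
                                              int(round(sigma * 1e6))))
            seeds = cell_ss.generate_state(2 * replicates) & 0x7FFFFFFF
            for rep in range(replicates):
                key = (round(float(mu), 10), round(float(sigma), 10), rep)
                if key in done:
                    continue
                params = EcologicalParams(S=S, mu=float(mu), sigma=float(sigma),
                                          gamma=gamma, lam=lam)
                M = sample_interactions(params, int(seeds[2 * rep]))
                rep_settings = IntegrationSettings(
                    dt=settings.dt, t_burn=settings.t_burn,
                    t_run=settings.t_run, store_stride=settings.store_stride,
                    divergence_threshold=settings.divergence_threshold,
                    seed_x0=int(seeds[2 * rep + 1]))
                x0 = initial_condition(params, rep_settings)
                traj = integrate(M, x0, rep_settings)
                lab = classify(traj, classifier)
                rows.append({"mu": key[0], "sigma": key[1], "replicate": rep,
                             "label": lab.label,
                             "n_recurrences": lab.n_recurrences,
                             "amplitude": lab.amplitude})
                if out is not None:
                    pd.DataFrame(rows).to_csv(out, index=False)
    return PhaseScan(results=pd.DataFrame(rows), replicates=replicates)
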