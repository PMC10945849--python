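"""Community-level statistics of chaotic species turnover.

Given a recorded trajectory this module computes the observables that
characterize boom-bust community dynamics: the effective community size
(reciprocal Simpson index) and the dominant component it defines,
Bray-Curtis similarity and closeness to quasi-equilibria, the collective
correlation and the predicted time-averaged total abundance, abundance
fluctuation / species abundance distributions with their power-law
exponent, autocorrelation functions and the turnover timescale, dominance
statistics, AFD typicality, and the selective-advantage decomposition of
the relative-abundance dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from . import _kernels
from .interactions import EcologicalParams, InteractionMatrix
from .simulate import Trajectory

__all__ = [
    "CommunitySummary",
    "AbundanceDistributions",
    "PowerLawFit",
    "DominanceReport",
    "effective_size",
    "dominant_component",
    "bray_curtis",
    "closeness_to_equilibrium",
    "collective_correlation",
    "collective_correlation_series",
    "predicted_X_bar",
    "critical_rho",
    "afd_sad",
    "fit_power_law",
    "fit_power_law_mle",
    "acf",
    "vector_acf",
    "fit_timescale",
    "dominance_stats",
    "typicality",
    "selection_decomposition",
    "selection_consistency",
    "summarize",
]


# ----------------------------------------------------------------------
# Effective size and the dominant component

def effective_size(x: np.ndarray) -> float:
    """Effective community size: reciprocal Simpson diversity 1 / sum p_i^2.

    Ranges from 1 (one species holds nearly all abundance) to S (all
    species equally abundant); its integer approximation is the richness
    of the dominant component.
    """
    x = np.asarray(x, dtype=float)
    tot = x.sum()
    if tot <= 0:
        raise ValueError("effective size undefined for a non-positive community")
    p = x / tot
    return 1.0 / np.sum(p * p)


def effective_size_series(traj: Trajectory) -> np.ndarray:
    p = traj.relative_abundances()
    return 1.0 / np.sum(p * p, axis=0)


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def dominant_component(x: np.ndarray) -> np.ndarray:
    """Indices of the round(Seff) most abundant species (at least 1).

    Ties are broken in favor of the lower species index.
    """
    x = np.asarray(x, dtype=float)
    r = max(1, _round_half_up(effective_size(x)))
    order = np.argsort(-x, kind="stable")
    return np.sort(order[:r])


def _dominance_masks(p: np.ndarray):
    """Per-frame dominant-set size, membership mask, share and threshold.

    Parameters
    ----------
    p : ndarray (S, T) of relative abundances.

    Returns
    -------
    r : ndarray (T,) int — dominant-component richness round(Seff).
    member : ndarray (S, T) bool — membership in the dominant component.
    share : ndarray (T,) — total relative abundance of the dominant set.
    threshold : ndarray (T,) — relative abundance of its last member.
    """
    S, T = p.shape
    seff = 1.0 / np.sum(p * p, axis=0)
    r = np.clip(np.floor(seff + 0.5).astype(int), 1, S)
    order = np.argsort(-p, axis=0, kind="stable")
    rank = np.empty_like(order)
    np.put_along_axis(rank, order, np.arange(S)[:, None].repeat(T, axis=1), axis=0)
    member = rank < r[None, :]
    p_sorted = np.take_along_axis(p, order, axis=0)
    csum = np.cumsum(p_sorted, axis=0)
    share = csum[r - 1, np.arange(T)]
    threshold = p_sorted[r - 1, np.arange(T)]
    return r, member, share, threshold


# ----------------------------------------------------------------------
# Similarity metrics

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis similarity between two abundance vectors.

    Computed as the abundance-weighted mean of min/mean ratios,

        BC = sum_i w_i * min(x_i, y_i) / mean(x_i, y_i),
        w_i = (x_i + y_i) / sum_j (x_j + y_j),

    which reduces algebraically to ``2 * sum_i min(x_i, y_i) / sum_i
    (x_i + y_i)``.  BC = 1 iff x = y, and BC ~ 0 when every species is
    abundant in one community and rare in the other, which makes it
    suitable when abundances span orders of magnitude.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have the same shape")
    tot = (x + y).sum()
    if tot <= 0:
        raise ValueError("Bray-Curtis undefined for two empty communities")
    return 2.0 * np.minimum(x, y).sum() / tot


@dataclass
class QuasiEquilibriumResult:
    similarity: float
    converged: bool
    diverged: bool
    members: np.ndarray
    x_dom: np.ndarray
    equilibrium: np.ndarray


def closeness_to_equilibrium(traj: Trajectory, M: InteractionMatrix,
                             t: float, tol: float = 1e-9,
                             t_max: float = 1e4) -> QuasiEquilibriumResult:
    """Similarity between the dominant component and its own equilibrium.

    The community at the stored time nearest ``t`` is restricted to its
    dominant component; that few-species subsystem is integrated without
    immigration (lam = 0) from the observed abundances until
    ``max_i |dx_i/dt| < tol`` (or ``t_max``), and the Bray-Curtis
    similarity between the observed and equilibrated compositions is
    returned.  Values near 1 indicate the community is tracking a
    few-species quasi-equilibrium; drops flag subversion by invaders.
    """
    if not traj.times[0] <= t <= traj.times[-1]:
        raise ValueError(f"t = {t} outside trajectory range")
    idx = int(np.argmin(np.abs(traj.times - t)))
    x_t = traj.x[:, idx]
    members = dominant_component(x_t)
    x_dom = x_t[members]
    A_sub = np.ascontiguousarray(M.coupling()[np.ix_(members, members)])
    x_star, converged, diverged = _kernels.relax_to_equilibrium(
        A_sub, np.log(x_dom), traj.settings.dt, tol, t_max)
    sim = np.nan if diverged else bray_curtis(x_dom, x_star)
    return QuasiEquilibriumResult(similarity=sim, converged=bool(converged),
                                  diverged=bool(diverged), members=members,
                                  x_dom=x_dom, equilibrium=x_star)


def closeness_series(traj: Trajectory, M: InteractionMatrix,
                     times: np.ndarray, **kw) -> np.ndarray:
    return np.array([closeness_to_equilibrium(traj, M, t, **kw).similarity
                     for t in times])


# ----------------------------------------------------------------------
# Collective correlation and the total-abundance relation

def collective_correlation_series(traj: Trajectory,
                                  M: InteractionMatrix) -> np.ndarray:
    """rho(t) = -sum_{i != j} z_ij p_i(t) p_j(t).

    Positive when pairs with less-competitive-than-average interactions
    co-occur; near zero when abundances and interactions are unrelated.
    """
    Z = M.z  # raises for sigma == 0; diagonal is zero
    p = traj.relative_abundances()
    return -np.sum(p * (Z @ p), axis=0)


def collective_correlation(traj: Trajectory, M: InteractionMatrix) -> float:
    """Time-averaged collective correlation rho_bar."""
    return float(collective_correlation_series(traj, M).mean())


def predicted_X_bar(mu: float, sigma: float, seff_bar: float,
                    rho_bar: float) -> float:
    """Predicted time-averaged total abundance.

    X_bar ~ 1 / (mu + (1 - mu)/Seff_bar - sigma * rho_bar), obtained by
    time-averaging the exact equation for d ln X / dt and neglecting
    correlations between the fluctuating factors and the O(S*lam)
    immigration term.
    """
    denom = mu + (1.0 - mu) / seff_bar - sigma * rho_bar
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator ({denom:.3g}): outside the regime "
            "of validity of the total-abundance relation")
    return 1.0 / denom


def critical_rho(mu: float, sigma: float, seff_bar: float) -> float:
    """Minimum collective correlation for boom-bust dynamics.

    rho_c = (1 - mu) / (sigma * Seff_bar); rho_bar >= rho_c is equivalent
    to the typical growth rate being negative (k = mu * X_bar - 1 > 0).
    """
    if sigma <= 0:
        raise ValueError("critical correlation undefined for sigma <= 0")
    return (1.0 - mu) / (sigma * seff_bar)


# ----------------------------------------------------------------------
# Abundance distributions and the power-law exponent

@dataclass
class AbundanceDistributions:
    """Log-binned abundance histograms in time (AFD) and across species (SAD).

    ``afd[i]`` is the fraction of recorded time species ``i`` spends in
    each bin (rows sum to 1); ``sad`` holds snapshot species counts per
    bin (each column sums to S).
    """

    edges: np.ndarray
    afd: np.ndarray                 # (S, n_bins)
    mean_afd: np.ndarray            # (n_bins,)
    sd_afd: np.ndarray              # (n_bins,) across-species SD
    snapshot_times: np.ndarray
    sad: np.ndarray                 # (n_bins, n_snapshots)

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center": self.centers,
                           "mean_afd": self.mean_afd, "sd_afd": self.sd_afd})
        for j, t in enumerate(self.snapshot_times):
            df[f"sad_t{t:g}"] = self.sad[:, j]
        return df


@dataclass
class PowerLawFit:
    """Least-squares power-law fit P(x) ~ x**(-nu) on a log-log grid."""

    nu: float
    window: tuple
    rms_residual: float
    n_points: int


def afd_sad(traj: Trajectory, bins_per_decade: int = 12,
            snapshot_times: np.ndarray | None = None) -> AbundanceDistributions:
    """Abundance fluctuation and species abundance distributions.

    Bins are log-spaced over [lam/10, 10].  Each species' AFD is its
    time-normalized abundance histogram; the species-averaged AFD and its
    across-species SD summarize the near-equivalence of species.  SADs
    are snapshot histograms at the requested times (default: four frames
    separated by ~10 turnover times).
    """
    lam = traj.params.lam
    lo, hi = lam / 10.0, 10.0
    n_bins = int(np.ceil(np.log10(hi / lo) * bins_per_decade))
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    S, T = traj.x.shape
    if T < 2:
        raise ValueError("trajectory too short for abundance histograms")

    logx = np.log10(np.clip(traj.x, lo, hi * (1 - 1e-12)))
    idx = ((logx - np.log10(lo)) / (np.log10(hi) - np.log10(lo)) * n_bins)
    idx = np.clip(idx.astype(int), 0, n_bins - 1)
    afd = np.zeros((S, n_bins))
    for i in range(S):
        afd[i] = np.bincount(idx[i], minlength=n_bins)
    afd /= afd.sum(axis=1, keepdims=True)

    if snapshot_times is None:
        spacing = 10 * 30.0  # ~10 turnover times of the reference dynamics
        n_snap = max(1, min(4, int(np.ptp(traj.times) / spacing)))
        snapshot_times = traj.times[0] + spacing * np.arange(1, n_snap + 1)
        snapshot_times = snapshot_times[snapshot_times <= traj.times[-1]]
        if len(snapshot_times) == 0:
            snapshot_times = traj.times[-1:]
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    sad = np.zeros((n_bins, len(snapshot_times)))
    for j, t in enumerate(snapshot_times):
        col = int(np.argmin(np.abs(traj.times - t)))
        sad[:, j] = np.bincount(idx[:, col], minlength=n_bins)

    return AbundanceDistributions(
        edges=edges, afd=afd, mean_afd=afd.mean(axis=0),
        sd_afd=afd.std(axis=0), snapshot_times=snapshot_times, sad=sad)


def fit_power_law(dist: AbundanceDistributions,
                  window: tuple | None = None) -> PowerLawFit:
    """Exponent of the power-law section of the species-averaged AFD.

    The probability density is estimated as bin probability over bin
    width at the geometric bin centers, and a straight line is fitted by
    least squares to log-density versus log-abundance inside ``window``
    (default [100 * lam, 0.01], the section bounded below by immigration
    and above by the carrying capacity).  For log-spaced bins the
    geometric-center density estimate of an exact power law is biased by
    a constant factor only, so the slope is unbiased.
    """
    if window is None:
        lam = dist.edges[0] * 10.0  # edges span [lam/10, 10]
        window = (100.0 * lam, 0.01)
    lo, hi = window
    centers = dist.centers
    density = dist.mean_afd / dist.widths
    mask = (centers >= lo) & (centers <= hi) & (density > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 populated bins in the fit window; "
                         "is the window empty (lam too large)?")
    lx = np.log10(centers[mask])
    ly = np.log10(density[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return PowerLawFit(nu=float(-slope), window=(lo, hi),
                       rms_residual=float(np.sqrt(np.mean(resid**2))),
                       n_points=int(mask.sum()))


def fit_power_law_mle(samples: np.ndarray, window: tuple) -> float:
    """Maximum-likelihood exponent of a window-truncated power law.

    Conditional MLE for samples restricted to [lo, hi] with density
    proportional to x**(-nu); a Hill-type alternative to the binned
    least-squares fit.
    """
    lo, hi = window
    x = np.asarray(samples, dtype=float)
    x = x[(x >= lo) & (x <= hi)]
    if x.size < 10:
        raise ValueError("too few samples inside the fit window")
    mean_log = np.mean(np.log(x / lo))
    r = np.log(hi / lo)
    R = hi / lo

    def score(nu):
        # d/dnu of the truncated-pareto log-likelihood (nu > 1 branch);
        # as nu -> 1 this tends to r/2 - mean_log (uniform-in-log limit)
        a = 1.0 - nu
        return -1.0 / a + r * R**a / (R**a - 1.0) - mean_log

    if score(1.0 + 1e-6) <= 0:
        raise ValueError("samples are shallower than x**-1 on the window; "
                         "no truncated-power-law MLE with nu > 1")
    return float(brentq(score, 1.0 + 1e-6, 50.0))


# ----------------------------------------------------------------------
# Autocorrelation and the turnover timescale

def acf(series: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Mean-subtracted autocorrelation, FFT-based, biased normalization.

    phi[0] = 1; lag k is divided by the full series length (biased
    estimator), which tapers the noisy large-lag tail.
    """
    f = np.asarray(series, dtype=float)
    n = f.size
    if max_lag is None:
        max_lag = n // 2
    df = f - f.mean()
    var = np.mean(df * df)
    if var == 0:
        raise ValueError("ACF undefined for a constant series")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(df, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: max_lag + 1]
    return ac / (n * var)


def vector_acf(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Variance-weighted average of per-species ACFs.

    phi_x = sum_i w_i phi_{x_i} / S with w_i proportional to var[x_i]:
    the natural ACF of the abundance vector, dominated by the species
    that actually fluctuate.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    S, n = x.shape
    if max_lag is None:
        max_lag = n // 2
    dx = x - x.mean(axis=1, keepdims=True)
    var = np.mean(dx * dx, axis=1)
    keep = var > 0
    if not np.any(keep):
        raise ValueError("ACF undefined: all series constant")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(dx[keep], nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : max_lag + 1]
    ac /= (n * var[keep, None])          # per-species phi, phi[0] = 1
    w = var[keep] / var[keep].sum()
    return w @ ac


def fit_timescale(lags: np.ndarray, phi: np.ndarray,
                  threshold: float = 0.05) -> float:
    """Decay constant of a least-squares exponential fit exp(-t/tau).

    Only lags up to the first crossing below ``threshold`` are used, to
    avoid fitting the noisy tail of the ACF.
    """
    lags = np.asarray(lags, dtype=float)
    phi = np.asarray(phi, dtype=float)
    below = np.nonzero(phi < threshold)[0]
    end = below[0] if below.size else phi.size
    if end < 3:
        raise ValueError("ACF drops below threshold too fast to fit a timescale")
    t, y = lags[:end], phi[:end]
    # log-linear initial guess, then least squares in linear space
    pos = y > 0
    tau0 = -1.0 / np.polyfit(t[pos], np.log(y[pos]), 1)[0]
    tau0 = abs(tau0) if np.isfinite(tau0) and tau0 != 0 else max(t[-1], 1.0)
    (tau,), _ = curve_fit(lambda tt, tau: np.exp(-tt / tau), t, y,
                          p0=[tau0], maxfev=10000)
    return float(abs(tau))


def turnover_timescale(traj: Trajectory, threshold: float = 0.05) -> float:
    """tau_dom: exponential decay time of the abundance-vector ACF."""
    phi = vector_acf(traj.x)
    lags = np.arange(phi.size) * traj.settings.store_stride
    return fit_timescale(lags, phi, threshold)


# ----------------------------------------------------------------------
# Dominance statistics and typicality

@dataclass
class DominanceReport:
    """Per-species dominance statistics over a long trajectory.

    fraction: share of recorded frames spent in the dominant component;
    bias: fraction normalized by the species median (1 at the middle
    rank); rank: 1 = most often dominant.  ``z_bias`` and ``theta``
    attach the net interaction bias and AFD typicality when available.
    """

    fraction: np.ndarray
    bias: np.ndarray
    rank: np.ndarray
    z_bias: np.ndarray | None = None
    theta: np.ndarray | None = None
    mean_dominant_size: float = np.nan
    too_short: bool = False

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"species": np.arange(self.fraction.size),
                           "fraction": self.fraction, "bias": self.bias,
                           "rank": self.rank})
        if self.z_bias is not None:
            df["z_bias"] = self.z_bias
        if self.theta is not None:
            df["theta"] = self.theta
        return df


def dominance_stats(traj: Trajectory, M: InteractionMatrix | None = None,
                    dist: AbundanceDistributions | None = None,
                    min_turnovers: int = 50,
                    tau_dom: float = 30.0) -> DominanceReport:
    """Rank species by the fraction of time spent in the dominant component."""
    p = traj.relative_abundances()
    r, member, _, _ = _dominance_masks(p)
    frac = member.mean(axis=1)
    med = np.median(frac)
    bias = frac / med if med > 0 else np.full_like(frac, np.nan)
    order = np.argsort(-frac, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(1, frac.size + 1)
    duration = np.ptp(traj.times)
    report = DominanceReport(
        fraction=frac, bias=bias, rank=rank,
        mean_dominant_size=float(r.mean()),
        too_short=duration < min_turnovers * tau_dom)
    if report.too_short:
        warnings.warn("trajectory covers fewer than "
                      f"{min_turnovers} turnover times; dominance statistics "
                      "may be unconverged", stacklevel=2)
    if M is not None and M.params.sigma > 0:
        report.z_bias = M.z_bias
    if dist is not None:
        report.theta = typicality(dist)
    return report


def typicality(dist: AbundanceDistributions) -> np.ndarray:
    """AFD typicality theta_i = 1 - KS distance to the average AFD.

    Computed from cumulative distributions over the common log-binned
    support; theta = 1 means the species' abundance fluctuation
    distribution matches the species average exactly.
    """
    cdf_i = np.cumsum(dist.afd, axis=1)
    cdf_bar = np.cumsum(dist.mean_afd)
    return 1.0 - np.max(np.abs(cdf_i - cdf_bar[None, :]), axis=1)


# ----------------------------------------------------------------------
# Selective advantage

@dataclass
class SelectionDecomposition:
    """Decomposition of relative-abundance dynamics into reference and bias.

    pi(t) = 1/Seff(t) - sigma*rho(t) is the reference proportion every
    species is attracted to in the absence of interaction residuals;
    s[i, t] = -sigma * sum_{j != i} z_ij p_j(t) is the instantaneous
    selection coefficient of species i, and s_bar its time average.
    """

    times: np.ndarray
    pi: np.ndarray
    s: np.ndarray
    s_bar: np.ndarray


def selection_decomposition(traj: Trajectory,
                            M: InteractionMatrix) -> SelectionDecomposition:
    if M.params.sigma <= 0:
        raise ValueError("selection decomposition requires sigma > 0")
    Z = M.z
    p = traj.relative_abundances()
    seff = 1.0 / np.sum(p * p, axis=0)
    rho = -np.sum(p * (Z @ p), axis=0)
    sigma = M.params.sigma
    s = -sigma * (Z @ p)
    pi = 1.0 / seff - sigma * rho
    return SelectionDecomposition(times=traj.times, pi=pi, s=s,
                                  s_bar=s.mean(axis=1))


def selection_consistency(traj: Trajectory, M: InteractionMatrix,
                          n_frames: int = 200) -> float:
    """Correlation between finite-difference dp/dt and its exact expression.

    The exact reduction of the abundance dynamics to proportions reads

        dp_i/dt = X p_i [(1 - mu)(1/Seff - p_i) + s_i - sigma*rho]
                  + (lam S / X)(1/S - p_i),

    which this check evaluates against centered finite differences of
    p_i(t) on the first ``n_frames`` stored frames.  Values near 1
    validate the decomposition; accuracy requires a store stride well
    below the turnover time.
    """
    dec = selection_decomposition(traj, M)
    p = traj.relative_abundances()[:, :n_frames]
    X = traj.total_abundance()[:n_frames]
    Z = M.z
    mu, sigma, lam, S = (M.params.mu, M.params.sigma, M.params.lam, M.S)
    seff = 1.0 / np.sum(p * p, axis=0)
    rho = -np.sum(p * (Z @ p), axis=0)
    s = dec.s[:, :n_frames]
    rhs = X * p * ((1 - mu) * (1.0 / seff - p) + s - sigma * rho) \
        + (lam * S / X) * (1.0 / S - p)
    dt_store = traj.settings.store_stride
    dp = (p[:, 2:] - p[:, :-2]) / (2 * dt_store)
    rhs_c = rhs[:, 1:-1]
    return float(np.corrcoef(dp.ravel(), rhs_c.ravel())[0, 1])


# ----------------------------------------------------------------------
# One-stop summary

@dataclass
class CommunitySummary:
    """Time-averaged community observables of one trajectory."""

    X_bar: float
    Seff_bar: float
    rho_bar: float
    rho_c: float
    tau_dom: float
    dominant_share: float
    dominance_threshold: float
    params: EcologicalParams | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("X_bar", "Seff_bar", "rho_bar", "rho_c", "tau_dom",
              "dominant_share", "dominance_threshold")}
        if self.params is not None:
            d["params"] = self.params.to_dict()
        return d


def summarize(traj: Trajectory,
              M: InteractionMatrix | None = None) -> CommunitySummary:
    """Compute the standard time-averaged observables of a trajectory."""
    if M is None:
        M = traj.interaction_matrix()
    p = traj.relative_abundances()
    _, _, share, thr = _dominance_masks(p)
    seff_bar = float(effective_size_series(traj).mean())
    sigma = traj.params.sigma
    rho_bar = collective_correlation(traj, M) if sigma > 0 else 0.0
    rho_c = critical_rho(traj.params.mu, sigma, seff_bar) if sigma > 0 else np.nan
    return CommunitySummary(
        X_bar=float(traj.total_abundance().mean()),
        Seff_bar=seff_bar,
        rho_bar=rho_bar,
        rho_c=rho_c,
        tau_dom=turnover_timescale(traj),
        dominant_share=float(share.mean()),
        dominance_threshold=float(thr.mean()),
        params=traj.params,
    )
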