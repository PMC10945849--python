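"""Experiment drivers, configuration, persistence and test fixtures.

A named experiment bundles a full pipeline (simulate -> analyze ->
report) behind a YAML-serializable configuration, writes its artifacts to
an output directory together with a manifest of seeds and timings, and is
deterministic: re-running the same config overwrites the same files with
the same contents.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .interactions import EcologicalParams, sample_interactions
from .simulate import (IntegrationSettings, initial_condition,
                       integrate, split_seed)
from . import observables as obs
from . import focal as focal_mod
from . import phases as phases_mod

__all__ = ["ExperimentConfig", "run_experiment", "make_fixture"]

EXPERIMENTS = ("reference_run", "afd_analysis", "dominance_analysis",
               "focal_comparison", "phase_scan")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run.

    Round-trips losslessly through YAML (`to_yaml` / `from_yaml`).
    """

    experiment: str
    out_dir: str
    seed: int = 0
    S: int = 500
    mu: float = 0.5
    sigma: float = 0.3
    gamma: float = 0.0
    lam: float = 1e-8
    dt: float = 0.01
    t_burn: float = 2000.0
    t_run: float = 10000.0
    store_stride: float = 1.0
    # phase-scan specific
    mu_range: tuple = (0.1, 0.9)
    sigma_range: tuple = (0.05, 0.45)
    grid_step: float = 0.2
    replicates: int = 5
    # focal-comparison specific
    focal_T: float = 1e5

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENTS}")

    @property
    def params(self) -> EcologicalParams:
        return EcologicalParams(S=self.S, mu=self.mu, sigma=self.sigma,
                                gamma=self.gamma, lam=self.lam)

    def settings(self, seed_x0: int) -> IntegrationSettings:
        return IntegrationSettings(dt=self.dt, t_burn=self.t_burn,
                                   t_run=self.t_run,
                                   store_stride=self.store_stride,
                                   seed_x0=seed_x0)

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["mu_range"] = list(self.mu_range)
        d["sigma_range"] = list(self.sigma_range)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "ExperimentConfig":
        p = Path(src)
        text = p.read_text() if p.exists() else str(src)
        d = yaml.safe_load(text)
        for key in ("mu_range", "sigma_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute the named pipeline and write its artifact bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    On a partial failure the manifest marks the stages completed so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    manifest = {"experiment": config.experiment, "seed": config.seed,
                "stages": [], "complete": False}
    t0 = time.time()

    def stage(name):
        manifest["stages"].append({"name": name,
                                   "elapsed_s": round(time.time() - t0, 2)})
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default))

    try:
        if config.experiment == "phase_scan":
            mus = np.arange(config.mu_range[0], config.mu_range[1] + 1e-12,
                            config.grid_step)
            sigmas = np.arange(config.sigma_range[0],
                               config.sigma_range[1] + 1e-12, config.grid_step)
            scan = phases_mod.phase_scan(
                mus, sigmas, replicates=config.replicates, S=config.S,
                lam=config.lam, gamma=config.gamma, seed=config.seed,
                out=out / "scan_results.csv")
            stage("scan")
            scan.probability().to_csv(out / "chaos_probability.csv", index=False)
            summary = {"n_cells": len(scan.counts()),
                       "replicates": config.replicates}
            (out / "scan_summary.json").write_text(
                json.dumps(summary, indent=2, default=_json_default))
            stage("report")
        else:
            m_seed, x0_seed = split_seed(config.seed)
            M = sample_interactions(config.params, m_seed)
            settings = config.settings(x0_seed)
            x0 = initial_condition(config.params, settings)
            traj = integrate(M, x0, settings)
            traj.save(out / "trajectory")
            stage("simulate")

            summary = obs.summarize(traj, M)
            (out / "community_summary.json").write_text(
                json.dumps(summary.to_dict(), indent=2, default=_json_default))
            stage("summarize")

            if config.experiment in ("afd_analysis", "dominance_analysis",
                                     "focal_comparison"):
                dist = obs.afd_sad(traj)
                dist.to_frame().to_csv(out / "distributions.csv", index=False)
                fit = obs.fit_power_law(dist)
                (out / "power_law.json").write_text(json.dumps(
                    {"nu": fit.nu, "window": list(fit.window),
                     "rms_residual": fit.rms_residual}, indent=2))
                stage("distributions")
            if config.experiment == "dominance_analysis":
                dist = obs.afd_sad(traj)
                report = obs.dominance_stats(traj, M, dist)
                report.to_frame().to_csv(out / "dominance.csv", index=False)
                stage("dominance")
            if config.experiment == "focal_comparison":
                ep = focal_mod.effective_params(summary, config.params)
                foc = focal_mod.simulate_focal(
                    ep, T=config.focal_T, seed=split_seed(config.seed, 3)[2])
                nu_ucna = (focal_mod.ucna_exponent(ep) if ep.boom_bust
                           else None)
                (out / "focal.json").write_text(json.dumps(
                    {"k": ep.k, "u": ep.u, "tau": ep.tau,
                     "mean_x": foc.mean_x, "nu_ucna": nu_ucna}, indent=2))
                stage("focal")
        manifest["complete"] = True
        stage("done")
    except Exception as exc:  # record partial progress before re-raising
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_json_default))
        raise
    return manifest


FIXTURE_KINDS = ("tiny_community", "known_powerlaw_samples", "ou_series",
                 "focal_series")


def make_fixture(kind: str, seed: int = 0, **kw):
    """Deterministic small synthetic inputs for unit tests.

    tiny_community : short trajectory of a small community (defaults
        S=30, sigma=0.3) plus its interaction matrix.
    known_powerlaw_samples : iid draws from an exact x**(-nu) density on
        a window, via inverse-CDF sampling (defaults nu=1.5 on
        [1e-6, 1e-2]).
    ou_series : exactly discretized Ornstein-Uhlenbeck path.
    focal_series : focal-model path at known (k, u, tau).
    """
    if kind == "tiny_community":
        params = EcologicalParams(S=kw.get("S", 30), mu=kw.get("mu", 0.5),
                                  sigma=kw.get("sigma", 0.3),
                                  lam=kw.get("lam", 1e-8))
        m_seed, x0_seed = split_seed(seed)
        M = sample_interactions(params, m_seed)
        settings = IntegrationSettings(t_burn=kw.get("t_burn", 100.0),
                                       t_run=kw.get("t_run", 200.0),
                                       store_stride=kw.get("store_stride", 1.0),
                                       seed_x0=x0_seed)
        traj = integrate(M, initial_condition(params, settings), settings)
        return traj, M
    if kind == "known_powerlaw_samples":
        nu = kw.get("nu", 1.5)
        lo, hi = kw.get("window", (1e-6, 1e-2))
        n = kw.get("n", 200_000)
        rng = np.random.default_rng(seed)
        u = rng.random(n)
        a = 1.0 - nu
        return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)
    if kind == "ou_series":
        return focal_mod.simulate_ou(tau=kw.get("tau", 5.0),
                                     dt=kw.get("dt", 0.05),
                                     T=kw.get("T", 10_000.0), seed=seed)
    if kind == "focal_series":
        ep = focal_mod.EffectiveParams(k=kw.get("k", 0.26), u=kw.get("u", 0.25),
                                       tau=kw.get("tau", 30.0),
                                       lam=kw.get("lam", 1e-8))
        return focal_mod.simulate_focal(ep, T=kw.get("T", 1e5), seed=seed,
                                        store_stride=kw.get("store_stride", 1.0))
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
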