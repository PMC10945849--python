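"""Abundance distributions and their power-law exponent.

Builds the abundance fluctuation distribution (AFD: one species'
histogram over time) and snapshot species abundance distributions (SAD)
from a community run, and fits the power-law section.
"""

import numpy as np

import dlv

params = dlv.EcologicalParams(S=200, mu=0.5, sigma=0.3, lam=1e-8)
settings = dlv.IntegrationSettings(t_burn=1000.0, t_run=5000.0, seed_x0=1)
M = dlv.sample_interactions(params, seed=3)
traj = dlv.integrate(M, dlv.initial_condition(params, settings), settings)

dist = dlv.afd_sad(traj)
fit = dlv.fit_power_law(dist)           # window [100*lam, 0.01]
theta = dlv.typicality(dist)

print(f"power-law exponent nu = {fit.nu:.3f} "
      f"(fit window {fit.window[0]:g}..{fit.window[1]:g}, "
      f"{fit.n_points} bins, rms residual {fit.rms_residual:.3f})")
print(f"AFD typicality: median {np.median(theta):.2f}, "
      f"min {theta.min():.2f}  (1 = identical to the species average)")
print(f"snapshot SADs at t = {dist.snapshot_times}")

# The AFD follows x^(-nu) between the immigration floor and the
# carrying-capacity ceiling; snapshot SADs look like subsamples of the
# average AFD, and high typicality says species are statistically
# near-equivalent despite their instantaneous differences.
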