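"""Fitting the focal-species model to an abundance time series.

Generates a synthetic boom-bust series at known parameters and recovers
(k, u, tau) by moment matching — the workflow one would apply to a
single-species abundance record.
"""

import dlv
from dlv.workbench import make_fixture

true = dict(k=0.26, u=0.25, tau=30.0)
run = make_fixture("focal_series", seed=4, T=1e5, **true)

fit = dlv.fit_effective_params(run.x, lam=1e-8, stride=1.0)
print("true:   k=%.3f  u=%.3f  tau=%.1f" % (true["k"], true["u"], true["tau"]))
print("fitted: k=%.3f  u=%.3f  tau=%.1f  (CDF distance %.4f)"
      % (fit.ep.k, fit.ep.u, fit.ep.tau, fit.distance))
if fit.too_short:
    print("warning: series shorter than 10 fitted correlation times")

# The fit matches the stationary log-abundance distribution and the
# abundance autocorrelation; with 1e5 time units of data the parameters
# come back within ~20 %.
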