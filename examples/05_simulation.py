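"""Simulation: parameter recovery and calibration of the additivity test.

Draws 200 heterogeneous networks (tau2 = 0.04) from the default study
conditions (placebo + six combination treatments of three components,
30 studies, log-OR standard errors 0.2-0.5), refits the additive model
on each, and reports the bias of the component estimates, the coverage
of their 95% confidence intervals, and the rejection rate of the
additivity test under additive truth (should sit near 5%).
"""

import numpy as np

from cnma import SimSpec, additivity_test, fit_cnma, fit_nma, simulate

spec = SimSpec(tau2_true=0.04)
nrep, z = 200, 1.959963984540054
cover = np.zeros(3)
errors = np.zeros((nrep, 3))
rejections = 0
for rep in range(nrep):
    sim = simulate(spec, seed=rep)
    fit = fit_cnma(sim.network, sim.comps, effects_model="random")
    se = fit.beta_se()
    cover += np.abs(fit.beta_hat - sim.beta_true) <= z * se
    errors[rep] = fit.beta_hat - sim.beta_true
    std = fit_nma(sim.network)
    add = fit_cnma(sim.network, sim.comps)
    rejections += additivity_test(std, add, weights="random").p < 0.05

print(f"components: {list(sim.comps.components)}, truth {sim.beta_true}")
print(f"mean bias per component:     {np.round(errors.mean(axis=0), 4)}")
print(f"95% CI coverage:             {cover / nrep}")
print(f"additivity rejection rate:   {rejections / nrep:.3f} (nominal 0.05)")
print("Bias near zero and coverage near 0.95 confirm the weighted least")
print("squares machinery and the moment tau2 estimator are calibrated.")
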