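"""Fit the mark-recapture (CJS) case model to simulated capture histories.

Builds the packaged swallows-style fixture — survival and detection on
the logit scale with environmental covariates and three non-centered
random-effect components (brood-on-survival, brood-on-detection,
year-on-survival; 5 fixed effects, 3 log-scale hyper-SDs, 172 random
effects) — and runs a short NUTS fit.  The latent alive states are
marginalized analytically, so the sampler sees a smooth 180-dimensional
posterior.
"""

import numpy as np

import lapnuts as ln
from lapnuts.diagnostics import count_divergences, monitor

model = ln.get_model("swallows", seed=0)
n_random = sum(s.role == "random" for s in model.specs)
print(f"fixed effects : {len(model.fixed_effect_names)}  {model.fixed_effect_names}")
print(f"hyper-SDs     : {len(model.hyper_names)}  {model.hyper_names}")
print(f"random effects: {n_random}")
print(f"total dim     : {model.dim}\n")

# short demonstration run; use iter=2000, warmup=1000, chains=3 for inference
fit = ln.sample(model, chains=1, iter=500, warmup=300, seed=1)

mon = monitor(fit)
print(mon.loc[model.fixed_effect_names + model.hyper_names].round(3))
print(f"\ndivergences: {count_divergences(fit)}")
print("exp(log_sigma_*) are the hypervariance scales; with a single short "
      "chain expect modest n_eff — this run demonstrates the model, not "
      "final inference.")
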