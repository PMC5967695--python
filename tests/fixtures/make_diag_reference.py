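"""Regenerate diag_reference.json (run from this directory).

Reference ESS / split-R-hat values computed with direct-sum (O(n^2))
autocovariances and an explicit Geyer initial-monotone-positive-sequence
loop — a brute-force transliteration of the estimator definitions,
independent of the package implementation.
"""
import json, math
import numpy as np

def brute_rhat(x):
    m, n = x.shape
    h = n // 2
    sc = np.concatenate([x[:, :h], x[:, n - h:]], axis=0)
    m2, n2 = sc.shape
    means = sc.mean(axis=1)
    W = np.mean([np.var(c, ddof=1) for c in sc])
    B_over_n = np.var(means, ddof=1)
    return math.sqrt(((n2 - 1) / n2 * W + B_over_n) / W)

def brute_acov(c):
    n = len(c); mu = c.mean()
    return np.array([sum((c[t] - mu) * (c[t + k] - mu) for t in range(n - k)) / n
                     for k in range(n)])

def brute_ess(x):
    m, n = x.shape
    h = n // 2
    sc = np.concatenate([x[:, :h], x[:, n - h:]], axis=0)
    m2, n2 = sc.shape
    acov = np.array([brute_acov(c) for c in sc])
    chain_var = acov[:, 0] * n2 / (n2 - 1)
    W = chain_var.mean()
    var_plus = W * (n2 - 1) / n2
    if m2 > 1:
        var_plus += np.var(sc.mean(axis=1), ddof=1)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    rho[0] = 1.0
    paired = []
    prev = float("inf")
    for k in range((n2 - 2) // 2 + 1):
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        g = min(g, prev)
        paired.append(g)
        prev = g
    tau = -1.0 + 2.0 * sum(paired) if paired else 0.0
    tau = max(tau, 1.0 / math.log10(n2 * m2 + 10.0))
    return min(m2 * n2 / tau, 2.0 * m2 * n2)

rng = np.random.default_rng(20260924)
fixtures = {}
def ar1(rho, m, n, shift=0.0):
    x = np.empty((m, n)); x[:, 0] = rng.standard_normal(m)
    for t in range(1, n):
        x[:, t] = rho * x[:, t - 1] + rng.standard_normal(m)
    return x + shift * np.arange(m)[:, None]

specs = {
    "iid": rng.standard_normal((4, 80)),
    "ar_half": ar1(0.5, 4, 80),
    "ar_strong": ar1(0.9, 4, 80),
    "shifted_chains": rng.standard_normal((4, 80)) + np.array([0., .5, 1., 1.5])[:, None],
    "antithetic_ish": ar1(-0.7, 4, 80),
}
for name, x in specs.items():
    fixtures[name] = {
        "draws": [[float(v) for v in row] for row in x],
        "rhat": brute_rhat(x),
        "ess": brute_ess(x),
    }
from pathlib import Path
with (Path(__file__).parent / "diag_reference.json").open("w") as fh:
    json.dump(fixtures, fh)
for name, f in fixtures.items():
    print(name, "rhat", round(f["rhat"], 5), "ess", round(f["ess"], 2))
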