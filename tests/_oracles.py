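"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (loops, direct formulas,
scalar optimization) kept independent of the package's vectorized code
paths so they can serve as references.
"""

import numpy as np
from scipy import optimize


def efron_partial_loglik(beta, entry, exit_, event, x):
    """Hand-written Efron partial log-likelihood, single stratum, 1 covariate.

    Risk intervals are (entry, exit]; ties handled by the Efron correction.
    """
    beta = float(beta)
    eta = beta * np.asarray(x, float)
    r = np.exp(eta)
    ll = 0.0
    for t in sorted(set(exit_[event.astype(bool)])):
        tied = [i for i in range(len(x)) if event[i] and exit_[i] == t]
        at_risk = [i for i in range(len(x)) if entry[i] < t <= exit_[i]]
        s0 = sum(r[i] for i in at_risk)
        s0d = sum(r[i] for i in tied)
        d = len(tied)
        ll += sum(eta[i] for i in tied)
        for ell in range(d):
            ll -= np.log(s0 - (ell / d) * s0d)
    return ll


def maximize_efron_oracle(entry, exit_, event, x, bound=4.0):
    """Argmax of the hand-written partial likelihood by scalar maximization
    (bounded golden-section / Brent), refined on a fine grid."""
    f = lambda b: -efron_partial_loglik(b, entry, exit_, event, x)
    res = optimize.minimize_scalar(f, bounds=(-bound, bound), method="bounded",
                                   options={"xatol": 1e-10})
    # guard against local issues with a coarse grid check
    grid = np.linspace(-bound, bound, 801)
    vals = [f(b) for b in grid]
    b0 = grid[int(np.argmin(vals))]
    if f(b0) < res.fun - 1e-12:
        res = optimize.minimize_scalar(f, bounds=(b0 - 0.1, b0 + 0.1),
                                       method="bounded",
                                       options={"xatol": 1e-10})
    return float(res.x)


def bh_adjust(p):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj
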