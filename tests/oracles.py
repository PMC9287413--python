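"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form demand function and
optimizer: utility maximization is done by grid refinement, and the Tobit
likelihood surface is explored by exhaustive grid search, so agreement is
evidence rather than tautology.
"""

import numpy as np

from ctblab.tobit import discount_weight, tobit_loglik


def ctb_utility(a, alpha, B, d, endowment=100.0):
    """CRRA utility of allocating ``a`` tokens to the earlier option."""
    a = np.asarray(a, dtype=float)
    return (d * a) ** alpha + B * (endowment - a) ** alpha


def grid_argmax_allocation(alpha, beta, delta, t, k, d, endowment=100.0,
                           n_stages=5, n_points=201):
    """Brute-force maximizer of the CTB utility by staged grid refinement.

    Final resolution ~ endowment * (2 / n_points)^n_stages ~ 1e-8 tokens,
    comfortably below the 1e-4 comparison tolerance.  Valid because the
    utility is strictly concave in the allocation for alpha < 1.
    """
    B = float(discount_weight(beta, delta, t, k))
    lo, hi = 0.0, float(endowment)
    for _ in range(n_stages):
        grid = np.linspace(lo, hi, n_points)
        u = ctb_utility(grid, alpha, B, d, endowment)
        i = int(np.argmax(u))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, n_points - 1)]
    return 0.5 * (lo + hi)


def grid_best_tobit_loglik(data, endowment=100.0,
                           alphas=None, betas=None, deltas=None, sigmas=None):
    """Best two-limit Tobit log-likelihood over an exhaustive parameter grid.

    Default grid pitches: 0.01 (alpha), 0.01 (beta), 0.001 (delta), 0.5
    (sigma) over boxes covering the simulated populations.
    """
    alphas = np.arange(0.80, 0.99, 0.01) if alphas is None else alphas
    betas = np.arange(0.85, 1.16, 0.01) if betas is None else betas
    deltas = np.arange(0.988, 0.9995, 0.001) if deltas is None else deltas
    sigmas = np.arange(1.0, 8.01, 0.5) if sigmas is None else sigmas
    a = data["tokens_early"].to_numpy(dtype=float)
    t = data["t_days"].to_numpy(dtype=float)
    k = data["k_days"].to_numpy(dtype=float)
    d = data["discount_factor"].to_numpy(dtype=float)
    best = -np.inf
    for alpha in alphas:
        for beta in betas:
            for delta in deltas:
                for sigma in sigmas:
                    ll = tobit_loglik((alpha, beta, delta, sigma),
                                      a, t, k, d, endowment)
                    if ll > best:
                        best = ll
    return best
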