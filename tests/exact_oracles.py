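"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the Fisher oracle
materializes every table with the observed margins using exact integer
arithmetic, and the Poisson oracle maximizes the log-likelihood with a
damped Newton iteration written from the score and Hessian directly.
"""

from __future__ import annotations

import math

import numpy as np

TIE_RTOL = 1e-7


def fisher_2xk_bruteforce(ref_counts, alt_counts, rtol: float = TIE_RTOL) -> float:
    """Exact probability-mass two-sided p by full enumeration with integer
    weights: p = (sum of products of per-column binomials over all tables
    with weight <= observed weight) / C(N, A)."""
    cols = [int(r) + int(a) for r, a in zip(ref_counts, alt_counts)]
    alts = [int(a) for a in alt_counts]
    A = sum(alts)
    N = sum(cols)
    w_obs = 1
    for c, a in zip(cols, alts):
        w_obs *= math.comb(c, a)
    included = 0

    def recurse(i: int, remaining: int, weight: int) -> None:
        nonlocal included
        if i == len(cols) - 1:
            if remaining <= cols[i]:
                w = weight * math.comb(cols[i], remaining)
                if w <= w_obs * (1.0 + rtol):
                    included += w
            return
        upper = min(cols[i], remaining)
        for a in range(upper + 1):
            recurse(i + 1, remaining - a, weight * math.comb(cols[i], a))

    recurse(0, A, 1)
    return included / math.comb(N, A)


def poisson_newton(y: np.ndarray, x: np.ndarray, max_iter: int = 200,
                   grad_tol: float = 1e-12) -> tuple[float, float]:
    """Maximize the Poisson log-likelihood of ``y ~ exp(b0 + b1 x)`` by a
    damped Newton iteration; returns (intercept, slope)."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, dtype=float)])
    beta = np.zeros(2)

    def loglik(b):
        eta = X @ b
        return float(np.sum(y * eta - np.exp(eta)))

    ll = loglik(beta)
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = -(X.T * mu) @ X
        if np.max(np.abs(grad)) < grad_tol:
            break
        step = np.linalg.solve(hess, -grad)
        # backtracking line search keeps the iteration globally stable
        t = 1.0
        while t > 1e-12:
            cand = beta + t * step
            if loglik(cand) >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll = loglik(beta)
    return float(beta[0]), float(beta[1])
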