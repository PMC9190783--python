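"""Scaled conjugate gradient minimization (Moller, Neural Networks 6:525, 1993).

A conjugate-gradient method whose step size comes from a one-sided estimate of
the Hessian-vector product with Levenberg-Marquardt-style scaling — no line
search, one or two gradient evaluations per iteration.  This is the standard
trainer for small pattern-recognition networks with cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["scg_minimize"]


def scg_minimize(fun, grad, x0, max_iter: int = 1000, tol: float = 1e-8, callback=None):
    """Minimize ``fun`` starting at ``x0``; returns the final iterate.

    ``callback(x, k)`` runs after each successful or failed step; returning
    True stops the optimization (used for validation-based early stopping).
    """
    sigma0 = 5.0e-5
    lamb = 5.0e-7
    lamb_bar = 0.0
    w = np.asarray(x0, dtype=float).copy()
    n = w.size
    fw = fun(w)
    g = grad(w)
    r = -g
    p = r.copy()
    success = True
    delta0 = 0.0
    for k in range(1, max_iter + 1):
        p2 = float(p @ p)
        if p2 < 1e-300:
            break
        pnorm = np.sqrt(p2)
        if success:
            sigma = sigma0 / pnorm
            s = (grad(w + sigma * p) - g) / sigma
            delta0 = float(p @ s)
        delta = delta0 + (lamb - lamb_bar) * p2
        if delta <= 0:  # make the Hessian estimate positive definite
            lamb_bar = 2.0 * (lamb - delta / p2)
            delta = -delta + lamb * p2
            lamb = lamb_bar
        mu = float(p @ r)
        alpha = mu / delta
        fw_new = fun(w + alpha * p)
        Delta = 2.0 * delta * (fw - fw_new) / (mu * mu)
        if Delta >= 0:  # successful step
            w = w + alpha * p
            fw = fw_new
            g = grad(w)
            r_new = -g
            lamb_bar = 0.0
            success = True
            if k % n == 0:  # restart the direction periodically
                p = r_new.copy()
            else:
                beta = float(r_new @ r_new - r_new @ r) / mu
                p = r_new + beta * p
            r = r_new
            if Delta >= 0.75:
                lamb = max(lamb * 0.25, 1e-15)
        else:
            lamb_bar = lamb
            success = False
        if Delta < 0.25:
            lamb = min(lamb + delta * (1.0 - Delta) / p2, 1e100)
        if callback is not None and callback(w, k):
            break
        if success and float(np.sqrt(r @ r)) < tol:
            break
    return w
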