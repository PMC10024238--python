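"""Limited-memory BFGS ascent with Armijo backtracking.

The mesh objectives are smooth only on the set of unfolded configurations;
outside it they are -inf.  scipy's bounded optimizers do not mix well with
infinite objective values, so we use a compact two-loop-recursion L-BFGS in
which the line search simply rejects (shrinks past) any step that lands on an
infeasible configuration.  Every accepted step strictly increases the
objective, which is what the coordinate-ascent callers rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lbfgs_maximize"]


def lbfgs_maximize(fun_grad, x0, max_iter=30, memory=8, gtol_rel=1e-4,
                   ftol_rel=1e-9, max_backtracks=30):
    """Maximize ``fun_grad(x) -> (value, grad)`` starting from ``x0``.

    ``value`` may be ``-inf`` to flag an infeasible point (gradient ignored);
    ``x0`` itself must be feasible.  Returns ``(x, value, n_iter)``.
    """
    x = np.asarray(x0, dtype=float).copy()
    shape = x.shape
    f, g = fun_grad(x)
    if not np.isfinite(f):
        raise ValueError("initial point infeasible")
    g = g.ravel().copy()
    x = x.ravel()
    g0_norm = np.linalg.norm(g)
    if g0_norm == 0:
        return x.reshape(shape), f, 0

    s_list, y_list, rho_list = [], [], []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gnorm = np.linalg.norm(g)
        if gnorm <= gtol_rel * g0_norm:
            break
        # two-loop recursion on the ascent direction
        q = g.copy()
        alphas = []
        for s, y, rho in zip(reversed(s_list), reversed(y_list),
                             reversed(rho_list)):
            a = rho * s.dot(q)
            alphas.append(a)
            q -= a * y
        if y_list:
            gamma = s_list[-1].dot(y_list[-1]) / y_list[-1].dot(y_list[-1])
            q *= gamma
        else:
            q /= max(np.linalg.norm(q), 1e-12)  # unit first step
        for (s, y, rho), a in zip(zip(s_list, y_list, rho_list),
                                  reversed(alphas)):
            b = rho * y.dot(q)
            q += (a - b) * s
        direction = q
        slope = g.dot(direction)
        if slope <= 0:  # not an ascent direction; fall back to gradient
            direction = g.copy()
            slope = g.dot(direction)

        step = 1.0
        accepted = False
        for _ in range(max_backtracks):
            x_new = x + step * direction
            f_new, g_new = fun_grad(x_new.reshape(shape))
            if np.isfinite(f_new) and f_new >= f + 1e-4 * step * slope:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        g_new = g_new.ravel()
        s_vec = x_new - x
        y_vec = g - g_new  # note: ascent; y is the *decrease* of gradient
        sy = s_vec.dot(y_vec)
        if sy > 1e-12 * np.linalg.norm(s_vec) * np.linalg.norm(y_vec):
            s_list.append(s_vec)
            y_list.append(y_vec)
            rho_list.append(1.0 / sy)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)
                rho_list.pop(0)
        improvement = f_new - f
        x, f, g = x_new, f_new, g_new
        if improvement <= ftol_rel * (abs(f) + 1e-12):
            break
    return x.reshape(shape), f, n_iter
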