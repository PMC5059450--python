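"""Independent numerical oracles used to validate the analytic kernels.

These deliberately avoid the closed-form solutions used by the
implementation: the birth-death propagation is integrated with an
adaptive ODE solver, and the DCCA coefficient is accumulated by direct
window-by-window summation with per-window polynomial fits.
"""

from __future__ import annotations

import math

import numpy as np

from .shiftbd import ShiftConfig, TreeIndex


def ode_loglik(index: TreeIndex, config: ShiftConfig) -> float:
    """Reconstructed-process log-likelihood via numerical integration.

    Same tip conditions, node joins and survival conditioning as
    :func:`paleodiv.shiftbd.bd_loglik`, but every branch segment is
    integrated with ``scipy.integrate.solve_ivp`` at tight tolerance.
    """
    from scipy.integrate import solve_ivp

    by_branch: dict[int, list] = {}
    for s in config.shifts:
        by_branch.setdefault(s.node, []).append(s)
    for lst in by_branch.values():
        lst.sort(key=lambda s: s.age)
    r_bottom = [None] * index.n
    stack = [index.root]
    while stack:
        v = stack.pop()
        if v == index.root:
            r_bottom[v] = config.root_regime
        else:
            br = by_branch.get(v)
            r_bottom[v] = br[0].regime if br else r_bottom[index.parent[v]]
        stack.extend(index.children[v])

    def integrate(e0, logd0, lam, mu, t0, t1):
        if t1 - t0 <= 0:
            return e0, logd0

        def rhs(_, y):
            e, d = y
            return [mu - (lam + mu) * e + lam * e * e,
                    -(lam + mu) * d + 2 * lam * e * d]

        sol = solve_ivp(rhs, (t0, t1), [e0, 1.0], rtol=1e-10, atol=1e-12)
        return sol.y[0][-1], logd0 + math.log(sol.y[1][-1])

    e_arr = [0.0] * index.n
    d_arr = [0.0] * index.n
    for v in range(index.n):
        if index.is_tip[v]:
            e, logd = 1.0 - index.f[v], math.log(index.f[v])
        else:
            c0, c1 = index.children[v]
            e = e_arr[c0]
            logd = d_arr[c0] + d_arr[c1] + math.log(r_bottom[v].lam)
        if v == index.root:
            return logd - 2.0 * math.log(1.0 - e)
        t = index.age[v]
        lam, mu = r_bottom[v].lam, r_bottom[v].mu
        br = by_branch.get(v, [])
        for k, s in enumerate(br):
            e, logd = integrate(e, logd, lam, mu, t, s.age)
            t = s.age
            nxt = br[k + 1].regime if k + 1 < len(br) else r_bottom[index.parent[v]]
            lam, mu = nxt.lam, nxt.mu
        e, logd = integrate(e, logd, lam, mu, t, index.age[index.parent[v]])
        e_arr[v], d_arr[v] = e, logd


def dcca_direct(x: np.ndarray, y: np.ndarray, s: int) -> float:
    """Direct-summation DCCA: explicit loops and per-window polyfits."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    px = np.cumsum(x - x.mean())
    py = np.cumsum(y - y.mean())
    t = np.arange(s + 1, dtype=float)
    fxy, fxx, fyy = [], [], []
    for i in range(len(x) - s):
        wx, wy = px[i:i + s + 1], py[i:i + s + 1]
        rx = wx - np.polyval(np.polyfit(t, wx, 1), t)
        ry = wy - np.polyval(np.polyfit(t, wy, 1), t)
        fxy.append(np.mean(rx * ry))
        fxx.append(np.mean(rx * rx))
        fyy.append(np.mean(ry * ry))
    return float(np.mean(fxy) / math.sqrt(np.mean(fxx) * np.mean(fyy)))
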