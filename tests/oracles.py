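"""Independent reference implementations used only to cross-check tests.

These deliberately share no code path with the package: the ROF oracle is
Chambolle's dual projection algorithm (not PDHG), and the ISODATA oracle is
a brute-force scan over all candidate thresholds for fixed points of the
class-mean-midpoint update.
"""

from __future__ import annotations

import numpy as np


def _grad(u):
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _div(px, py):
    d = np.zeros_like(px)
    d[0, :] += px[0, :]
    d[1:-1, :] += px[1:-1, :] - px[:-2, :]
    d[-1, :] -= px[-2, :]
    d[:, 0] += py[:, 0]
    d[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    d[:, -1] -= py[:, -2]
    return d


def rof_chambolle(f: np.ndarray, lam: float, n_iter: int = 6000, tau: float = 0.248) -> np.ndarray:
    """Chambolle's projection algorithm for the dual ROF problem.

    Fixed-point iteration on the dual field p with |p| <= 1; the primal
    solution is ``f - lam * div(p)``. Run long enough this converges to the
    exact ROF minimizer for the same forward-difference discretization.
    """
    f = np.asarray(f, dtype=float)
    px = np.zeros_like(f)
    py = np.zeros_like(f)
    for _ in range(n_iter):
        gx, gy = _grad(_div(px, py) - f / lam)
        den = 1.0 + tau * np.hypot(gx, gy)
        px = (px + tau * gx) / den
        py = (py + tau * gy) / den
    return f - lam * _div(px, py)


def isodata_fixed_points(values: np.ndarray) -> list[float]:
    """All fixed points of the ISODATA update found by brute-force scan.

    The class-mean-midpoint update depends on a threshold only through the
    partition it induces, so it suffices to scan one candidate per distinct
    partition (midpoints between consecutive unique values plus the
    extremes). A candidate whose updated threshold induces the same
    partition is a fixed point: re-applying the update there changes
    nothing. The updated value itself is returned.
    """
    values = np.asarray(values, dtype=float).ravel()
    uniq = np.unique(values)
    candidates = list((uniq[:-1] + uniq[1:]) / 2.0) + list(uniq)
    fixed = []
    for t in candidates:
        fg = values[values < t]
        bg = values[values >= t]
        if fg.size == 0 or bg.size == 0:
            continue
        t_new = (fg.mean() + bg.mean()) / 2.0
        if np.array_equal(values < t, values < t_new):
            fixed.append(float(t_new))
    return sorted(set(fixed))
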