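"""Rudin-Osher-Fatemi (ROF) total-variation denoising via primal-dual hybrid gradient.

The ROF model approximates a grayscale image ``f`` by the minimizer of

    E(u) = lam * ||u||_TV + 1/2 * sum((f - u)^2)

where ``||u||_TV`` is the discrete isotropic total variation.  Minimizing E
removes fine-scale detail (wires, leads, rib texture) while preserving the
sharp, large-scale boundaries of the lung fields — unlike Gaussian blurring,
which degrades edges indiscriminately.

The saddle-point form is solved with a primal-dual hybrid gradient (PDHG)
iteration with fixed step sizes.  The discrete gradient uses forward
differences with replicate (Neumann) boundary conditions; its operator norm
squared is bounded by 8, so the step-size product ``tau * sigma * 8 <= 1``
guarantees convergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TVParams", "DenoiseTrace", "tv_seminorm", "rof_energy", "denoise_pdhg"]

# Squared operator norm of the forward-difference gradient.
_L2 = 8.0


@dataclass
class TVParams:
    """Parameters of the PDHG solver for the ROF problem.

    lam
        Regularization weight λ; larger values remove more detail.  The
        default 0.12 (for intensities in [0, 1] at a 512-px working height)
        is the smallest value that reliably diffuses ~3-px-wide wires.
    max_iter
        Iteration cap.
    rel_tol
        Stop when the relative change ``||u_k - u_{k-1}|| / ||u_{k-1}||``
        falls below this value.
    tau, sigma
        Primal and dual step sizes; must satisfy ``tau * sigma * 8 <= 1``.
    """

    lam: float = 0.12
    max_iter: int = 300
    rel_tol: float = 1e-4
    tau: float = 1.0 / math.sqrt(_L2)
    sigma: float = 1.0 / math.sqrt(_L2)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.tau * self.sigma * _L2 > 1.0 + 1e-12:
            raise ValueError(
                f"step sizes violate tau*sigma*8 <= 1: {self.tau * self.sigma * _L2:.4f}"
            )


@dataclass
class DenoiseTrace:
    """Record of a PDHG run: per-iteration ROF energies and termination info."""

    energies: list[float] = field(default_factory=list)
    iterations_run: int = 0
    converged: bool = False


def _grad(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference gradient with replicate boundary (zero at last row/col)."""
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _div(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Discrete divergence, the negative adjoint of :func:`_grad`."""
    d = np.zeros_like(px)
    d[0, :] += px[0, :]
    d[1:-1, :] += px[1:-1, :] - px[:-2, :]
    d[-1, :] -= px[-2, :]
    d[:, 0] += py[:, 0]
    d[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    d[:, -1] -= py[:, -2]
    return d


def tv_seminorm(u: np.ndarray) -> float:
    """Discrete isotropic total variation of ``u``.

    Sum over pixels of the Euclidean norm of the forward-difference gradient
    (replicate boundary).  Zero iff ``u`` is constant.
    """
    u = np.asarray(u, dtype=float)
    gx, gy = _grad(u)
    return float(np.sum(np.hypot(gx, gy)))


def rof_energy(u: np.ndarray, f: np.ndarray, lam: float) -> float:
    """ROF objective ``lam * TV(u) + 1/2 * sum((f - u)^2)``."""
    u = np.asarray(u, dtype=float)
    f = np.asarray(f, dtype=float)
    if u.shape != f.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs f {f.shape}")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    return lam * tv_seminorm(u) + 0.5 * float(np.sum((f - u) ** 2))


def denoise_pdhg(f: np.ndarray, params: TVParams | None = None) -> tuple[np.ndarray, DenoiseTrace]:
    """Approximately minimize the ROF energy with a PDHG iteration.

    The dual variable is the vector field p with ``|p| <= lam`` pointwise;
    each iteration ascends the dual (gradient step + projection onto the
    lam-ball), descends the primal (proximal step of the quadratic fidelity),
    and over-relaxes the primal iterate.  Deterministic: the primal is
    initialized to ``f`` and the dual to zero.

    Returns the denoised image clipped to [0, 1] and a :class:`DenoiseTrace`
    with the energy history.
    """
    if params is None:
        params = TVParams()
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("input image contains non-finite values")

    lam, tau, sigma = params.lam, params.tau, params.sigma
    u = f.copy()
    u_bar = u.copy()
    px = np.zeros_like(f)
    py = np.zeros_like(f)

    trace = DenoiseTrace(energies=[rof_energy(u, f, lam)])
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        gx, gy = _grad(u_bar)
        px += sigma * gx
        py += sigma * gy
        norm = np.maximum(1.0, np.hypot(px, py) / lam)
        px /= norm
        py /= norm

        u_prev = u
        u = (u_prev + tau * (_div(px, py) + f)) / (1.0 + tau)
        u_bar = 2.0 * u - u_prev

        trace.energies.append(rof_energy(u, f, lam))
        denom = np.linalg.norm(u_prev)
        delta = np.linalg.norm(u - u_prev) / denom if denom > 0 else np.linalg.norm(u - u_prev)
        if delta < params.rel_tol:
            converged = True
            break

    trace.iterations_run = it
    trace.converged = converged
    return np.clip(u, 0.0, 1.0), trace
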