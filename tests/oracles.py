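"""Independent slow oracles used to validate the sparse stationary solver.

These deliberately avoid the package's solver path: Jacobi relaxation and
explicit-Euler time stepping iterate the stencil directly on dense arrays,
and the 1D strip profile is the closed form of the two-term recurrence.
"""

from __future__ import annotations

import numpy as np


def _stencil_sum(u: np.ndarray) -> np.ndarray:
    """Sum of the four neighbors with zero (absorbing) ghost values."""
    s = np.zeros_like(u)
    s[1:, :] += u[:-1, :]
    s[:-1, :] += u[1:, :]
    s[:, 1:] += u[:, :-1]
    s[:, :-1] += u[:, 1:]
    return s


def jacobi_solve(
    source_mask: np.ndarray,
    source_values: np.ndarray,
    D: float,
    gamma: float,
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Jacobi relaxation of the stationary stencil equations to convergence."""
    u = np.where(source_mask, source_values, 0.0).astype(np.float64)
    denom = 4.0 * D + gamma
    for _ in range(max_iter):
        new = _stencil_sum(u) * D / denom
        new[source_mask] = source_values[source_mask]
        delta = np.abs(new - u).max()
        u = new
        if delta < tol:
            return u
    raise RuntimeError(f"Jacobi did not converge below {tol} in {max_iter} iterations")


def euler_steady_state(
    source_mask: np.ndarray,
    source_values: np.ndarray,
    D: float,
    gamma: float,
    dt: float | None = None,
    tol: float = 1e-13,
    max_steps: int = 500_000,
) -> np.ndarray:
    """Explicit-Euler time stepping of du/dt = D lap(u) - gamma u to rest."""
    if dt is None:
        dt = 0.9 / (4.0 * D + gamma)  # below the explicit stability limit
    u = np.where(source_mask, source_values, 0.0).astype(np.float64)
    for _ in range(max_steps):
        lap = _stencil_sum(u) - 4.0 * u
        new = u + dt * (D * lap - gamma * u)
        new[source_mask] = source_values[source_mask]
        delta = np.abs(new - u).max()
        u = new
        if delta < tol * dt:
            return u
    raise RuntimeError("explicit Euler did not reach steady state")


def strip_profile_closed_form(
    n: int, source_index: int, value: float, D: float, gamma: float
) -> np.ndarray:
    """Closed form of D (u_{k+1} - 2 u_k + u_{k-1}) = gamma u_k on a 1D lattice.

    Dirichlet-0 ghost sites at k = -1 and k = n; u pinned to ``value`` at
    ``source_index``. The homogeneous solution is a combination of lambda**k
    and lambda**-k with lambda + 1/lambda = 2 + gamma/D; imposing u(-1) = 0
    on the left segment and u(n) = 0 on the right gives ratios of sinh-like
    differences.
    """
    g = gamma / D
    lam = 1.0 + g / 2.0 + np.sqrt(g + g * g / 4.0)

    def f(k: np.ndarray) -> np.ndarray:  # vanishes at k = -1
        return lam ** (k + 1.0) - lam ** -(k + 1.0)

    def h(k: np.ndarray) -> np.ndarray:  # vanishes at k = n
        return lam ** (n - k + 0.0) - lam ** -(n - k + 0.0)

    k = np.arange(n, dtype=np.float64)
    u = np.empty(n)
    left = k <= source_index
    u[left] = value * f(k[left]) / f(np.float64(source_index))
    u[~left] = value * h(k[~left]) / h(np.float64(source_index))
    return u
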