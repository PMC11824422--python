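"""Diffusion engine for expected folded site-frequency spectra.

Solves the one-locus Wright-Fisher diffusion forward in time on a
frequency grid for a piecewise-constant population-size history with
genic selection, and integrates the resulting allele-frequency density
against binomial sampling weights to obtain the expected SFS of a
sample of ``n`` haplotypes.

Conventions
-----------
* Time is measured in units of ``2 * N_anc`` generations.
* ``theta = 4 * N_anc * mu * L``; all spectra returned here are per
  unit theta (multiply by a fitted theta to get absolute counts).
* ``gamma = 2 * N_anc * s`` where ``s`` is the selective (dis)advantage
  of the derived allele in a haploid carrier.  Deleterious mutations
  have ``gamma < 0``.

The density ``phi(x, t)`` obeys

    d(phi)/dt = -d(M phi)/dx + (1/2) d^2(V phi)/dx^2

with ``M = gamma * x * (1 - x)`` and ``V = x * (1 - x) / nu`` where
``nu`` is the population size relative to the ancestral size.  New
mutations are injected near ``x = 0`` at a rate calibrated so that the
neutral equilibrium density is exactly ``1/x`` per unit theta.

Spatial discretization is a Chang-Cooper (exponentially fitted) finite
volume scheme; because ``M/V = gamma * nu`` is constant in ``x`` the
scheme represents equilibria of the continuous problem exactly on the
grid.  Results are computed on three grids of increasing size and
Richardson-extrapolated to zero spacing.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import gammaln

__all__ = [
    "expected_folded_sfs",
    "expected_unfolded_sfs",
    "fold",
    "default_pts",
    "EngineError",
]


class EngineError(RuntimeError):
    """Raised when the diffusion solve produces non-finite output."""


def default_pts(n: int) -> tuple[int, int, int]:
    """Three grid sizes for extrapolation; the largest is >= 8 * n."""
    base = max(100, 8 * n)
    return (base, base + 40, base + 80)


@lru_cache(maxsize=64)
def _grid(pts: int, crowding: float = 0.9) -> np.ndarray:
    """Frequency grid on [0, 1], denser near the boundaries."""
    u = np.linspace(0.0, 1.0, pts)
    return u - crowding * np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _delta(w: np.ndarray) -> np.ndarray:
    """Chang-Cooper weights 1/w - 1/(e^w - 1), stable near w = 0."""
    out = np.empty_like(w)
    small = np.abs(w) < 1e-8
    out[small] = 0.5 - w[small] / 12.0
    ws = w[~small]
    out[~small] = 1.0 / ws - 1.0 / np.expm1(ws)
    return out


def _operator(x: np.ndarray, nu: float, gamma: float):
    """Tridiagonal generator acting on phi at interior nodes.

    Returns (lower, diag, upper, source) where source is the constant
    mutation influx (per unit theta) into each interior cell.
    """
    h = np.diff(x)                      # edge widths, len P-1
    cell = 0.5 * (x[2:] - x[:-2])       # interior cell widths, len P-2
    V = x * (1.0 - x) / nu
    r = 2.0 * gamma * nu                # 2 M / V, constant in x
    w = r * h
    dlt = _delta(w)
    # Flux across edge j+1/2:  J = P_j * psi_j - Q_j * psi_{j+1},  psi = V phi
    P = 0.5 * r * (1.0 - dlt) + 0.5 / h
    Q = 0.5 / h - 0.5 * r * dlt

    # d(phi_j)/dt = [ P_{j-1} V_{j-1} phi_{j-1}
    #                 - (Q_{j-1} + P_j) V_j phi_j
    #                 + Q_j V_{j+1} phi_{j+1} ] / cell_j
    lower = P[:-1] * V[:-2] / cell      # coeff on phi_{j-1}
    diag = -(Q[:-1] + P[1:]) * V[1:-1] / cell
    upper = Q[1:] * V[2:] / cell        # coeff on phi_{j+1}
    # psi vanishes at both boundaries (V(0) = V(1) = 0), so the first
    # lower and last upper coefficients are inert; zero them for safety.
    lower[0] = 0.0
    upper[-1] = 0.0

    source = np.zeros_like(diag)
    source[0] = 0.5 / (x[1] * cell[0])  # calibrated: neutral equilibrium = 1/x
    return lower, diag, upper, source


def _banded(lower, diag, upper, a: float, b: float) -> np.ndarray:
    """Banded form of (a * I + b * A) for scipy.linalg.solve_banded."""
    m = diag.size
    ab = np.zeros((3, m))
    ab[0, 1:] = b * upper[:-1]
    ab[1, :] = a + b * diag
    ab[2, :-1] = b * lower[1:]
    return ab


def _equilibrium(x: np.ndarray, nu: float, gamma: float) -> np.ndarray:
    lower, diag, upper, source = _operator(x, nu, gamma)
    ab = _banded(lower, diag, upper, 0.0, 1.0)
    phi = solve_banded((1, 1), ab, -source)
    return phi


def _integrate_epoch(phi: np.ndarray, x: np.ndarray, nu: float, gamma: float,
                     duration: float) -> np.ndarray:
    """Advance interior density phi for `duration` under size nu.

    Crank-Nicolson with a few initial implicit-Euler (Rannacher) steps
    to damp oscillations from the discontinuous coefficient change.
    """
    if duration <= 0:
        return phi
    lower, diag, upper, source = _operator(x, nu, gamma)
    nsteps = int(np.clip(np.ceil(duration / 1e-3), 30, 400))
    dt = duration / nsteps
    n_rannacher = min(2, nsteps)

    ab_be = _banded(lower, diag, upper, 1.0, -dt)
    for _ in range(n_rannacher):
        phi = solve_banded((1, 1), ab_be, phi + dt * source)

    remaining = nsteps - n_rannacher
    if remaining > 0:
        ab_cn = _banded(lower, diag, upper, 1.0, -0.5 * dt)
        A_lo, A_di, A_up = lower, diag, upper
        for _ in range(remaining):
            rhs = phi + 0.5 * dt * (
                A_di * phi
                + np.concatenate(([0.0], A_lo[1:] * phi[:-1]))
                + np.concatenate((A_up[:-1] * phi[1:], [0.0]))
            ) + dt * source
            phi = solve_banded((1, 1), ab_cn, rhs)
    return phi


def _phi_to_sfs(phi_int: np.ndarray, x: np.ndarray, n: int) -> np.ndarray:
    """Expected unfolded SFS entries i = 1..n-1 from the interior density."""
    xi = x[1:-1]
    i = np.arange(1, n)
    logw = (
        gammaln(n + 1) - gammaln(i + 1)[:, None] - gammaln(n - i + 1)[:, None]
        + i[:, None] * np.log(xi)[None, :]
        + (n - i)[:, None] * np.log1p(-xi)[None, :]
    )
    g = np.exp(logw) * phi_int[None, :]           # integrand at interior nodes
    # Boundary limits: x * phi is finite at 0 (-> contributes to i = 1 only),
    # (1 - x) * phi finite at 1 (-> i = n - 1 only).
    g0 = np.zeros(n - 1)
    g0[0] = n * (x[1] * phi_int[0])
    g1 = np.zeros(n - 1)
    g1[-1] = n * ((1.0 - x[-2]) * phi_int[-1])
    full = np.column_stack([g0, g, g1])
    return np.trapezoid(full, x, axis=1)


def fold(unfolded: np.ndarray) -> np.ndarray:
    """Fold an unfolded spectrum X_1..X_{n-1} to minor-allele bins 1..n//2."""
    n = unfolded.size + 1
    half = n // 2
    out = np.zeros(half)
    for i in range(1, half + 1):
        if i == n - i:
            out[i - 1] = unfolded[i - 1]
        else:
            out[i - 1] = unfolded[i - 1] + unfolded[n - i - 1]
    return out


def _single_grid_sfs(epochs: tuple, durations: tuple, gamma: float,
                     n: int, pts: int) -> np.ndarray:
    x = _grid(pts)
    phi = _equilibrium(x, epochs[0], gamma)
    for nu, dur in zip(epochs[1:], durations):
        phi = _integrate_epoch(phi, x, nu, gamma, dur)
    return _phi_to_sfs(phi, x, n)


def expected_unfolded_sfs(epochs, change_times, gamma: float, n: int,
                          pts=None) -> np.ndarray:
    """Expected unfolded SFS per unit theta.

    Parameters
    ----------
    epochs : sequence of relative sizes, oldest first; epochs[0] must be 1.
    change_times : times before present (units of 2 N_anc generations) of
        each size change, strictly decreasing, one per epoch after the first.
    gamma : scaled selection coefficient 2 * N_anc * s (<= 0).
    n : sample size in haplotypes.
    pts : three grid sizes for Richardson extrapolation.
    """
    epochs = tuple(float(e) for e in epochs)
    change_times = tuple(float(t) for t in change_times)
    if len(change_times) != len(epochs) - 1:
        raise ValueError("need one change time per epoch after the first")
    if any(e <= 0 for e in epochs):
        raise ValueError("relative sizes must be positive")
    if abs(epochs[0] - 1.0) > 1e-12:
        raise ValueError("ancestral epoch must have relative size 1")
    if any(t2 >= t1 for t1, t2 in zip(change_times, change_times[1:])):
        raise ValueError("change times must strictly decrease toward present")
    if n < 2:
        raise ValueError("need n >= 2 haplotypes")
    # Convert times-before-present to epoch durations.
    durations = tuple(
        t - (change_times[k + 1] if k + 1 < len(change_times) else 0.0)
        for k, t in enumerate(change_times)
    )
    if pts is None:
        pts = default_pts(n)
    pts = tuple(int(p) for p in pts)

    values = [_single_grid_sfs(epochs, durations, gamma, n, p) for p in pts]
    hs = [_grid(p)[1] for p in pts]
    result = _richardson(values, hs)
    if not np.all(np.isfinite(result)):
        raise EngineError(
            f"non-finite spectrum (epochs={epochs}, times={change_times}, "
            f"gamma={gamma}, pts={pts})"
        )
    # Extrapolation can produce slightly negative entries for tiny bins.
    return np.maximum(result, 0.0)


def _richardson(values, hs) -> np.ndarray:
    """Quadratic extrapolation to h = 0 through three (h, value) pairs."""
    out = np.zeros_like(values[0])
    for i, (hi, vi) in enumerate(zip(hs, values)):
        w = 1.0
        for j, hj in enumerate(hs):
            if j != i:
                w *= (0.0 - hj) / (hi - hj)
        out = out + w * vi
    return out


def expected_folded_sfs(epochs, change_times, gamma: float, n: int,
                        pts=None) -> np.ndarray:
    """Expected folded SFS (bins 1..n//2) per unit theta."""
    return fold(expected_unfolded_sfs(epochs, change_times, gamma, n, pts))
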