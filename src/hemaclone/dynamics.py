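"""Deterministic time integration of the mean-field clone-count equations.

The expected number ``c_k(t)`` of clones represented by exactly ``k``
progenitor cells obeys a birth-death-immigration ladder,

    dc_k/dt = alpha*(c_{k-1} - c_k) + r*[(k-1) c_{k-1} - k c_k]
              + mu*[(k+1) c_{k+1} - k c_k],

with the growth rate ``r = r(N_p)`` evaluated from the instantaneous total
progenitor population ``N_p = u + sum_k k c_k`` (plus tracked tail cells) and
``u`` the unlabeled progenitor population.  The ladder is truncated at
``k_max`` with an absorbing tail accumulator so that clone number is
conserved exactly; integration uses stiff adaptive error control.

This module is the numerical oracle for the closed-form stationary laws in
:mod:`hemaclone.steady_state`: the negative-binomial fixed point must make
the right-hand side vanish, and long-time integration must converge to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import nbinom

from .steady_state import ModelParams, growth_rate

__all__ = ["TruncatedCloneState", "default_k_max", "rhs", "integrate",
           "initial_empty", "stationary_state"]


@dataclass
class TruncatedCloneState:
    """Clone-resolved mean-field state at one instant.

    ``c[k]`` for k = 0..k_max are expected clone counts (``c[0]`` counts
    clones absent from the progenitor pool); ``tail_clones``/``tail_cells``
    accumulate flux absorbed above the truncation.
    """

    t: float
    c: np.ndarray
    u: float
    N_d: float
    tail_clones: float = 0.0
    tail_cells: float = 0.0

    @property
    def k_max(self) -> int:
        return self.c.size - 1

    @property
    def N_p(self) -> float:
        k = np.arange(self.c.size)
        return float(self.u + np.dot(k, self.c) + self.tail_cells)

    @property
    def total_clones(self) -> float:
        return float(self.c.sum() + self.tail_clones)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.c, [self.u, self.N_d,
                                        self.tail_clones, self.tail_cells]])

    @classmethod
    def unpack(cls, t: float, y: np.ndarray) -> "TruncatedCloneState":
        return cls(t=t, c=y[:-4].copy(), u=float(y[-4]), N_d=float(y[-3]),
                   tail_clones=float(y[-2]), tail_cells=float(y[-1]))


def default_k_max(a: float, rbar: float, tail_tol: float = 1e-12,
                  safety: float = 4.0) -> int:
    """Smallest k with stationary NB tail mass below ``tail_tol``, times a
    safety factor for transients (the front of the relaxing distribution is
    broader than the stationary law)."""
    k_star = int(nbinom.isf(tail_tol, a, 1.0 - rbar)) + 1
    return int(safety * k_star) + 2


def initial_empty(params: ModelParams, k_max: int) -> TruncatedCloneState:
    """Post-transplant initial condition: every clone present as one HSC,
    empty progenitor and differentiated pools."""
    c = np.zeros(k_max + 1)
    c[0] = params.C
    return TruncatedCloneState(t=0.0, c=c, u=0.0, N_d=0.0)


def stationary_state(params: ModelParams, k_max: int) -> TruncatedCloneState:
    """Closed-form fixed point: c = C * NB(a, rbar), u and N_d at balance."""
    from .steady_state import steady_state_Np, progenitor_clone_dist
    Np_star, rbar, _ = steady_state_Np(params)
    r = growth_rate(Np_star, params.p, params.K)
    a = params.alpha / r
    P = progenitor_clone_dist(a, rbar, k_max=k_max)
    c = params.C * P.values
    # u* solves (r - mu) u + alpha U = 0
    u = params.alpha * params.U / (params.mu - r) if params.U > 0 else 0.0
    N_d = params.w * Np_star
    return TruncatedCloneState(t=0.0, c=c, u=float(u), N_d=float(N_d))


def _rhs_vec(y: np.ndarray, params: ModelParams) -> np.ndarray:
    c = y[:-4]
    u, N_d = y[-4], y[-3]
    tail_cells = y[-1]
    k_max = c.size - 1
    k = np.arange(k_max + 1)
    N_p = u + np.dot(k, c) + tail_cells
    r = growth_rate(N_p, params.p, params.K)
    mu = params.mu
    alpha = params.alpha

    dc = np.zeros_like(c)
    # immigration (HSC differentiation)
    dc[1:] += alpha * c[:-1]
    dc -= alpha * c
    # progenitor birth
    dc[1:] += r * k[:-1] * c[:-1]
    dc -= r * k * c
    # progenitor death
    dc[:-1] += mu * k[1:] * c[1:]
    dc -= mu * k * c
    # absorbing boundary: flux out of k_max feeds the tail accumulator
    out_flux = (alpha + r * k_max) * c[k_max]
    d_tail_clones = out_flux
    d_tail_cells = (k_max + 1) * out_flux
    du = (r - mu) * u + alpha * params.U
    dNd = (1.0 + params.eta) * params.omega * N_p - params.mu_d * N_d
    return np.concatenate([dc, [du, dNd, d_tail_clones, d_tail_cells]])


def rhs(state: TruncatedCloneState, params: ModelParams) -> TruncatedCloneState:
    """Time derivative of a truncated clone state (same container, dotted)."""
    if state.k_max < 2:
        raise ValueError("k_max must be >= 2")
    dy = _rhs_vec(state.pack(), params)
    return TruncatedCloneState.unpack(state.t, dy)


def integrate(state0: TruncatedCloneState, params: ModelParams,
              t_grid, k_max: int | None = None, rtol: float = 1e-8,
              atol: float = 1e-12, tail_tol: float = 1e-6,
              method: str = "BDF") -> list[TruncatedCloneState]:
    """Integrate the truncated system over an increasing time grid.

    Raises if the integrator fails (reporting the failing time) or if the
    absorbed tail mass grows beyond ``tail_tol`` (signalling that ``k_max``
    is too small for the requested horizon).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if k_max is not None and k_max != state0.k_max:
        c = np.zeros(k_max + 1)
        n = min(c.size, state0.c.size)
        c[:n] = state0.c[:n]
        state0 = TruncatedCloneState(state0.t, c, state0.u, state0.N_d,
                                     state0.tail_clones, state0.tail_cells)
    y0 = state0.pack()
    sol = solve_ivp(lambda _t, y: _rhs_vec(y, params),
                    (state0.t, float(t_grid[-1])), y0, t_eval=t_grid,
                    method=method, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    states = [TruncatedCloneState.unpack(t, sol.y[:, i])
              for i, t in enumerate(sol.t)]
    if states[-1].tail_clones > tail_tol * params.C:
        raise RuntimeError(
            f"absorbed tail mass {states[-1].tail_clones:.3g} exceeds tolerance; "
            "increase k_max")
    return states
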