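"""Exact stationary law of a single marked lineage, by direct linear solve.

The closed forms in :mod:`hemaclone.steady_state` use the mean-field
peripheral law — differentiated counts Poisson around ``w*k`` given the
*current* progenitor count ``k`` — which assumes ``k`` is quasi-static over
the peripheral relaxation time ``1/mu_d``.  For small clones and slow
peripheral turnover that approximation is visibly imperfect.  This module
computes the exact stationary joint distribution of one lineage's
(progenitor, differentiated) cell counts from the master equation of the
continuous-time Markov process (immigration ``alpha``, birth ``r k``, death
``mu_p k``, symmetric/asymmetric terminal differentiation ``eta omega k`` /
``(1-eta) omega k``, peripheral death ``mu_d n``) at a fixed growth rate
``r``, by solving the stationary linear system on a truncated (k, n) grid.

It is the reference against which both the stochastic simulator and the
mean-field laws are validated.  The growth rate is frozen at its mean-field
steady-state value, so cross-clone fluctuations of ``r`` through the shared
carrying capacity remain outside this oracle.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse import csr_matrix, lil_matrix
from scipy.sparse.linalg import spsolve
from scipy.stats import binom, nbinom, poisson

from .steady_state import ModelParams, SizeDistribution, growth_rate, \
    steady_state_Np

__all__ = ["joint_lineage_stationary", "lineage_read_law"]


def joint_lineage_stationary(params: ModelParams, r: float | None = None,
                             k_max: int | None = None,
                             n_max: int | None = None,
                             tail_tol: float = 1e-11) -> np.ndarray:
    """Stationary joint pmf pi[k, n] of one lineage's cell counts.

    ``r`` defaults to the mean-field steady-state growth rate.  The grid is
    truncated where the marginal laws carry less than ``tail_tol`` mass.
    """
    if r is None:
        Np_star, _, _ = steady_state_Np(params)
        r = float(growth_rate(Np_star, params.p, params.K))
    mu = params.mu
    if r >= mu:
        raise ValueError("stationarity requires r < mu for a single lineage")
    a = params.alpha / r
    rbar = r / mu
    if k_max is None:
        k_max = int(nbinom.isf(tail_tol, a, 1.0 - rbar)) + 2
    if n_max is None:
        mean_n = params.w * k_max
        n_max = int(mean_n + 12.0 * math.sqrt(mean_n + 1.0) + 20.0)

    def idx(k: int, n: int) -> int:
        return k * (n_max + 1) + n

    size = (k_max + 1) * (n_max + 1)
    Q = lil_matrix((size, size))
    alpha, mu_p = params.alpha, params.mu_p
    eta, omega, mu_d = params.eta, params.omega, params.mu_d
    for k in range(k_max + 1):
        for n in range(n_max + 1):
            i = idx(k, n)
            out = 0.0
            if k < k_max:
                w_ = alpha + r * k
                Q[i, idx(k + 1, n)] += w_
                out += w_
            if k > 0:
                Q[i, idx(k - 1, n)] += mu_p * k
                out += mu_p * k
                if eta > 0.0:
                    w_ = eta * omega * k
                    Q[i, idx(k - 1, min(n + 2, n_max))] += w_
                    out += w_
                if eta < 1.0:
                    w_ = (1.0 - eta) * omega * k
                    Q[i, idx(k, min(n + 1, n_max))] += w_
                    out += w_
            if n > 0:
                Q[i, idx(k, n - 1)] += mu_d * n
                out += mu_d * n
            Q[i, i] -= out
    A = csr_matrix(Q).T.tolil()
    A[0, :] = 1.0  # replace one balance row by normalization
    b = np.zeros(size)
    b[0] = 1.0
    pi = spsolve(csr_matrix(A), b)
    pi = np.maximum(pi.reshape(k_max + 1, n_max + 1), 0.0)
    return pi / pi.sum()


def lineage_read_law(params: ModelParams, S: float, q_max: int,
                     sampling: str = "binomial",
                     pi: np.ndarray | None = None) -> SizeDistribution:
    """Exact read-count law: eps-thinning of the joint stationary peripheral
    marginal, with ``eps = S/N_d*`` at the mean-field differentiated pool."""
    if pi is None:
        pi = joint_lineage_stationary(params)
    Np_star, _, _ = steady_state_Np(params)
    eps = S / (params.w * Np_star)
    pn = pi.sum(axis=0)
    n = np.arange(pn.size)
    q = np.arange(q_max + 1)
    if sampling == "binomial":
        kern = binom.pmf(q[:, None], n[None, :], eps)
    elif sampling == "poisson":
        kern = poisson.pmf(q[:, None], eps * n[None, :])
    else:
        raise ValueError("sampling must be 'binomial' or 'poisson'")
    values = kern @ pn
    return SizeDistribution(values, truncated_mass=max(0.0, 1.0 - values.sum()),
                            kind="lineage-exact")
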