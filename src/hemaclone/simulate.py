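"""Stochastic simulation of clonally tracked repopulation plus read sampling.

Realises the continuous-time Markov process behind the mean-field model:
``U + C`` hematopoietic stem cells each fire asymmetric differentiation
events at rate ``alpha`` (adding one progenitor to their lineage without
consuming the HSC); progenitors replicate at the shared density-dependent
rate ``r(N_p) = p*K/(N_p+K)``, die at ``mu_p``, and terminally differentiate
at ``omega`` (symmetric with probability ``eta``: the progenitor is removed
and two differentiated cells appear; otherwise the progenitor is kept and
one appears).  Differentiated cells die at ``mu_d``.  HSCs never die or
replicate.

Two integration methods are provided: an exact-event (Gillespie) kernel
compiled with numba, holding the pools as flat arrays of cell->clone labels
so that every event is O(1); and a fixed-step tau-leap scheme for large
carrying capacities, with Poisson event counts per channel and per clone and
negative-count clamping (counted and reported).

Read sampling thins each clone's differentiated count with probability
``eps = S/N_d`` (binomially, or Poisson as the analytic model assumes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .steady_state import EffectiveParams, steady_state_Np, ModelParams
from .vis_io import SizeHistogram

__all__ = ["SimConfig", "SimState", "simulate", "sample_reads",
           "sample_steady_state_reads"]

# status codes returned by the SSA kernel
_OK, _EVENT_CAP, _POOL_CAP = 0, 1, 2


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.  Rates per month; populations in cells."""

    alpha: float
    p: float
    mu_p: float
    mu_d: float
    eta: float
    omega: float
    K: float
    U: int
    C: int
    sample_times: tuple = (12.0,)
    S_per_sample: int = 1000
    f: float = 0.05
    seed: int = 0
    method: str = "exact-event"
    max_events: int = 2_000_000_000
    pool_margin: float = 6.0  # capacity as multiple of the mean-field fixed point

    def __post_init__(self) -> None:
        for name in ("alpha", "p", "mu_p", "mu_d", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.p <= self.mu_p + self.eta * self.omega:
            # the regulated regime assumes net positive low-density growth;
            # subcritical runs remain well defined (immigration-death balance)
            # and are useful for validating the K -> infinity limit
            warnings.warn(
                "p <= mu_p + eta*omega: progenitors are subcritical even at "
                "low density; the carrying capacity is then irrelevant",
                stacklevel=2)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.C < 1:
            raise ValueError("C must be >= 1")
        if self.U < 0:
            raise ValueError("U must be non-negative")
        if not 0.0 < self.f <= 1.0:
            raise ValueError("f must lie in (0, 1]")
        if self.method not in ("exact-event", "tau-leap"):
            raise ValueError("method must be 'exact-event' or 'tau-leap'")
        if len(self.sample_times) == 0 or any(
                t2 <= t1 for t1, t2 in zip(self.sample_times, self.sample_times[1:])):
            raise ValueError("sample_times must be nonempty and increasing")

    def model_params(self, S: float | None = None) -> ModelParams:
        return ModelParams(alpha=self.alpha, p=self.p, mu_p=self.mu_p,
                           mu_d=self.mu_d, eta=self.eta, omega=self.omega,
                           K=self.K, U=self.U, C=self.C,
                           S=self.S_per_sample if S is None else S)


@dataclass
class SimState:
    """Per-clone snapshot.  Index j < C are labeled clones; unlabeled cells
    are pooled in ``u_prog``/``u_diff``."""

    t: float
    n_prog: np.ndarray
    n_diff: np.ndarray
    u_prog: int
    u_diff: int
    clamped: int = 0  # tau-leap only: number of negative-count clamps

    @property
    def N_p(self) -> int:
        return int(self.u_prog + self.n_prog.sum())

    @property
    def N_d(self) -> int:
        return int(self.u_diff + self.n_diff.sum())


@njit(cache=False)
def _ssa_kernel(alpha, p, mu_p, mu_d, eta, omega, K, U, C,
                times, cap_p, cap_d, max_events, seed,
                prog_snap, diff_snap):  # pragma: no cover - compiled
    np.random.seed(seed)
    prog = np.empty(cap_p, dtype=np.int32)   # cell -> clone label (C = unlabeled)
    diff = np.empty(cap_d, dtype=np.int32)
    n_p = 0
    n_d = 0
    t = 0.0
    it = 0
    n_times = times.shape[0]
    hsc_total = float(U + C)
    events = 0
    while True:
        r = p * K / (n_p + K)
        a_hsc = alpha * hsc_total
        a_birth = r * n_p
        a_pdeath = mu_p * n_p
        a_tdiff = omega * n_p
        a_ddeath = mu_d * n_d
        a_tot = a_hsc + a_birth + a_pdeath + a_tdiff + a_ddeath
        if a_tot <= 0.0:
            t = times[n_times - 1] + 1.0
        else:
            t += -math.log(np.random.random()) / a_tot
        while it < n_times and t > times[it]:
            for i in range(n_p):
                prog_snap[it, prog[i]] += 1
            for i in range(n_d):
                diff_snap[it, diff[i]] += 1
            it += 1
        if it >= n_times:
            return _OK
        u = np.random.random() * a_tot
        if u < a_hsc:
            hsc = int(np.random.random() * hsc_total)
            clone = hsc if hsc < C else C
            if n_p >= cap_p:
                return _POOL_CAP
            prog[n_p] = clone
            n_p += 1
        elif u < a_hsc + a_birth:
            idx = int(np.random.random() * n_p)
            if n_p >= cap_p:
                return _POOL_CAP
            prog[n_p] = prog[idx]
            n_p += 1
        elif u < a_hsc + a_birth + a_pdeath:
            idx = int(np.random.random() * n_p)
            prog[idx] = prog[n_p - 1]
            n_p -= 1
        elif u < a_hsc + a_birth + a_pdeath + a_tdiff:
            idx = int(np.random.random() * n_p)
            clone = prog[idx]
            if np.random.random() < eta:
                prog[idx] = prog[n_p - 1]
                n_p -= 1
                if n_d + 2 > cap_d:
                    return _POOL_CAP
                diff[n_d] = clone
                diff[n_d + 1] = clone
                n_d += 2
            else:
                if n_d >= cap_d:
                    return _POOL_CAP
                diff[n_d] = clone
                n_d += 1
        else:
            idx = int(np.random.random() * n_d)
            diff[idx] = diff[n_d - 1]
            n_d -= 1
        events += 1
        if events >= max_events:
            return _EVENT_CAP


def _pool_caps(config: SimConfig) -> tuple[int, int]:
    params = config.model_params()
    try:
        Np_star, _, _ = steady_state_Np(params)
    except ValueError:
        Np_star = config.K
    cap_p = int(config.pool_margin * Np_star + 10 * config.C + 1000)
    w = params.w if config.mu_d > 0 else 10.0
    cap_d = int(config.pool_margin * max(w, 1.0) * Np_star + 10 * config.C + 1000)
    return cap_p, cap_d


def _simulate_exact(config: SimConfig) -> list[SimState]:
    times = np.asarray(config.sample_times, dtype=np.float64)
    cap_p, cap_d = _pool_caps(config)
    prog_snap = np.zeros((times.size, config.C + 1), dtype=np.int64)
    diff_snap = np.zeros((times.size, config.C + 1), dtype=np.int64)
    status = _ssa_kernel(config.alpha, config.p, config.mu_p, config.mu_d,
                         config.eta, config.omega, float(config.K),
                         config.U, config.C, times, cap_p, cap_d,
                         config.max_events, config.seed % (2 ** 32),
                         prog_snap, diff_snap)
    if status == _EVENT_CAP:
        raise RuntimeError(
            f"event cap {config.max_events} exceeded; K is inconsistent with "
            "the exact-event method (use tau-leap or a smaller system)")
    if status == _POOL_CAP:
        raise RuntimeError("cell pool capacity exceeded: runaway growth")
    states = []
    for i, t in enumerate(times):
        states.append(SimState(t=float(t),
                               n_prog=prog_snap[i, :config.C].copy(),
                               n_diff=diff_snap[i, :config.C].copy(),
                               u_prog=int(prog_snap[i, config.C]),
                               u_diff=int(diff_snap[i, config.C])))
    return states


def _simulate_tau_leap(config: SimConfig) -> list[SimState]:
    rng = np.random.default_rng(config.seed)
    per_cell = max(config.p, config.mu_p, config.omega, config.mu_d, config.alpha)
    dt = 0.05 / per_cell
    # slot C pools the unlabeled lineage (U HSCs feed it)
    n_prog = np.zeros(config.C + 1, dtype=np.int64)
    n_diff = np.zeros(config.C + 1, dtype=np.int64)
    hsc = np.ones(config.C + 1, dtype=np.float64)
    hsc[config.C] = config.U
    t = 0.0
    clamped = 0
    out: list[SimState] = []
    times = list(config.sample_times)
    it = 0
    t_end = times[-1]
    n_steps = int(math.ceil(t_end / dt))
    for _step in range(n_steps):
        N_p = int(n_prog.sum())
        r = config.p * config.K / (N_p + config.K)
        arr = rng.poisson(config.alpha * hsc * dt)
        births = rng.poisson(r * n_prog * dt)
        deaths = rng.poisson(config.mu_p * n_prog * dt)
        sym = rng.poisson(config.eta * config.omega * n_prog * dt)
        asym = rng.poisson((1.0 - config.eta) * config.omega * n_prog * dt)
        ddeaths = rng.poisson(config.mu_d * n_diff * dt)
        n_prog += arr + births - deaths - sym
        neg = n_prog < 0
        clamped += int(neg.sum())
        n_prog[neg] = 0
        n_diff += 2 * sym + asym - ddeaths
        neg = n_diff < 0
        clamped += int(neg.sum())
        n_diff[neg] = 0
        t += dt
        while it < len(times) and t >= times[it] - 1e-12:
            out.append(SimState(t=times[it], n_prog=n_prog[:config.C].copy(),
                                n_diff=n_diff[:config.C].copy(),
                                u_prog=int(n_prog[config.C]),
                                u_diff=int(n_diff[config.C]),
                                clamped=clamped))
            it += 1
    while it < len(times):  # guard against rounding at the final step
        out.append(SimState(t=times[it], n_prog=n_prog[:config.C].copy(),
                            n_diff=n_diff[:config.C].copy(),
                            u_prog=int(n_prog[config.C]),
                            u_diff=int(n_diff[config.C]), clamped=clamped))
        it += 1
    return out


def simulate(config: SimConfig) -> list[SimState]:
    """Run one replicate; returns the system state at each requested time.

    Initial condition: one HSC per labeled clone plus ``U`` unlabeled HSCs,
    empty progenitor and differentiated pools (transplanted progenitors are
    ignored).  Identical config and seed give identical output.
    """
    if config.method == "exact-event":
        return _simulate_exact(config)
    return _simulate_tau_leap(config)


def sample_reads(state: SimState, S: int, f: float, mode: str = "binomial",
                 seed: int | np.random.Generator = 0,
                 animal_id: str = "sim", cell_type: str = "PBMC"
                 ) -> tuple[pd.DataFrame, dict]:
    """Sequence ``S`` marked cells from the differentiated pool.

    Each labeled clone's read count is a thinning of its differentiated-cell
    count with success probability ``eps = S/N_d(marked)`` — binomial, or
    Poisson under the analytic model's approximation.  Clones with zero reads
    are omitted.  Returns table rows and per-sample metadata (realized total
    reads and marked fraction ``f``).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    n_marked = int(state.n_diff.sum())
    if n_marked < 1:
        return (pd.DataFrame(columns=["animal_id", "cell_type", "months",
                                      "clone_id", "reads"]),
                {"animal_id": animal_id, "cell_type": cell_type,
                 "months": state.t, "S": 0, "f": f, "N_d_true": n_marked})
    eps = S / n_marked
    if eps > 1.0:
        raise ValueError(f"eps = S/N_d = {eps:.3g} > 1: cannot sample more "
                         "cells than the marked pool holds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "binomial":
        q = rng.binomial(state.n_diff, eps)
    elif mode == "poisson":
        q = rng.poisson(eps * state.n_diff)
    else:
        raise ValueError("mode must be 'binomial' or 'poisson'")
    keep = q >= 1
    clones = np.nonzero(keep)[0]
    rows = pd.DataFrame({
        "animal_id": animal_id, "cell_type": cell_type, "months": state.t,
        "clone_id": [f"clone{j:06d}" for j in clones],
        "reads": q[keep].astype(int),
    })
    meta = {"animal_id": animal_id, "cell_type": cell_type, "months": state.t,
            "S": int(q[keep].sum()), "f": f, "N_d_true": n_marked}
    return rows, meta


def sample_steady_state_reads(eff: EffectiveParams, C: int,
                              seed: int | np.random.Generator = 0
                              ) -> SizeHistogram:
    """Draw a stationary read-count histogram directly from the analytic law.

    Composes the stationary pipeline clone by clone: progenitor size
    ``k ~ NB(a, rbar)``, reads ``q ~ Poisson(eps_w * k)``; zero-read clones
    are suppressed.  This is the fast fixture generator for inference tests —
    exchangeable across clones and exactly matched to
    :func:`hemaclone.steady_state.sampled_clone_dist`.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if eff.eps_w == 0.0:
        return SizeHistogram(q=np.array([], dtype=int),
                             n_q=np.array([], dtype=int), S=0, f=1.0)
    k = rng.negative_binomial(eff.a, 1.0 - eff.rbar, size=C)
    reads = rng.poisson(eff.eps_w * k)
    reads = reads[reads >= 1]
    if reads.size == 0:
        return SizeHistogram(q=np.array([], dtype=int),
                             n_q=np.array([], dtype=int), S=0, f=1.0)
    q, n_q = np.unique(reads, return_counts=True)
    return SizeHistogram(q=q.astype(int), n_q=n_q.astype(int),
                         S=int(reads.sum()), f=1.0)
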