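"""Steady-state clone-size distributions for the three-pool hematopoiesis model.

The model tracks clonal lineages seeded by ``C`` marked (and ``U`` unmarked)
hematopoietic stem cells.  Each HSC feeds its lineage by asymmetric
differentiation at rate ``alpha`` (a Poisson immigration process), progenitor
cells replicate at a carrying-capacity-regulated rate ``r(N_p) = p K/(N_p+K)``
and are removed at combined rate ``mu = mu_p + eta*omega``.  Terminal
differentiation feeds a peripheral pool with influx ``(1+eta)*omega*N_p`` and
per-cell turnover ``mu_d``; a small fraction ``eps = S/N_d`` of peripheral
cells is sequenced.

At steady state the per-clone progenitor size ``k`` follows a negative
binomial law with shape ``a = alpha/r`` and ratio ``rbar = r/mu``; the
peripheral size given ``k`` is Poisson with mean ``w*k`` where
``w = (1+eta)*omega/mu_d``; and for ``eps << 1`` the sampled read count is
Poisson with mean ``eps*w*k``.  All three stages, the exact sampled-clone
fraction, and the effective parameters ``(a, R)`` are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import nbinom, poisson

__all__ = [
    "ModelParams",
    "EffectiveParams",
    "SizeDistribution",
    "growth_rate",
    "steady_state_Np",
    "delta_approx",
    "progenitor_clone_dist",
    "peripheral_clone_dist",
    "peripheral_conditional",
    "sampled_clone_dist",
    "sampled_clone_dist_two_stage",
    "cumulative_F_and_Q",
    "sampled_clone_fraction",
    "effective_from_mechanistic",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Mechanistic parameter set.  All rates are per month, populations in cells.

    Parameters
    ----------
    alpha : HSC asymmetric differentiation rate (per HSC per month).
    p : free progenitor replication rate.
    mu_p : progenitor death rate.
    mu_d : differentiated-cell death rate.
    eta : probability that terminal differentiation is symmetric, in [0, 1].
    omega : terminal differentiation rate.
    K : progenitor carrying capacity (half-maximum of the growth law).
    U : number of active unmarked HSCs.
    C : number of active marked HSC clones.
    S : reads sequenced per sample (optional; needed to derive ``eps``).
    """

    alpha: float
    p: float
    mu_p: float
    mu_d: float
    eta: float
    omega: float
    K: float
    U: float
    C: float
    S: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha", "p", "mu_p", "mu_d", "omega", "K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("carrying capacity K must be >= 1")
        if self.mu <= 0:
            raise ValueError("combined removal rate mu = mu_p + eta*omega must be positive")

    @property
    def mu(self) -> float:
        """Combined progenitor removal rate mu_p + eta*omega."""
        return self.mu_p + self.eta * self.omega

    @property
    def w(self) -> float:
        """Peripheral amplification w = (1+eta)*omega/mu_d."""
        return (1.0 + self.eta) * self.omega / self.mu_d

    def epsilon(self, N_d: float) -> float:
        """Sampling fraction eps = S/N_d; warns when the eps<<1 collapse is dubious."""
        if self.S is None:
            raise ValueError("S not set on ModelParams")
        eps = self.S / N_d
        if eps > 0.1:
            warnings.warn(
                f"sampling fraction eps={eps:.3g} > 0.1; the small-sample "
                "Poisson collapse of the read-sampling step may be inaccurate",
                stacklevel=2,
            )
        return eps


@dataclass(frozen=True)
class EffectiveParams:
    """The two fit-identifiable combinations plus the (nearly inert) eps_w.

    ``a = alpha/r`` is the HSC differentiation rate normalised by the
    steady-state progenitor growth rate; ``R = eps_w/ln(1/rbar)`` couples the
    sampling depth to the carrying-capacity-imposed cutoff.  ``rbar = r/mu``
    and ``delta = 1 - rbar`` are derived.
    """

    a: float
    R: float
    eps_w: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("a must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.eps_w < 0:
            raise ValueError("eps_w must be non-negative")
        if self.eps_w > 0 and not 0.0 < self.rbar < 1.0:
            raise ValueError("derived rbar must lie in (0, 1)")

    @property
    def rbar(self) -> float:
        return math.exp(-self.eps_w / self.R)

    @property
    def delta(self) -> float:
        # 1 - exp(-eps_w/R), computed without cancellation
        return -math.expm1(-self.eps_w / self.R)


@dataclass
class SizeDistribution:
    """Expected clone counts (or probabilities) indexed by integer size 0..q_max.

    ``values[k]`` is the mass at size ``k``; ``truncated_mass`` bounds the
    neglected tail beyond the stored range.
    """

    values: np.ndarray
    truncated_mass: float = 0.0
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if np.any(self.values < -1e-15):
            raise ValueError("size-distribution entries must be non-negative")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.values.size)

    def normalized(self) -> "SizeDistribution":
        total = self.values.sum() + self.truncated_mass
        return SizeDistribution(self.values / total,
                                self.truncated_mass / total, self.kind)

    def mean(self) -> float:
        total = self.values.sum()
        return float(np.dot(self.sizes, self.values) / total)

    def to_tsv(self, path) -> None:
        """Write as two-column TSV (size, value)."""
        arr = np.column_stack([self.sizes, self.values])
        np.savetxt(path, arr, fmt=["%d", "%.17g"], delimiter="\t",
                   header="size\tvalue", comments="")


# ---------------------------------------------------------------------------
# mean-field fixed point
# ---------------------------------------------------------------------------

def growth_rate(N_p: float, p: float, K: float) -> float:
    """Hill-regulated progenitor growth rate r(N_p) = p*K/(N_p+K)."""
    if K <= 0:
        raise ValueError("K must be positive")
    return p * K / (np.asarray(N_p, dtype=float) + K)


def steady_state_Np(params: ModelParams) -> tuple[float, float, float]:
    """Positive root of alpha*(U+C) + (r(N_p) - mu)*N_p = 0.

    Returns ``(N_p_star, rbar, delta)`` where ``rbar = r(N_p_star)/mu`` and
    ``delta = 1 - rbar``.  The balance is a quadratic in ``N_p``; the positive
    root exists whenever ``alpha*(U+C) > 0`` or ``p > mu``.
    """
    mu = params.mu
    influx = params.alpha * (params.U + params.C)
    b = influx + (params.p - mu) * params.K
    disc = b * b + 4.0 * mu * params.K * influx
    Np_star = (b + math.sqrt(disc)) / (2.0 * mu)
    if Np_star <= 0:
        raise ValueError(
            "no positive steady state: p <= mu with no HSC influx (alpha*(U+C)=0)")
    rbar = growth_rate(Np_star, params.p, params.K) / mu
    return Np_star, float(rbar), float(1.0 - rbar)


def delta_approx(params: ModelParams) -> float:
    """Leading-order delta = alpha*(U+C)/((p-mu)*K), valid for delta << 1.

    Exhibits the inverse proportionality of the growth shortfall to the
    carrying capacity.
    """
    mu = params.mu
    if params.p <= mu:
        raise ValueError("delta_approx requires the regulated regime p > mu")
    return params.alpha * (params.U + params.C) / ((params.p - mu) * params.K)


# ---------------------------------------------------------------------------
# stationary distributions
# ---------------------------------------------------------------------------

def progenitor_clone_dist(a: float, rbar: float, k_max: int | None = None,
                          tail_tol: float = 1e-12) -> SizeDistribution:
    """Stationary per-clone progenitor size law: negative binomial NB(a, rbar).

    Derived from the one-step balance of the birth-death-immigration process,
    ``(alpha + r*k) P_k = mu*(k+1) P_{k+1}``:

        P_k = (1-rbar)^a * Gamma(a+k)/(Gamma(a) k!) * rbar^k

    ``k_max`` is auto-extended until the neglected tail mass is below
    ``tail_tol``.  Evaluation is in log space and is finite for ``k_max`` up
    to 1e7.
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if not 0.0 < rbar < 1.0:
        raise ValueError("rbar must lie in (0, 1)")
    if k_max is None:
        k_max = int(nbinom.isf(tail_tol, a, 1.0 - rbar)) + 1
    k = np.arange(k_max + 1)
    logp = (a * np.log1p(-rbar) + gammaln(a + k) - gammaln(a)
            - gammaln(k + 1.0) + k * math.log(rbar))
    values = np.exp(logp)
    tail = float(nbinom.sf(k_max, a, 1.0 - rbar))
    return SizeDistribution(values, truncated_mass=tail, kind="progenitor")


def peripheral_conditional(k: int, w: float):
    """Stationary peripheral clone size given progenitor size k: Poisson(w*k)."""
    return poisson(w * k)


def peripheral_clone_dist(P_k: SizeDistribution, w: float,
                          n_max: int | None = None,
                          tail_tol: float = 1e-10) -> SizeDistribution:
    """Marginal stationary peripheral-pool clone-size law.

    The peripheral count of a clone with ``k`` progenitors receives influx at
    constant rate ``(1+eta)*omega*k`` and is cleared per cell at ``mu_d``, so
    its stationary law is Poisson with mean ``w*k``.  The marginal is the
    mixture ``y_n/C = sum_k P_k Poisson(n; w*k)``.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    pk = P_k.values
    k = np.arange(pk.size)
    means = w * k
    if n_max is None:
        big = means.max()
        n_max = int(big + 12.0 * math.sqrt(big + 1.0) + 20.0)
    n = np.arange(n_max + 1)
    out = np.zeros(n_max + 1)
    # chunk over k to bound memory
    step = max(1, int(4e6 / (n_max + 1)))
    for lo in range(0, pk.size, step):
        hi = min(lo + step, pk.size)
        out += pk[lo:hi] @ poisson.pmf(n[None, :], means[lo:hi, None])
    tail = max(0.0, 1.0 - P_k.truncated_mass - out.sum())
    return SizeDistribution(out, truncated_mass=tail + P_k.truncated_mass,
                            kind="peripheral")


# -- NB-mixed-Poisson read-count law ----------------------------------------
#
# With reads | k ~ Poisson(lam*k) and k ~ NB(a, rbar), the pgf of the read
# count is  F(z) = ((1-rbar)/(1 - s*exp(lam*z)))^a  with  s = rbar*exp(-lam).
# Writing A(z) = ln F(z), the Taylor coefficients A_j (j>=1) are
#   A_j = a * s * W_{j-1},   W_m = (lam/(1-s))^{m+1}/(m+1)! * E_m(s)
# where E_m is the Eulerian polynomial.  The scaled coefficients
#   d_{m,i} = Eulerian(m,i) * s^i * (lam/(1-s))^{m+1} / (m+1)!
# obey a positive (hence numerically stable) two-term recurrence, and the pmf
# follows from the standard exp-of-series recursion
#   q*m_q = sum_{j=1}^{q} j*A_j * m_{q-j},   m_0 = ((1-rbar)/(1-s))^a.
# Every term is positive, so the computation is exact to roundoff.

def _log_series_coeffs(rbar: float, lam: float, q_max: int) -> np.ndarray:
    """Return B_j = A_j/a for j = 0..q_max (B_0 unused, set to 0)."""
    s = rbar * math.exp(-lam)
    rho = lam / (-math.expm1(math.log(rbar) - lam))  # lam/(1-s), stable
    B = np.zeros(q_max + 1)
    if q_max >= 1:
        d = np.array([rho])  # row m=0: E_0 = 1
        B[1] = s * d[0]
        for m in range(1, q_max):
            i = np.arange(m + 1)
            dn = np.zeros(m + 1)
            dn[:m] += (i[:m] + 1.0) * d
            dn[1:] += (m - i[1:]) * s * d
            d = dn * (rho / (m + 1))
            B[m + 1] = s * d.sum()
    return B


def _nb_poisson_pmf(a: float, rbar: float, lam: float, q_max: int,
                    coeffs: np.ndarray | None = None) -> np.ndarray:
    """pmf of the Poisson(lam*k) mixture over k ~ NB(a, rbar), q = 0..q_max."""
    if coeffs is None:
        coeffs = _log_series_coeffs(rbar, lam, q_max)
    jA = np.arange(q_max + 1) * (a * coeffs)
    m = np.empty(q_max + 1)
    # m_0 = ((1-rbar)/(1-s))^a without cancellation; 1-s = -expm1(ln rbar - lam)
    log_m0 = a * (np.log1p(-rbar) - math.log(-math.expm1(math.log(rbar) - lam)))
    m[0] = math.exp(log_m0)
    for q in range(1, q_max + 1):
        m[q] = np.dot(jA[1:q + 1], m[q - 1::-1]) / q
    return m


def _default_q_max(a: float, rbar: float, lam: float, tail_tol: float) -> int:
    # the pgf is singular at z* = 1 + ln(1/rbar)/lam, so coefficients decay
    # like z*^-q; start at the mean plus enough e-foldings for the tail bound
    ln_zstar = math.log1p(-math.log(rbar) / lam)
    mean = lam * a * rbar / (1.0 - rbar)
    efold = -math.log(max(tail_tol, 1e-16)) + 10.0
    return int(mean + 3.0 * math.sqrt(mean + 1.0) + efold / ln_zstar) + 10


def sampled_clone_dist(a: float, rbar: float, eps_w: float,
                       q_max: int | None = None, tail_tol: float = 1e-10,
                       method: str = "pgf") -> SizeDistribution:
    """Expected sampled clone-size distribution ⟨m_q⟩/C over read counts q.

    Implements the small-sampling-fraction collapse of the sequencing step:
    reads of a clone with ``k`` progenitors are Poisson with mean
    ``eps_w * k``, mixed over the stationary NB(a, rbar) progenitor law.

    ``method='pgf'`` (default) uses an exact generating-function power-series
    recursion, ``method='kernel-sum'`` brute-force summation over k (slow;
    used for validation).  Truncation is adaptive so the neglected mass is
    below ``tail_tol``.
    """
    if a <= 0 or not 0.0 < rbar < 1.0:
        raise ValueError("require a > 0 and 0 < rbar < 1")
    if eps_w < 0:
        raise ValueError("eps_w must be non-negative")
    if eps_w == 0.0:
        values = np.zeros((q_max or 1) + 1)
        values[0] = 1.0
        return SizeDistribution(values, truncated_mass=0.0, kind="sampled")
    auto = q_max is None
    if auto:
        q_max = _default_q_max(a, rbar, eps_w, tail_tol)
    if q_max > 200_000:
        raise ValueError(
            f"q_max={q_max} exceeds the supported range for the log-factorial "
            "recursion; truncate the requested distribution")
    while True:
        if method == "pgf":
            m = _nb_poisson_pmf(a, rbar, eps_w, q_max)
        elif method == "kernel-sum":
            m = _kernel_sum_pmf(a, rbar, eps_w, q_max, tail_tol)
        else:
            raise ValueError(f"unknown method {method!r}")
        tail = max(0.0, 1.0 - m.sum())
        if not auto or tail <= tail_tol or q_max >= 100_000:
            return SizeDistribution(m, truncated_mass=tail, kind="sampled")
        q_max *= 2  # extend geometrically until the tail bound is met


def _kernel_sum_pmf(a: float, rbar: float, lam: float, q_max: int,
                    tail_tol: float) -> np.ndarray:
    """Direct summation sum_k P_k Pois(q; lam*k); validation route.

    The Poisson kernel at read count q peaks near k = q/lam, so the k range
    must cover both the NB bulk and the kernel peak of the largest q.
    """
    k_hi = int(nbinom.isf(tail_tol * 1e-2, a, 1.0 - rbar)) + 1
    k_hi = max(k_hi, int((q_max + 14.0 * math.sqrt(q_max + 1.0)) / lam) + 1)
    if k_hi > 50_000_000:
        raise ValueError("kernel-sum validation route infeasible at this "
                         "parameter point; use method='pgf'")
    k = np.arange(k_hi + 1)
    logP = (a * np.log1p(-rbar) + gammaln(a + k) - gammaln(a)
            - gammaln(k + 1.0) + k * math.log(rbar))
    P = np.exp(logP)
    lk = lam * k
    out = np.empty(q_max + 1)
    for q in range(q_max + 1):
        out[q] = float(np.dot(P, poisson.pmf(q, lk)))
    return out


def sampled_clone_dist_two_stage(a: float, rbar: float, eps: float, w: float,
                                 q_max: int, tail_tol: float = 1e-10,
                                 sampling: str = "poisson") -> SizeDistribution:
    """Exact two-stage sampled law, without the eps<<1 collapse.

    Reads are drawn from the peripheral clone size ``l`` (``Poisson(eps*l)``
    or ``Binomial(l, eps)``), and ``l | k`` is Poisson(w*k); the mixture runs
    over the stationary NB(a, rbar) progenitor law.  Used to validate the
    default single-Poisson collapse and to compare against simulations where
    eps is not small.
    """
    if sampling not in ("poisson", "binomial"):
        raise ValueError("sampling must be 'poisson' or 'binomial'")
    from scipy.stats import binom
    k_hi = int(nbinom.isf(tail_tol * 1e-2, a, 1.0 - rbar)) + 1
    k = np.arange(k_hi + 1)
    logP = (a * np.log1p(-rbar) + gammaln(a + k) - gammaln(a)
            - gammaln(k + 1.0) + k * math.log(rbar))
    Pk = np.exp(logP)
    q = np.arange(q_max + 1)
    out = np.zeros(q_max + 1)
    for ki, pk in zip(k, Pk):
        if pk < 1e-18 and ki > 0:
            continue
        mean_l = w * ki
        lo = max(0, int(mean_l - 12 * math.sqrt(mean_l + 1) - 5))
        hi = int(mean_l + 12 * math.sqrt(mean_l + 1) + 10)
        l = np.arange(lo, hi + 1)
        pl = poisson.pmf(l, mean_l)
        if sampling == "poisson":
            kern = poisson.pmf(q[:, None], eps * l[None, :])
        else:
            kern = binom.pmf(q[:, None], l[None, :], eps)
        out += pk * (kern @ pl)
    tail = max(0.0, 1.0 - out.sum())
    return SizeDistribution(out, truncated_mass=tail, kind="sampled")


def cumulative_F_and_Q(m: SizeDistribution, S: int) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative F(q) = sum_{k<=q} m_k and detected-clone fraction Q(q).

    ``Q(q) = (F(q)-F(0))/(F(S)-F(0))`` is the fraction of sampled clones with
    at most ``q`` reads; it is nondecreasing with ``Q(S) = 1`` and invariant
    under rescaling of ``m``.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    values = m.values
    F = np.cumsum(values)
    top = min(S, values.size - 1)
    denom = F[top] - F[0]
    if denom <= 0:
        raise ValueError("no sampled clones: F(S) = F(0)")
    q = np.arange(1, top + 1)
    Q = (F[1:top + 1] - F[0]) / denom
    return q, Q


def sampled_clone_fraction(a: float, delta: float, eps_w: float,
                           form: str = "exact"):
    """Expected fraction of active clones detected in a sample, C_s/C.

    ``form='exact'`` evaluates ``1 - (delta/(1-(1-delta)e^{-eps_w}))^a``;
    ``form='log_approx'`` evaluates ``a*ln(eps_w/delta + 1)`` and also returns
    a flag marking the regime (eps_w << 1 and result << 1) where the
    approximation is trustworthy.
    """
    if a <= 0 or not 0.0 < delta < 1.0 or eps_w < 0:
        raise ValueError("require a > 0, delta in (0,1), eps_w >= 0")
    if form == "exact":
        denom = -np.expm1(math.log1p(-delta) - eps_w)  # 1-(1-delta)e^{-eps_w}
        return float(-np.expm1(a * (math.log(delta) - math.log(denom))))
    if form == "log_approx":
        value = float(a * math.log1p(eps_w / delta))
        valid = eps_w < 0.1 and value < 0.1
        return value, valid
    raise ValueError("form must be 'exact' or 'log_approx'")


def effective_from_mechanistic(params: ModelParams,
                               S: float | None = None) -> EffectiveParams:
    """Map a mechanistic parameter set to the fit-identifiable (a, R, eps_w).

    Solves the mean-field fixed point, then ``a = alpha/r(N_p*)``,
    ``eps = S/N_d*`` with ``N_d* = w*N_p*``, and ``R = eps_w/ln(1/rbar)``.
    """
    if S is None:
        S = params.S
    if S is None:
        raise ValueError("the number of reads S is required to derive eps_w")
    Np_star, rbar, _delta = steady_state_Np(params)
    r = growth_rate(Np_star, params.p, params.K)
    a = params.alpha / r
    Nd_star = params.w * Np_star
    eps = S / Nd_star
    eps_w = eps * params.w
    R = eps_w / (-math.log(rbar))
    return EffectiveParams(a=float(a), R=float(R), eps_w=float(eps_w))
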