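"""Shared fixtures: seeded synthetic histograms and the reduced-K
exact-event validation ensemble (expensive; session-scoped and reused by the
simulator, distribution and acceptance tests)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import hemaclone as hc
from hemaclone.presets import (OPERATING_POINT, VALIDATION_S,
                               ssa_validation_config,
                               validation_model_params)

N_REPS = 200
T_RELAXED = 70.0
T_LATE = 100.0
SAMPLE_F = 0.05


@dataclass
class ValidationEnsemble:
    """Raw per-replicate output of the reduced-K stationary validation runs."""

    n_prog: list          # per-rep labeled progenitor counts at T_RELAXED
    n_diff: list          # per-rep labeled differentiated counts at T_RELAXED
    reads_t1: list        # per-rep read counts (q >= 1) at T_RELAXED
    reads_t2: list        # per-rep read counts at T_LATE
    a: float
    rbar: float
    delta: float
    eps: float
    w: float
    C: int
    n_reps: int


@pytest.fixture(scope="session")
def validation_ensemble() -> ValidationEnsemble:
    params = validation_model_params()
    Np_star, rbar, delta = hc.steady_state_Np(params)
    r = hc.growth_rate(Np_star, params.p, params.K)
    a = params.alpha / r
    eps = VALIDATION_S / (params.w * Np_star)
    n_prog, n_diff, reads_t1, reads_t2 = [], [], [], []
    for i in range(N_REPS):
        cfg = ssa_validation_config(sample_times=(T_RELAXED, T_LATE),
                                    seed=2000 + i)
        st1, st2 = hc.simulate(cfg)
        n_prog.append(st1.n_prog)
        n_diff.append(st1.n_diff)
        t1, _ = hc.sample_reads(st1, VALIDATION_S, SAMPLE_F,
                                mode="binomial", seed=2 * i)
        t2, _ = hc.sample_reads(st2, VALIDATION_S, SAMPLE_F,
                                mode="binomial", seed=2 * i + 1)
        reads_t1.append(t1["reads"].to_numpy())
        reads_t2.append(t2["reads"].to_numpy())
    return ValidationEnsemble(n_prog=n_prog, n_diff=n_diff,
                              reads_t1=reads_t1, reads_t2=reads_t2,
                              a=float(a), rbar=float(rbar), delta=float(delta),
                              eps=float(eps), w=float(params.w),
                              C=int(params.C), n_reps=N_REPS)


@pytest.fixture(scope="session")
def operating_histogram_1e5() -> hc.SizeHistogram:
    """Stationary synthetic read histogram at the RQ5427 operating point."""
    return hc.sample_steady_state_reads(OPERATING_POINT, 100_000, seed=42)


def binned_fractions(per_rep_counts, n_bins: int, denom: int) -> np.ndarray:
    """Per-replicate occupancy fractions with the far tail pooled into the
    last bin; rows are replicates."""
    out = np.zeros((len(per_rep_counts), n_bins))
    for i, counts in enumerate(per_rep_counts):
        c = np.bincount(np.minimum(np.asarray(counts), n_bins - 1),
                        minlength=n_bins)
        out[i] = c / denom
    return out


def pooled_theory(values: np.ndarray, truncated: float, n_bins: int) -> np.ndarray:
    """Theory mass per bin matching :func:`binned_fractions` pooling."""
    head = values[:n_bins - 1]
    return np.concatenate([head, [values[n_bins - 1:].sum() + truncated]])


def max_abs_z(frac: np.ndarray, theory: np.ndarray) -> float:
    """Largest |z| of replicate-mean occupancy against theory, using the
    replicate-to-replicate scatter as the Monte-Carlo SE."""
    mean = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / np.sqrt(frac.shape[0])
    keep = se > 0
    return float(np.max(np.abs(mean[keep] - theory[keep]) / se[keep]))
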