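"""Composite-likelihood estimation of a constant effective population size.

Each locus contributes its neutral HMM log-likelihood, conditioned on the
event that the samples are polymorphic overall: the likelihood is divided by
(1 - P{no focal alleles observed} - P{no non-focal alleles observed}), where
the two correction terms are the HMM likelihoods of the pseudo-datasets with
a_t = 0 (resp. a_t = n_t) at every sampled time.  Without this conditioning
the composite surface is nearly flat in Ne.  The initial distribution is
always fixed to the uniform density (it is never co-estimated here, which
would bias the size estimate).

Per-locus likelihoods are summed on a grid of candidate Ne values; the
estimate is the argmax of a cubic interpolant through (log Ne, composite ll).

Loci sharing a sampling scheme (same T, times and sample sizes) are processed
in a single batched forward pass using powers of the neutral transition
matrix between sampling times, which makes scans over thousands of
identically-designed loci cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .em_fit import discretized_beta
from .hmm_core import TemporalObservations, emission_probs
from .wf_model import FrequencyGrid, SelectionParams, chebychev_grid, transition_matrix

logger = logging.getLogger(__name__)

__all__ = ["NeGrid", "conditioned_neutral_ll", "estimate_ne", "default_ne_grid"]

_NEUTRAL = SelectionParams(0.0, 0.0)


@dataclass
class NeGrid:
    values: np.ndarray
    composite_ll: np.ndarray
    ne_hat: float
    n_loci_used: int = 0
    n_loci_skipped: int = 0


def default_ne_grid(ne_guess: float, n_points: int = 9) -> np.ndarray:
    """Nine log-spaced candidates spanning [guess/8, 8*guess]."""
    return np.exp(np.linspace(np.log(ne_guess / 8), np.log(ne_guess * 8), n_points))


def _scheme_key(obs: TemporalObservations):
    times = obs.sample_times
    return (obs.T, tuple(times.tolist()), tuple(obs.n[times - 1].tolist()))


def _is_polymorphic(obs: TemporalObservations) -> bool:
    return obs.a.sum() > 0 and obs.a.sum() < obs.n.sum()


def _gap_operators(P: np.ndarray, times: np.ndarray) -> list[np.ndarray]:
    """Transition operators bridging consecutive sampling times (and the
    stretch from generation 1 to the first sampling time)."""
    gaps = np.diff(np.concatenate([[1], times]))
    ops = []
    cache: dict[int, np.ndarray] = {}
    for gap in gaps:
        gap = int(gap)
        if gap not in cache:
            cache[gap] = np.linalg.matrix_power(P, gap)
        ops.append(cache[gap])
    return ops


def _batched_neutral_ll(
    counts: np.ndarray,
    sizes: np.ndarray,
    ops: list[np.ndarray],
    init: np.ndarray,
    grid: FrequencyGrid,
) -> np.ndarray:
    """Log-likelihoods for L loci sharing a sampling scheme.

    ``counts`` is (L, K); ``sizes`` length K; ``ops`` the K gap operators.
    """
    L, K = counts.shape
    uniq: dict[tuple[int, int], np.ndarray] = {}
    alpha = np.broadcast_to(init, (L, init.size)).copy()
    ll = np.zeros(L)
    for k in range(K):
        alpha = alpha @ ops[k]
        n_k = int(sizes[k])
        col = counts[:, k]
        em = np.empty_like(alpha)
        for a_val in np.unique(col):
            key = (n_k, int(a_val))
            if key not in uniq:
                uniq[key] = emission_probs(n_k, int(a_val), grid)
            em[col == a_val] = uniq[key]
        alpha *= em
        c = alpha.sum(axis=1)
        bad = c <= 0
        if np.any(bad):
            ll[bad] = -np.inf
            c = np.where(bad, 1.0, c)
        ll += np.log(c, where=c > 0, out=np.full(L, -np.inf))
        alpha /= c[:, None]
    return ll


def conditioned_neutral_ll(
    obs: TemporalObservations,
    Ne: float,
    grid: FrequencyGrid | None = None,
) -> float:
    """Neutral log-likelihood conditioned on polymorphic samples overall."""
    if not _is_polymorphic(obs):
        raise ValueError(
            "conditioning undefined: samples carry no focal or no non-focal alleles"
        )
    if grid is None:
        grid = chebychev_grid(500)
    times = obs.sample_times
    sizes = obs.n[times - 1]
    P = transition_matrix(grid, _NEUTRAL, Ne)
    ops = _gap_operators(P, times)
    init = discretized_beta(1.0, 1.0, grid)
    counts = np.vstack(
        [obs.a[times - 1], np.zeros_like(sizes), sizes]
    )
    ll, ll0, ll1 = _batched_neutral_ll(counts, sizes, ops, init, grid)
    denom = 1.0 - np.exp(ll0) - np.exp(ll1)
    if denom <= 0:
        raise ValueError("conditioning denominator non-positive for this locus")
    return float(ll - np.log(denom))


def estimate_ne(
    loci: list[TemporalObservations],
    ne_grid: np.ndarray,
    grid: FrequencyGrid | None = None,
) -> NeGrid:
    """Grid-based composite-likelihood estimate of a shared constant Ne."""
    ne_grid = np.sort(np.asarray(ne_grid, dtype=float))
    if ne_grid.size < 1:
        raise ValueError("need at least one candidate Ne")
    if grid is None:
        grid = chebychev_grid(500)
    init = discretized_beta(1.0, 1.0, grid)

    groups: dict[tuple, list[np.ndarray]] = {}
    skipped = 0
    for obs in loci:
        if not _is_polymorphic(obs):
            skipped += 1
            continue
        times = obs.sample_times
        groups.setdefault(_scheme_key(obs), []).append(obs.a[times - 1])
    used = sum(len(v) for v in groups.values())
    if used == 0:
        raise ValueError("no polymorphic loci available for Ne estimation")
    if skipped:
        logger.info("Ne estimation skipped %d monomorphic-sample loci", skipped)

    composite = np.zeros(ne_grid.size)
    for j, ne in enumerate(ne_grid):
        P = transition_matrix(grid, _NEUTRAL, float(ne))
        total = 0.0
        for (T, times_t, sizes_t), count_rows in groups.items():
            times = np.asarray(times_t, dtype=np.int64)
            sizes = np.asarray(sizes_t, dtype=np.int64)
            ops = _gap_operators(P, times)
            counts = np.vstack(count_rows)
            ll = _batched_neutral_ll(counts, sizes, ops, init, grid)
            pseudo = np.vstack([np.zeros_like(sizes), sizes])
            ll0, ll1 = _batched_neutral_ll(pseudo, sizes, ops, init, grid)
            denom = 1.0 - np.exp(ll0) - np.exp(ll1)
            if denom <= 0:
                raise ValueError(
                    "conditioning denominator non-positive for a sampling scheme"
                )
            total += float(ll.sum() - counts.shape[0] * np.log(denom))
        composite[j] = total

    if ne_grid.size == 1:
        return NeGrid(ne_grid, composite, float(ne_grid[0]), used, skipped)
    if ne_grid.size < 3:
        ne_hat = float(ne_grid[int(np.argmax(composite))])
        return NeGrid(ne_grid, composite, ne_hat, used, skipped)

    x = np.log(ne_grid)
    spline = CubicSpline(x, composite)
    xs = np.linspace(x[0], x[-1], 2001)
    ys = spline(xs)
    ne_hat = float(np.exp(xs[int(np.argmax(ys))]))
    if np.argmax(ys) in (0, ys.size - 1):
        logger.warning("composite surface peaks at the grid boundary")
    return NeGrid(ne_grid, composite, ne_hat, used, skipped)
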