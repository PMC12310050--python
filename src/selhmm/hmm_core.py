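"""Binomial-emission HMM machinery: emissions, scaled forward-backward,
posterior moments and the data log-likelihood.

The hidden state F_t is the discretized population allele frequency; the
observation at a sampled generation t is the focal-allele count
a_t ~ Bin(n_t, F_t).  Generations without data use n_t = 0, which makes the
emission vector identically one and is skipped in the recursions.

The E-step of the selection EM only needs a handful of posterior expectations
summed over generations, so instead of materializing the (T-1) x M x M joint
posteriors xi, :func:`forward_backward` accumulates those sums on the fly
(the full xi tensor is available on request for small problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
from numba import njit
from scipy.special import gammaln

from .wf_model import BandedTransition, FrequencyGrid

__all__ = [
    "TemporalObservations",
    "Posteriors",
    "EStepMoments",
    "emission_probs",
    "forward_backward",
]


@dataclass(frozen=True)
class TemporalObservations:
    """One locus's temporal sample: dense per-generation (n_t, a_t) arrays.

    Generations are 1-based, t = 1..T; unsampled generations carry n_t = 0.
    """

    n: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=np.int64)
        a = np.asarray(self.a, dtype=np.int64)
        if n.shape != a.shape or n.ndim != 1 or n.size < 1:
            raise ValueError("n and a must be 1-D arrays of equal length")
        if np.any(n < 0) or np.any(a < 0) or np.any(a > n):
            raise ValueError("counts must satisfy 0 <= a_t <= n_t")
        n.setflags(write=False)
        a.setflags(write=False)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "a", a)

    @classmethod
    def from_samples(cls, T: int, times, n, a) -> "TemporalObservations":
        """Build from sparse (t_k, n_k, a_k) triples; times are 1-based."""
        times = np.asarray(times, dtype=np.int64)
        if np.any(times < 1) or np.any(times > T):
            raise ValueError("sampling times must lie in [1, T]")
        if times.size != np.unique(times).size:
            raise ValueError("sampling times must be distinct")
        nd = np.zeros(T, dtype=np.int64)
        ad = np.zeros(T, dtype=np.int64)
        nd[times - 1] = n
        ad[times - 1] = a
        return cls(nd, ad)

    @property
    def T(self) -> int:
        return self.n.size

    @property
    def sample_times(self) -> np.ndarray:
        """1-based generations that carry data."""
        return np.nonzero(self.n)[0] + 1

    @property
    def n_samples_total(self) -> int:
        return int(self.n.sum())

    def pooled_maf(self) -> float:
        """Minor allele frequency pooling all samples across time."""
        tot = self.n.sum()
        if tot == 0:
            return np.nan
        f = self.a.sum() / tot
        return float(min(f, 1.0 - f))

    def truncated(self, k: int) -> "TemporalObservations":
        """Keep only the first k sampled timepoints (trajectory ends there)."""
        times = self.sample_times
        if not 1 <= k <= times.size:
            raise ValueError("k outside the number of sampled timepoints")
        last = times[k - 1]
        return TemporalObservations(self.n[:last].copy(), self.a[:last].copy())


@dataclass
class EStepMoments:
    """Posterior-expectation accumulators feeding the closed-form M-step.

    All sums run over the T-1 transition steps t = 1..T-1, with
    H_t := F_t (1 - F_t):

    - ``s_h``     = sum_t E[H_t]
    - ``s_fh``    = sum_t E[F_t H_t]
    - ``s_f2h``   = sum_t E[F_t^2 H_t]
    - ``s_f2``    = sum_t E[F_t^2]
    - ``s_cross`` = sum_t E[F_t F_{t+1}]   (the only term needing xi)
    - ``e_first`` = E[F_1], ``e_last`` = E[F_T]
    """

    s_h: float
    s_fh: float
    s_f2h: float
    s_f2: float
    s_cross: float
    e_first: float
    e_last: float

    @property
    def s_incr(self) -> float:
        """sum_t E[F_t (F_{t+1} - F_t)]."""
        return self.s_cross - self.s_f2


@dataclass
class Posteriors:
    """Marginal posteriors gamma (T x M), E-step moments, log-likelihood."""

    gamma: np.ndarray
    moments: EStepMoments | None
    log_likelihood: float
    xi: np.ndarray | None = field(default=None, repr=False)


def emission_probs(n: int, a: int, grid: FrequencyGrid) -> np.ndarray:
    """Binomial emission vector over grid states: P(a | n, F = g_i)."""
    if a < 0 or a > n:
        raise ValueError("need 0 <= a <= n")
    if n == 0:
        return np.ones(grid.M)
    g = grid.nodes[1:-1]
    lbinom = gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
    e = np.empty(grid.M)
    e[1:-1] = np.exp(lbinom + a * np.log(g) + (n - a) * np.log1p(-g))
    # fixed states emit deterministically
    e[0] = 1.0 if a == 0 else 0.0
    e[-1] = 1.0 if a == n else 0.0
    return e


def _emissions(obs: TemporalObservations, grid: FrequencyGrid) -> dict[int, np.ndarray]:
    return {
        int(t): emission_probs(int(obs.n[t - 1]), int(obs.a[t - 1]), grid)
        for t in obs.sample_times
    }


@njit(cache=True)
def _fb_banded_kernel(band, lo, init, g, em_times, em_vals, T):
    """Forward-backward over a banded transition; returns
    (status, ll, gamma, cross) with status 0 on success, 1 on zero
    likelihood.  ``em_times`` are 0-based time indices of the emission rows
    in ``em_vals``."""
    M = init.size
    width = band.shape[1]
    K = em_times.size
    alpha = np.zeros((T, M))
    logc = np.zeros(T)
    gamma = np.zeros((T, M))

    a = init.copy()
    k = 0
    for t in range(T):
        if t > 0:
            nxt = np.zeros(M)
            for i in range(M):
                ai = a[i]
                if ai != 0.0:
                    base = lo[i]
                    for w in range(width):
                        nxt[base + w] += ai * band[i, w]
            a = nxt
        sampled = k < K and em_times[k] == t
        if sampled:
            a = a * em_vals[k]
            k += 1
            c = a.sum()
            if c <= 0.0 or not np.isfinite(c):
                return 1, -np.inf, gamma, 0.0
            a = a / c
            logc[t] = np.log(c)
        alpha[t] = a

    ll = logc.sum()
    # backward pass: W holds e_t * beta_t
    W = np.ones(M)
    k = K - 1
    if k >= 0 and em_times[k] == T - 1:
        W = W * em_vals[k]
        k -= 1
    gamma[T - 1] = alpha[T - 1]
    cross = 0.0
    for t in range(T - 2, -1, -1):
        # beta_t = P @ W_{t+1} / c_{t+1}; cross_t = (alpha_t*g) P (W_{t+1}*g)/c_{t+1}
        beta = np.zeros(M)
        ct = math.exp(logc[t + 1])
        cr = 0.0
        for i in range(M):
            base = lo[i]
            acc = 0.0
            accg = 0.0
            for w in range(width):
                j = base + w
                acc += band[i, w] * W[j]
                accg += band[i, w] * W[j] * g[j]
            beta[i] = acc / ct
            cr += alpha[t, i] * g[i] * accg
        cross += cr / ct
        gamma[t] = alpha[t] * beta
        if k >= 0 and em_times[k] == t:
            W = beta * em_vals[k]
            k -= 1
        else:
            W = beta
    return 0, ll, gamma, cross


def _fb_banded(
    obs: TemporalObservations,
    transition: BandedTransition,
    init: np.ndarray,
    grid: FrequencyGrid,
    ems: dict[int, np.ndarray] | None,
) -> Posteriors:
    if ems is None:
        ems = _emissions(obs, grid)
    times = np.array(sorted(ems), dtype=np.int64) - 1  # 0-based
    em_vals = (
        np.vstack([ems[int(t) + 1] for t in times])
        if times.size
        else np.zeros((0, grid.M))
    )
    status, ll, gamma, cross = _fb_banded_kernel(
        transition.band,
        transition.lo,
        np.asarray(init, dtype=float),
        grid.nodes,
        times,
        em_vals,
        obs.T,
    )
    if status != 0:
        return Posteriors(np.full((obs.T, grid.M), np.nan), None, -np.inf, None)
    g = grid.nodes
    h = g * (1.0 - g)
    T = obs.T
    gsum = gamma[: T - 1].sum(axis=0) if T > 1 else np.zeros(grid.M)
    moments = EStepMoments(
        s_h=float(gsum @ h),
        s_fh=float(gsum @ (g * h)),
        s_f2h=float(gsum @ (g * g * h)),
        s_f2=float(gsum @ (g * g)),
        s_cross=float(cross),
        e_first=float(gamma[0] @ g),
        e_last=float(gamma[T - 1] @ g),
    )
    return Posteriors(gamma, moments, float(ll), None)


def forward_backward(
    obs: TemporalObservations,
    transition: np.ndarray,
    init: np.ndarray,
    grid: FrequencyGrid,
    *,
    return_xi: bool = False,
    want_moments: bool = True,
    ems: dict[int, np.ndarray] | None = None,
) -> Posteriors:
    """Scaled forward-backward pass returning posteriors and the exact
    data log-likelihood.

    Scaling factors are accumulated only at sampled generations: with a
    row-stochastic transition the forward variable stays normalized across
    unsampled steps, so their scale factor is identically one.  A dataset
    whose likelihood is exactly zero (data incompatible with the initial
    distribution's support) is reported with log-likelihood -inf and NaN
    posteriors rather than raising.  ``ems`` may carry precomputed emission
    vectors keyed by 1-based generation (they depend only on the data and
    grid, so EM iterations reuse them).
    """
    if isinstance(transition, BandedTransition):
        if return_xi:
            transition = transition.dense()
        else:
            return _fb_banded(obs, transition, init, grid, ems)
    P = np.asarray(transition)
    init = np.asarray(init, dtype=float)
    T, M = obs.T, init.size
    if P.shape != (M, M):
        raise ValueError("transition matrix shape does not match init")
    g = grid.nodes
    if ems is None:
        ems = _emissions(obs, grid)

    alpha = np.empty((T, M))
    logc = np.zeros(T)
    a = init * ems[1] if 1 in ems else init.copy()
    sampled = 1 in ems
    for t in range(1, T + 1):
        if t > 1:
            a = a @ P
            e = ems.get(t)
            sampled = e is not None
            if sampled:
                a = a * e
        if sampled or t == 1:
            c = a.sum()
            if c <= 0.0 or not np.isfinite(c):
                nan = np.full((T, M), np.nan)
                return Posteriors(nan, None, -np.inf, None)
            a = a / c
            logc[t - 1] = math.log(c)
        alpha[t - 1] = a

    ll = float(logc.sum())
    cvals = np.exp(logc)

    # Backward pass; W[t] stores the emission-weighted backward variable
    # e_t * beta_t needed for the joint-posterior cross terms.
    beta = np.ones(M)
    W = np.empty((T, M))
    W[T - 1] = beta if (e := ems.get(T)) is None else e
    gamma = np.empty((T, M))
    gamma[T - 1] = alpha[T - 1]
    xi = np.empty((T - 1, M, M)) if return_xi else None
    for t in range(T - 1, 0, -1):  # computes beta_t from beta_{t+1}
        if return_xi:
            xi[t - 1] = alpha[t - 1][:, None] * P * W[t][None, :] / cvals[t]
        beta = P @ W[t]
        if cvals[t] != 1.0:
            beta /= cvals[t]
        gamma[t - 1] = alpha[t - 1] * beta
        e = ems.get(t)
        W[t - 1] = beta if e is None else beta * e

    s_cross = 0.0
    if want_moments and T > 1:
        # sum_t E[F_t F_{t+1}] via one matrix product over all steps
        left = (alpha[: T - 1] * g) @ P
        s_cross = float(
            np.einsum("tm,tm->", left, W[1:] * g / cvals[1:, None])
        )

    moments = None
    if want_moments:
        h = g * (1.0 - g)
        gsum = gamma[: T - 1].sum(axis=0) if T > 1 else np.zeros(M)
        moments = EStepMoments(
            s_h=float(gsum @ h),
            s_fh=float(gsum @ (g * h)),
            s_f2h=float(gsum @ (g * g * h)),
            s_f2=float(gsum @ (g * g)),
            s_cross=s_cross,
            e_first=float(gamma[0] @ g),
            e_last=float(gamma[T - 1] @ g),
        )
    return Posteriors(gamma, moments, ll, xi)
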