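"""Discretized Wright-Fisher transition model under general diploid selection.

The population frequency of a focal allele A evolves according to the discrete
Wright-Fisher model with relative fitnesses 1+s2 : 1+s1 : 1 for genotypes
AA : Aa : aa.  For HMM inference the frequency is discretized onto a grid of
``M`` states spanning [0, 1], and the one-generation transition kernel is the
normal (diffusion) approximation integrated over each grid interval, with the
outermost intervals extended to +/- infinity so that mass leaving [0, 1] is
absorbed at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "FrequencyGrid",
    "SelectionParams",
    "PopSizeSchedule",
    "BandedTransition",
    "chebychev_grid",
    "mean_next_freq",
    "transition_matrix",
    "banded_transition",
]


@dataclass(frozen=True)
class SelectionParams:
    """Diploid selection coefficients (s1 heterozygote, s2 homozygote).

    The fitness parameterization 1+s2 : 1+s1 : 1 is meaningful for
    s1, s2 > -1; the container itself admits any real values because the
    EM M-step maximizes over all of R^2 before convergence.
    """

    s1: float = 0.0
    s2: float = 0.0


@dataclass(frozen=True)
class FrequencyGrid:
    """Hidden state space: strictly increasing frequencies with 0 and 1 endpoints.

    ``midpoints`` holds the M+1 interval boundaries (g_j + g_{j-1})/2 with
    -inf and +inf sentinels at the two ends; interval j brackets node j.
    """

    nodes: np.ndarray
    midpoints: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2:
            raise ValueError("grid needs at least two nodes")
        if nodes[0] != 0.0 or nodes[-1] != 1.0:
            raise ValueError("grid must span exactly [0, 1]")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("grid nodes must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)
        mids = np.empty(nodes.size + 1)
        mids[0] = -np.inf
        mids[-1] = np.inf
        mids[1:-1] = 0.5 * (nodes[1:] + nodes[:-1])
        mids.setflags(write=False)
        nodes.setflags(write=False)
        object.__setattr__(self, "midpoints", mids)

    @property
    def M(self) -> int:
        return self.nodes.size

    # Finite interval boundaries, used when integrating densities on [0, 1]
    # (e.g. the discretized beta initial distribution).
    def boundaries01(self) -> np.ndarray:
        b = self.midpoints.copy()
        b[0], b[-1] = 0.0, 1.0
        return b


@dataclass(frozen=True)
class PopSizeSchedule:
    """Per-generation diploid effective sizes; a scalar means constant size."""

    sizes: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.atleast_1d(np.asarray(self.sizes, dtype=float))
        if np.any(sizes <= 0):
            raise ValueError("effective population sizes must be positive")
        sizes.setflags(write=False)
        object.__setattr__(self, "sizes", sizes)

    @property
    def constant(self) -> bool:
        return self.sizes.size == 1

    def at(self, t: int) -> float:
        """Diploid size governing the transition from generation t to t+1 (1-based)."""
        if self.constant:
            return float(self.sizes[0])
        return float(self.sizes[t - 1])

    def expand(self, n_transitions: int) -> np.ndarray:
        if self.constant:
            return np.full(n_transitions, self.sizes[0])
        if self.sizes.size != n_transitions:
            raise ValueError(
                f"schedule has {self.sizes.size} entries, need {n_transitions}"
            )
        return np.asarray(self.sizes)


def chebychev_grid(M: int) -> FrequencyGrid:
    """Chebychev-node frequency grid with M states.

    Nodes are (1 + cos(pi i / (M-1)))/2 sorted ascending; the density of
    points is highest near the boundaries 0 and 1, where the Wright-Fisher
    transition kernel is narrowest.
    """
    if M < 2:
        raise ValueError("need at least two grid states")
    i = np.arange(M)
    nodes = 0.5 + 0.5 * np.cos(2.0 * np.pi * i / (2.0 * (M - 1)))
    nodes = np.sort(nodes)
    nodes[0], nodes[-1] = 0.0, 1.0  # cos endpoints, exact up to rounding
    return FrequencyGrid(nodes)


def mean_next_freq(p, params: SelectionParams):
    """Expected next-generation frequency p' = p + p(1-p)(s1(1-2p) + s2 p)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("frequency must lie in [0, 1]")
    out = p + p * (1.0 - p) * (params.s1 * (1.0 - 2.0 * p) + params.s2 * p)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BandedTransition:
    """Windowed storage of the transition matrix.

    Because the per-generation drift variance g(1-g)/(2 Ne) is tiny, each
    row's normal kernel is supported on a handful of neighboring grid
    intervals.  Row i holds ``width`` consecutive entries starting at column
    ``lo[i]``; mass beyond the +/- nsd-standard-deviation window is folded
    into the window's edge entries, so every row still sums to one exactly.
    """

    band: np.ndarray  # (M, width)
    lo: np.ndarray  # (M,) first column of each row's window

    @property
    def M(self) -> int:
        return self.band.shape[0]

    @property
    def width(self) -> int:
        return self.band.shape[1]

    def dense(self) -> np.ndarray:
        P = np.zeros((self.M, self.M))
        for i in range(self.M):
            P[i, self.lo[i] : self.lo[i] + self.width] = self.band[i]
        return P


def banded_transition(
    grid: FrequencyGrid, params: SelectionParams, Ne: float, nsd: float = 12.0
) -> BandedTransition:
    """Banded one-generation transition (see :class:`BandedTransition`).

    Numerically identical to :func:`transition_matrix` up to normal tail
    mass beyond ``nsd`` standard deviations (< 1e-30 at the default), which
    is folded back into the window edges to keep rows exactly stochastic.
    """
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    g = grid.nodes
    M = g.size
    h = g * (1.0 - g)
    mu = mean_next_freq(g, params)
    sd = np.sqrt(h / (2.0 * Ne))
    bounds = grid.boundaries01()  # finite interval edges, length M+1

    # window of grid nodes within mu +/- nsd*sd for each interior row
    lo = np.searchsorted(g, mu - nsd * sd, side="left") - 1
    hi = np.searchsorted(g, mu + nsd * sd, side="right")
    lo = np.clip(lo, 0, M - 1)
    hi = np.clip(hi, 0, M - 1)
    lo[0], hi[0] = 0, 0
    lo[-1], hi[-1] = M - 1, M - 1
    width = int((hi - lo).max()) + 1
    lo = np.minimum(lo, M - width)  # right-align windows that would overflow

    band = np.zeros((M, width))
    interior = np.arange(1, M - 1)
    # boundary columns of each window, evaluated at the interval edges;
    # the first edge is forced to -inf and the last to +inf so that the
    # window absorbs all remaining tail mass.
    cols = lo[interior, None] + np.arange(width + 1)[None, :]
    edge = bounds[np.clip(cols, 0, M)]
    edge[:, 0] = -np.inf
    edge[:, -1] = np.inf
    z = (edge - mu[interior, None]) / sd[interior, None]
    band[interior, :] = np.diff(ndtr(z), axis=1)
    band[0, 0] = 1.0
    band[M - 1, width - 1] = 1.0
    lo[M - 1] = M - width
    return BandedTransition(band, lo.astype(np.int64))


def transition_matrix(
    grid: FrequencyGrid, params: SelectionParams, Ne: float
) -> np.ndarray:
    """Row-stochastic one-generation transition matrix on the grid.

    Row i integrates a normal density with mean mu_i(s1, s2) and variance
    g_i(1-g_i)/(2 Ne) over the grid intervals; the sentinel boundaries at
    +/- infinity push any mass outside [0, 1] into the boundary states.  The
    fixed states g=0 and g=1 have zero variance and are exact point masses
    (absorbing), matching the diffusion's absorbing boundaries.
    """
    if Ne <= 0:
        raise ValueError("Ne must be positive")
    g = grid.nodes
    M = g.size
    h = g * (1.0 - g)
    mu = mean_next_freq(g, params)
    P = np.zeros((M, M))
    interior = slice(1, M - 1)
    sd = np.sqrt(h[interior] / (2.0 * Ne))
    z = (grid.midpoints[None, :] - mu[interior, None]) / sd[:, None]
    cdf = ndtr(z)  # ndtr(+/-inf) = 1/0 exactly
    P[interior, :] = np.diff(cdf, axis=1)
    P[0, 0] = 1.0
    P[M - 1, M - 1] = 1.0
    return P
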