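"""Hybrid EM estimator for diploid selection coefficients.

E-step expectations are computed under the discretized HMM; the M-step
maximizes the Gaussian path likelihood of the continuous Wright-Fisher
diffusion in closed form.  Because the expectation and maximization live in
slightly different models, the iteration is not an exact EM and monotone
ascent of the log-likelihood is not guaranteed; the fit therefore tracks the
running maximum of the likelihood trace and always performs a minimum number
of iterations (default 5) so that near-neutral fits are not frozen at the
s = 0 starting point.

The one-parameter selection modes (additive, dominant, recessive,
heterozygote difference) are linear constraints a*s1 - b*s2 = 0; restricted
to such a line the expected complete-data log-likelihood remains an exact
quadratic, so the constrained M-step is a closed-form 1-D maximizer -- the
Lagrange multiplier never needs to be represented explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc

from .hmm_core import EStepMoments, TemporalObservations, forward_backward
from .wf_model import (
    FrequencyGrid,
    SelectionParams,
    banded_transition,
    chebychev_grid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODES",
    "ConstraintSpec",
    "InitialDistribution",
    "EMConfig",
    "EMResult",
    "trajectory_mle",
    "m_step_unconstrained",
    "m_step_constrained",
    "discretized_beta",
    "beta_init_update",
    "run_em",
    "fit_all_modes",
]


@dataclass(frozen=True)
class ConstraintSpec:
    """A selection mode: either unconstrained, neutral, or a line a*s1 = b*s2.

    The direction vector (b, a) spans the constraint line; the scalar
    coordinate along it is the mode's reported selection coefficient s
    (s = s2 for additive/dominant/recessive, s = s1 for heterozygote
    difference).
    """

    mode: str
    a: float = 0.0
    b: float = 0.0

    _KNOWN = (
        "neutral",
        "additive",
        "dominant",
        "recessive",
        "het_diff",
        "unconstrained",
    )

    def __post_init__(self) -> None:
        if self.mode not in self._KNOWN:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.is_linear and self.a == 0.0 and self.b == 0.0:
            raise ValueError("constraint coefficients (a, b) must not both be zero")

    @property
    def is_linear(self) -> bool:
        return self.mode in ("additive", "dominant", "recessive", "het_diff")

    def direction(self) -> np.ndarray:
        """Unit-coordinate direction (s1, s2) per unit of the mode's s."""
        if self.mode == "additive":
            return np.array([0.5, 1.0])  # s = s2, s1 = s2/2
        if self.mode == "dominant":
            return np.array([1.0, 1.0])  # s = s1 = s2
        if self.mode == "recessive":
            return np.array([0.0, 1.0])  # s = s2, s1 = 0
        if self.mode == "het_diff":
            return np.array([1.0, 0.0])  # s = s1, s2 = 0
        raise ValueError(f"mode {self.mode!r} has no 1-D direction")

    @classmethod
    def for_mode(cls, mode: str) -> "ConstraintSpec":
        coeffs = {
            "additive": (2.0, 1.0),
            "dominant": (1.0, 1.0),
            "recessive": (1.0, 0.0),
            "het_diff": (0.0, 1.0),
        }
        a, b = coeffs.get(mode, (0.0, 0.0))
        return cls(mode, a, b)

    def params_from_s(self, s: float) -> SelectionParams:
        d = self.direction()
        return SelectionParams(s1=float(s * d[0]), s2=float(s * d[1]))


MODES = ("neutral", "additive", "dominant", "recessive", "het_diff")


@dataclass
class InitialDistribution:
    """Initial allele-frequency distribution over the grid.

    When ``estimate`` is true, a beta distribution with shape parameters
    (alpha, beta) is fitted alongside the selection coefficients; the mass
    assigned to each grid state is the beta integral over the state's
    interval, so the boundary states 0 and 1 carry the tail mass.
    """

    alpha: float = 1.0
    beta: float = 1.0
    estimate: bool = True
    fixed_mass: np.ndarray | None = None

    def mass(self, grid: FrequencyGrid) -> np.ndarray:
        if self.fixed_mass is not None:
            m = np.asarray(self.fixed_mass, dtype=float)
            if m.size != grid.M:
                raise ValueError("fixed initial mass length != grid size")
            return m / m.sum()
        return discretized_beta(self.alpha, self.beta, grid)

    @classmethod
    def uniform(cls) -> "InitialDistribution":
        """Uniform density on [0, 1] (Beta(1,1)), held fixed."""
        return cls(1.0, 1.0, estimate=False)

    @classmethod
    def fixed(cls, mass: np.ndarray) -> "InitialDistribution":
        return cls(estimate=False, fixed_mass=np.asarray(mass, dtype=float))


@dataclass(frozen=True)
class EMConfig:
    M: int = 500
    tol: float = 1e-3
    min_iters: int = 5
    max_iters: int = 500

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.min_iters < 1 or self.max_iters < self.min_iters:
            raise ValueError("invalid EM configuration")


@dataclass
class EMResult:
    mode: str
    s1: float
    s2: float
    alpha: float
    beta: float
    log_likelihood: float
    ll_trace: list[float]
    n_iter: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def s(self) -> float:
        """The mode's scalar coefficient (s2 except for het_diff)."""
        return self.s1 if self.mode == "het_diff" else self.s2


def discretized_beta(alpha: float, beta: float, grid: FrequencyGrid) -> np.ndarray:
    """Beta(alpha, beta) probability mass per grid interval.

    Uses the same midpoint intervals as the transition matrix; the two
    boundary intervals integrate from 0 and to 1 respectively, so the fixed
    states receive the beta tail mass.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta shape parameters must be positive")
    b = grid.boundaries01()
    cdf = betainc(alpha, beta, b)
    mass = np.diff(cdf)
    s = mass.sum()
    if not np.isfinite(s) or s <= 0:
        raise ValueError("degenerate discretized beta distribution")
    return mass / s


def _normal_equations(mom: EStepMoments) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic form of the expected Gaussian path log-likelihood.

    Up to an additive constant and a positive factor, the objective is
    Q(s1, s2) = L . s - s^T A s / 2 with A the curvature matrix and L the
    linear term; its stationary point solves A s = L.
    """
    A = np.array(
        [
            [
                mom.s_h - 4.0 * mom.s_fh + 4.0 * mom.s_f2h,
                mom.s_fh - 2.0 * mom.s_f2h,
            ],
            [mom.s_fh - 2.0 * mom.s_f2h, mom.s_f2h],
        ]
    )
    l2 = mom.s_incr
    l1 = (mom.e_last - mom.e_first) - 2.0 * l2
    return A, np.array([l1, l2])


def m_step_unconstrained(mom: EStepMoments) -> SelectionParams:
    """Closed-form maximizer of the expected complete-data log-likelihood."""
    A, L = _normal_equations(mom)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    scale = max(abs(A).max(), 1.0)
    if abs(det) < 1e-14 * scale**2:
        if np.allclose(L, 0.0, atol=1e-14):
            return SelectionParams(0.0, 0.0)
        raise np.linalg.LinAlgError("singular M-step normal equations")
    s = np.linalg.solve(A, L)
    return SelectionParams(float(s[0]), float(s[1]))


def m_step_constrained(
    mom: EStepMoments, constraint: ConstraintSpec
) -> SelectionParams:
    """Maximizer restricted to the constraint line a*s1 = b*s2.

    The objective is quadratic, so along the line s = s * v (v the direction
    vector) the maximizer is s* = (v.L) / (v.A v) in closed form.
    """
    A, L = _normal_equations(mom)
    v = constraint.direction()
    curv = float(v @ A @ v)
    if curv <= 0 or not np.isfinite(curv):
        return constraint.params_from_s(0.0)
    s = float(v @ L) / curv
    return constraint.params_from_s(s)


def trajectory_mle(traj: np.ndarray, Ne: float | None = None) -> SelectionParams:
    """Closed-form (s1, s2) MLE for a fully observed frequency trajectory.

    This is the degenerate case of the M-step where the posteriors are point
    masses on the observed path; the Gaussian path likelihood is quadratic in
    (s1, s2) and independent of Ne at its maximum.
    """
    p = np.asarray(traj, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("trajectory needs at least two generations")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("frequencies must lie in [0, 1]")
    pt, pn = p[:-1], p[1:]
    h = pt * (1.0 - pt)
    mom = EStepMoments(
        s_h=float(h.sum()),
        s_fh=float((pt * h).sum()),
        s_f2h=float((pt * pt * h).sum()),
        s_f2=float((pt * pt).sum()),
        s_cross=float((pt * pn).sum()),
        e_first=float(p[0]),
        e_last=float(p[-1]),
    )
    return m_step_unconstrained(mom)


def beta_init_update(
    gamma1: np.ndarray,
    grid: FrequencyGrid,
    start: tuple[float, float] = (1.0, 1.0),
    maxiter: int = 400,
) -> tuple[float, float]:
    """Update (alpha, beta) by maximizing sum_m gamma(1, m) ln p(m; alpha, beta).

    Optimized on the log scale with shapes bounded in [1e-3, 1e3]; on
    optimizer failure the previous values are kept with a warning.  A capped
    ``maxiter`` gives a partial (generalized-EM) update: warm-started from
    the previous iterate, the outer EM loop still converges to the same
    stationary point while each update stays cheap.
    """
    gamma1 = np.asarray(gamma1, dtype=float)
    b = grid.boundaries01()
    lo, hi = np.log(1e-3), np.log(1e3)

    def neg_obj(x: np.ndarray) -> float:
        mass = betainc(np.exp(x[0]), np.exp(x[1]), b)
        mass = mass[1:] - mass[:-1]
        lp = np.log(np.maximum(mass, 1e-300))
        return -float(gamma1 @ lp)

    x0 = np.log(np.clip(start, 1e-3, 1e3))
    step = 0.15
    simplex = np.array([x0, x0 + [step, 0.0], x0 + [0.0, step]])
    res = minimize(
        neg_obj,
        x0,
        method="Nelder-Mead",
        bounds=[(lo, hi), (lo, hi)],
        options={
            "xatol": 1e-7 if maxiter >= 400 else 1e-5,
            "fatol": 1e-11 if maxiter >= 400 else 1e-9,
            "maxiter": maxiter,
            "initial_simplex": simplex,
        },
    )
    if not np.isfinite(res.fun):
        warnings.warn("beta initial-distribution update failed; keeping previous")
        return start
    al, be = np.exp(res.x)
    return float(al), float(be)


def run_em(
    obs: TemporalObservations,
    constraint: ConstraintSpec,
    Ne: float,
    config: EMConfig = EMConfig(),
    init: InitialDistribution | None = None,
    grid: FrequencyGrid | None = None,
) -> EMResult:
    """Fit one selection mode by the hybrid EM-HMM.

    Alternates a forward-backward E-step with the closed-form M-step for the
    selection coefficients (per the constraint) and a numeric update of the
    beta initial distribution when it is estimated.  Stops once the
    log-likelihood change drops below ``config.tol`` and at least
    ``config.min_iters`` iterations have run; the reported log-likelihood is
    the maximum over the iteration trace, and the reported parameters are the
    ones that achieved it.
    """
    if obs.n_samples_total == 0:
        raise ValueError("all-missing data: nothing to fit")
    if init is None:
        init = InitialDistribution()
    else:
        init = replace(init)
    if grid is None:
        grid = chebychev_grid(config.M)
    flags: list[str] = []
    if not np.any((obs.a > 0) & (obs.a < obs.n)) and (
        obs.a.sum() == 0 or obs.a.sum() == obs.n.sum()
    ):
        flags.append("monomorphic_samples")

    from .hmm_core import _emissions

    ems = _emissions(obs, grid)  # emissions do not change across iterations
    fixed_pi = init.mass(grid) if (init.fixed_mass is not None or not init.estimate) else None
    params = SelectionParams(0.0, 0.0)
    alpha, beta = init.alpha, init.beta
    trace: list[float] = []
    best = (-np.inf, params, alpha, beta)
    converged = False
    k = 0
    while k < config.max_iters:
        k += 1
        P = banded_transition(grid, params, Ne)
        pi = fixed_pi if fixed_pi is not None else discretized_beta(alpha, beta, grid)
        post = forward_backward(obs, P, pi, grid, ems=ems)
        ll = post.log_likelihood
        trace.append(ll)
        if not np.isfinite(ll):
            flags.append("neg_inf_ll")
            break
        if ll > best[0]:
            best = (ll, params, alpha, beta)
        if (
            k >= config.min_iters
            and len(trace) >= 2
            and abs(trace[-1] - trace[-2]) < config.tol
        ):
            converged = True
            break
        # M-step
        if constraint.mode == "unconstrained":
            try:
                params = m_step_unconstrained(post.moments)
            except np.linalg.LinAlgError:
                flags.append("singular_m_step")
        elif constraint.is_linear:
            params = m_step_constrained(post.moments, constraint)
        # neutral: selection stays (0, 0)
        if init.estimate:
            alpha, beta = beta_init_update(
                post.gamma[0], grid, start=(alpha, beta), maxiter=60
            )
    if not converged and k >= config.max_iters:
        flags.append("max_iters")
        logger.warning("EM did not converge in %d iterations", config.max_iters)

    ll, params, alpha, beta = best
    return EMResult(
        mode=constraint.mode,
        s1=params.s1,
        s2=params.s2,
        alpha=alpha,
        beta=beta,
        log_likelihood=ll,
        ll_trace=trace,
        n_iter=k,
        converged=converged,
        flags=flags,
    )


def fit_all_modes(
    obs: TemporalObservations,
    Ne: float,
    config: EMConfig = EMConfig(),
    init: InitialDistribution | None = None,
    modes: tuple[str, ...] = MODES,
    grid: FrequencyGrid | None = None,
) -> dict[str, EMResult]:
    """Fit each requested selection mode independently on the same data."""
    if grid is None:
        grid = chebychev_grid(config.M)
    out: dict[str, EMResult] = {}
    for mode in modes:
        out[mode] = run_em(
            obs, ConstraintSpec.for_mode(mode), Ne, config, init, grid
        )
    return out
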