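"""Canned simulation studies for validating the estimator.

These reproduce the standard study conditions used throughout the package's
validation: neutral calibration of the likelihood-ratio tests, parameter
recovery under each selection mode, and recovery of the effective population
size from batches of neutral loci.  The default design is Ne = 10,000,
T = 251 generations, initial frequency fixed at 0.25, K = 11 equidistant
sampling times of 50 haploids each, with directional-mode segregation
conditioning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .em_fit import EMConfig, ConstraintSpec, InitialDistribution, fit_all_modes, run_em
from .ne_estimator import default_ne_grid, estimate_ne
from .selection_tests import ModeLikelihoods, delta_statistic
from .simulator import SimulationConfig, simulate_dataset
from .wf_model import chebychev_grid

__all__ = [
    "neutral_calibration_study",
    "parameter_recovery_study",
    "ne_recovery_study",
]

_FIT_MODE_FOR_SIM = {
    "additive": "additive",
    "dominant": "dominant",
    "recessive": "recessive",
    "overdominance": "het_diff",
    "underdominance": "het_diff",
}


def neutral_calibration_study(
    n_replicates: int = 1000,
    Ne: float = 10_000.0,
    T: int = 251,
    p0: float = 0.25,
    K: int = 11,
    n_per_time: int = 50,
    M: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate neutral replicates and fit all one-parameter modes.

    Returns one row per replicate with per-mode log-likelihoods and
    selection estimates, the single-alternative D statistics and p-values,
    and the multiple-alternative delta statistic with its chi-square(1)
    p-value.
    """
    reps = simulate_dataset(
        SimulationConfig(
            mode="neutral", T=T, Ne=Ne, init=p0, K=K,
            n_per_time=n_per_time, n_replicates=n_replicates, seed=seed,
        )
    )
    config = EMConfig(M=M)
    grid = chebychev_grid(M)
    rows = []
    for obs in reps.observations:
        res = fit_all_modes(obs, Ne, config, InitialDistribution(), grid=grid)
        ll0 = res["neutral"].log_likelihood
        row = {"ll0": ll0}
        for mode in ("additive", "dominant", "recessive", "het_diff"):
            ll = res[mode].log_likelihood
            D = max(0.0, 2.0 * (ll - ll0))
            row[f"ll_{mode}"] = ll
            row[f"s_{mode}"] = res[mode].s
            row[f"D_{mode}"] = D
            row[f"p_{mode}"] = chi2.sf(D, df=1)
        ml = ModeLikelihoods(
            ll0, row["ll_additive"], row["ll_dominant"],
            row["ll_recessive"], row["ll_het_diff"], row["s_het_diff"],
        )
        row["delta"] = delta_statistic(ml)
        row["p_delta"] = chi2.sf(row["delta"], df=1)
        rows.append(row)
    return pd.DataFrame(rows)


def parameter_recovery_study(
    sim_mode: str,
    s: float,
    n_replicates: int = 200,
    Ne: float = 10_000.0,
    T: int = 251,
    p0: float = 0.25,
    M: int = 250,
    seed: int = 0,
) -> np.ndarray:
    """Estimates of s from replicates simulated and fitted under one mode."""
    reps = simulate_dataset(
        SimulationConfig(
            mode=sim_mode, s=s, T=T, Ne=Ne, init=p0,
            n_replicates=n_replicates, seed=seed,
        )
    )
    fit_mode = _FIT_MODE_FOR_SIM[sim_mode]
    constraint = ConstraintSpec.for_mode(fit_mode)
    config = EMConfig(M=M)
    grid = chebychev_grid(M)
    return np.array(
        [
            run_em(obs, constraint, Ne, config, InitialDistribution(), grid).s
            for obs in reps.observations
        ]
    )


def ne_recovery_study(
    n_batches: int = 10,
    loci_per_batch: int = 2000,
    Ne: float = 10_000.0,
    ne_guess: float = 5000.0,
    M: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Composite-likelihood Ne estimates from batches of neutral loci.

    The grid guess is deliberately off the truth; the default grid spans
    a 64-fold range around it.
    """
    grid = chebychev_grid(M)
    ne_hats = []
    for b in range(n_batches):
        reps = simulate_dataset(
            SimulationConfig(
                mode="neutral", Ne=Ne, n_replicates=loci_per_batch,
                seed=seed + 7919 * b,
            )
        )
        res = estimate_ne(
            list(reps.observations), default_ne_grid(ne_guess), grid=grid
        )
        ne_hats.append(res.ne_hat)
    return np.asarray(ne_hats)
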