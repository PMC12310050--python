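"""Discrete Wright-Fisher forward simulator for temporal allele-count data.

Each replicate draws an initial frequency, propagates a frequency trajectory
by binomial reproduction with selection (absorbing at 0 and 1), thins the
planned haploid sample sizes by a missingness probability, draws binomial
samples at the sampling times, and finally applies the selection-mode
specific segregation conditioning by rejection: directional modes require
the focal allele not fixed in the first sample and not lost in the last;
overdominance requires it segregating in the last sample; underdominance in
the first.

One root seed drives everything: per-replicate RNG streams are spawned
deterministically, so a fixed seed reproduces a dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hmm_core import TemporalObservations
from .wf_model import PopSizeSchedule, SelectionParams

__all__ = [
    "SimulationConfig",
    "ReplicateSet",
    "sim_params_for_mode",
    "equidistant_times",
    "simulate_trajectory",
    "draw_initial",
    "apply_conditioning",
    "sample_observations",
    "simulate_dataset",
    "permute_sampling_times",
]

_MAX_REJECTIONS = 1_000_000

SIM_MODES = (
    "neutral",
    "additive",
    "dominant",
    "recessive",
    "overdominance",
    "underdominance",
)


def sim_params_for_mode(mode: str, s: float) -> SelectionParams:
    """Map a simulation mode's scalar s to (s1, s2).

    Over-/underdominance use the complete heterozygote-difference
    parameterization s1 = s, s2 = 0 (s > 0 resp. s < 0).
    """
    if mode == "neutral":
        return SelectionParams(0.0, 0.0)
    if mode == "additive":
        return SelectionParams(s / 2.0, s)
    if mode == "dominant":
        return SelectionParams(s, s)
    if mode == "recessive":
        return SelectionParams(0.0, s)
    if mode == "overdominance":
        if s <= 0:
            raise ValueError("overdominance requires s > 0")
        return SelectionParams(s, 0.0)
    if mode == "underdominance":
        if s >= 0:
            raise ValueError("underdominance requires s < 0")
        return SelectionParams(s, 0.0)
    raise ValueError(f"unknown simulation mode {mode!r}")


def equidistant_times(T: int, K: int) -> np.ndarray:
    """K equidistant 1-based sampling times including both endpoints 1 and T."""
    if K < 2 or T < 2:
        raise ValueError("need K >= 2 sampling times over T >= 2 generations")
    times = np.rint(np.linspace(1, T, K)).astype(np.int64)
    if np.unique(times).size != K:
        raise ValueError("K too large for T: duplicate sampling times")
    return times


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one simulated dataset (the defaults follow the standard
    simulation study: Ne = 10,000, T = 251 generations, initial frequency
    0.25, 11 equidistant sampling times of 50 haploids each)."""

    mode: str = "neutral"
    s: float = 0.0
    T: int = 251
    Ne: PopSizeSchedule | float = 10_000.0
    init: str | float = 0.25  # fixed p, "one_over_i", or "explicit"
    init_freqs: np.ndarray | None = None  # used when init == "explicit"
    times: np.ndarray | None = None  # default: K equidistant
    K: int = 11
    n_per_time: int | np.ndarray = 50
    missingness: float | np.ndarray = 0.0
    n_replicates: int = 1
    seed: int = 0
    condition: bool = True
    keep_trajectories: bool = False

    def schedule(self) -> PopSizeSchedule:
        ne = self.Ne
        return ne if isinstance(ne, PopSizeSchedule) else PopSizeSchedule(np.array([ne]))

    def sampling_times(self) -> np.ndarray:
        if self.times is not None:
            t = np.asarray(self.times, dtype=np.int64)
            if np.any(t < 1) or np.any(t > self.T):
                raise ValueError("sampling times must lie in [1, T]")
            return t
        return equidistant_times(self.T, self.K)

    def sample_sizes(self) -> np.ndarray:
        times = self.sampling_times()
        n = np.broadcast_to(np.asarray(self.n_per_time, dtype=np.int64), times.shape)
        return n.copy()


@dataclass
class ReplicateSet:
    observations: list[TemporalObservations]
    config: SimulationConfig
    rejections: np.ndarray
    trajectories: list[np.ndarray] | None = None
    seeds: list[int] = field(default_factory=list)


def draw_initial(
    spec: str | float,
    Ne: float,
    rng: np.random.Generator,
    explicit: float | None = None,
) -> float:
    """Draw a replicate's initial frequency.

    ``spec`` is either a fixed frequency, "one_over_i" for the neutral
    standing-variation law P(i) proportional to 1/i on i in {1, .., 2Ne-1}
    (frequency i/(2Ne)), or "explicit" to use the supplied per-replicate
    value (the hook for data-matched designs).
    """
    if spec == "one_over_i":
        m = int(round(2 * Ne)) - 1
        if m < 1:
            raise ValueError("2Ne must exceed 1 for one_over_i initial draws")
        i = np.arange(1, m + 1)
        w = 1.0 / i
        idx = rng.choice(m, p=w / w.sum())
        return float(i[idx] / (2.0 * Ne))
    if spec == "explicit":
        if explicit is None:
            raise ValueError("explicit initial frequency not provided")
        return float(explicit)
    p = float(spec)
    if not 0.0 <= p <= 1.0:
        raise ValueError("fixed initial frequency must lie in [0, 1]")
    return p


def simulate_trajectory(
    p0: float,
    T: int,
    params: SelectionParams,
    schedule: PopSizeSchedule,
    rng: np.random.Generator,
) -> np.ndarray:
    """Forward-simulate p_1..p_T; p_{t+1} = Bin(2Ne_t, p'_t) / (2Ne_t)."""
    ne = schedule.expand(T - 1)
    p = np.empty(T)
    p[0] = p0
    x = p0
    for t in range(T - 1):
        if x <= 0.0 or x >= 1.0:
            p[t + 1 :] = x  # absorbed
            return p
        two_ne = int(round(2.0 * ne[t]))
        pp = x + x * (1.0 - x) * (
            params.s1 * (1.0 - 2.0 * x) + params.s2 * x
        )
        pp = min(max(pp, 0.0), 1.0)
        x = rng.binomial(two_ne, pp) / two_ne
        p[t + 1] = x
    return p


def sample_observations(
    traj: np.ndarray,
    times: np.ndarray,
    n_per_time: np.ndarray,
    missingness: float | np.ndarray,
    rng: np.random.Generator,
) -> TemporalObservations:
    """Binomial sampling of haplotypes at the given times, after thinning the
    planned sample sizes by the per-time missingness probability."""
    times = np.asarray(times, dtype=np.int64)
    n_plan = np.asarray(n_per_time, dtype=np.int64)
    miss = np.broadcast_to(np.asarray(missingness, dtype=float), times.shape)
    if np.any((miss < 0) | (miss > 1)):
        raise ValueError("missingness probabilities must lie in [0, 1]")
    n_eff = rng.binomial(n_plan, 1.0 - miss)
    p = traj[times - 1]
    a = rng.binomial(n_eff, p)
    return TemporalObservations.from_samples(traj.size, times, n_eff, a)


def apply_conditioning(obs: TemporalObservations, mode: str) -> bool:
    """Mode-specific segregation conditioning, evaluated on the samples.

    Timepoints with no surviving samples (n = 0 after missingness thinning)
    cannot witness fixation or loss, so the rule is evaluated at the first
    and last timepoints that carry data.
    """
    times = obs.sample_times
    if times.size == 0:
        return False
    first, last = times[0] - 1, times[-1] - 1
    if mode == "overdominance":
        return 0 < obs.a[last] < obs.n[last]
    if mode == "underdominance":
        return 0 < obs.a[first] < obs.n[first]
    # neutral and directional modes: not fixed at first, not lost at last
    return obs.a[first] < obs.n[first] and obs.a[last] > 0


def simulate_dataset(config: SimulationConfig) -> ReplicateSet:
    """Simulate conditioned replicates by rejection sampling."""
    if config.mode not in SIM_MODES:
        raise ValueError(f"unknown simulation mode {config.mode!r}")
    params = sim_params_for_mode(config.mode, config.s)
    schedule = config.schedule()
    times = config.sampling_times()
    n_plan = config.sample_sizes()
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_replicates)
    ne_first = schedule.at(1)

    obs_list: list[TemporalObservations] = []
    trajs: list[np.ndarray] | None = [] if config.keep_trajectories else None
    rejections = np.zeros(config.n_replicates, dtype=np.int64)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        explicit = None
        if config.init == "explicit":
            if config.init_freqs is None:
                raise ValueError("init='explicit' requires init_freqs")
            explicit = float(
                np.asarray(config.init_freqs)[r % len(config.init_freqs)]
            )
        while True:
            p0 = draw_initial(config.init, ne_first, rng, explicit)
            traj = simulate_trajectory(p0, config.T, params, schedule, rng)
            obs = sample_observations(
                traj, times, n_plan, config.missingness, rng
            )
            if not config.condition or apply_conditioning(obs, config.mode):
                break
            rejections[r] += 1
            if rejections[r] >= _MAX_REJECTIONS:
                raise RuntimeError(
                    f"replicate {r}: conditioning event not hit in "
                    f"{_MAX_REJECTIONS} attempts"
                )
        obs_list.append(obs)
        if trajs is not None:
            trajs.append(traj)
    return ReplicateSet(
        observations=obs_list,
        config=config,
        rejections=rejections,
        trajectories=trajs,
        seeds=[int(s.generate_state(1)[0] % (2**31)) for s in streams],
    )


def permute_sampling_times(
    dataset: ReplicateSet, rng: np.random.Generator
) -> ReplicateSet:
    """Shuffle the assignment of (n, a) sample blocks to sampling times.

    Each replicate's multiset of samples is preserved; only which timepoint
    each block is attached to changes.  Used as a negative control: under
    neutrality the permuted dataset should be statistically indistinguishable
    from the original.
    """
    new_obs = []
    for obs in dataset.observations:
        times = obs.sample_times
        perm = rng.permutation(times.size)
        new_obs.append(
            TemporalObservations.from_samples(
                obs.T,
                times,
                obs.n[times - 1][perm],
                obs.a[times - 1][perm],
            )
        )
    return replace(dataset, observations=new_obs)
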