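"""Genome-scan layer: SNP filters, windowed p-value aggregation, FDR
thresholds, region calling, and parametric-bootstrap confidence intervals.

Isolated low p-values at single SNPs are a common artifact in ancient-DNA
scans; true sweeps drag linked neighbors along (hitchhiking).  To exploit
this, each SNP's p-value is combined with its 50 nearest neighbors via a
Brown's-method style statistic S = -sum log p, referred to a scaled
chi-square distribution fitted genome-wide by moment matching.  Candidate
regions are contiguous runs of post-processed significance that also contain
at least one raw-significant SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .em_fit import EMConfig, ConstraintSpec, InitialDistribution, run_em
from .simulator import SimulationConfig, simulate_dataset
from .wf_model import chebychev_grid

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRecord",
    "RegionCall",
    "snp_filters",
    "brown_window_pvalues",
    "bh_select",
    "call_regions",
    "bootstrap_ci",
]

_SIM_MODE_FOR_FIT = {
    "additive": "additive",
    "dominant": "dominant",
    "recessive": "recessive",
}


@dataclass
class ScanRecord:
    """Per-SNP scan state (positions 1-based inclusive)."""

    locus_id: str
    chrom: str
    position: int
    n_timepoints: int
    n_samples_total: int
    pooled_maf: float
    raw_p: float = np.nan
    post_p: float = np.nan
    filter_pass: bool = False
    filter_reasons: list[str] = field(default_factory=list)
    label: str = ""


@dataclass
class RegionCall:
    chrom: str
    start: int
    end: int
    member_ids: list[str]
    lead_id: str
    lead_p: float
    n_raw_significant: int
    n_post_significant: int


def snp_filters(
    n_timepoints: int,
    n_samples_total: int,
    pooled_maf: float,
    min_samples: int = 50,
) -> tuple[bool, list[str]]:
    """Three per-SNP filters: >= 2 sampled timepoints, strictly more than
    ``min_samples`` samples in total, and pooled minor allele frequency
    strictly above 0.05."""
    reasons = []
    if n_timepoints < 2:
        reasons.append("timepoints")
    if not n_samples_total > min_samples:
        reasons.append("total_samples")
    if not pooled_maf > 0.05:
        reasons.append("maf")
    return (not reasons), reasons


def _window_sums(neglogp: np.ndarray, window: int) -> np.ndarray:
    """Window sums of -log p centered on each locus (window//2 upstream,
    window//2 - 1 downstream, plus the focal locus), truncated at the
    chromosome ends and rescaled to the full window size."""
    m = neglogp.size
    up = window // 2
    down = window - up - 1
    cum = np.concatenate([[0.0], np.cumsum(neglogp)])
    idx = np.arange(m)
    lo = np.maximum(idx - up, 0)
    hi = np.minimum(idx + down, m - 1)
    sums = cum[hi + 1] - cum[lo]
    actual = hi - lo + 1
    return sums * (window / actual)


def brown_window_pvalues(
    pvalues_by_chrom: dict[str, np.ndarray], window: int = 50
) -> dict[str, np.ndarray]:
    """Post-processed p-values by a windowed Brown's-method statistic.

    For each SNP (ordered by position within its chromosome) the statistic is
    S = -sum log p over the ``window``-SNP window centered on it.  A scaled
    chi-square (scale c, dof f) is fitted to all S genome-wide by moment
    matching, c = Var/(2 Mean) and f = 2 Mean^2/Var, and the post-processed
    p-value is its upper tail at S.
    """
    from scipy.stats import chi2

    sums: dict[str, np.ndarray] = {}
    tiny = np.finfo(float).tiny
    for chrom, p in pvalues_by_chrom.items():
        p = np.asarray(p, dtype=float)
        if np.any(p <= 0):
            warnings.warn("p-values of 0 clamped to the smallest positive float")
            p = np.maximum(p, tiny)
        if np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        sums[chrom] = _window_sums(-np.log(p), window)
    pooled = np.concatenate(list(sums.values()))
    mean, var = pooled.mean(), pooled.var()
    if var <= 1e-12 * mean**2:
        # numerically constant sums: no ranking information, post p = 1
        return {chrom: np.ones_like(s) for chrom, s in sums.items()}
    c = var / (2.0 * mean)
    f = 2.0 * mean**2 / var
    return {chrom: chi2.sf(s / c, df=f) for chrom, s in sums.items()}


def bh_select(pvalues, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (threshold, boolean selection).

    The threshold is p_(k) for the largest k with p_(k) <= k*alpha/m, or 0
    with an empty selection when no p-value passes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) * alpha) / m
    passing = np.nonzero(ranked <= crit)[0]
    if passing.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    k = passing[-1]
    thr = float(ranked[k])
    return thr, p <= thr


def call_regions(
    records: list[ScanRecord],
    raw_threshold: float,
    post_threshold: float,
) -> list[RegionCall]:
    """Contiguous runs of post-significant SNPs containing at least one SNP
    that is significant under BOTH the raw and the post-processed BH
    thresholds.  The lead SNP is the member with the smallest raw p-value."""
    by_chrom: dict[str, list[ScanRecord]] = {}
    for rec in records:
        if rec.filter_pass:
            by_chrom.setdefault(rec.chrom, []).append(rec)
    regions: list[RegionCall] = []
    for chrom in sorted(by_chrom):
        recs = sorted(by_chrom[chrom], key=lambda r: r.position)
        run: list[ScanRecord] = []
        for rec in recs + [None]:
            if rec is not None and rec.post_p <= post_threshold:
                run.append(rec)
                continue
            if run:
                raw_sig = [
                    r
                    for r in run
                    if r.raw_p <= raw_threshold and r.post_p <= post_threshold
                ]
                if raw_sig:
                    lead = min(run, key=lambda r: r.raw_p)
                    regions.append(
                        RegionCall(
                            chrom=chrom,
                            start=run[0].position,
                            end=run[-1].position,
                            member_ids=[r.locus_id for r in run],
                            lead_id=lead.locus_id,
                            lead_p=lead.raw_p,
                            n_raw_significant=len(raw_sig),
                            n_post_significant=len(run),
                        )
                    )
                run = []
    return regions


def bootstrap_ci(
    mode: str,
    s_hat: float,
    init_freq: float,
    times: np.ndarray,
    n_per_time: np.ndarray,
    Ne: float,
    reps: int = 1000,
    rng: np.random.Generator | None = None,
    config: EMConfig = EMConfig(),
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-bootstrap confidence interval for a lead SNP's s-hat.

    Simulates ``reps`` replicates at the fitted mode, coefficient, initial
    frequency and sampling scheme, refits the same mode, subtracts the mean
    bias (mean simulated s-hat minus s-hat), and returns the outer quantiles
    of the corrected estimates.
    """
    if reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if rng is None:
        rng = np.random.default_rng()
    seed = int(rng.integers(2**31 - 1))
    times = np.asarray(times, dtype=np.int64)
    sim_mode = _SIM_MODE_FOR_FIT.get(mode)
    if sim_mode is None:
        if mode != "het_diff":
            raise ValueError(f"cannot bootstrap mode {mode!r}")
        sim_mode = "overdominance" if s_hat > 0 else "underdominance"
        if s_hat == 0:
            sim_mode = "neutral"
    sim = simulate_dataset(
        SimulationConfig(
            mode=sim_mode if s_hat != 0 else "neutral",
            s=s_hat,
            T=int(times[-1]),
            Ne=Ne,
            init=float(init_freq),
            times=times,
            n_per_time=np.asarray(n_per_time, dtype=np.int64),
            n_replicates=reps,
            seed=seed,
        )
    )
    grid = chebychev_grid(config.M)
    constraint = ConstraintSpec.for_mode(mode)
    estimates = []
    failures = 0
    for obs in sim.observations:
        try:
            res = run_em(obs, constraint, Ne, config, InitialDistribution(), grid)
            estimates.append(res.s)
        except (ValueError, FloatingPointError):
            failures += 1
    if failures > 0.1 * reps:
        raise RuntimeError(f"{failures}/{reps} bootstrap refits failed")
    if failures:
        logger.warning("%d bootstrap refits failed and were excluded", failures)
    est = np.asarray(estimates)
    corrected = est - (est.mean() - s_hat)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(corrected, lo)),
        float(np.quantile(corrected, 1.0 - lo)),
    )
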