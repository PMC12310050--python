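"""Likelihood-ratio tests against neutrality and selection-mode classification.

For a single one-parameter alternative the statistic D = 2(ll_s - ll_0) is
referred to a chi-square distribution with one degree of freedom.  With
multiple alternatives the statistic

    delta = -2 (ll_0 - max(ll_add, ll_dom, ll_rec, ll_het))

is likewise referred to chi-square(1); this choice is deliberately simple and
known to be mildly anti-conservative in the tail (a chi-square(2) reference,
offered for comparison only, calibrates worse).  Significant loci are
labelled by the argmax mode, with the heterozygote-difference mode split into
overdominant (s1 > 0) and underdominant (s1 < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "ModeLikelihoods",
    "ClassificationResult",
    "lrt_pvalue",
    "delta_statistic",
    "classify",
    "roc_auc",
    "confusion_matrix",
    "LABELS",
]

LABELS = (
    "neutral",
    "additive",
    "dominant",
    "recessive",
    "overdominant",
    "underdominant",
)

_ALT_ORDER = ("additive", "dominant", "recessive", "het_diff")


@dataclass(frozen=True)
class ModeLikelihoods:
    """Per-mode maximized log-likelihoods plus the het-diff s1 sign carrier."""

    ll0: float
    ll_add: float
    ll_dom: float
    ll_rec: float
    ll_het: float
    s1_het: float = 0.0

    def alt_lls(self) -> dict[str, float]:
        return {
            "additive": self.ll_add,
            "dominant": self.ll_dom,
            "recessive": self.ll_rec,
            "het_diff": self.ll_het,
        }


@dataclass(frozen=True)
class ClassificationResult:
    statistic: float
    p_value: float
    label: str
    tie_broken: bool = False


def lrt_pvalue(ll_s: float, ll_0: float) -> tuple[float, float]:
    """Likelihood-ratio statistic D = 2(ll_s - ll_0) and chi-square(1) p-value.

    Small negative differences from numeric noise are clamped to zero
    (the alternative nests the null).
    """
    D = 2.0 * (ll_s - ll_0)
    if D < 0.0:
        D = 0.0
    return D, float(chi2.sf(D, df=1))


def delta_statistic(ml: ModeLikelihoods) -> float:
    """delta = -2 (ll0 - max mode ll), clamped at 0; equals the largest D."""
    best = max(ml.alt_lls().values())
    return max(0.0, -2.0 * (ml.ll0 - best))


def classify(
    ml: ModeLikelihoods, threshold: float = 0.05, df: int = 1
) -> ClassificationResult:
    """Classify a locus's selection mode from its per-mode likelihoods.

    Rejects neutrality when the chi-square(df) p-value of delta falls below
    ``threshold``; significant loci get the argmax mode, ties resolved in the
    fixed order additive, dominant, recessive, het_diff (and flagged).
    ``df=2`` is offered for calibration comparisons only.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    delta = delta_statistic(ml)
    p = float(chi2.sf(delta, df=df))
    if p >= threshold:
        return ClassificationResult(delta, p, "neutral")
    lls = ml.alt_lls()
    best = max(lls.values())
    winners = [m for m in _ALT_ORDER if lls[m] == best]
    mode = winners[0]
    if mode == "het_diff":
        label = "overdominant" if ml.s1_het > 0 else "underdominant"
    else:
        label = mode
    return ClassificationResult(delta, p, label, tie_broken=len(winners) > 1)


def roc_auc(neutral_stats, selected_stats) -> float:
    """Rank-based AUC: P(selected statistic > neutral statistic), ties 1/2."""
    x = np.asarray(neutral_stats, dtype=float)
    y = np.asarray(selected_stats, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both statistic lists must be nonempty")
    order = np.concatenate([x, y])
    ranks = pd.Series(order).rank(method="average").to_numpy()
    ry = ranks[x.size :]
    u = ry.sum() - y.size * (y.size + 1) / 2.0
    return float(u / (x.size * y.size))


def confusion_matrix(true_labels, inferred_labels) -> pd.DataFrame:
    """Row-normalized confusion table over the six selection labels."""
    true_labels = list(true_labels)
    inferred_labels = list(inferred_labels)
    if len(true_labels) != len(inferred_labels):
        raise ValueError("label lists must have equal length")
    for lab in set(true_labels) | set(inferred_labels):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}")
    mat = pd.DataFrame(0.0, index=list(LABELS), columns=list(LABELS))
    for t, i in zip(true_labels, inferred_labels):
        mat.loc[t, i] += 1.0
    sums = mat.sum(axis=1)
    nonzero = sums > 0
    mat.loc[nonzero] = mat.loc[nonzero].div(sums[nonzero], axis=0)
    return mat
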