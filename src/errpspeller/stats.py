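"""Condition statistics: exact Wilcoxon signed-rank tests, binomial chance
thresholds, and FBon vs FBoff comparisons.

The small sample sizes here (6 CV folds per subject, 10 subjects) demand the
*exact* two-sided signed-rank distribution: with six folds all favouring one
condition the attainable two-sided p is 2/2^6 = 0.0313, which a normal
approximation misstates badly. The exact distribution is built by dynamic
programming over rank sums (equivalent to enumerating all 2^n sign
assignments, midranks handle ties), switching to the tie-corrected normal
approximation above n = 25.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank_exact", "binomial_chance_threshold",
    "compare_conditions", "ConditionComparison",
]

logger = logging.getLogger(__name__)

EXACT_LIMIT = 25


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p of the signed-rank statistic via the characteristic
    polynomial of the rank-sum distribution (ties allowed via midranks)."""
    # work in half-rank integer units so midranks stay integral
    units = np.round(ranks * 2).astype(int)
    total = int(units.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for u in units:
        shifted = np.zeros_like(dist)
        shifted[u:] = dist[: total + 1 - u]
        dist = dist + shifted
    dist /= dist.sum()
    w_units = int(round(w_plus * 2))
    p_low = float(dist[: w_units + 1].sum())
    p_high = float(dist[w_units:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def wilcoxon_signed_rank_exact(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (standard convention; count logged). All
    differences zero returns p = 1 with a warning. Exact distribution for
    n <= 25 effective pairs, tie-corrected normal approximation beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D samples, n >= 2")
    d = x - y
    nz = d != 0
    n_dropped = int(np.sum(~nz))
    if n_dropped:
        logger.info("wilcoxon: dropped %d zero differences", n_dropped)
    d = d[nz]
    if len(d) == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if len(d) <= EXACT_LIMIT:
        return _exact_two_sided_p(ranks, w_plus)
    res = sps.wilcoxon(d, method="approx", alternative="two-sided")
    return float(res.pvalue)


def binomial_chance_threshold(n: int, confidence: float = 0.95,
                              method: str = "normal") -> float:
    """Smallest accuracy credibly above chance for a 2-class test of ``n``
    trials.

    ``method='normal'`` returns the Gaussian upper bound
    ``0.5 + z_conf * sqrt(0.25 / n)`` (the dashed chance line drawn in
    accuracy panels); ``method='exact'`` returns the smallest ``k/n`` whose
    upper-tail Binomial(n, 0.5) probability is at most ``1 - confidence``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    if method == "normal":
        return float(0.5 + sps.norm.ppf(confidence) * np.sqrt(0.25 / n))
    if method == "exact":
        k = np.arange(n + 1)
        tail = sps.binom.sf(k - 1, n, 0.5)  # P(X >= k)
        ok = np.nonzero(tail <= 1.0 - confidence)[0]
        return float(k[ok[0]] / n) if len(ok) else 1.0
    raise ValueError("method must be 'normal' or 'exact'")


@dataclass
class ConditionComparison:
    """FBon vs FBoff comparison of one metric across subjects and folds."""

    metric: str
    per_subject: dict[str, tuple[float, float]]    # subject -> (FBon, FBoff)
    across_subject_p: float
    per_subject_p: dict[str, float]
    flagged: dict[str, bool]                        # per-subject p < level
    level: float = 0.05

    @property
    def significant_across(self) -> bool:
        return self.across_subject_p < self.level


def compare_conditions(results: dict, metric: str = "accuracy",
                       level: float = 0.05) -> ConditionComparison:
    """Compare FBon vs FBoff cross-validation results.

    ``results`` maps subject id -> {'FBon': CVResult, 'FBoff': CVResult}.
    Across subjects: paired Wilcoxon on the per-subject fold means. Per
    subject: Wilcoxon across fold pairs (matched by fold index), flagged at
    ``level``. Raises (naming the subject) when a condition is missing.
    """
    if metric not in ("accuracy", "auc"):
        raise ValueError("metric must be 'accuracy' or 'auc'")
    for subject, pair in results.items():
        for cond in ("FBon", "FBoff"):
            if cond not in pair:
                raise ValueError(f"subject {subject!r} missing condition {cond}")

    def fold_values(cv):
        return cv.fold_accuracies if metric == "accuracy" else cv.fold_aucs

    per_subject, per_subject_p, flagged = {}, {}, {}
    on_means, off_means = [], []
    for subject, pair in results.items():
        on, off = pair["FBon"], pair["FBoff"]
        m_on, m_off = float(fold_values(on).mean()), float(fold_values(off).mean())
        per_subject[subject] = (m_on, m_off)
        on_means.append(m_on)
        off_means.append(m_off)
        v_on, v_off = fold_values(on), fold_values(off)
        k = min(len(v_on), len(v_off))
        if k >= 2:
            p = wilcoxon_signed_rank_exact(v_on[:k], v_off[:k])
        else:
            p = 1.0
        per_subject_p[subject] = p
        flagged[subject] = p < level
    across = wilcoxon_signed_rank_exact(on_means, off_means) \
        if len(on_means) >= 2 else 1.0
    return ConditionComparison(
        metric=metric, per_subject=per_subject, across_subject_p=across,
        per_subject_p=per_subject_p, flagged=flagged, level=level,
    )
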