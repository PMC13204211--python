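"""Nonparametric statistical scheme: tie-corrected Kruskal-Wallis with an
exact small-sample option, the two-stage adaptive linear step-up FDR
procedure of Benjamini, Krieger and Yekutieli, targeted reference-profile
post hoc comparisons, and median/IQR summaries.

Percentile rule: linear interpolation, pinned and printed in reports
(software defaults differ across tools).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2, mannwhitneyu, rankdata

from .types import GroupComparison

#: Below this pooled sample size the Kruskal-Wallis p-value is computed by
#: exhaustive permutation instead of the chi-square approximation.
EXACT_N_MAX = 10


def _kw_statistic(samples: Sequence[np.ndarray]) -> float:
    """Tie-corrected H.  All-tied data (tie correction 0) yields H = 0."""
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = rankdata(pooled)  # mid-ranks
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(tie_counts**3 - tie_counts)) / (n_total**3 - n_total)
    if correction == 0.0:
        return 0.0
    return h / correction


def _exact_permutation_p(samples: Sequence[np.ndarray], h_obs: float) -> float:
    """Exhaustive permutation p-value: the proportion of reassignments of
    the pooled observations to the group sizes with H >= observed."""
    pooled = np.concatenate(samples)
    sizes = [s.size for s in samples]
    idx_all = list(range(pooled.size))
    count = 0
    total = 0

    def recurse(remaining: List[int], gi: int, chosen: List[np.ndarray]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            groups = chosen + [pooled[remaining]]
            total += 1
            if _kw_statistic(groups) >= h_obs - 1e-12:
                count += 1
            return
        for comb in itertools.combinations(remaining, sizes[gi]):
            rest = [i for i in remaining if i not in set(comb)]
            recurse(rest, gi + 1, chosen + [pooled[list(comb)]])

    recurse(idx_all, 0, [])
    return count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]], method: str = "auto"
) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis test over two or more samples.

    Returns ``(H, p)``.  ``method``: "asymptotic" refers H to chi-square
    with k-1 df; "exact" enumerates all permutations; "auto" (default)
    uses the exact path when the pooled size is at most ``EXACT_N_MAX``.
    H = 0 and p = 1 when every pooled observation is tied.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group must contain at least one observation")
    n_total = sum(s.size for s in samples)
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    h = _kw_statistic(samples)
    if np.unique(np.concatenate(samples)).size == 1:
        return 0.0, 1.0
    use_exact = method == "exact" or (method == "auto" and n_total <= EXACT_N_MAX)
    if use_exact:
        p = _exact_permutation_p(samples, h)
    else:
        p = float(chi2.sf(h, df=len(samples) - 1))
    return float(h), p


def bky_fdr(
    pvals: Sequence[float], alpha: float = 0.05
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-stage adaptive linear step-up FDR control.

    Stage 1 runs the linear step-up at level ``alpha' = alpha/(1+alpha)``;
    the number of non-rejections estimates the true nulls ``m0``.  Stage 2
    re-runs the step-up at ``alpha' * m/m0``.  If the first stage rejects
    nothing, nothing is rejected; if it rejects everything, everything is.

    Returns ``(reject, adjusted)`` where ``adjusted`` is scaled so that
    ``adjusted <= alpha`` reproduces the decisions exactly:
    ``adjusted_i = (1+alpha) * min_{j>=i} (m0 * p_(j) / j)`` (clipped to 1).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    r1 = _step_up_count(p, alpha1, m)
    if r1 == 0:
        m0 = m
        reject = np.zeros(m, dtype=bool)
    elif r1 == m:
        m0 = 0
        reject = np.ones(m, dtype=bool)
    else:
        m0 = m - r1
        r2 = _step_up_count(p, alpha1 * m / m0, m)
        order = np.argsort(p, kind="stable")
        reject = np.zeros(m, dtype=bool)
        reject[order[:r2]] = True
    adjusted = _step_up_adjusted(p, m0 if m0 > 0 else 0, alpha)
    return reject, adjusted


def _step_up_count(p: np.ndarray, level: float, m: int) -> int:
    """Number of rejections of the linear step-up at ``level`` with m
    hypotheses: largest k with p_(k) <= k * level / m."""
    srt = np.sort(p)
    below = srt <= (np.arange(1, m + 1) * level / m)
    return int(np.nonzero(below)[0][-1] + 1) if below.any() else 0


def _step_up_adjusted(p: np.ndarray, m0: int, alpha: float) -> np.ndarray:
    m = p.size
    if m0 == 0:
        return np.zeros(m)
    order = np.argsort(p, kind="stable")
    srt = p[order]
    vals = m0 * srt / np.arange(1, m + 1)
    vals = np.minimum.accumulate(vals[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum((1.0 + alpha) * vals, 1.0)
    return adjusted


def describe(sample: Sequence[float]) -> Tuple[float, Tuple[float, float]]:
    """Median and 25th-75th percentile interval (linear interpolation)."""
    s = np.asarray(sample, dtype=float)
    if s.size == 0:
        raise ValueError("sample must be nonempty")
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def _pairwise_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum comparison (documented, swappable choice for the
    pairwise statistic).  Degenerate all-tied data returns p = 1."""
    if np.unique(np.concatenate([x, y])).size == 1:
        return 1.0
    return float(mannwhitneyu(x, y, alternative="two-sided").pvalue)


def targeted_posthoc(
    metric: str,
    per_profile_samples: Mapping[object, Sequence[float]],
    alpha: float = 0.05,
) -> GroupComparison:
    """Targeted comparison design for one metric.

    The reference is the profile whose median is closest to the global
    (pooled) median of the metric; ties go to the lowest profile id and are
    flagged.  Every other profile is compared to the reference with a
    two-sample rank test, and the raw p-values pass through the two-stage
    FDR procedure.  The omnibus Kruskal-Wallis across all profiles is
    reported alongside.
    """
    keys = sorted(per_profile_samples)
    if len(keys) < 2:
        raise ValueError("need at least two profiles with data")
    samples = {k: np.asarray(per_profile_samples[k], dtype=float) for k in keys}
    if any(s.size == 0 for s in samples.values()):
        raise ValueError("every profile must contain at least one observation")
    pooled = np.concatenate([samples[k] for k in keys])
    global_median = float(np.median(pooled))
    dists = {k: abs(float(np.median(samples[k])) - global_median) for k in keys}
    best = min(dists.values())
    tied = [k for k in keys if math.isclose(dists[k], best, abs_tol=1e-12)]
    reference = tied[0]
    h, p = kruskal_wallis([samples[k] for k in keys], method="asymptotic")
    others = [k for k in keys if k != reference]
    raw = [_pairwise_p(samples[k], samples[reference]) for k in others]
    reject, adjusted = bky_fdr(raw, alpha=alpha)
    posthoc = [
        {
            "pair": (k, reference),
            "p_raw": raw[i],
            "q": float(adjusted[i]),
            "reject": bool(reject[i]),
        }
        for i, k in enumerate(others)
    ]
    return GroupComparison(
        groups=[str(k) for k in keys],
        H=h,
        p=p,
        posthoc=posthoc,
        reference=str(reference),
        reference_tie=len(tied) > 1,
    )
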