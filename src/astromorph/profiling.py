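"""Median stratification and assignment to the six morphometric profiles.

Each cell's six metrics are binarized against the cohort's global medians
(tie at the median counts as "below" — small even cohorts frequently place
the median exactly on a data value, so the rule must be explicit) and the
resulting pattern is looked up in the profile signature table.  Profiles 4
and 6 share a signature; a documented rank-based disambiguator separates
them.  Patterns matching no row are reported as "unclassified", never
forced into a nearest profile.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import rankdata

from .reference import TABLE_PATTERNS
from .types import GlobalMedians, METRIC_NAMES, MetricVector, ProfileAssignment

#: pattern -> candidate profile ids (4 and 6 collide by design)
_PATTERN_LOOKUP: Dict[Tuple[str, ...], Tuple[int, ...]] = {}
for _pid, _pat in TABLE_PATTERNS.items():
    _PATTERN_LOOKUP.setdefault(_pat, ())
    _PATTERN_LOOKUP[_pat] = _PATTERN_LOOKUP[_pat] + (_pid,)


def global_medians(cohort: Sequence[MetricVector]) -> GlobalMedians:
    """Pooled per-metric medians (midpoint rule for even n) and IQRs
    (25th-75th percentile, linear interpolation)."""
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    medians, iqrs = {}, {}
    for metric in METRIC_NAMES:
        values = np.array([getattr(v, metric) for v in cohort], dtype=float)
        medians[metric] = float(np.median(values))
        q1, q3 = np.percentile(values, [25, 75])
        iqrs[metric] = (float(q1), float(q3))
    return GlobalMedians(medians=medians, iqrs=iqrs)


def binarize(
    vector: Union[MetricVector, Mapping[str, float]],
    medians: GlobalMedians,
    metrics: Sequence[str] = METRIC_NAMES,
) -> Tuple[str, ...]:
    """Per-metric side of the global median: "above" iff value > median,
    "below" otherwise (ties are below).  Accepts a MetricVector or a
    plain metric->value mapping (which may cover a subset of metrics)."""
    values = vector.as_dict() if isinstance(vector, MetricVector) else vector
    return tuple(
        "above" if values[m] > medians[m] else "below" for m in metrics
    )


def assign_profile(
    pattern: Tuple[str, ...],
    intersections_rank: Optional[float] = None,
    length_rank: Optional[float] = None,
) -> ProfileAssignment:
    """Look a pattern up in the signature table.

    The shared 4/6 pattern is resolved by comparing the cell's standardized
    cohort ranks: a higher total-intersections rank than max-process-length
    rank means denser branching (profile 4), otherwise longer radial
    extension (profile 6).  This disambiguator is a documented local rule,
    flagged via ``disambiguator_used``, and swappable.
    """
    candidates = _PATTERN_LOOKUP.get(tuple(pattern), ())
    if len(candidates) == 0:
        return ProfileAssignment(pattern=tuple(pattern), profile_id="unclassified")
    if len(candidates) == 1:
        return ProfileAssignment(pattern=tuple(pattern), profile_id=candidates[0])
    if intersections_rank is None or length_rank is None:
        raise ValueError(
            f"pattern shared by profiles {candidates} needs cohort ranks to resolve"
        )
    profile_id = 4 if intersections_rank > length_rank else 6
    return ProfileAssignment(pattern=tuple(pattern), profile_id=profile_id,
                             disambiguator_used=True)


def assign_profiles(
    cohort: Sequence[MetricVector],
    medians: Optional[GlobalMedians] = None,
) -> List[ProfileAssignment]:
    """Binarize and assign every cell of a cohort.

    ``medians`` defaults to the cohort's own pooled medians; pass an
    explicit :class:`GlobalMedians` to stratify against a reference cohort
    instead.  Assignment depends only on (vector, cohort): permuting the
    cohort list permutes the result identically.
    """
    if len(cohort) == 0:
        return []
    if medians is None:
        medians = global_medians(cohort)
    inter = np.array([v.total_intersections for v in cohort], dtype=float)
    length = np.array([v.max_process_length for v in cohort], dtype=float)
    n = len(cohort)
    inter_rank = rankdata(inter) / (n + 1)  # standardized mid-ranks in (0, 1)
    length_rank = rankdata(length) / (n + 1)
    out = []
    for i, vec in enumerate(cohort):
        pattern = binarize(vec, medians)
        assignment = assign_profile(pattern, float(inter_rank[i]), float(length_rank[i]))
        assignment.cell_id = vec.cell_id
        out.append(assignment)
    return out
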