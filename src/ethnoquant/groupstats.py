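"""Nonparametric comparison of informant knowledge across demographic strata.

Knowledge is the per-informant use-report count.  Two strata are compared
with a two-sided Mann-Whitney U test, three or more with Kruskal-Wallis,
both with midrank tie handling at the 0.01 significance level the source
survey used.  For small samples the U test switches to an exact permutation
enumeration over all group assignments (which handles ties without any
approximation); large samples use the tie- and continuity-corrected normal
approximation.  The heavy lifting of the asymptotic tests is delegated to
scipy.stats; this module owns the exact path and the reporting structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import InformantProfile

__all__ = [
    "GroupComparison",
    "compare_two_groups",
    "compare_k_groups",
    "compare_groups",
    "compare_all_variables",
    "exact_mann_whitney_p",
]

#: the seven grouping variables of the survey design
GROUPING_VARIABLES = (
    "locality",
    "education",
    "gender",
    "social_position",
    "occupation",
    "civil_status",
    "age_group",
)

_EXACT_MAX_ARRANGEMENTS = 200_000


@dataclass(frozen=True)
class GroupComparison:
    grouping_variable: str
    groups: tuple[tuple[str, int, float], ...]  # (label, n, median)
    statistic: float
    statistic_name: str  # "mann_whitney_U" | "kruskal_wallis_H"
    p_value: float
    alpha: float = 0.01
    method: str = "asymptotic"

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def n_total(self) -> int:
        return sum(n for _, n, _ in self.groups)


def _split(scores: Mapping[str, float], grouping: Mapping[str, str]):
    groups: dict[str, list[float]] = {}
    for informant, label in grouping.items():
        if informant in scores:
            groups.setdefault(label, []).append(scores[informant])
    for label, vals in groups.items():
        if not vals:
            raise ValueError(f"group {label!r} is empty")
    return groups


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Mann-Whitney U of x over y, midranks for ties."""
    u = 0.0
    for xi in x:
        for yi in y:
            u += 1.0 if xi > yi else (0.5 if xi == yi else 0.0)
    return u


def exact_mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates all C(n+m, n) splits of the pooled sample and counts those
    whose U deviates from its null mean nm/2 by at least the observed
    deviation.  Ties need no correction — the permutation distribution is
    computed on the data as they are.
    """
    pooled = list(x) + list(y)
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0
    dev = abs(u_obs - mu) - 1e-9
    hits = 0
    idx = range(len(pooled))
    for chosen in combinations(idx, n):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen_set]
        if abs(_u_statistic(xs, ys) - mu) >= dev:
            hits += 1
    return hits / comb(n + m, n)


def compare_two_groups(
    scores: Mapping[str, float],
    grouping: Mapping[str, str],
    alpha: float = 0.01,
    method: str = "auto",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two strata.

    ``method`` is "exact" (full enumeration), "asymptotic" (normal
    approximation with tie and continuity correction), or "auto": exact when
    the number of arrangements is enumerable, asymptotic otherwise.
    """
    groups = _split(scores, grouping)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 group labels, got {sorted(groups)}")
    (la, xa), (lb, xb) = sorted(groups.items())
    if method == "auto":
        method = "exact" if comb(len(xa) + len(xb), len(xa)) <= _EXACT_MAX_ARRANGEMENTS else "asymptotic"
    u = _u_statistic(xa, xb)
    if method == "exact":
        p = exact_mann_whitney_p(xa, xb)
    elif method == "asymptotic":
        p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic").pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        grouping_variable="",
        groups=((la, len(xa), median(xa)), (lb, len(xb), median(xb))),
        statistic=u,
        statistic_name="mann_whitney_U",
        p_value=float(min(p, 1.0)),
        alpha=alpha,
        method=method,
    )


def compare_k_groups(
    scores: Mapping[str, float],
    grouping: Mapping[str, str],
    alpha: float = 0.01,
) -> GroupComparison:
    """Kruskal-Wallis H comparison of three or more strata (tie-corrected)."""
    groups = _split(scores, grouping)
    if len(groups) < 3:
        raise ValueError(f"need >= 3 group labels, got {sorted(groups)}")
    labels = sorted(groups)
    samples = [groups[l] for l in labels]
    if all(len(set(s)) == 1 for s in samples) and len({s[0] for s in samples}) == 1:
        h, p = 0.0, 1.0  # all observations identical; H is 0 by definition
    else:
        h, p = stats.kruskal(*samples)
    return GroupComparison(
        grouping_variable="",
        groups=tuple((l, len(groups[l]), median(groups[l])) for l in labels),
        statistic=float(h),
        statistic_name="kruskal_wallis_H",
        p_value=float(p),
        alpha=alpha,
    )


def compare_groups(
    scores: Mapping[str, float],
    grouping: Mapping[str, str],
    alpha: float = 0.01,
) -> GroupComparison:
    """Dispatch on the number of labels: U test for 2, Kruskal-Wallis for 3+."""
    labels = {grouping[i] for i in grouping if i in scores}
    if len(labels) < 2:
        raise ValueError("need at least 2 group labels")
    if len(labels) == 2:
        return compare_two_groups(scores, grouping, alpha=alpha)
    return compare_k_groups(scores, grouping, alpha=alpha)


def compare_all_variables(
    scores: Mapping[str, float],
    profiles: Sequence[InformantProfile],
    variables: Sequence[str] = GROUPING_VARIABLES,
    alpha: float = 0.01,
) -> list[GroupComparison]:
    """One comparison block per demographic variable, in the given order."""
    out = []
    for var in variables:
        grouping = {p.informant_id: getattr(p, var) for p in profiles if getattr(p, var)}
        cmp = compare_groups(scores, grouping, alpha=alpha)
        out.append(
            GroupComparison(
                grouping_variable=var,
                groups=cmp.groups,
                statistic=cmp.statistic,
                statistic_name=cmp.statistic_name,
                p_value=cmp.p_value,
                alpha=cmp.alpha,
                method=cmp.method,
            )
        )
    return out
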