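"""Group-level statistics for the metric tables.

One-way ANOVA (F reported) for metrics that pass normality and
equal-variance checks; ANOVA on ranks (Kruskal–Wallis H) otherwise;
Bonferroni-corrected pooled-variance pairwise t tests post hoc after a
significant omnibus test.  Two-way repeated-measures designs and Dunn's
method are deliberately not implemented here: they are routine and
better served by dedicated statistics software, and the pipeline emits
long-format tables ready for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import GatingError, ValidationError


class TestKind(str, Enum):
    ANOVA_F = "ANOVA_F"
    KRUSKAL_H = "KRUSKAL_H"


@dataclass
class PairwiseResult:
    pair: tuple[int, int] | tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    test: TestKind
    statistic: float
    dof: tuple[int, ...]
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)


def _check_groups(groups, min_n: int = 2):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < min_n:
            raise ValidationError(f"group {i} has n={g.size} < {min_n}")
    return groups


def one_way_anova(groups) -> GroupComparison:
    """Classical one-way ANOVA: F with (k-1, N-k) degrees of freedom."""
    groups = _check_groups(groups)
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n_total = sum(g.size for g in groups)
    return GroupComparison(TestKind.ANOVA_F, float(f), (k - 1, n_total - k), float(p))


def kruskal_wallis(groups) -> GroupComparison:
    """ANOVA on ranks: tie-corrected H with a chi-square(k-1) p-value."""
    groups = _check_groups(groups)
    h, p = stats.kruskal(*groups)
    return GroupComparison(TestKind.KRUSKAL_H, float(h), (len(groups) - 1,), float(p))


def bonferroni_pairwise_t(
    groups,
    labels=None,
    omnibus_p: float | None = None,
    alpha: float = 0.05,
    force: bool = False,
) -> list[PairwiseResult]:
    """All pairwise t tests with pooled within-group variance, Bonferroni-adjusted.

    Adjusted p = min(1, m * p) for m comparisons.  When ``omnibus_p``
    is given it is enforced as a gate: post-hoc tests after a
    non-significant omnibus test raise :class:`GatingError` unless
    ``force=True``.
    """
    groups = _check_groups(groups)
    if omnibus_p is not None and omnibus_p >= alpha and not force:
        raise GatingError(
            f"omnibus p={omnibus_p:.3g} >= {alpha}: post-hoc comparisons are gated"
        )
    k = len(groups)
    n_total = sum(g.size for g in groups)
    df = n_total - k
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sp2 = ssw / df
    m = k * (k - 1) // 2
    labels = labels if labels is not None else list(range(k))
    out = []
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        if sp2 == 0:
            t = 0.0 if gi.mean() == gj.mean() else np.inf
        else:
            t = (gi.mean() - gj.mean()) / np.sqrt(sp2 * (1 / gi.size + 1 / gj.size))
        p_raw = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                statistic=float(t),
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, m * p_raw)),
            )
        )
    return out


def compare_groups(
    groups,
    labels=None,
    alpha: float = 0.05,
    gate_alpha: float = 0.05,
) -> GroupComparison:
    """Route to ANOVA or Kruskal–Wallis via normality/equal-variance gating.

    Shapiro–Wilk is applied per group (n >= 3) and Levene's test across
    groups at ``gate_alpha``; failing either routes the comparison to
    the rank-based test.  Pairwise Bonferroni comparisons are attached
    when the omnibus test is significant at ``alpha``.
    """
    groups = _check_groups(groups)
    normal = True
    for g in groups:
        if g.size >= 3 and np.ptp(g) > 0:
            if stats.shapiro(g).pvalue < gate_alpha:
                normal = False
                break
    equal_var = True
    if all(np.ptp(g) > 0 for g in groups):
        if stats.levene(*groups).pvalue < gate_alpha:
            equal_var = False
    result = one_way_anova(groups) if (normal and equal_var) else kruskal_wallis(groups)
    if result.p_value < alpha:
        result.pairwise = bonferroni_pairwise_t(
            groups, labels=labels, omnibus_p=result.p_value, alpha=alpha
        )
    return result
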