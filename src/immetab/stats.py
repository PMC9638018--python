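"""Statistical helpers shared across pipeline stages.

Paired two-sided t tests for matched (e.g. per-donor) designs, one-way ANOVA
with Bonferroni-adjusted pairwise post-tests for multi-group comparisons, and
the rank-sum comparison used for non-normal score distributions.  The
multiple-testing family is the set of pairwise comparisons within a single
analysis (per-panel convention).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "paired_t", "anova_bonferroni", "wilcoxon_rank_sum"]


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    adjustment: str = "none"
    comparison: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def paired_t(x, y) -> StatResult:
    """Two-sided paired Student's t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length ({len(x)} vs {len(y)})")
    if len(x) < 2:
        raise ValueError("need >= 2 pairs")
    diffs = x - y
    if np.std(diffs, ddof=1) == 0:
        raise ValueError(
            "degenerate paired t test: all pairwise differences identical (sd = 0)"
        )
    res = sps.ttest_rel(x, y)
    return StatResult("paired_t", float(res.statistic), float(res.pvalue), [len(x)])


def wilcoxon_rank_sum(x, y) -> StatResult:
    """Two-sided two-sample rank-sum (Mann-Whitney) test; exact for small
    untied samples, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult("wilcoxon_rank_sum", float(res.statistic), float(res.pvalue), [len(x), len(y)])


def anova_bonferroni(groups: dict[str, np.ndarray]) -> list[StatResult]:
    """One-way ANOVA F test plus Bonferroni-adjusted pairwise t post-tests.

    Returns the omnibus F result followed by one result per group pair with
    ``p_adj = min(1, m * p_raw)`` where ``m`` is the number of pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    for name, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {name!r} is a singleton; cannot estimate variance")
    f_res = sps.f_oneway(*arrays)
    out = [
        StatResult(
            "anova_oneway",
            float(f_res.statistic),
            float(f_res.pvalue),
            [len(a) for a in arrays],
            comparison="omnibus",
        )
    ]
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    m = len(pairs)
    for i, j in pairs:
        t_res = sps.ttest_ind(arrays[i], arrays[j])
        out.append(
            StatResult(
                "t_pairwise",
                float(t_res.statistic),
                min(1.0, m * float(t_res.pvalue)),
                [len(arrays[i]), len(arrays[j])],
                adjustment=f"bonferroni(m={m})",
                comparison=f"{names[i]} vs {names[j]}",
            )
        )
    return out
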