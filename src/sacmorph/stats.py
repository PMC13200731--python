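"""The statistical battery applied across all pipeline stages.

Group summaries are mean +- s.e.m.; two-group comparisons use the pooled
(Student's) unpaired two-tailed t-test (Welch available behind a flag);
three or more groups use one-way ANOVA with Tukey's HSD, or Kruskal-Wallis
with Dunn's multiple-comparisons test for distributions; binary proportions
use the two-sided Fisher exact test; per-cell curves (Sholl, branch level,
puncta distributions) are reduced to trapezoid areas under the curve and
compared by t-test on the per-cell AUCs; fluorescence ROI readouts are
normalized against a background ROI by ratio or subtraction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

log = logging.getLogger("sacmorph.stats")


@dataclass
class GroupComparison:
    method: str
    statistic: float
    p_value: float
    group_summaries: list[dict] = field(default_factory=list)
    pairwise: list[dict] | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
            "pairwise": self.pairwise,
        }


def _summary(sample: np.ndarray, label: str | int) -> dict:
    sample = np.asarray(sample, dtype=float)
    n = len(sample)
    sem = float(sample.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return {"group": label, "n": n, "mean": float(sample.mean()), "sem": sem}


def ttest_unpaired(a, b, welch: bool = False) -> GroupComparison:
    """Unpaired two-tailed t-test; pooled variance (Student's) by default.

    Degenerate zero-variance input is resolved without error: equal means
    give p = 1, unequal means give p = 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    summaries = [_summary(a, "a"), _summary(b, "b")]
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison("ttest", 0.0, 1.0, summaries)
        log.warning("zero variance with unequal means; reporting p = 0")
        return GroupComparison("ttest", math.inf, 0.0, summaries)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison("ttest", float(t), float(p), summaries)


def group_compare(groups: list, method: str = "anova_tukey") -> GroupComparison:
    """Omnibus comparison of >= 3 groups with pairwise post-hoc tests.

    ``anova_tukey``: one-way ANOVA, Tukey HSD adjusted pairwise p-values.
    ``kw_dunn``: Kruskal-Wallis (tie-corrected), Dunn's z-tests with
    Bonferroni adjustment.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use ttest_unpaired for two")
    groups = [np.asarray(g, dtype=float) for g in groups]
    summaries = [_summary(g, i) for i, g in enumerate(groups)]
    if method == "anova_tukey":
        if any(len(g) < 2 for g in groups):
            raise ValueError("ANOVA needs n >= 2 per group")
        if all(g.std(ddof=1) == 0 for g in groups) and len(
            {g.mean() for g in groups}
        ) == 1:
            return GroupComparison("anova_tukey", 0.0, 1.0, summaries, [])
        f, p = sps.f_oneway(*groups)
        tk = sps.tukey_hsd(*groups)
        pairwise = [
            {"pair": [i, j], "p_adjusted": float(tk.pvalue[i, j])}
            for i, j in itertools.combinations(range(len(groups)), 2)
        ]
        return GroupComparison("anova_tukey", float(f), float(p), summaries, pairwise)
    if method == "kw_dunn":
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            # all observations tied: no evidence of any difference
            return GroupComparison("kw_dunn", 0.0, 1.0, summaries, [])
        h, p = sps.kruskal(*groups)
        pairwise = _dunn_pairwise(groups)
        return GroupComparison("kw_dunn", float(h), float(p), summaries, pairwise)
    raise ValueError(f"unknown method {method!r}")


def _dunn_pairwise(groups: list[np.ndarray]) -> list[dict]:
    """Dunn's post-hoc z-tests on rank sums, tie-corrected, Bonferroni."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start: start + len(g)].mean())
        start += len(g)
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se = math.sqrt(
            (n * (n + 1) / 12.0 - tie_term)
            * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        out.append({"pair": [i, j], "p_adjusted": float(min(1.0, p_raw * n_pairs))})
    return out


def fisher_exact_2x2(table) -> GroupComparison:
    """Two-sided Fisher exact test by hypergeometric probability ordering.

    The two-sided p-value sums the probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    summaries = [
        {"group": i, "n": int(t[i].sum()),
         "proportion": float(t[i, 0] / t[i].sum())}
        for i in range(2)
    ]
    return GroupComparison("fisher", float(odds), float(p), summaries)


def trapezoid_auc(x, y) -> float:
    """Trapezoid area under a sampled curve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("curve needs >= 2 matched (x, y) points")
    return float(np.trapezoid(y, x))


def auc_compare(curves_a: list, curves_b: list) -> GroupComparison:
    """Compare two groups of per-cell curves via their trapezoid AUCs.

    Every curve is an ``(x, y)`` pair; all curves within a group must share
    the same x-grid.  Per-cell AUCs are reduced with the pooled t-test and
    each group's AUC mean +- s.e.m. is reported.
    """
    aucs = []
    for curves in (curves_a, curves_b):
        if not curves:
            raise ValueError("empty curve group")
        x0 = np.asarray(curves[0][0], dtype=float)
        vals = []
        for x, y in curves:
            if len(x) != len(x0) or not np.allclose(x, x0):
                raise ValueError("curves within a group must share an x-grid")
            vals.append(trapezoid_auc(x, y))
        aucs.append(np.array(vals))
    cmp = ttest_unpaired(aucs[0], aucs[1])
    return GroupComparison("auc_ttest", cmp.statistic, cmp.p_value,
                           cmp.group_summaries)


def roi_normalize(signal_mean: float, background_mean: float,
                  mode: str = "ratio") -> float:
    """Normalize an ROI fluorescence readout against a background ROI.

    ``ratio`` divides (the no-enrichment baseline is 1); ``subtract``
    removes the background level and may legitimately be negative.
    """
    if mode == "ratio":
        if background_mean <= 0:
            raise ValueError("ratio mode needs background > 0")
        return float(signal_mean / background_mean)
    if mode == "subtract":
        return float(signal_mean - background_mean)
    raise ValueError(f"unknown mode {mode!r}")
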