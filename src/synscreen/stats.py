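"""Group summaries and rank-based comparisons for assay measures.

The measures produced upstream (interaction scores, recruitment ratios,
per-area densities) are typically non-normal, so comparisons follow the
standard non-parametric route: a normality pre-check, Mann-Whitney for two
groups, Kruskal-Wallis omnibus followed by Dunn's pairwise post-hoc for
three or more.  The omnibus and two-group tests delegate to scipy; Dunn's
z-statistics use the standard large-sample rank formulas with tie
correction, with p-value adjustment delegated to statsmodels
(``p_adjust="none"`` keeps Dunn's own unadjusted two-sided p-values).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "summarize_groups",
    "normality_check",
    "dunn_posthoc",
    "compare_groups",
]


@dataclass
class GroupComparison:
    """Result of a two- or multi-group rank comparison.

    ``pairwise`` maps unordered label pairs to adjusted p-values and is
    only populated when an omnibus test over >= 3 groups was run.
    """

    groups: dict[str, np.ndarray]
    omnibus_stat: float
    omnibus_p: float
    test_name: str
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_unadjusted: dict[tuple[str, str], float] = field(default_factory=dict)
    normal: dict[str, bool] = field(default_factory=dict)


def summarize_groups(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean, SEM (sample SD / sqrt(n)) and n per group; SEM is NaN for n = 1."""
    rows = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": label, "mean": float(v.mean()), "sem": sem, "n": v.size})
    return pd.DataFrame(rows).set_index("group")


def normality_check(values: Sequence[float], alpha: float = 0.05) -> tuple[bool, float]:
    """D'Agostino-Pearson normality test; returns (looks_normal, p)."""
    stat, p = sps.normaltest(np.asarray(values, dtype=float))
    return bool(p >= alpha), float(p)


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    p_adjust: str = "none",
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Dunn's pairwise z-tests on joint ranks, with tie correction.

    For groups i, j with mean joint ranks R̄_i, R̄_j over N pooled values,

        z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T) (1/n_i + 1/n_j)),
        T = Σ(t³ − t) / (12 (N − 1))  over tie groups of size t,

    and p = 2(1 − Φ(|z|)).  ``p_adjust`` is a statsmodels method name
    ("none", "bonferroni", "holm", ...); returns (adjusted, unadjusted)
    p-value maps keyed by label pair.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for label, arr in zip(labels, arrays):
        mean_ranks[label] = float(ranks[start : start + arr.size].mean())
        sizes[label] = arr.size
        start += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw.append(2.0 * sps.norm.sf(abs(z)))
    if p_adjust == "none":
        adj = list(raw)
    else:
        adj = list(multipletests(raw, method=p_adjust)[1])
    return (
        {pair: float(p) for pair, p in zip(pairs, adj)},
        {pair: float(p) for pair, p in zip(pairs, raw)},
    )


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: str | None = None,
    p_adjust: str = "none",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Two-group Mann-Whitney or multi-group Kruskal-Wallis + Dunn's.

    ``design`` is "two_group" or "multi_group"; when omitted it is inferred
    from the number of groups.  Each group is also run through the
    normality pre-check (reported, not acted on — the rank tests are used
    either way, matching the study's analysis path for its non-normal
    measures).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for label, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {label!r} is empty")
    if design is None:
        design = "two_group" if len(groups) == 2 else "multi_group"
    if design == "two_group":
        if len(groups) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        (la, va), (lb, vb) = groups.items()
        stat, p = sps.mannwhitneyu(va, vb, alternative="two-sided")
        result = GroupComparison(
            groups=groups, omnibus_stat=float(stat), omnibus_p=float(p),
            test_name="mann-whitney",
        )
    elif design == "multi_group":
        if len(groups) < 3:
            raise ValueError("multi_group design requires >= 3 groups")
        stat, p = sps.kruskal(*groups.values())
        adj, raw = dunn_posthoc(groups, p_adjust=p_adjust)
        result = GroupComparison(
            groups=groups, omnibus_stat=float(stat), omnibus_p=float(p),
            test_name="kruskal-wallis+dunn", pairwise=adj, pairwise_unadjusted=raw,
        )
    else:
        raise ValueError(f"unknown design {design!r}")
    result.normal = {
        label: normality_check(v, normality_alpha)[0] if v.size >= 8 else False
        for label, v in groups.items()
    }
    return result
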