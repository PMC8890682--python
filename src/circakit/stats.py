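"""Group-comparison decision tree for onset delays and acrophases.

The gate mirrors common chronobiology practice: per-group normality
(Lilliefors/Kolmogorov-Smirnov with estimated parameters) and homogeneity
of variances (Bartlett). If both pass, Student's t-test (2 groups) or
one-way ANOVA with Tukey's HSD (>2 groups); otherwise Mann-Whitney (2) or
Kruskal-Wallis with Dunn's multiple-comparison test (>2). The chosen branch
is recorded in ``test_name`` so downstream tables can report which test
produced each p-value.

Circular quantities (onsets, acrophases) should be unwrapped to a common
branch — e.g. via the delay statistic's signed difference mapped to
(-12, 12] — before being passed here; the tests themselves are linear.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import kstest_normal

from .errors import InvalidArgumentError


@dataclass
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    groups: Tuple[str, ...]
    posthoc: Optional[List[Tuple[Tuple[str, str], float]]] = None
    normality_p: Dict[str, float] = field(default_factory=dict)
    variance_p: float = float("nan")
    parametric: bool = True


def _as_groups(samples) -> "dict[str, np.ndarray]":
    if isinstance(samples, dict):
        items = list(samples.items())
    else:
        items = [(f"group{i + 1}", g) for i, g in enumerate(samples)]
    out = {}
    for name, vals in items:
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise InvalidArgumentError(f"group {name!r} needs >= 2 values")
        out[str(name)] = arr
    if len(out) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    return out


def _dunn_posthoc(groups: "dict[str, np.ndarray]"):
    """Dunn's rank-based pairwise z tests after Kruskal-Wallis, with tie
    correction and Bonferroni adjustment over the pair family."""
    names = list(groups)
    pooled = np.concatenate([groups[n] for n in names])
    ranks = sps.rankdata(pooled)
    n_tot = pooled.size
    # mean rank per group
    mean_rank, start = {}, 0
    for n in names:
        k = groups[n].size
        mean_rank[n] = ranks[start:start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = abs(mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * sps.norm.sf(z) * len(pairs))
        out.append(((a, b), float(p)))
    return out


def _tukey_posthoc(groups: "dict[str, np.ndarray]"):
    names = list(groups)
    res = sps.tukey_hsd(*[groups[n] for n in names])
    out = []
    for i, j in itertools.combinations(range(len(names)), 2):
        out.append(((names[i], names[j]), float(res.pvalue[i, j])))
    return out


def compare_groups(samples, alpha_normality: float = 0.05) -> ComparisonResult:
    """Run the normality/variance-gated comparison on >= 2 groups.

    ``samples`` is a mapping of group label to values, or a sequence of
    value sequences (auto-labelled). Groups with fewer than 4 values skip
    the normality test (it has no power there) and count as normal.
    """
    groups = _as_groups(samples)
    names = tuple(groups)

    norm_p = {}
    for name, vals in groups.items():
        if vals.size < 4 or np.ptp(vals) == 0:
            norm_p[name] = 1.0
            continue
        _, p = kstest_normal(vals)
        norm_p[name] = float(p)
    all_normal = all(p >= alpha_normality for p in norm_p.values())

    if all(np.ptp(g) > 0 for g in groups.values()):
        _, var_p = sps.bartlett(*groups.values())
        var_p = float(var_p)
    else:
        var_p = 1.0 if len({np.ptp(g) for g in groups.values()}) == 1 else 0.0
    parametric = all_normal and (np.isnan(var_p) or var_p >= alpha_normality)

    posthoc = None
    if len(groups) == 2:
        a, b = groups.values()
        if parametric:
            stat, p = sps.ttest_ind(a, b, equal_var=True)
            test_name = "t-test"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "Mann-Whitney"
    else:
        if parametric:
            stat, p = sps.f_oneway(*groups.values())
            posthoc = _tukey_posthoc(groups)
            test_name = "one-way ANOVA + Tukey"
        else:
            stat, p = sps.kruskal(*groups.values())
            posthoc = _dunn_posthoc(groups)
            test_name = "Kruskal-Wallis + Dunn"

    return ComparisonResult(
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        groups=names,
        posthoc=posthoc,
        normality_p=norm_p,
        variance_p=var_p,
        parametric=parametric,
    )
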