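"""Nonparametric reporting: group comparisons, median/IQR, mechanical plane.

Comparisons follow the single-run, within-condition convention: a
Kruskal-Wallis test across all groups plus two-sided Mann-Whitney U tests
for planned pairs, with a fixed significance/trend labeling of the p-value
(*** < 0.001, ** < 0.01, * < 0.05, 0.05 <= p < 0.1 "trend", else "NS") and
no multiple-testing correction by default (Holm adjustment is available as
an option). Distributions are summarized as median and interquartile range
with linearly interpolated quartiles. The mechanical plane plots the
relaxation frequency omega_c against the effective rigidity k_eff per cell
with a purely descriptive ordinary-least-squares trend line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dynamics import DynamicsRecord
from .thermal import ThermalContext

__all__ = ["GroupComparison", "significance_label", "compare_groups",
           "summarize", "mech_plane"]

_EXACT_MAX_N = 8


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    statistic: float
    p: float
    label: str
    test: str                  # mann_whitney | kruskal_wallis


def significance_label(p: float) -> str:
    """Map a p-value to the fixed reporting label.

    The trend band is inclusive at its lower edge: 0.05 <= p < 0.1.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "trend"
    return "NS"


def _mannwhitney(a: np.ndarray, b: np.ndarray):
    """Two-sided Mann-Whitney U; exact null for small tie-free samples."""
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (len(a) <= _EXACT_MAX_N and len(b) <= _EXACT_MAX_N
                         and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(values_by_group: Mapping[str, Sequence[float]],
                   pairs: Sequence[tuple] | None = None,
                   holm: bool = False) -> list:
    """Kruskal-Wallis across all groups plus planned pairwise Mann-Whitney tests.

    ``pairs`` defaults to all unordered group pairs in insertion order.
    With ``holm=True`` the pairwise p-values are Holm-adjusted before
    labeling (off by default, matching the plain reporting convention).
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} needs >= 3 values")

    names = list(groups)
    out = []
    kw_stat, kw_p = sps.kruskal(*groups.values())
    out.append(GroupComparison(group_a="<all>", group_b="<all>",
                               statistic=float(kw_stat), p=float(kw_p),
                               label=significance_label(float(kw_p)),
                               test="kruskal_wallis"))

    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    results = []
    for ga, gb in pairs:
        stat, p = _mannwhitney(groups[ga], groups[gb])
        results.append((ga, gb, stat, p))
    pvals = np.array([r[3] for r in results])
    if holm and pvals.size:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (pvals.size - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        pvals = adj
    for (ga, gb, stat, _), p in zip(results, pvals):
        out.append(GroupComparison(group_a=ga, group_b=gb, statistic=stat,
                                   p=float(p), label=significance_label(float(p)),
                                   test="mann_whitney"))
    return out


def summarize(values: Sequence[float]):
    """(median, IQR) with linearly interpolated quartiles."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(values, [25, 50, 75], method="linear")
    return float(med), float(q3 - q1)


def mech_plane(records: Sequence[DynamicsRecord]):
    """(condition, k_eff, omega_c) table plus a descriptive OLS trend line.

    Returns ``(table, fit)`` where ``fit`` is a dict with slope, intercept,
    slope standard error and r, or ``None`` (with the table flagged) when
    fewer than 2 distinct k_eff values are available.
    """
    records = list(records)
    if len(records) < 2:
        return _plane_table(records), None
    k = np.array([r.k_eff for r in records])
    w = np.array([r.omega_c for r in records])
    if np.unique(k).size < 2:
        return _plane_table(records), None
    res = sps.linregress(k, w)
    fit = {"slope": float(res.slope), "intercept": float(res.intercept),
           "slope_stderr": float(res.stderr), "r": float(res.rvalue)}
    return _plane_table(records), fit


def _plane_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [{"condition": r.condition, "cell_id": r.cell_id,
          "k_eff": r.k_eff, "omega_c": r.omega_c} for r in records]
    )
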