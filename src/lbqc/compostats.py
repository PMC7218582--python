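"""Compositional transforms and the kit-comparison statistics.

Count-based multiplicative zero replacement, the isometric log-ratio pivot
coordinate of a taxon of interest, and a one-way ANOVA with Tukey HSD
simultaneous confidence intervals on the pivot coordinates.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ProportionTable

__all__ = [
    "replace_zeros",
    "ilr_pivot",
    "pivot_coordinates",
    "TukeyInterval",
    "AnovaTukeyResult",
    "pivot_anova_tukey",
]


def replace_zeros(
    p: ProportionTable,
    library_sizes: Mapping[str, float] | pd.Series,
    alpha: float = 0.5,
) -> ProportionTable:
    """Bayesian-multiplicative zero replacement.

    Per column with D parts, N total reads and Z zero cells: each zero cell
    becomes δ = α/(N + α·D), nonzero cells are scaled by (1 − Z·δ)/S where S
    is their original sum, so the output is a strictly positive composition
    and ratios among originally nonzero parts are preserved.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    D = len(p.otu_ids)
    out = p.data.copy().astype(float)
    for sid in p.sample_ids:
        col = out[sid].to_numpy(dtype=float)
        if (col == 0).all():
            raise ValueError(f"column {sid!r} is entirely zero")
        n_reads = float(library_sizes[sid])
        delta = alpha / (n_reads + alpha * D)
        zeros = col == 0
        z = int(zeros.sum())
        if z == 0:
            continue
        scale = (1.0 - z * delta) / col[~zeros].sum()
        col = np.where(zeros, delta, col * scale)
        out[sid] = col
    return ProportionTable(out, frozenset())


def ilr_pivot(x: Sequence[float] | np.ndarray, pivot: int = 0) -> float:
    """First ilr (pivot) coordinate of a strictly positive composition.

    z = sqrt((D−1)/D) · ln(x_pivot / geometric mean of the other parts);
    scale-invariant and invariant to permutations of the non-pivot parts.
    """
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("composition must be a vector with at least 2 parts")
    if (v <= 0).any():
        raise ValueError("composition has zero parts; apply replace_zeros first")
    d = len(v)
    others = np.delete(v, pivot)
    gm = math.exp(np.log(others).mean())
    return math.sqrt((d - 1) / d) * math.log(v[pivot] / gm)


def pivot_coordinates(p: ProportionTable, pivot_otu: str) -> pd.Series:
    """Pivot coordinate of ``pivot_otu`` for every sample column."""
    if pivot_otu not in p.otu_ids:
        raise ValueError(f"unknown pivot OTU {pivot_otu!r}")
    idx = p.otu_ids.index(pivot_otu)
    vals = {
        sid: ilr_pivot(p.data[sid].to_numpy(dtype=float), idx)
        for sid in p.sample_ids
    }
    return pd.Series(vals, name=pivot_otu)


@functools.lru_cache(maxsize=256)
def _studentized_range_quantile(alpha: float, n_groups: int, df: int) -> float:
    """Upper-alpha quantile of the studentized range distribution; cached
    because the numerical inversion of its double-integral CDF is costly."""
    return float(stats.studentized_range.isf(alpha, n_groups, df))


@dataclass(frozen=True)
class TukeyInterval:
    group_a: str
    group_b: str
    difference: float  # mean_a − mean_b
    lower: float
    upper: float
    significant: bool  # interval excludes zero at the simultaneous 5% level


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict[str, float]
    intervals: list[TukeyInterval]


def pivot_anova_tukey(
    values: Sequence[float] | np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD simultaneous confidence intervals.

    F = MS_between/MS_within with (a−1, N−a) df; the interval for groups
    i, j is (ȳ_i−ȳ_j) ± q_{1−α, a, N−a}·sqrt((MSE/2)(1/n_i + 1/n_j)), and a
    pair is significant iff its interval excludes zero.
    """
    y = np.asarray(values, dtype=float)
    g = list(groups)
    if len(y) != len(g):
        raise ValueError("values and groups must align")
    labels = sorted(set(g))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    by = {lab: y[np.array(g) == lab] for lab in labels}
    for lab, v in by.items():
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 observations")
    n_total = len(y)
    a = len(labels)
    grand = y.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b, df_w = a - 1, n_total - a
    ms_between = ss_between / df_b
    mse = ss_within / df_w
    if mse == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else math.inf
        p = 1.0 if ms_between == 0.0 else 0.0
    else:
        f_stat = ms_between / mse
        p = float(stats.f.sf(f_stat, df_b, df_w))
    q_crit = _studentized_range_quantile(alpha, a, df_w)
    intervals = []
    for i in range(a):
        for j in range(i + 1, a):
            va, vb = by[labels[i]], by[labels[j]]
            diff = float(va.mean() - vb.mean())
            half = q_crit * math.sqrt((mse / 2.0) * (1 / len(va) + 1 / len(vb)))
            lo, hi = diff - half, diff + half
            intervals.append(
                TukeyInterval(
                    labels[i], labels[j], diff, lo, hi, lo > 0 or hi < 0
                )
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=p,
        df_between=df_b,
        df_within=df_w,
        group_means={lab: float(v.mean()) for lab, v in by.items()},
        intervals=intervals,
    )
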