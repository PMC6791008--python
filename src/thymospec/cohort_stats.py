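"""Cohort-level statistics: Kruskal-Wallis + Dunn, Pearson, Table-1 summaries.

The study variables are not normally distributed, so three-group
comparisons use the nonparametric Kruskal-Wallis H test (tie-corrected);
when the omnibus test is significant, pairwise Dunn z-tests with Bonferroni
adjustment follow.  With exactly two groups, the omnibus p-value itself is
reported and no post-hoc is run.  Demographic tables use Fisher's exact
test for categorical variables and the unpaired t-test for continuous
ones.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, ValidationError

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseTest:
    group_a: str
    group_b: str
    dunn_z: float
    p_raw: float
    p_adjusted: float  # Bonferroni


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    group_n: dict[str, int]
    group_median: dict[str, float]
    group_iqr: dict[str, tuple[float, float]]
    kw_h: float
    kw_p: float
    pairwise: list[PairwiseTest] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    variable_pair: tuple[str, str]
    stratum: str
    n: int
    r: float  # NaN when undefined (zero variance)
    p: float
    undefined: bool = False


@dataclass(frozen=True)
class CohortSummary:
    continuous: pd.DataFrame  # variable x group medians/IQR
    categorical: pd.DataFrame  # counts and percents
    pairwise_p: pd.DataFrame  # variable x group-pair p-values


def _median_iqr(values: np.ndarray) -> tuple[float, tuple[float, float]]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def dunn_test(
    groups: Mapping[str, Sequence[float]], adjust: str = "bonferroni"
) -> list[PairwiseTest]:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum over tied values of (t^3 - t).  Adjustment: Bonferroni.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = float(ranks[start : start + sizes[g]].mean())
        start += sizes[g]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    m = math.comb(len(names), 2)
    out = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p_raw * m) if adjust == "bonferroni" else p_raw
        out.append(PairwiseTest(a, b, float(z), float(p_raw), float(p_adj)))
    return out


def compare_groups(
    groups: Mapping[str, Sequence[float]], variable: str = "", alpha: float = ALPHA
) -> GroupComparison:
    """Kruskal-Wallis omnibus with conditional Dunn post-hoc.

    Pairwise tests are run only when the omnibus p <= alpha and more than
    two groups are present; with exactly two groups the omnibus p is the
    reported two-group p-value.
    """
    if len(groups) < 2:
        raise ConfigurationError("compare_groups needs >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValidationError(f"group {g!r} has n={len(v)} < 2")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):  # all identical: no evidence of difference
        kw_h, kw_p = 0.0, 1.0
    else:
        kw_h, kw_p = sps.kruskal(*arrays.values())
    pairwise: list[PairwiseTest] = []
    if kw_p <= alpha and len(groups) > 2:
        pairwise = dunn_test(arrays)
    med = {}
    iqr = {}
    for g, v in arrays.items():
        med[g], iqr[g] = _median_iqr(v)
    return GroupComparison(
        variable=variable,
        group_n={g: int(v.size) for g, v in arrays.items()},
        group_median=med,
        group_iqr=iqr,
        kw_h=float(kw_h),
        kw_p=float(kw_p),
        pairwise=pairwise,
    )


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    strata: Sequence[str] | None = None,
    variable_pair: tuple[str, str] = ("x", "y"),
) -> list[CorrelationResult]:
    """Pearson r with two-sided p per stratum (or overall when unstratified)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValidationError("x and y must be paired")
    labels = np.asarray(strata) if strata is not None else np.full(xa.size, "all")
    out = []
    for s in pd.unique(labels):
        mask = labels == s
        xs, ys = xa[mask], ya[mask]
        keep = np.isfinite(xs) & np.isfinite(ys)
        xs, ys = xs[keep], ys[keep]
        if xs.size < 3:
            raise ValidationError(f"stratum {s!r} has n={xs.size} < 3")
        if np.std(xs) == 0 or np.std(ys) == 0:
            out.append(CorrelationResult(variable_pair, str(s), int(xs.size), math.nan, math.nan, True))
            continue
        r, p = sps.pearsonr(xs, ys)
        out.append(CorrelationResult(variable_pair, str(s), int(xs.size), float(r), float(p)))
    return out


TABLE1_CONTINUOUS = ("age", "cd4_abs", "cd4_pct", "cd8_abs", "cd8_pct", "cd4_cd8_ratio")
TABLE1_CATEGORICAL = ("gender",)


def summarize_table1(metadata: pd.DataFrame, group_col: str = "group") -> CohortSummary:
    """Demographic/clinical summary: median (Q1-Q3) per group plus pairwise
    p-values (unpaired t for continuous, Fisher exact for categorical)."""
    required = {group_col, *TABLE1_CONTINUOUS, *TABLE1_CATEGORICAL}
    missing = sorted(required - set(metadata.columns))
    if missing:
        raise ValidationError(f"metadata missing column(s): {', '.join(missing)}")
    groups = list(dict.fromkeys(metadata[group_col]))
    cont_rows = {}
    for var in TABLE1_CONTINUOUS:
        row = {}
        for g in groups:
            med, (q1, q3) = _median_iqr(metadata.loc[metadata[group_col] == g, var].to_numpy(float))
            row[g] = f"{med:g} ({q1:g}-{q3:g})"
        cont_rows[var] = row
    cat_rows = {}
    for var in TABLE1_CATEGORICAL:
        for level in sorted(metadata[var].unique()):
            row = {}
            for g in groups:
                sub = metadata[metadata[group_col] == g]
                k = int((sub[var] == level).sum())
                row[g] = f"{k} ({100.0 * k / len(sub):.1f}%)"
            cat_rows[f"{var}={level}"] = row
    pair_rows = {}
    for a, b in itertools.combinations(groups, 2):
        col = {}
        sub_a = metadata[metadata[group_col] == a]
        sub_b = metadata[metadata[group_col] == b]
        for var in TABLE1_CONTINUOUS:
            t, p = sps.ttest_ind(sub_a[var].to_numpy(float), sub_b[var].to_numpy(float))
            col[var] = float(p)
        for var in TABLE1_CATEGORICAL:
            levels = sorted(metadata[var].unique())
            if len(levels) == 2:
                table = [
                    [int((sub_a[var] == levels[0]).sum()), int((sub_a[var] == levels[1]).sum())],
                    [int((sub_b[var] == levels[0]).sum()), int((sub_b[var] == levels[1]).sum())],
                ]
                _, p = sps.fisher_exact(table)
                col[var] = float(p)
        pair_rows[f"{a} vs {b}"] = col
    return CohortSummary(
        continuous=pd.DataFrame(cont_rows).T,
        categorical=pd.DataFrame(cat_rows).T if cat_rows else pd.DataFrame(),
        pairwise_p=pd.DataFrame(pair_rows),
    )


def category_proportion_test(
    fraction_nonnormal: Mapping[str, float],
    groups: Mapping[str, str],
    alpha: float = ALPHA,
) -> GroupComparison:
    """Compare the per-subject fraction of non-normal TRBV subgroups across
    groups (pooled shifted + restricted + mono/oligoclonal vs normal).

    Subjects absent from ``fraction_nonnormal`` (zero detected subgroups)
    are excluded upstream.
    """
    by_group: dict[str, list[float]] = {}
    for sid, frac in fraction_nonnormal.items():
        by_group.setdefault(groups[sid], []).append(frac)
    return compare_groups(by_group, variable="fraction_nonnormal", alpha=alpha)
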