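"""Repeatability (intraclass correlation) from one-way ANOVA components,
and the trend test on per-parallel deviation proportions.

With individuals as groups and repeated journeys as replicates, the
one-way ANOVA mean squares give the variance components

    s2_within = MS_within
    s2_among  = (MS_among - MS_within) / n0,   n0 = (N - sum(n_i^2)/N) / (a - 1)

and repeatability r = s2_among / (s2_among + s2_within) — the share of
total variance due to consistent differences among individuals.  A
negative s2_among (MS_among < MS_within) is reported as-is, so slightly
negative r values are representable.  The trend test is the
Cochran-Armitage chi-square for a linear trend in proportions across
ordered, equally spaced bins (df = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GroupedValues:
    """Per-individual repeated measurements of one migration variable."""

    groups: tuple[tuple[str, tuple[float, ...]], ...]
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 individuals")
        if any(len(vals) == 0 for _, vals in self.groups):
            raise ValueError("every individual needs at least one value")
        n_total = sum(len(vals) for _, vals in self.groups)
        if n_total < len(self.groups) + 1:
            raise ValueError("need at least one individual with repeated values")

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, Sequence[float]]], **kw) -> "GroupedValues":
        return cls(tuple((str(i), tuple(float(v) for v in vals)) for i, vals in pairs), **kw)


@dataclass(frozen=True)
class RepeatabilityResult:
    variable: str
    ms_among: float
    ms_within: float
    n0: float
    s2_among: float
    s2_within: float
    r: float | None
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    degenerate: bool = False  # all values identical: r undefined


def anova_components(data: GroupedValues) -> RepeatabilityResult:
    """One-way ANOVA variance components and repeatability for one variable."""
    values = [np.asarray(vals, dtype=float) for _, vals in data.groups]
    ns = np.array([v.size for v in values])
    a = len(values)
    n_total = int(ns.sum())
    grand = np.concatenate(values).mean()

    ss_among = float(sum(n * (v.mean() - grand) ** 2 for n, v in zip(ns, values)))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in values))
    df_num = a - 1
    df_den = n_total - a
    ms_among = ss_among / df_num
    ms_within = ss_within / df_den
    n0 = (n_total - float((ns ** 2).sum()) / n_total) / df_num

    if ms_among == 0.0 and ms_within == 0.0:
        return RepeatabilityResult(
            variable=data.variable, ms_among=0.0, ms_within=0.0, n0=n0,
            s2_among=0.0, s2_within=0.0, r=None, f_statistic=0.0,
            df_num=df_num, df_den=df_den, p_value=1.0, degenerate=True,
        )

    s2_among = (ms_among - ms_within) / n0
    s2_within = ms_within
    total = s2_among + s2_within
    r = s2_among / total if total != 0.0 else None
    if ms_within == 0.0:
        f = float("inf")
        p = 0.0
        r = 1.0
    else:
        f = ms_among / ms_within
        p = float(stats.f.sf(f, df_num, df_den))
    return RepeatabilityResult(
        variable=data.variable, ms_among=ms_among, ms_within=ms_within, n0=n0,
        s2_among=s2_among, s2_within=s2_within, r=r, f_statistic=f,
        df_num=df_num, df_den=df_den, p_value=p,
    )


def trend_test(bins: Sequence[tuple[int, int]]) -> tuple[float, int, float]:
    """Cochran-Armitage chi-square for trend in proportions.

    ``bins`` is an ordered list of (n_significant, n_total) pairs; scores
    are equally spaced (the parallels are 3 degrees apart).  Returns
    (chi2, df=1, p).
    """
    bins = [(int(k), int(n)) for k, n in bins]
    if len(bins) < 2:
        raise ValueError("need at least 2 ordered bins")
    if any(n < 0 or k < 0 or k > n for k, n in bins):
        raise ValueError("counts must satisfy 0 <= n_significant <= n_total")
    ks = np.array([k for k, _ in bins], dtype=float)
    ns = np.array([n for _, n in bins], dtype=float)
    if ns.sum() == 0:
        raise ValueError("all bin totals are zero")
    scores = np.arange(len(bins), dtype=float)
    n_tot = ns.sum()
    p_bar = ks.sum() / n_tot
    if p_bar in (0.0, 1.0):
        return 0.0, 1, 1.0
    num = float(np.sum(scores * (ks - ns * p_bar))) ** 2
    den = p_bar * (1.0 - p_bar) * (np.sum(ns * scores ** 2) - np.sum(ns * scores) ** 2 / n_tot)
    if den == 0.0:
        return 0.0, 1, 1.0
    chi2 = num / den
    return float(chi2), 1, float(stats.chi2.sf(chi2, 1))


def repeatability_table(datasets: Sequence[GroupedValues]):
    """Table-2-shaped DataFrame: variable, df, F, r, p per migration variable."""
    import pandas as pd

    rows = []
    for d in datasets:
        res = anova_components(d)
        rows.append(
            {
                "variable": res.variable,
                "df": f"{res.df_num}, {res.df_den}",
                "F": res.f_statistic,
                "r": res.r,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)
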