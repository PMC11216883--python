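"""Group summaries and hypothesis tests for assay records.

The reporting layer mirrors standard fluorescence-assay practice: per-group
mean ± SD and median/quartile summaries, two-tailed Welch t tests, one-way
fixed-effects ANOVA with Tukey(-Kramer) HSD post hoc pairwise comparisons,
and a type-II two-way ANOVA for factorial designs.  The one-way ANOVA F,
the Tukey adjusted p (studentized-range distribution) and the Welch t are
computed from their closed forms here; the two-way ANOVA delegates to
statsmodels.

Significance tiers follow the four-star convention:
``* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001``.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    for cut, label in STAR_TIERS:
        if p < cut:
            return label
    return "ns"


@dataclass(frozen=True)
class GroupComparison:
    """One family of comparisons over the groups of a metric."""

    metric: str
    test: str  # t_test | anova_tukey | two_way_anova
    groups: Mapping[str, np.ndarray]
    statistic: float  # F for ANOVA, t for the t test
    p_value: float
    comparisons: pd.DataFrame  # per-pair estimate / p / adjusted p / stars
    summary: pd.DataFrame  # per-group n, mean, sd, median, quartiles

    def __post_init__(self) -> None:
        ps = self.comparisons.filter(like="p_").to_numpy(dtype=float)
        if ps.size and (np.nanmin(ps) < 0 or np.nanmax(ps) > 1):
            raise ValueError("p-values must lie in [0, 1]")


def summarize(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group n, mean, sample SD (n−1), median and linear-interp quartiles.

    A singleton group has no sample SD; it is reported as NaN.
    """
    rows = []
    for name, values in groups.items():
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
        rows.append(
            {
                "group": name,
                "n": v.size,
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else np.nan,
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(rows)


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def _anova_f(g: Mapping[str, np.ndarray]):
    """Classical fixed-effects one-way ANOVA decomposition."""
    if len(g) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(v.size < 2 for v in g.values()):
        raise ValueError("every group needs at least 2 values")
    names = list(g)
    ns = np.array([g[n].size for n in names])
    means = np.array([g[n].mean() for n in names])
    N, k = ns.sum(), len(names)
    grand = sum(g[n].sum() for n in names) / N
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g[n] - g[n].mean()) ** 2) for n in names))
    df_b, df_w = k - 1, N - k
    ms_within = ss_within / df_w
    if ms_within == 0:
        raise ValueError("zero within-group variance: ANOVA undefined")
    F = (ss_between / df_b) / ms_within
    p = float(sps.f.sf(F, df_b, df_w))
    return F, p, ms_within, df_w, names, ns, means


def anova_type1_calibration(
    k: int = 3, n: int = 10, reps: int = 5000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the one-way ANOVA under equal-mean groups.

    Simulates ``reps`` null experiments of ``k`` standard-normal groups of
    size ``n`` and returns the fraction whose ANOVA p falls below ``alpha``.
    A calibrated test sits near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        data = rng.normal(size=(k, n))
        _, p, *_ = _anova_f({str(i): data[i] for i in range(k)})
        if p < alpha:
            rejections += 1
    return rejections / reps


def one_way_anova_tukey(
    groups: Mapping[str, Sequence[float]], metric: str = ""
) -> GroupComparison:
    """Fixed-effects one-way ANOVA with Tukey-Kramer HSD pairwise post hoc.

    F = MS_between / MS_within.  For each pair the studentized-range
    statistic is q = |mean_i − mean_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j))
    and the adjusted p is its survival probability at k groups and the
    within-group df; the unadjusted pairwise p uses the same pooled-variance
    standard error with a t reference.
    """
    g = _as_groups(groups)
    F, p, ms_within, df_w, names, ns, means = _anova_f(g)
    k = len(names)

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(ms_within * (1 / ns[i] + 1 / ns[j]))
            q = abs(diff) / np.sqrt(ms_within / 2 * (1 / ns[i] + 1 / ns[j]))
            p_adj = float(sps.studentized_range.sf(q, k, df_w)) if q > 0 else 1.0
            p_raw = float(2 * sps.t.sf(abs(diff) / se, df_w)) if se > 0 else 1.0
            rows.append(
                {
                    "group1": names[i],
                    "group2": names[j],
                    "estimate": float(diff),
                    "statistic": float(q),
                    "p_unadjusted": min(1.0, p_raw),
                    "p_adjusted": min(1.0, p_adj),
                    "stars": stars(min(1.0, p_adj)),
                }
            )
    return GroupComparison(
        metric=metric,
        test="anova_tukey",
        groups=g,
        statistic=float(F),
        p_value=p,
        comparisons=pd.DataFrame(rows),
        summary=summarize(g),
    )


def two_sample_t(
    groups: Mapping[str, Sequence[float]], metric: str = ""
) -> GroupComparison:
    """Two-tailed Welch (unequal-variance) t test on exactly two groups."""
    g = _as_groups(groups)
    if len(g) != 2:
        raise ValueError("the t test takes exactly 2 groups")
    (n1_name, a), (n2_name, b) = g.items()
    if a.size < 2 or b.size < 2:
        raise ValueError("every group needs at least 2 values")
    diff = float(b.mean() - a.mean())
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0:
        t_stat, p, df = (0.0, 1.0, float(a.size + b.size - 2)) if diff == 0 else (
            np.inf,
            0.0,
            float(a.size + b.size - 2),
        )
    else:
        t_stat = diff / np.sqrt(se2)
        df = se2**2 / (
            (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
            + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
        )
        p = float(2 * sps.t.sf(abs(t_stat), df))
    comparisons = pd.DataFrame(
        [
            {
                "group1": n1_name,
                "group2": n2_name,
                "estimate": diff,
                "statistic": float(t_stat),
                "df": float(df),
                "p_unadjusted": p,
                "p_adjusted": p,
                "stars": stars(p),
            }
        ]
    )
    return GroupComparison(
        metric=metric,
        test="t_test",
        groups=g,
        statistic=float(t_stat),
        p_value=p,
        comparisons=comparisons,
        summary=summarize(g),
    )


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Type-II two-way ANOVA table (robust to unbalanced designs)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    formula = "_y ~ C(_a) * C(_b)" if interaction else "_y ~ C(_a) + C(_b)"
    table = sm.stats.anova_lm(ols(formula, data=df).fit(), typ=2)
    table.index = [
        str(ix).replace("C(_a)", factor_a).replace("C(_b)", factor_b)
        for ix in table.index
    ]
    return table


def compare_conditions(
    records: pd.DataFrame,
    value_column: str = "normalized_value",
    group_column: str = "condition",
) -> pd.DataFrame:
    """Run one Tukey family per (assay, metric) of an assay-record table.

    Metrics with fewer than two eligible groups are skipped.  Returns the
    tidy comparisons table with group summaries merged in.
    """
    out = []
    eligible = records[~records.get("excluded", False).astype(bool)]
    eligible = eligible.dropna(subset=[value_column])
    # timecourse metrics form one family per day (day 0 is identically 1)
    for (assay, metric, day), sub in eligible.groupby(
        ["assay", "metric", "day"], dropna=False
    ):
        groups = {
            str(name): grp[value_column].to_numpy()
            for name, grp in sub.groupby(group_column)
            if len(grp) >= 2
        }
        if len(groups) < 2:
            continue
        try:
            comp = one_way_anova_tukey(groups, metric=metric)
        except ValueError as exc:
            logging.getLogger("organoquant").warning(
                "skipping %s/%s day=%s: %s", assay, metric, day, exc
            )
            continue
        table = comp.comparisons.copy()
        table.insert(0, "assay", assay)
        table.insert(1, "metric", metric)
        table.insert(2, "day", day)
        table["anova_F"] = comp.statistic
        table["anova_p"] = comp.p_value
        out.append(table)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)
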