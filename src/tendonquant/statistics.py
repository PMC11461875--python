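"""Cohort statistics: ANOVA with Tukey HSD post hoc.

The study design has three loading groups (ML = minimal, RL = reduced,
FL = full loading) crossed with healing time.  Early healing (weeks 1-3, all
groups) is analysed per metric with a fixed-effects two-way ANOVA
(load x time, interaction included, Type II sums of squares for the
unbalanced ML cell) followed by Tukey HSD across load groups within each
week.  Late healing (FL only, weeks 3/12/20) uses a one-way ANOVA over time
with Tukey HSD across weeks.

Input is a long-format table with columns ``section_id, group, week, metric,
value`` — one value per section and metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ValidationError

LONG_COLUMNS = ("section_id", "group", "week", "metric", "value")
EARLY_WEEKS = (1, 2, 3)
EARLY_GROUPS = ("ML", "RL", "FL")
LATE_WEEKS = (3, 12, 20)
LATE_GROUP = "FL"


@dataclass
class EffectStats:
    ss: float
    df: float
    F: float
    p: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectStats]
    residual_ss: float
    residual_df: float
    n: int

    def effect(self, name: str) -> EffectStats:
        return self.effects[name]


@dataclass
class TukeyResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adj: float
    reject: bool


def _metric_frame(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    missing = set(LONG_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"long table lacks columns {sorted(missing)}")
    df = table.loc[table["metric"] == metric].dropna(subset=["value"]).copy()
    if df.empty:
        raise ValidationError(f"no observations for metric {metric!r}")
    df["value"] = df["value"].astype(float)
    return df


def _check_cells(df: pd.DataFrame, factors: list[str]) -> None:
    levels = [sorted(df[f].unique(), key=str) for f in factors]
    for f, lv in zip(factors, levels):
        if len(lv) < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    counts = df.groupby(factors, observed=True).size()
    if len(factors) == 2:
        for a in levels[0]:
            for b in levels[1]:
                if (a, b) not in counts.index:
                    raise ValidationError(
                        f"empty cell: {factors[0]}={a}, {factors[1]}={b}"
                    )


def _degenerate_result(df: pd.DataFrame, effect_dfs: dict[str, float]) -> AnovaResult:
    # all observations identical: every F is 0 by contract, p = 1
    n = len(df)
    used = sum(effect_dfs.values())
    return AnovaResult(
        effects={k: EffectStats(0.0, v, 0.0, 1.0) for k, v in effect_dfs.items()},
        residual_ss=0.0,
        residual_df=n - 1 - used,
        n=n,
    )


def _from_anova_table(tab: pd.DataFrame, name_map: dict[str, str], n: int) -> AnovaResult:
    effects = {}
    for row_name, out_name in name_map.items():
        row = tab.loc[row_name]
        F = float(row["F"]) if np.isfinite(row["F"]) else 0.0
        p = float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else 1.0
        effects[out_name] = EffectStats(float(row["sum_sq"]), float(row["df"]), F, p)
    resid = tab.loc["Residual"]
    return AnovaResult(effects, float(resid["sum_sq"]), float(resid["df"]), n)


def two_way_anova(
    table: pd.DataFrame,
    metric: str,
    factor_a: str = "group",
    factor_b: str = "week",
) -> AnovaResult:
    """Two-factor fixed-effects ANOVA with interaction (Type II SS)."""
    df = _metric_frame(table, metric)
    _check_cells(df, [factor_a, factor_b])
    la = df[factor_a].nunique()
    lb = df[factor_b].nunique()
    df[factor_a] = df[factor_a].astype(str)
    df[factor_b] = df[factor_b].astype(str)
    if np.ptp(df["value"].to_numpy()) == 0.0:
        return _degenerate_result(
            df,
            {
                factor_a: la - 1,
                factor_b: lb - 1,
                f"{factor_a}:{factor_b}": (la - 1) * (lb - 1),
            },
        )
    model = ols(f"value ~ C({factor_a}) * C({factor_b})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    name_map = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": f"{factor_a}:{factor_b}",
    }
    return _from_anova_table(tab, name_map, len(df))


def one_way_anova(table: pd.DataFrame, metric: str, factor: str = "week") -> AnovaResult:
    """Single-factor fixed-effects ANOVA."""
    df = _metric_frame(table, metric)
    _check_cells(df, [factor])
    levels = df[factor].nunique()
    df[factor] = df[factor].astype(str)
    if np.ptp(df["value"].to_numpy()) == 0.0:
        return _degenerate_result(df, {factor: levels - 1})
    model = ols(f"value ~ C({factor})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = anova_lm(model, typ=2)
    return _from_anova_table(tab, {f"C({factor})": factor}, len(df))


def tukey_hsd(
    table: pd.DataFrame,
    metric: str,
    between: str = "group",
    within: tuple[str, object] | None = None,
    alpha: float = 0.05,
) -> list[TukeyResult]:
    """Tukey HSD pairwise comparisons, optionally within one stratum.

    ``within=("week", 2)`` restricts the comparison to load groups at week 2,
    using only that stratum's data (and hence its pooled residual variance),
    which matches post hoc load comparisons at each time point.
    """
    df = _metric_frame(table, metric)
    if within is not None:
        col, level = within
        df = df[df[col] == level]
    groups = df[between].astype(str)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValidationError(
            f"stratum {within} has fewer than 2 levels of {between!r}"
        )
    if (df.groupby(groups, observed=True).size() < 2).any() and np.ptp(
        df["value"].to_numpy()
    ) != 0.0:
        raise ValidationError("each compared group needs at least 2 observations")
    values = df["value"].to_numpy()
    if np.ptp(values) == 0.0:
        means = df.groupby(groups, observed=True)["value"].mean()
        out = []
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                out.append(TukeyResult(a, b, float(means[b] - means[a]), 1.0, False))
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pairwise_tukeyhsd(values, groups.to_numpy(), alpha=alpha)
    from itertools import combinations

    out = []
    pairs = list(combinations(res.groupsunique, 2))
    for (a, b), diff, p, rej in zip(pairs, res.meandiffs, res.pvalues, res.reject):
        p = float(p) if np.isfinite(p) else 1.0
        out.append(TukeyResult(str(a), str(b), float(diff), p, bool(rej)))
    return out


#: metrics carried per stain vs. taken from the collagen-1 section only
STAIN_METRICS = ("mean_intensity", "normalized_mean_intensity")
COLLAGEN1_METRICS = (
    "vessel_area_fraction",
    "normalized_vessel_area_fraction",
    "nuclei_area_fraction",
    "normalized_nuclei_area_fraction",
    "mean_aspect_ratio",
    "orientation_fwhm_deg",
)


def cohort_to_long(cohort: pd.DataFrame) -> pd.DataFrame:
    """Reshape the per-section cohort table into the long statistics format.

    Stain intensity metrics become ``mean_intensity_<stain>``; vessel and
    nucleus metrics are taken from the collagen-1 sections (where they are
    measured) under their own names.
    """
    rows = []
    for _, r in cohort.iterrows():
        base = {
            "section_id": r["section_id"],
            "group": r["group"],
            "week": r["week"],
        }
        for m in STAIN_METRICS:
            if m in r and pd.notna(r[m]):
                rows.append({**base, "metric": f"{m}_{r['stain_kind']}", "value": r[m]})
        if r["stain_kind"] == "collagen1":
            for m in COLLAGEN1_METRICS:
                if m in r and pd.notna(r[m]):
                    rows.append({**base, "metric": m, "value": r[m]})
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


@dataclass
class CohortAnalysis:
    """All ANOVA/Tukey results for one cohort, per metric."""

    alpha: float
    early_anova: dict[str, AnovaResult] = field(default_factory=dict)
    early_tukey: dict[tuple[str, int], list[TukeyResult]] = field(default_factory=dict)
    late_anova: dict[str, AnovaResult] = field(default_factory=dict)
    late_tukey: dict[str, list[TukeyResult]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def analyze_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    metrics: list[str] | None = None,
) -> CohortAnalysis:
    """Run the full statistical stage on a long-format metric table.

    Early healing: two-way load x time ANOVA on weeks 1-3 across ML/RL/FL,
    with within-week Tukey across load groups.  Late healing: one-way ANOVA
    over weeks 3/12/20 in FL, with Tukey across weeks.  Metrics or strata
    with insufficient data are skipped with a recorded warning rather than
    aborting the whole analysis.
    """
    out = CohortAnalysis(alpha=alpha)
    table = table.copy()
    if metrics is None:
        metrics = sorted(table["metric"].unique())
    week_num = pd.to_numeric(table["week"], errors="coerce")

    table["week"] = week_num.astype("Int64")
    early = table[week_num.isin(EARLY_WEEKS) & table["group"].isin(EARLY_GROUPS)]
    late = table[(table["group"] == LATE_GROUP) & week_num.isin(LATE_WEEKS)]

    for metric in metrics:
        try:
            out.early_anova[metric] = two_way_anova(early, metric)
            for wk in EARLY_WEEKS:
                out.early_tukey[(metric, wk)] = tukey_hsd(
                    early, metric, between="group", within=("week", wk), alpha=alpha
                )
        except ValidationError as exc:
            out.warnings.append(f"early-healing analysis skipped for {metric}: {exc}")
        try:
            sub = late[late["metric"] == metric].dropna(subset=["value"])
            have_weeks = set(pd.to_numeric(sub["week"]).unique())
            if not set(LATE_WEEKS) <= have_weeks:
                raise ValidationError(
                    f"late weeks present {sorted(have_weeks)} != {list(LATE_WEEKS)}"
                )
            out.late_anova[metric] = one_way_anova(late, metric, factor="week")
            out.late_tukey[metric] = tukey_hsd(
                late, metric, between="week", alpha=alpha
            )
        except ValidationError as exc:
            out.warnings.append(f"late-healing analysis skipped for {metric}: {exc}")
    return out
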