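"""Per-region factorial ANOVA and activation-pattern classification.

Each brain region is analysed with a two-way ANOVA with treatment
(MA vs SAL) and time of day (light vs dark phase) as factors.  The model is
fitted as a cell-means regression with sum-to-zero contrasts and
Type-III-style partial F tests, which on the balanced study design reduces
exactly to the classical balanced two-way decomposition; on unbalanced data
(dropped animals) it remains well defined rather than silently wrong.

A region's combination of significant effects assigns it to one of five
activation patterns:

=======  =========  ======  ===========
pattern  treatment  time    interaction
=======  =========  ======  ===========
1        yes        no      no
2        no         yes     no
3        yes        (any)   yes
4        yes        yes     no
5        no         no      no
other    no         (any)   yes
=======  =========  ======  ===========

The "other" row covers combinations absent from the published taxonomy
(an interaction without a treatment main effect) rather than forcing a
wrong label.  Trend-level effects (0.05 < p < 0.1) are annotated but never
influence the classification.

Simple-effects post hocs (MA vs SAL within each phase, light vs dark within
each treatment) use the pooled ANOVA error term with a Bonferroni factor of
4, the size of the per-region contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import DegenerateDataError, DesignError
from .sample_table import PHASES, TREATMENTS, region_columns, validate_sample_table

#: Number of simple-effect contrasts per region; the Bonferroni family size.
N_CONTRASTS = 4

#: p-value band reported as a trend annotation (never used by the classifier).
TREND_BAND = (0.05, 0.10)


@dataclass
class AnovaResult:
    """Two-way ANOVA summary for one region."""

    region: str
    f_treatment: float
    p_treatment: float
    f_time: float
    p_time: float
    f_interaction: float
    p_interaction: float
    df_num: int
    df_den: int
    cell_means: pd.DataFrame  # treatment x phase
    cell_ns: pd.DataFrame
    mse: float


@dataclass
class PatternLabel:
    """Activation-pattern assignment for one region."""

    region: str
    pattern: str  # "1".."5" or "other"
    flags: Tuple[bool, bool, bool]  # (treatment, time, interaction) significant at alpha
    alpha: float
    trends: Dict[str, float] = field(default_factory=dict)  # effect -> trend p


@dataclass
class ContrastResult:
    """One simple-effect contrast tested against the pooled error term."""

    name: str
    estimate: float
    se: float
    t: float
    df: int
    p_raw: float
    p_adj: float


@dataclass
class PosthocResult:
    """The four simple-effect contrasts for one region, Bonferroni-adjusted."""

    region: str
    contrasts: Dict[str, ContrastResult]
    alpha: float


def _region_frame(table: pd.DataFrame, region: str) -> pd.DataFrame:
    if region not in table.columns:
        raise KeyError(f"region {region!r} not in table")
    df = table[["treatment", "phase", region]].rename(columns={region: "y"})
    counts = df.groupby(["treatment", "phase"], observed=True).size()
    for t in TREATMENTS:
        for p in PHASES:
            n = counts.get((t, p), 0)
            if n == 0:
                raise DesignError(f"empty design cell ({t}, {p}) for region {region!r}")
            if n < 2:
                raise DesignError(
                    f"design cell ({t}, {p}) for region {region!r} has {n} observation(s); "
                    "at least 2 are required"
                )
    return df


def two_way_anova(table: pd.DataFrame, region: str) -> AnovaResult:
    """Two-way (treatment × phase) ANOVA for one region.

    Raises :class:`DesignError` for an empty/under-filled cell and
    :class:`DegenerateDataError` when the residual variance is zero.
    """
    df = _region_frame(table, region)
    model = smf.ols("y ~ C(treatment, Sum) * C(phase, Sum)", data=df).fit()
    # floating-point-relative zero: noiseless data leaves SSR ~ 1e-27
    ssr_floor = 1e-12 * max(float(model.centered_tss), 1.0)
    if model.df_resid <= 0 or not np.isfinite(model.mse_resid) or model.ssr <= ssr_floor:
        raise DegenerateDataError(
            f"zero residual variance for region {region!r}; F statistics are undefined"
        )
    aov = sm.stats.anova_lm(model, typ=3)
    t_row = "C(treatment, Sum)"
    p_row = "C(phase, Sum)"
    i_row = "C(treatment, Sum):C(phase, Sum)"
    cell_means = (
        df.groupby(["treatment", "phase"], observed=True)["y"].mean().unstack()
        .reindex(index=list(TREATMENTS), columns=list(PHASES))
    )
    cell_ns = (
        df.groupby(["treatment", "phase"], observed=True)["y"].size().unstack()
        .reindex(index=list(TREATMENTS), columns=list(PHASES))
    )
    return AnovaResult(
        region=region,
        f_treatment=float(aov.loc[t_row, "F"]),
        p_treatment=float(aov.loc[t_row, "PR(>F)"]),
        f_time=float(aov.loc[p_row, "F"]),
        p_time=float(aov.loc[p_row, "PR(>F)"]),
        f_interaction=float(aov.loc[i_row, "F"]),
        p_interaction=float(aov.loc[i_row, "PR(>F)"]),
        df_num=1,
        df_den=int(model.df_resid),
        cell_means=cell_means,
        cell_ns=cell_ns,
        mse=float(model.mse_resid),
    )


def pattern_from_flags(treatment: bool, time: bool, interaction: bool) -> str:
    """Map the three significance flags to an activation-pattern label.

    Total and deterministic: every one of the 8 flag combinations maps to
    exactly one of ``"1"``–``"5"`` or ``"other"``.
    """
    if interaction:
        return "3" if treatment else "other"
    if treatment and time:
        return "4"
    if treatment:
        return "1"
    if time:
        return "2"
    return "5"


def classify_pattern(result: AnovaResult, alpha: float = 0.05) -> PatternLabel:
    """Assign an :class:`AnovaResult` to one of the five activation patterns."""
    flags = (
        result.p_treatment < alpha,
        result.p_time < alpha,
        result.p_interaction < alpha,
    )
    lo, hi = TREND_BAND
    trends = {
        name: p
        for name, p in (
            ("treatment", result.p_treatment),
            ("time", result.p_time),
            ("interaction", result.p_interaction),
        )
        if lo < p < hi
    }
    return PatternLabel(
        region=result.region,
        pattern=pattern_from_flags(*flags),
        flags=flags,
        alpha=alpha,
        trends=trends,
    )


def simple_effects(table: pd.DataFrame, region: str, alpha: float = 0.05) -> PosthocResult:
    """The four simple-effect contrasts for one region.

    Each contrast compares two cell means with a t statistic built on the
    pooled ANOVA mean-square error and its residual degrees of freedom;
    raw two-sided p values are Bonferroni-multiplied by the family size (4)
    and capped at 1.
    """
    res = two_way_anova(table, region)
    means, ns = res.cell_means, res.cell_ns
    specs = [
        ("MA_vs_SAL_light", ("MA", "light"), ("SAL", "light")),
        ("MA_vs_SAL_dark", ("MA", "dark"), ("SAL", "dark")),
        ("light_vs_dark_MA", ("MA", "light"), ("MA", "dark")),
        ("light_vs_dark_SAL", ("SAL", "light"), ("SAL", "dark")),
    ]
    contrasts: Dict[str, ContrastResult] = {}
    for name, (t1, p1), (t2, p2) in specs:
        est = float(means.loc[t1, p1] - means.loc[t2, p2])
        se = float(np.sqrt(res.mse * (1.0 / ns.loc[t1, p1] + 1.0 / ns.loc[t2, p2])))
        t = est / se
        p_raw = float(2.0 * scipy.stats.t.sf(abs(t), res.df_den))
        contrasts[name] = ContrastResult(
            name=name,
            estimate=est,
            se=se,
            t=float(t),
            df=res.df_den,
            p_raw=p_raw,
            p_adj=min(1.0, N_CONTRASTS * p_raw),
        )
    return PosthocResult(region=region, contrasts=contrasts, alpha=alpha)


def analyze_activation(
    table: pd.DataFrame, alpha: float = 0.05, posthoc: bool = True
) -> Tuple[List[AnovaResult], List[PatternLabel], List[PosthocResult]]:
    """Run ANOVA, classification, and (optionally) post hocs for every region."""
    table = validate_sample_table(table)
    results, labels, posthocs = [], [], []
    for region in region_columns(table):
        res = two_way_anova(table, region)
        results.append(res)
        labels.append(classify_pattern(res, alpha=alpha))
        if posthoc:
            posthocs.append(simple_effects(table, region, alpha=alpha))
    return results, labels, posthocs


def results_frame(results: List[AnovaResult], labels: List[PatternLabel]) -> pd.DataFrame:
    """Tidy one-row-per-region summary of ANOVA statistics and pattern labels."""
    by_region = {lab.region: lab for lab in labels}
    rows = []
    for r in results:
        lab = by_region[r.region]
        rows.append(
            {
                "region": r.region,
                "F_treatment": r.f_treatment, "p_treatment": r.p_treatment,
                "F_time": r.f_time, "p_time": r.p_time,
                "F_interaction": r.f_interaction, "p_interaction": r.p_interaction,
                "df_num": r.df_num, "df_den": r.df_den,
                "pattern": lab.pattern,
                "treatment_sig": lab.flags[0],
                "time_sig": lab.flags[1],
                "interaction_sig": lab.flags[2],
                "trends": ";".join(f"{k}={v:.3f}" for k, v in sorted(lab.trends.items())),
            }
        )
    return pd.DataFrame(rows)


def posthoc_frame(posthocs: List[PosthocResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast summary of the simple-effect tests."""
    rows = []
    for ph in posthocs:
        for c in ph.contrasts.values():
            rows.append(
                {
                    "region": ph.region, "contrast": c.name, "estimate": c.estimate,
                    "se": c.se, "t": c.t, "df": c.df,
                    "p_raw": c.p_raw, "p_bonferroni": c.p_adj,
                }
            )
    return pd.DataFrame(rows)
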