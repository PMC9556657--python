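"""Grade-stratified exposure summaries and one-way ANOVA.

Density statistics are reported among neighborhoods with any exposure in
the period considered (the zero-exposure mass otherwise swamps the mean);
a switch includes the zeros.  The ANOVA is the classical between/within
sum-of-squares F test applied grade-wise to counts or densities, at
α = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["grade_summary", "one_way_anova", "AnovaResult", "anova_table"]

GRADE_ORDER = ("A", "B", "C", "D")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


def grade_summary(
    exposures: pd.DataFrame,
    periods: tuple[str, ...] = ("all", "pre", "post"),
    exposed_only: bool = True,
) -> pd.DataFrame:
    """Per-grade, per-period exposure summary.

    ``exposures`` is the table from :func:`holcwells.geometry.exposure_table`
    (needs ``grade``, ``count_<period>``, ``density_<period>``).  Density
    mean/sd/median are computed over the exposed subset (count ≥ 1 in that
    period) unless ``exposed_only=False``; sd is the sample (n−1) form.
    """
    rows = []
    for period in periods:
        cnt, dens = f"count_{period}", f"density_{period}"
        for grade in GRADE_ORDER:
            sub = exposures[exposures["grade"] == grade]
            if len(sub) == 0:
                logger.warning("no neighborhoods with grade %s", grade)
                rows.append({"grade": grade, "period": period, "n_neighborhoods": 0})
                continue
            exposed = sub[sub[cnt] >= 1]
            d = (exposed if exposed_only else sub)[dens]
            rows.append({
                "grade": grade,
                "period": period,
                "n_neighborhoods": len(sub),
                "n_exposed": len(exposed),
                "total_wells": int(sub[cnt].sum()),
                "mean_density": d.mean() if len(d) else np.nan,
                "sd_density": d.std(ddof=1) if len(d) > 1 else np.nan,
                "median_density": d.median() if len(d) else np.nan,
            })
    return pd.DataFrame(rows)


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classical one-way ANOVA F test across grade strata.

    F = (SSB / df_between) / (SSW / df_within); the p-value is the upper
    tail of the F(df_between, df_within) distribution.  Zero within-group
    variance with unequal means returns F = +inf, p = 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    n = sum(len(g) for g in groups)
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return AnovaResult(0.0, dfb, dfw, 1.0)
        logger.warning("zero within-group variance with unequal means: F = +inf")
        return AnovaResult(float("inf"), dfb, dfw, 0.0)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(stats.f.sf(F, dfb, dfw))
    return AnovaResult(float(F), dfb, dfw, p)


def anova_table(
    exposures: pd.DataFrame,
    periods: tuple[str, ...] = ("all", "pre", "post"),
    metrics: tuple[str, ...] = ("count", "density"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the grade-wise ANOVA for each period × metric and label results."""
    rows = []
    for period in periods:
        for metric in metrics:
            col = f"{metric}_{period}"
            groups = [
                exposures.loc[exposures["grade"] == g, col].to_numpy()
                for g in GRADE_ORDER
                if (exposures["grade"] == g).any()
            ]
            try:
                res = one_way_anova(groups)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s: %s", col, exc)
                continue
            rows.append({
                "period": period,
                "metric": metric,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "significant": res.p < alpha,
            })
    return pd.DataFrame(rows)
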