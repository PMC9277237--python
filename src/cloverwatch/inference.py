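"""Statistical models linking camera-observed visitation to seed set.

Three analyses:

1. A two-group linear model of seed set on a binary visitation indicator
   (visited by any pollinator class, or by bumblebees only), reported as
   an F-test with 1 and n-2 degrees of freedom.
2. An AIC comparison of the two visitor definitions fitted to the same
   observations. With equal parameter counts the Gaussian AIC difference
   reduces to ``n * ln(RSS_bee / RSS_any)``.
3. A (weighted) least-squares regression of the Seed Lateness Index on
   the Visit Lateness Index, with weights ``w = 0.25 - |s - 0.25|`` so
   inflorescences whose SLI is ill-determined (seed set near 0 or 0.5)
   contribute little. Observations with w = 0 contribute nothing and are
   not counted in the residual degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "TwoGroupFit",
    "WeightedRegressionFit",
    "gaussian_aic",
    "two_group_seedset_model",
    "compare_visitor_definitions",
    "sli_vli_regression",
]

GROUPINGS = {"any_visit": "visited_any", "bumblebee_only": "visited_bumblebee"}


@dataclass
class TwoGroupFit:
    """One-way comparison of seed set between visited and unvisited heads."""

    grouping: str
    n: int
    mean_unvisited: float
    mean_visited: float
    mean_difference_pct: float  # visited minus unvisited, percentage points
    F: float
    df: tuple[int, int]
    p_value: float
    r_squared: float
    rss: float
    aic: float


@dataclass
class WeightedRegressionFit:
    """Least-squares fit of SLI (percentile) on VLI (days)."""

    n: int
    slope: float
    intercept: float
    F: float
    df_residual: int
    p_value: float
    r_squared: float
    weighted: bool


def gaussian_aic(rss: float, n: int, k: int) -> float:
    """AIC under a Gaussian likelihood, up to an additive constant in n.

    ``n * ln(RSS/n) + 2k`` with k counting mean parameters plus the error
    variance. The dropped constant cancels in any AIC difference between
    models fitted to the same n observations.
    """
    if rss <= 0:
        raise DegenerateDataError("AIC undefined for a saturated (zero-RSS) fit")
    return n * math.log(rss / n) + 2 * k


def _restrict(index_table: pd.DataFrame, fully_recorded_only: bool) -> pd.DataFrame:
    df = index_table
    if fully_recorded_only and "fully_recorded" in df.columns:
        df = df[df["fully_recorded"]]
    return df[df["s"].notna()]


def two_group_seedset_model(
    index_table: pd.DataFrame,
    grouping: str = "any_visit",
    fully_recorded_only: bool = True,
) -> TwoGroupFit:
    """OLS of seed set on a binary visitation indicator.

    ``grouping`` is ``any_visit`` (bumblebee and/or moth and/or other seen
    on camera) or ``bumblebee_only``. The model is fitted to fully
    recorded inflorescences with measurable seed set; the F statistic is
    the standard one-way decomposition with df = (1, n-2) and equals the
    squared pooled two-sample t statistic.
    """
    if grouping not in GROUPINGS:
        raise ConfigurationError(f"grouping must be one of {sorted(GROUPINGS)}")
    df = _restrict(index_table, fully_recorded_only)
    g = df[GROUPINGS[grouping]].astype(bool).to_numpy()
    y = df["s"].to_numpy(float)
    n = len(y)
    if g.sum() < 2 or (~g).sum() < 2:
        raise DegenerateDataError(
            f"two-group model needs >= 2 observations per group "
            f"(visited={int(g.sum())}, unvisited={int((~g).sum())})"
        )
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant seed set: no variance to decompose")
    X = sm.add_constant(g.astype(float))
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    if rss <= 0 or not np.isfinite(fit.fvalue):
        raise DegenerateDataError("zero residual variance: F statistic undefined")
    return TwoGroupFit(
        grouping=grouping,
        n=n,
        mean_unvisited=float(y[~g].mean()),
        mean_visited=float(y[g].mean()),
        mean_difference_pct=float((y[g].mean() - y[~g].mean()) * 100),
        F=float(fit.fvalue),
        df=(1, n - 2),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        rss=rss,
        aic=gaussian_aic(rss, n, k=3),
    )


def compare_visitor_definitions(
    index_table: pd.DataFrame, fully_recorded_only: bool = True
) -> dict:
    """Does adding moth (and other) visits improve the seed-set model?

    Fits the ``bumblebee_only`` and ``any_visit`` two-group models on the
    identical observation set and returns both fits plus
    ``delta_aic = AIC(bumblebee_only) - AIC(any_visit)``; positive values
    favour the definition that counts all visitor classes. Both models
    have the same parameter count, so delta_aic = n * ln(RSS_bee/RSS_any).
    """
    df = _restrict(index_table, fully_recorded_only)
    fit_any = two_group_seedset_model(df, "any_visit", fully_recorded_only=False)
    fit_bee = two_group_seedset_model(df, "bumblebee_only", fully_recorded_only=False)
    if fit_any.n != fit_bee.n:
        raise DegenerateDataError("models fitted to differing observation sets")
    return {
        "any_visit": fit_any,
        "bumblebee_only": fit_bee,
        "delta_aic": fit_bee.aic - fit_any.aic,
    }


def sli_vli_regression(
    index_table: pd.DataFrame,
    weighted: bool = True,
    include_zero_weight: bool = False,
) -> WeightedRegressionFit:
    """(Weighted) least squares of SLI on VLI across inflorescences.

    Only inflorescences with a defined VLI (seen visited) and a defined
    SLI (>= 1 seeded floret) enter. In the weighted fit, observations with
    w = 0 contribute zero weight — equivalently they are excluded, and n
    and the residual degrees of freedom (n - 2) count w > 0 observations
    only. ``include_zero_weight`` re-admits them to the *unweighted* fit.
    """
    df = index_table[index_table["vli"].notna() & index_table["sli"].notna()]
    if weighted:
        w = df["w"].to_numpy(float)
        if np.all(w <= 0):
            raise DegenerateDataError("all regression weights are zero")
        df = df[df["w"] > 0]
        w = df["w"].to_numpy(float)
    else:
        if not include_zero_weight and "w" in df.columns:
            df = df[df["w"] > 0]
        w = np.ones(len(df))
    n = len(df)
    if n < 3:
        raise DegenerateDataError(f"regression needs >= 3 observations, have {n}")
    X = sm.add_constant(df["vli"].to_numpy(float))
    y = df["sli"].to_numpy(float)
    fit = sm.WLS(y, X, weights=w).fit()
    return WeightedRegressionFit(
        n=n,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        F=float(fit.fvalue),
        df_residual=int(fit.df_resid),
        p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared),
        weighted=weighted,
    )
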