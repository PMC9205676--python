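"""Dose-gradient regressions of β-diversity and slope comparison.

Each organism group's treatment-vs-ambient dissimilarity (βsor or one of
its components) is regressed on log₂(dose) by ordinary least squares;
the ambient level is excluded (log₂ 0 is undefined and its
dissimilarity-to-self is 0 by construction).  Slopes are compared
between groups by covariance analysis: the pooled model
``response ~ x + group + x:group`` is fitted per pair of groups and the
interaction coefficient tested, which for balanced designs equals the
difference of the separately fitted slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["GradientFit", "fit_dissimilarity_gradient", "compare_slopes"]

_RESPONSES = ("beta_sor", "beta_sim", "beta_nes")


@dataclass(frozen=True)
class GradientFit:
    group: str
    response: str
    slope: float
    intercept: float
    r2: float
    p_slope: float
    n: int


def _dose_axis(levels: pd.Series) -> np.ndarray:
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("ambient (0) rows must be excluded before log2")
    return np.log2(levels)


def fit_dissimilarity_gradient(
    comparisons: pd.DataFrame,
    response: str = "beta_sor",
    level_means: bool = False,
    include_block: bool = False,
) -> pd.DataFrame:
    """OLS fit of a dissimilarity component on log₂(dose), per group.

    Parameters
    ----------
    comparisons : treatment-vs-ambient table with columns group, block,
        n_level and the three partition components
    response : one of beta_sor, beta_sim, beta_nes
    level_means : regress on per-level means instead of all block-level
        points (reduces n from levels × blocks to levels)
    include_block : add block as a categorical covariate

    Returns a DataFrame with one row per group: slope, intercept, R²,
    slope p-value (t-test) and n.
    """
    if response not in _RESPONSES:
        raise ValueError(f"response must be one of {_RESPONSES}")
    df = comparisons[comparisons["n_level"] != 0].copy()
    rows = []
    for g, sub in df.groupby("group", sort=True):
        if level_means:
            sub = (sub.groupby("n_level", as_index=False)[response].mean())
        if sub["n_level"].nunique() < 3:
            raise ValueError(
                f"group {g!r}: need >= 3 distinct non-ambient levels"
            )
        x = _dose_axis(sub["n_level"])
        y = sub[response].to_numpy(dtype=float)
        X = pd.DataFrame({"x": x})
        if include_block and not level_means:
            X = pd.concat(
                [X, pd.get_dummies(sub["block"], prefix="block",
                                   drop_first=True, dtype=float)
                 .set_index(X.index)],
                axis=1,
            )
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        rows.append(
            GradientFit(
                group=g,
                response=response,
                slope=float(fit.params["x"]),
                intercept=float(fit.params["const"]),
                r2=float(fit.rsquared),
                p_slope=float(fit.pvalues["x"]),
                n=int(len(y)),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def compare_slopes(
    comparisons: pd.DataFrame,
    response: str = "beta_sor",
    groups=None,
) -> pd.DataFrame:
    """Pairwise slope comparison among groups by covariance analysis.

    For each pair of groups fits the pooled model
    ``response ~ x + group + x:group`` on the non-ambient rows and
    reports the interaction estimate (slope difference), its F statistic
    and p-value.
    """
    if response not in _RESPONSES:
        raise ValueError(f"response must be one of {_RESPONSES}")
    df = comparisons[comparisons["n_level"] != 0]
    all_groups = sorted(df["group"].unique()) if groups is None else list(groups)
    if len(all_groups) < 2:
        raise ValueError("need at least 2 groups to compare slopes")
    rows = []
    for i, ga in enumerate(all_groups):
        for gb in all_groups[i + 1:]:
            sub = df[df["group"].isin([ga, gb])]
            x = _dose_axis(sub["n_level"])
            ind = (sub["group"] == gb).to_numpy(dtype=float)
            X = sm.add_constant(
                np.column_stack([x, ind, x * ind])
            )
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(
                    f"singular design comparing {ga!r} vs {gb!r}"
                )
            fit = sm.OLS(sub[response].to_numpy(dtype=float), X).fit()
            t = fit.tvalues[3]
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "response": response,
                    "slope_diff": float(fit.params[3]),
                    "interaction_F": float(t ** 2),
                    "p": float(fit.pvalues[3]),
                }
            )
    return pd.DataFrame(rows)
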