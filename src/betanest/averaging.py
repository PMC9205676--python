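"""AICc-based all-subsets model selection and multimodel averaging.

Explains a β-diversity component with N-induced environmental change:
the predictors are per-comparison deltas (treatment plot minus the
same-block ambient plot) of soil total N, DIN, pH, exchangeable Al³⁺ and
Mn²⁺, z-scored so coefficients are standardized effect sizes.

The workflow mirrors common ecological practice ("dredge"-style):

1. collinearity screening by variance inflation factors,
   VIF_j = 1 / (1 − R²_j) from regressing predictor j on the others;
2. all 2^p OLS subsets ranked by the small-sample Akaike criterion
   AICc = −2·logLik + 2k + 2k(k+1)/(n − k − 1), with k counting the
   intercept, slopes and residual variance;
3. Akaike weights w_i ∝ exp(−ΔAICc_i/2) over the candidate set;
4. model averaging over the confidence set ΔAICc < 4 with renormalised
   weights — by default *full* (zero-substitution) averaging, where a
   model not containing a predictor contributes a coefficient of 0, with
   unconditional standard errors combining within-model variance and
   between-model coefficient spread;
5. relative effects: |averaged estimate| as a percentage of the sum of
   absolute averaged estimates.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CollinearityReport",
    "ModelSet",
    "AveragedModel",
    "environmental_deltas",
    "standardize",
    "vif",
    "all_subsets_aicc",
    "average_parameters",
    "relative_effects",
    "explained_variability",
]

_Z_95 = 1.959963984540054  # standard normal 97.5% quantile


def environmental_deltas(
    env: pd.DataFrame,
    meta: pd.DataFrame,
    comparisons: pd.DataFrame,
    covariates=None,
) -> pd.DataFrame:
    """Treatment-minus-ambient covariate changes aligned with a
    treatment-vs-ambient comparison table.

    For each comparison row the delta is the treatment sample's covariate
    value minus the same-block ambient sample's value.  Returns one row
    per comparison row, unstandardized.
    """
    env = env.set_index("sample") if "sample" in env.columns else env
    meta_idx = meta.set_index("sample") if "sample" in meta.columns else meta
    if covariates is None:
        covariates = [c for c in env.columns]
    ambient = {}
    for _, row in meta_idx[meta_idx["n_level"] == 0].iterrows():
        ambient[(row.get("group"), row["block"])] = row.name
    rows = []
    for _, comp in comparisons.iterrows():
        key = (comp.get("group"), comp["block"])
        if key not in ambient:
            raise ValueError(f"no ambient sample for {key}")
        trt, amb = comp["sample"], ambient[key]
        rows.append(env.loc[trt, covariates] - env.loc[amb, covariates])
    return pd.DataFrame(rows).reset_index(drop=True)


def standardize(X: pd.DataFrame):
    """Z-score each column (sample SD, n−1 denominator).

    Returns ``(Z, center, scale)`` so the transform is invertible.
    Raises on zero-variance columns, naming them.
    """
    X = pd.DataFrame(X).astype(float)
    center = X.mean()
    scale = X.std(ddof=1)
    dead = scale.index[(scale == 0) | scale.isna()].tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}")
    return (X - center) / scale, center, scale


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor, 1/(1 − R²_j).

    Each predictor is regressed on all others (with intercept).  A
    perfectly collinear predictor yields ``inf`` with a warning.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than predictors + 1")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]))
        r2 = sm.OLS(X[col], others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            warnings.warn(
                f"predictor {col!r} is perfectly collinear (VIF -> inf)",
                stacklevel=2,
            )
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


@dataclass(frozen=True)
class CollinearityReport:
    vif: pd.Series


@dataclass
class _FittedSubset:
    predictors: tuple
    k: int
    aicc: float
    params: pd.Series       # includes "const"
    bse: pd.Series
    r2: float


@dataclass
class ModelSet:
    """All-subsets OLS fits ranked by AICc."""

    table: pd.DataFrame                 # predictors, k, aicc, delta, weight
    models: list = field(repr=False, default_factory=list)
    response_name: str = "y"
    n: int = 0
    predictor_names: tuple = ()

    def best(self) -> _FittedSubset:
        return self.models[int(self.table["aicc"].idxmin())]


def _aicc_from_fit(fit, n: int) -> tuple[float, int]:
    # k counts intercept + slopes + residual variance
    k = int(fit.df_model) + 2
    if n - k - 1 <= 0:
        return np.nan, k
    aicc = -2.0 * fit.llf + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)
    return float(aicc), k


def all_subsets_aicc(y, X: pd.DataFrame, max_models: int = 4096) -> ModelSet:
    """Fit every predictor subset (including intercept-only) by OLS.

    Returns the model set with AICc, ΔAICc relative to the best model and
    Akaike weights normalised over all candidates.  Subsets for which the
    small-sample correction is undefined (n − k − 1 ≤ 0) are excluded
    with a warning.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("y and X row counts differ")
    p = X.shape[1]
    if 2 ** p > max_models:
        raise ValueError(f"2^{p} candidate models exceed cap {max_models}")
    names = tuple(X.columns)
    models: list[_FittedSubset] = []
    skipped = []
    for r in range(p + 1):
        for subset in itertools.combinations(names, r):
            design = sm.add_constant(
                X[list(subset)] if subset else pd.DataFrame(index=X.index),
                has_constant="add",
            )
            fit = sm.OLS(y, design).fit()
            aicc, k = _aicc_from_fit(fit, n)
            if np.isnan(aicc):
                skipped.append(subset)
                continue
            models.append(
                _FittedSubset(
                    predictors=subset,
                    k=k,
                    aicc=aicc,
                    params=fit.params,
                    bse=fit.bse,
                    r2=float(fit.rsquared),
                )
            )
    if skipped:
        warnings.warn(
            f"{len(skipped)} subset(s) dropped: AICc undefined (n - k - 1 <= 0)",
            stacklevel=2,
        )
    if not models:
        raise ValueError("no fittable subsets")
    aiccs = np.array([m.aicc for m in models])
    delta = aiccs - aiccs.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    table = pd.DataFrame(
        {
            "predictors": [",".join(m.predictors) for m in models],
            "k": [m.k for m in models],
            "r2": [m.r2 for m in models],
            "aicc": aiccs,
            "delta_aicc": delta,
            "weight": w,
        }
    )
    return ModelSet(table=table, models=models, n=n, predictor_names=names)


@dataclass
class AveragedModel:
    """Model-averaged standardized coefficients over the ΔAICc confidence set."""

    table: pd.DataFrame          # estimate, se, ci_low, ci_high, significant,
                                 # relative_effect per predictor
    n_models: int
    delta_threshold: float
    method: str
    r2_global: float
    r2_best: float


def average_parameters(
    model_set: ModelSet,
    delta_threshold: float = 4.0,
    method: str = "full",
) -> AveragedModel:
    """Average coefficients over models with ΔAICc below the threshold.

    ``method="full"`` (default) substitutes 0 for a predictor absent from
    a model, shrinking weakly supported effects toward zero;
    ``method="conditional"`` averages only over the models containing the
    predictor.  Unconditional SEs follow the weighted combination of
    within-model variance and between-model spread,
    SE_j = Σ wᵢ·sqrt(var(β̂_j|modelᵢ) + (β̂_ij − β̄_j)²); 95% CIs use the
    normal quantile.
    """
    if method not in ("full", "conditional"):
        raise ValueError("method must be 'full' or 'conditional'")
    tab = model_set.table
    keep = np.flatnonzero((tab["delta_aicc"] < delta_threshold).to_numpy())
    if keep.size == 0:
        raise ValueError("no models within the AICc threshold")
    w = tab["weight"].to_numpy()[keep]
    w = w / w.sum()
    models = [model_set.models[i] for i in keep]
    rows = {}
    for name in model_set.predictor_names:
        beta = np.array(
            [m.params.get(name, 0.0) for m in models]
        )
        var = np.array(
            [m.bse.get(name, 0.0) ** 2 for m in models]
        )
        contains = np.array([name in m.predictors for m in models])
        if method == "full":
            wj, bj, vj = w, beta, var
        else:
            if not contains.any():
                rows[name] = (0.0, np.nan)
                continue
            wj = w[contains] / w[contains].sum()
            bj, vj = beta[contains], var[contains]
        est = float(np.sum(wj * bj))
        se = float(np.sum(wj * np.sqrt(vj + (bj - est) ** 2)))
        rows[name] = (est, se)
    estimates = pd.Series({k: v[0] for k, v in rows.items()})
    ses = pd.Series({k: v[1] for k, v in rows.items()})
    ci_low = estimates - _Z_95 * ses
    ci_high = estimates + _Z_95 * ses
    significant = (ci_low > 0) | (ci_high < 0)
    rel = relative_effects(estimates)
    table = pd.DataFrame(
        {
            "estimate": estimates,
            "se": ses,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "significant": significant,
            "relative_effect": rel,
        }
    )
    r2_global = _global_r2(model_set)
    r2_best = model_set.best().r2
    return AveragedModel(
        table=table,
        n_models=len(models),
        delta_threshold=delta_threshold,
        method=method,
        r2_global=r2_global,
        r2_best=r2_best,
    )


def _global_r2(model_set: ModelSet) -> float:
    full = [m for m in model_set.models
            if m.predictors == model_set.predictor_names]
    return full[0].r2 if full else np.nan


def relative_effects(estimates: pd.Series) -> pd.Series:
    """|estimate| as a percentage of the summed |estimates| (sums to 100)."""
    est = pd.Series(estimates, dtype=float).abs()
    total = est.sum()
    if total == 0:
        raise ValueError("all averaged estimates are zero")
    return est / total * 100.0


def explained_variability(model_set: ModelSet) -> dict:
    """Percent of response variability explained.

    Reported as the global (all-predictors) model's R² × 100, alongside
    the best-AICc model's R² × 100.
    """
    return {
        "global_r2_percent": _global_r2(model_set) * 100.0,
        "best_model_r2_percent": model_set.best().r2 * 100.0,
    }
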