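"""Leave-one-out influence diagnostics and exclusion-impact summaries.

Cook's distance for observation i is computed from exact refits (never the
one-step hat-matrix approximation):

    D_i = sum_j (yhat_j - yhat_j^(i))^2 / (q * MSE)

where yhat_j is the full-model predicted probability for observation j,
yhat_j^(i) the prediction from the model refitted without observation i,
MSE the mean squared error of the full model on the binary outcome (a
Brier-type quantity, (1/n) sum (y_j - yhat_j)^2, by default) and q the
number of estimated coefficients (intercept included, by default).  Both
conventions only rescale all D_i by a common constant, so they can change
which values clear an absolute threshold but never the influence ordering;
both are configurable.

Individuals with D_i above a threshold (0.05 by default) are flagged as
outliers, and `exclusion_impact` quantifies how removing each one shifts the
age odds ratio under the standard and the robust estimator, reporting the
percent change of the *excess risk* OR - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import DesignMatrix, fit_irls
from .robust import RobustConfig, fit_robust

__all__ = ["CookReport", "ExclusionImpactRow", "cooks_distance", "flag_outliers", "exclusion_impact"]


@dataclass
class CookReport:
    """Per-individual exact leave-one-out Cook's distances."""

    ids: list[str]
    cook_d: np.ndarray  # NaN where the leave-one-out refit failed
    q: int
    mse: float
    threshold: float
    estimator: str
    failed_ids: list[str] = field(default_factory=list)

    def flagged_ids(self) -> list[str]:
        return flag_outliers(self, self.threshold)

    def to_frame(self) -> pd.DataFrame:
        flags = set(self.flagged_ids())
        return pd.DataFrame(
            {
                "id": self.ids,
                "cook_d": self.cook_d,
                "flagged": [i in flags for i in self.ids],
            }
        )


@dataclass
class ExclusionImpactRow:
    """Effect of excluding one individual on the age odds ratio."""

    excluded_id: str
    outcome_status: int
    age: float
    or_standard: float
    ci_standard: tuple[float, float]
    pct_change_standard: float
    or_robust: float
    ci_robust: tuple[float, float]
    pct_change_robust: float
    defined: bool = True


def _fit_predict(
    X: DesignMatrix,
    y: np.ndarray,
    estimator: str,
    config: RobustConfig | None,
):
    """Fit with the chosen estimator, return (fit, fitted probabilities)."""
    if estimator == "standard":
        fit = fit_irls(X, y)
    elif estimator == "robust":
        fit = fit_robust(X, y, config)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return fit


def cooks_distance(
    X: DesignMatrix,
    y: np.ndarray,
    ids: list[str] | None = None,
    estimator: str = "standard",
    threshold: float = 0.05,
    config: RobustConfig | None = None,
    mse_denominator: str = "n",
    q_convention: str = "coefficients",
) -> CookReport:
    """Exact leave-one-out Cook's distances under the chosen estimator.

    ``mse_denominator``: "n" (Brier-type, default) or "n_minus_q" (residual
    MSE).  ``q_convention``: "coefficients" (p, intercept included, default)
    or "explanatory" (p - 1).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.n, X.p
    if n < p + 2:
        raise ValueError(f"need n >= p + 2 for leave-one-out refits (n={n}, p={p})")
    if ids is None:
        ids = [str(i) for i in range(n)]
    full = _fit_predict(X, y, estimator, config)
    yhat = full.fitted_mu
    q = p if q_convention == "coefficients" else p - 1
    if q < 1:
        raise ValueError("q convention yields q < 1")
    denom_n = n if mse_denominator == "n" else n - q
    mse = float(np.sum((y - yhat) ** 2)) / denom_n
    cook = np.empty(n)
    failed: list[str] = []
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi = DesignMatrix(X.values[mask], list(X.column_names))
        try:
            fit_i = _fit_predict(Xi, y[mask], estimator, config)
            if not fit_i.converged:
                raise RuntimeError("leave-one-out refit did not converge")
        except Exception:
            cook[i] = np.nan
            failed.append(ids[i])
            mask[i] = True
            continue
        mask[i] = True
        eta = X.values @ fit_i.beta
        yhat_i = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        cook[i] = float(np.sum((yhat - yhat_i) ** 2)) / (q * mse)
    return CookReport(
        ids=list(ids),
        cook_d=cook,
        q=q,
        mse=mse,
        threshold=threshold,
        estimator=estimator,
        failed_ids=failed,
    )


def flag_outliers(report: CookReport, threshold: float = 0.05) -> list[str]:
    """Ids with D_i strictly above the threshold, descending by D_i."""
    order = np.argsort(-np.nan_to_num(report.cook_d, nan=-np.inf), kind="stable")
    return [
        report.ids[i]
        for i in order
        if not math.isnan(report.cook_d[i]) and report.cook_d[i] > threshold
    ]


def _age_or(fit, age_col: int, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    from scipy import stats as _st

    z = _st.norm.ppf(0.5 + level / 2.0)
    b = fit.beta[age_col]
    s = fit.se()[age_col]
    return float(np.exp(b)), (float(np.exp(b - z * s)), float(np.exp(b + z * s)))


def excess_risk_change(or_excl: float, or_ref: float) -> float:
    """Percent change of the excess risk OR - 1 after exclusion."""
    return 100.0 * ((or_excl - 1.0) / (or_ref - 1.0) - 1.0)


def exclusion_impact(
    X: DesignMatrix,
    y: np.ndarray,
    ids: list[str],
    exclude_ids: list[str],
    age_column: str = "age",
    config: RobustConfig | None = None,
) -> list[ExclusionImpactRow]:
    """Refit both estimators without each listed individual in turn.

    Reports the age OR with 95% CI for each exclusion and the percent change
    of the excess risk (OR - 1) relative to the all-data reference fits.
    """
    y = np.asarray(y, dtype=float)
    age_col = X.column_names.index(age_column)
    ref_std = fit_irls(X, y)
    ref_rob = fit_robust(X, y, config)
    or_std_ref, _ = _age_or(ref_std, age_col)
    or_rob_ref, _ = _age_or(ref_rob, age_col)
    rows: list[ExclusionImpactRow] = []
    for eid in exclude_ids:
        i = ids.index(eid)
        mask = np.ones(X.n, dtype=bool)
        mask[i] = False
        Xi = DesignMatrix(X.values[mask], list(X.column_names))
        try:
            f_std = fit_irls(Xi, y[mask])
            f_rob = fit_robust(Xi, y[mask], config)
            if not (f_std.converged and f_rob.converged):
                raise RuntimeError("refit did not converge")
            or_s, ci_s = _age_or(f_std, age_col)
            or_r, ci_r = _age_or(f_rob, age_col)
            rows.append(
                ExclusionImpactRow(
                    excluded_id=eid,
                    outcome_status=int(y[i]),
                    age=float(X.values[i, age_col]),
                    or_standard=or_s,
                    ci_standard=ci_s,
                    pct_change_standard=excess_risk_change(or_s, or_std_ref),
                    or_robust=or_r,
                    ci_robust=ci_r,
                    pct_change_robust=excess_risk_change(or_r, or_rob_ref),
                )
            )
        except Exception:
            rows.append(
                ExclusionImpactRow(
                    excluded_id=eid,
                    outcome_status=int(y[i]),
                    age=float(X.values[i, age_col]),
                    or_standard=np.nan,
                    ci_standard=(np.nan, np.nan),
                    pct_change_standard=np.nan,
                    or_robust=np.nan,
                    ci_robust=(np.nan, np.nan),
                    pct_change_robust=np.nan,
                    defined=False,
                )
            )
    return rows


def impact_frame(rows: list[ExclusionImpactRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "excluded_id": [r.excluded_id for r in rows],
            "status": [r.outcome_status for r in rows],
            "age": [r.age for r in rows],
            "or_standard": [r.or_standard for r in rows],
            "ci_low_standard": [r.ci_standard[0] for r in rows],
            "ci_high_standard": [r.ci_standard[1] for r in rows],
            "pct_change_standard": [r.pct_change_standard for r in rows],
            "or_robust": [r.or_robust for r in rows],
            "ci_low_robust": [r.ci_robust[0] for r in rows],
            "ci_high_robust": [r.ci_robust[1] for r in rows],
            "pct_change_robust": [r.pct_change_robust for r in rows],
        }
    )
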