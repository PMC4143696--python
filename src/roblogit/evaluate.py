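"""Cross-validated clinical performance metrics for risk prediction models.

Leave-one-out cross-validation (LOOCV) produces, for each individual, the
predicted disease probability from a model fitted without that individual.
From these out-of-sample probabilities the module derives, on a grid of
probability cutoffs c = 0.0, 0.1, ..., 1.0:

* concordance — the count (and percentage) of correctly classified statuses,
* sensitivity and specificity,
* the clinical net benefit
      NB(c) = sens * (cases/n) - (1 - spec) * (controls/n) * c/(1 - c),
  undefined at c = 1 (reported as NaN),

plus the overall trapezoidal AUC and the integrated discrimination
improvement (IDI) between the robust and standard models, i.e. the
difference of their discrimination slopes (mean predicted risk in cases
minus controls).

Classification is "case iff probability >= c"; the c = 1.0 row follows the
classify-none-positive convention (sensitivity 0, specificity 1), the
special case a fitted probability strictly inside (0,1) produces anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import DesignMatrix, fit_irls, inverse_logit
from .robust import RobustConfig, fit_robust

__all__ = [
    "CutoffMetrics",
    "CVResult",
    "AgeOddsTable",
    "loocv_probabilities",
    "metrics_at_cutoff",
    "net_benefit",
    "auc_trapezoid",
    "idi",
    "odds_by_age_quartile",
    "cross_validate",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))


@dataclass
class CutoffMetrics:
    """Confusion-matrix metrics of a probability rule at one cutoff."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def concordance_n(self) -> int:
        return self.tp + self.tn

    @property
    def concordance_pct(self) -> float:
        return 100.0 * self.concordance_n / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def net_benefit(self) -> float:
        return net_benefit(
            self.sensitivity, self.specificity, self.tp + self.fn, self.tn + self.fp, self.cutoff
        )


@dataclass
class AgeOddsTable:
    """Cases:controls counts and odds per empirical age quartile."""

    boundaries: tuple[float, float, float]
    cases: list[int]
    controls: list[int]

    @property
    def odds(self) -> list[float]:
        return [
            (c / k) if k > 0 else float("inf") for c, k in zip(self.cases, self.controls)
        ]

    def labels(self) -> list[str]:
        q1, q2, q3 = self.boundaries
        return [f"<{q1:g}", f"[{q1:g}, {q2:g})", f"[{q2:g}, {q3:g})", f">={q3:g}"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval": self.labels(),
                "cases": self.cases,
                "controls": self.controls,
                "odds": self.odds,
            }
        )


@dataclass
class CVResult:
    """LOOCV probabilities and derived metrics for both estimators."""

    probs_standard: np.ndarray
    probs_robust: np.ndarray
    y: np.ndarray
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    metrics_standard: list[CutoffMetrics] = field(default_factory=list)
    metrics_robust: list[CutoffMetrics] = field(default_factory=list)
    auc_standard: float = float("nan")
    auc_robust: float = float("nan")
    idi: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        """Cutoff-by-cutoff report shaped like a standard CV summary table."""
        rows = []
        for ms, mr in zip(self.metrics_standard, self.metrics_robust):
            rows.append(
                {
                    "cutoff": ms.cutoff,
                    "std_concordance_n": ms.concordance_n,
                    "std_concordance_pct": ms.concordance_pct,
                    "std_sensitivity": ms.sensitivity,
                    "std_specificity": ms.specificity,
                    "std_net_benefit": ms.net_benefit,
                    "rob_concordance_n": mr.concordance_n,
                    "rob_concordance_pct": mr.concordance_pct,
                    "rob_sensitivity": mr.sensitivity,
                    "rob_specificity": mr.specificity,
                    "rob_net_benefit": mr.net_benefit,
                }
            )
        return pd.DataFrame(rows)


def loocv_probabilities(
    X: DesignMatrix,
    y: np.ndarray,
    estimator: str = "standard",
    config: RobustConfig | None = None,
) -> np.ndarray:
    """Out-of-sample probability for each individual from n leave-one-out refits.

    The model formula is fixed: variant selection is NOT redone per fold.
    A fold whose refit fails yields NaN for that individual.
    """
    y = np.asarray(y, dtype=float)
    n = X.n
    if n < X.p + 2:
        raise ValueError("need n >= p + 2 for leave-one-out refits")
    probs = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xi = DesignMatrix(X.values[mask], list(X.column_names))
        try:
            if estimator == "standard":
                fit = fit_irls(Xi, y[mask])
            elif estimator == "robust":
                fit = fit_robust(Xi, y[mask], config)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            if not fit.converged:
                raise RuntimeError("fold refit did not converge")
            probs[i] = inverse_logit(X.values[i] @ fit.beta)
        except (ValueError, RuntimeError):
            pass
        mask[i] = True
    return probs


def metrics_at_cutoff(probs: np.ndarray, y: np.ndarray, c: float) -> CutoffMetrics:
    """Classify positive iff prob >= c; at c = 1.0 classify none positive."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if c >= 1.0:
        positive = np.zeros(probs.size, dtype=bool)
    else:
        positive = probs >= c
    cases = y == 1
    return CutoffMetrics(
        cutoff=c,
        tp=int(np.sum(positive & cases)),
        fp=int(np.sum(positive & ~cases)),
        tn=int(np.sum(~positive & ~cases)),
        fn=int(np.sum(~positive & cases)),
    )


def net_benefit(
    sensitivity: float,
    specificity: float,
    n_cases: int,
    n_controls: int,
    c: float,
) -> float:
    """Clinical net benefit at threshold probability c.

    NB(c) = sens * prevalence - (1 - spec) * (1 - prevalence) * c/(1-c).
    Undefined at c = 1 (returns NaN, the table's "-" marker).
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    if c == 1.0:
        return float("nan")
    n = n_cases + n_controls
    return (
        sensitivity * n_cases / n
        - (1.0 - specificity) * (n_controls / n) * c / (1.0 - c)
    )


def auc_trapezoid(probs: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equals the Mann-Whitney probability P(p_case > p_control) with ties
    counted 1/2.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    n_cases = int(np.sum(y == 1))
    n_controls = int(np.sum(y == 0))
    if n_cases == 0 or n_controls == 0:
        raise ValueError("AUC undefined with a single-class outcome")
    # ROC points at every distinct threshold, descending
    order = np.argsort(-probs, kind="mergesort")
    sorted_p = probs[order]
    sorted_y = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(sorted_p)), sorted_p.size - 1]
    tp = np.cumsum(sorted_y)[distinct]
    fp = np.cumsum(1 - sorted_y)[distinct]
    tpr = np.r_[0.0, tp / n_cases]
    fpr = np.r_[0.0, fp / n_controls]
    return float(np.trapezoid(tpr, fpr))


def idi(probs_robust: np.ndarray, probs_standard: np.ndarray, y: np.ndarray) -> float:
    """Integrated discrimination improvement, robust minus standard.

    The difference of discrimination slopes: (mean risk in cases - mean risk
    in controls) under the robust model minus the same under the standard
    model.  Positive means the robust model separates cases from controls
    better.
    """
    y = np.asarray(y, dtype=float)
    pr = np.asarray(probs_robust, dtype=float)
    ps = np.asarray(probs_standard, dtype=float)
    cases = y == 1
    if not cases.any() or cases.all():
        raise ValueError("IDI undefined with a single-class outcome")
    slope_rob = pr[cases].mean() - pr[~cases].mean()
    slope_std = ps[cases].mean() - ps[~cases].mean()
    return float(slope_rob - slope_std)


def odds_by_age_quartile(ages: np.ndarray, y: np.ndarray) -> AgeOddsTable:
    """Cases:controls odds within the four empirical age quartile intervals.

    Cutpoints are the 25/50/75% empirical quantiles (linear interpolation);
    intervals are (-inf, Q1), [Q1, Q2), [Q2, Q3), [Q3, inf).
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(y, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 individuals for quartile intervals")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("need both cases and controls")
    q1, q2, q3 = np.quantile(ages, [0.25, 0.5, 0.75])
    edges = [-np.inf, q1, q2, q3, np.inf]
    cases, controls = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        inside = (ages >= lo) & (ages < hi)
        cases.append(int(np.sum(inside & (y == 1))))
        controls.append(int(np.sum(inside & (y == 0))))
    return AgeOddsTable(
        boundaries=(float(q1), float(q2), float(q3)), cases=cases, controls=controls
    )


def cross_validate(
    X: DesignMatrix,
    y: np.ndarray,
    config: RobustConfig | None = None,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> CVResult:
    """LOOCV both estimators on a fixed model formula; derive all metrics."""
    y = np.asarray(y, dtype=float)
    ps = loocv_probabilities(X, y, "standard")
    pr = loocv_probabilities(X, y, "robust", config)
    result = CVResult(probs_standard=ps, probs_robust=pr, y=y, cutoffs=cutoffs)
    ok = ~(np.isnan(ps) | np.isnan(pr))
    result.metrics_standard = [metrics_at_cutoff(ps[ok], y[ok], c) for c in cutoffs]
    result.metrics_robust = [metrics_at_cutoff(pr[ok], y[ok], c) for c in cutoffs]
    result.auc_standard = auc_trapezoid(ps[ok], y[ok])
    result.auc_robust = auc_trapezoid(pr[ok], y[ok])
    result.idi = idi(pr[ok], ps[ok], y[ok])
    return result
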