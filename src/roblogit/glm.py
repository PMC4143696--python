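"""Standard logistic regression by iteratively reweighted least squares.

This module carries the "standard" arm of the standard-vs-robust comparison:
maximum-likelihood logistic regression fitted by IRLS with step-halving,
the residual deviance, likelihood-ratio (deviance) tests for nested models,
Wald odds-ratio confidence intervals, and the Pearson chi-square screen used
to decide which covariates enter the baseline model.

No penalisation is applied anywhere; (quasi-)complete separation is detected
by coefficient divergence and reported through the ``converged`` flag rather
than silently regularised away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DesignMatrix",
    "StandardFit",
    "EstimationError",
    "UsageError",
    "fit_irls",
    "deviance_test",
    "wald_or_ci",
    "chi2_screen",
    "predict_prob",
    "inverse_logit",
    "bernoulli_deviance",
]

#: Linear predictors are clipped at +/- this value before the inverse logit.
#: Purely a numerical overflow guard (sigmoid(30) is 1 - 9.4e-14), not a
#: statistical choice.
ETA_CLIP = 30.0

#: A coefficient exceeding this magnitude during iteration is taken as
#: evidence of (quasi-)complete separation.
SEPARATION_BOUND = 30.0


class EstimationError(ValueError):
    """Raised for rank deficiency and other unrecoverable fitting problems."""


class UsageError(ValueError):
    """Raised when operations are combined inconsistently (e.g. non-nested)."""


@dataclass
class DesignMatrix:
    """An n x p design with an all-ones first column (the intercept).

    Construction checks full column rank and n > p; both are prerequisites
    for every estimator in the package.
    """

    values: np.ndarray
    column_names: list[str]
    #: fit-time invariants (full rank, n > p); disable for prediction-only rows
    check: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise EstimationError("design matrix must be 2-dimensional")
        n, p = self.values.shape
        if len(self.column_names) != p:
            raise EstimationError("column_names length does not match p")
        if not np.allclose(self.values[:, 0], 1.0):
            raise EstimationError("first column must be the all-ones intercept")
        if not self.check:
            return
        if n <= p:
            raise EstimationError(f"need n > p, got n={n}, p={p}")
        if np.linalg.matrix_rank(self.values) < p:
            raise EstimationError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def with_column(self, values: np.ndarray, name: str) -> "DesignMatrix":
        """Return a new design with one extra column appended."""
        col = np.asarray(values, dtype=float).reshape(-1, 1)
        return DesignMatrix(
            np.hstack([self.values, col]), [*self.column_names, name]
        )


@dataclass
class StandardFit:
    """A fitted maximum-likelihood logistic regression."""

    beta: np.ndarray
    fitted_mu: np.ndarray
    deviance: float
    vcov: np.ndarray
    converged: bool
    n_iter: int
    X: DesignMatrix = field(repr=False)
    y: np.ndarray = field(repr=False)

    @property
    def p(self) -> int:
        return self.beta.size

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


def inverse_logit(eta: np.ndarray) -> np.ndarray:
    """Logistic function with the +/-ETA_CLIP overflow guard."""
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -ETA_CLIP, ETA_CLIP)))


def bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """-2 log-likelihood of a Bernoulli fit (the residual deviance)."""
    mu = np.clip(mu, 1e-15, 1 - 1e-15)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _check_binary(y: np.ndarray, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise UsageError(f"y must have shape ({n},), got {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise UsageError("y must be binary 0/1")
    return y


def fit_irls(
    X: DesignMatrix,
    y: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> StandardFit:
    """Fit logistic regression by IRLS with step-halving.

    Convergence means the score equations X'(y - mu) = 0 hold to within
    ``tol`` in the max norm.  Separation (any |beta_k| exceeding
    SEPARATION_BOUND) is reported as ``converged=False``.
    """
    y = _check_binary(y, X.n)
    Xv = X.values
    beta = np.zeros(X.p)
    mu = inverse_logit(Xv @ beta)
    dev = bernoulli_deviance(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = mu * (1 - mu)
        # guard against zero weights at saturated observations
        W = np.maximum(W, 1e-10)
        z = Xv @ beta + (y - mu) / W
        XtW = Xv.T * W
        try:
            step_target = np.linalg.solve(XtW @ Xv, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"weighted normal equations singular: {exc}") from exc
        # step-halving keeps the deviance non-increasing
        direction = step_target - beta
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * direction
            cand_dev = bernoulli_deviance(y, inverse_logit(Xv @ cand))
            if cand_dev <= dev + 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * direction
        mu = inverse_logit(Xv @ beta)
        dev = bernoulli_deviance(y, mu)
        score = Xv.T @ (y - mu)
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            converged = False
            break
        if np.max(np.abs(score)) <= tol:
            converged = True
            break
    W = np.maximum(mu * (1 - mu), 1e-10)
    fisher = (Xv.T * W) @ Xv
    try:
        vcov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"Fisher information singular: {exc}") from exc
    return StandardFit(
        beta=beta,
        fitted_mu=mu,
        deviance=dev,
        vcov=vcov,
        converged=converged,
        n_iter=it,
        X=X,
        y=y,
    )


def deviance_test(
    fit_full: StandardFit, fit_reduced: StandardFit
) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested maximum-likelihood fits.

    Returns (deviance difference, df, chi-square p-value).
    """
    if not set(fit_reduced.X.column_names) <= set(fit_full.X.column_names):
        raise UsageError(
            "reduced model columns must be a subset of the full model columns"
        )
    if fit_full.y.shape != fit_reduced.y.shape or not np.array_equal(
        fit_full.y, fit_reduced.y
    ):
        raise UsageError("nested fits must share the same response vector")
    df = fit_full.p - fit_reduced.p
    statistic = fit_reduced.deviance - fit_full.deviance
    if statistic < -1e-8:
        raise UsageError(
            f"reduced model fits better than full ({statistic:.3g}); models "
            "are not nested as claimed"
        )
    statistic = max(statistic, 0.0)
    p_value = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return statistic, df, p_value


def wald_or_ci(
    fit: StandardFit, level: float = 0.95
) -> list[tuple[str, float, float, float]]:
    """Per-coefficient odds ratios with Wald confidence intervals.

    Returns (name, OR, lower, upper) per column.  Refuses a non-converged fit
    because its standard errors are meaningless under separation.
    """
    if not fit.converged:
        raise EstimationError(
            "refusing Wald intervals from a non-converged fit (possible separation)"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for name, b, s in zip(fit.X.column_names, fit.beta, fit.se()):
        out.append(
            (name, float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s)))
        )
    return out


def chi2_screen(
    outcome: np.ndarray, covariate: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square independence test of outcome vs. a categorical covariate.

    Pairs with a missing covariate value (None/NaN) are excluded.  No
    continuity correction is applied.  Returns (statistic, df, p).
    """
    outcome = np.asarray(outcome)
    covariate = np.asarray(covariate, dtype=object)
    keep = np.array(
        [
            c is not None and not (isinstance(c, float) and np.isnan(c))
            for c in covariate
        ]
    )
    outcome, covariate = outcome[keep], covariate[keep]
    o_levels = sorted(set(outcome.tolist()))
    c_levels = sorted(set(covariate.tolist()), key=str)
    if len(c_levels) < 2:
        raise UsageError("covariate must have at least 2 observed categories")
    if len(o_levels) < 2:
        raise UsageError("outcome must have at least 2 observed categories")
    table = np.zeros((len(o_levels), len(c_levels)))
    for o, c in zip(outcome, covariate):
        table[o_levels.index(o), c_levels.index(c)] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UsageError("contingency table has an empty margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def predict_prob(fit: StandardFit, X_new: DesignMatrix) -> np.ndarray:
    """Predicted probabilities for new rows under a fitted model."""
    if X_new.column_names != fit.X.column_names:
        raise UsageError(
            f"column mismatch: fit has {fit.X.column_names}, "
            f"new design has {X_new.column_names}"
        )
    return inverse_logit(X_new.values @ fit.beta)
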