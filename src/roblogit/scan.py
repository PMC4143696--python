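"""Single-variant association scan on top of the baseline covariate model.

Each variant's additive dosage column is appended to the baseline design and
the augmented model is compared to the baseline: by the classical deviance
drop (standard logistic regression) or by the robust quasi-deviance
Lambda_QM (robust logistic regression).  Ranking by the largest statistic is
identical to ranking by the smallest fitted-model (quasi-)deviance, since all
variants share the same baseline.  Both statistics are referred to
chi-square(1); for Lambda_QM this is a working approximation (the exact
asymptotic null is a weighted chi-square).

Linkage disequilibrium is deliberately ignored during selection; pairwise
genotypic r^2 is provided for post-hoc inspection of selected variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import DesignMatrix, deviance_test, fit_irls
from .ingest import MISSING, GenotypeMatrix
from .robust import RobustConfig, fit_robust, quasi_deviance_test

__all__ = ["ScanResult", "scan_variants", "qq_points", "pairwise_r2"]


@dataclass
class ScanResult:
    """Ranked per-variant association statistics against a common baseline."""

    table: pd.DataFrame  # variant_id, chrom, pos, statistic, p, rank, converged
    estimator: str
    baseline_terms: list[str]

    @property
    def p_values(self) -> np.ndarray:
        return self.table.loc[self.table["converged"], "p"].to_numpy()

    def top(self, k: int = 1) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank")


def scan_variants(
    base_X: DesignMatrix,
    y: np.ndarray,
    G: GenotypeMatrix,
    estimator: str = "standard",
    config: RobustConfig | None = None,
) -> ScanResult:
    """Fit baseline + one variant at a time; rank by the association statistic.

    Rank 1 is the largest statistic (equivalently, the smallest augmented
    model (quasi-)deviance).  Variants whose augmented fit fails (collinear
    dosage, non-convergence) get a missing statistic and are ranked last.
    Ties break by chromosome position, then variant id.
    """
    y = np.asarray(y, dtype=float)
    if G.missing_mask().any():
        raise ValueError("scan requires a complete (filtered) genotype matrix")
    if estimator == "standard":
        base_fit = fit_irls(base_X, y)
    elif estimator == "robust":
        config = config or RobustConfig()
        base_fit = fit_robust(base_X, y, config)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not base_fit.converged:
        raise RuntimeError("baseline model did not converge; scan aborted")

    stat = np.full(G.n_variants, np.nan)
    pval = np.full(G.n_variants, np.nan)
    ok = np.zeros(G.n_variants, dtype=bool)
    for j in range(G.n_variants):
        dosage = G.dosages[:, j].astype(float)
        try:
            Xj = base_X.with_column(dosage, f"snp:{G.variants[j].variant_id}")
            if estimator == "standard":
                fit_j = fit_irls(Xj, y)
                if not fit_j.converged:
                    raise RuntimeError("augmented fit did not converge")
                # baseline refit is shared; deviance_test needs nested columns
                s, _, p = deviance_test(fit_j, base_fit)
            else:
                fit_j = fit_robust(Xj, y, config)
                if not fit_j.converged:
                    raise RuntimeError("augmented fit did not converge")
                res = quasi_deviance_test(fit_j, base_fit, config)
                s, p = max(res.lambda_qm, 0.0), res.p_value
        except Exception:
            continue
        stat[j], pval[j], ok[j] = s, p, True

    order_key = pd.DataFrame(
        {
            "neg_stat": [-s if np.isfinite(s) else np.inf for s in stat],
            "pos": [v.position for v in G.variants],
            "vid": [v.variant_id for v in G.variants],
        }
    )
    order = order_key.sort_values(["neg_stat", "pos", "vid"], kind="mergesort").index
    rank = np.empty(G.n_variants, dtype=int)
    rank[order] = np.arange(1, G.n_variants + 1)
    table = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in G.variants],
            "chrom": [v.chromosome for v in G.variants],
            "pos": [v.position for v in G.variants],
            "statistic": stat,
            "p": pval,
            "rank": rank,
            "converged": ok,
        }
    )
    return ScanResult(table=table, estimator=estimator, baseline_terms=list(base_X.column_names))


def qq_points(scan: ScanResult) -> np.ndarray:
    """(expected, observed) -log10 p-value quantile pairs for a QQ plot.

    Expected quantiles are -log10((i - 0.5)/m) for the i-th smallest of m
    valid p-values.
    """
    p = np.sort(scan.p_values)  # ascending: p_(1) is the most significant
    m = p.size
    if m == 0:
        raise ValueError("no valid p-values to plot")
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p, 1e-300, None))
    return np.column_stack([expected, observed])


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite r^2)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.any(g1 == MISSING) or np.any(g2 == MISSING):
        raise ValueError("dosage vectors must be complete (no missing calls)")
    if np.std(g1) == 0 or np.std(g2) == 0:
        raise ValueError("r^2 undefined for a monomorphic dosage vector")
    r = np.corrcoef(g1, g2)[0, 1]
    return float(r * r)
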