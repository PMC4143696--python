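"""End-to-end orchestration: ingest, screen, fit, diagnose, scan, evaluate.

The analysis sequence mirrors how such a comparison is run in practice:

1. filter raw phenotypes/genotypes to an analysis-ready dataset;
2. chi-square screen of categorical covariates (gender, smoking) — only
   covariates significant at the 5% level join age in the baseline model;
3. baseline (age) model under both estimators;
4. Cook's-distance outlier diagnostics on the baseline model and
   exclusion-impact tables for the flagged individuals;
5. genome scan under both estimators (deviance / quasi-deviance drop);
6. leave-one-out cross-validation of the age + top-SNP model per estimator,
   with concordance, sensitivity, specificity, net benefit, AUC and IDI.

Every stage's output is a plain table; ``run_analysis`` returns them in a
:class:`ReportBundle` and (optionally) writes them as TSVs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .evaluate import DEFAULT_CUTOFFS, CVResult, odds_by_age_quartile
from .glm import DesignMatrix, StandardFit, chi2_screen, fit_irls, wald_or_ci
from .influence import CookReport, cooks_distance, exclusion_impact, impact_frame
from .ingest import (
    FilteredDataset,
    GenotypeMatrix,
    PhenotypeRecord,
    apply_filters,
    read_genotypes,
    read_phenotypes,
)
from .robust import RobustConfig, RobustFit, fit_robust, robust_or_ci
from .scan import ScanResult, qq_points, scan_variants

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "build_baseline_design"]

SCREEN_ALPHA = 0.05  # strict "<" inclusion threshold for screened covariates


@dataclass(frozen=True)
class AnalysisConfig:
    """All switches of one analysis run (hashable into run metadata)."""

    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    huber_c: float = 1.345
    use_leverage_weights: bool = True
    cook_threshold: float = 0.05
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    estimators: tuple[str, ...] = ("standard", "robust")
    mse_denominator: str = "n"
    q_convention: str = "coefficients"
    seed: int = 0
    out_dir: str | None = None

    def robust_config(self) -> RobustConfig:
        return RobustConfig(c=self.huber_c, use_leverage_weights=self.use_leverage_weights)

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    """Every table the pipeline produces, plus run metadata."""

    dataset: FilteredDataset
    screen: pd.DataFrame
    baseline_terms: list[str]
    fit_standard: StandardFit | None
    fit_robust: RobustFit | None
    cook: CookReport | None
    impact: pd.DataFrame | None
    scans: dict[str, ScanResult]
    selected: dict[str, str]
    cv: CVResult | None
    age_odds: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | os.PathLike) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dataset.write_filter_log(out / "filter_log.tsv")
        self.screen.to_csv(out / "covariate_screen.tsv", sep="\t", index=False)
        fits = []
        for est, fit, orci in (
            ("standard", self.fit_standard, wald_or_ci),
            ("robust", self.fit_robust, robust_or_ci),
        ):
            if fit is None:
                continue
            for name, orr, lo, hi in orci(fit):
                fits.append(
                    {
                        "estimator": est,
                        "term": name,
                        "beta": float(np.log(orr)),
                        "OR": orr,
                        "CI_low": lo,
                        "CI_high": hi,
                    }
                )
        pd.DataFrame(fits).to_csv(out / "baseline_fits.tsv", sep="\t", index=False)
        if self.cook is not None:
            self.cook.to_frame().to_csv(out / "cook_distances.tsv", sep="\t", index=False)
        if self.impact is not None:
            self.impact.to_csv(out / "exclusion_impact.tsv", sep="\t", index=False)
        for est, scan in self.scans.items():
            scan.table.to_csv(out / f"scan_{est}.tsv", sep="\t", index=False)
            qq = qq_points(scan)
            pd.DataFrame(qq, columns=["expected", "observed"]).to_csv(
                out / f"qq_{est}.tsv", sep="\t", index=False
            )
        if self.cv is not None:
            self.cv.to_frame().to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
            pd.DataFrame(
                {
                    "auc_standard": [self.cv.auc_standard],
                    "auc_robust": [self.cv.auc_robust],
                    "idi": [self.cv.idi],
                }
            ).to_csv(out / "cv_summary.tsv", sep="\t", index=False)
        self.age_odds.to_csv(out / "age_odds.tsv", sep="\t", index=False)
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2)


def build_baseline_design(
    dataset: FilteredDataset, extra_terms: Sequence[str] = ()
) -> DesignMatrix:
    """Intercept + age design (age is pre-committed, never screened)."""
    cols = [np.ones(len(dataset.phenotypes)), dataset.age]
    names = ["intercept", "age"]
    for term in extra_terms:
        values = [getattr(r, term) for r in dataset.phenotypes]
        levels = sorted({v for v in values if v is not None}, key=str)
        if len(levels) != 2:
            raise ValueError(f"screened covariate {term!r} must be binary")
        cols.append(np.array([1.0 if v == levels[1] else 0.0 for v in values]))
        names.append(term)
    return DesignMatrix(np.column_stack(cols), names)


def _screen_covariates(dataset: FilteredDataset) -> tuple[pd.DataFrame, list[str]]:
    y = dataset.y.astype(int)
    rows, included = [], []
    for term in ("gender", "smoking"):
        values = np.array(
            [getattr(r, term) for r in dataset.phenotypes], dtype=object
        )
        try:
            statistic, df, p = chi2_screen(y, values)
        except Exception as exc:
            rows.append(
                {"covariate": term, "statistic": np.nan, "df": 0, "p": np.nan,
                 "included": False, "note": str(exc)}
            )
            continue
        keep = p < SCREEN_ALPHA
        rows.append(
            {"covariate": term, "statistic": statistic, "df": df, "p": p,
             "included": keep, "note": ""}
        )
        if keep:
            included.append(term)
    return pd.DataFrame(rows), included


def run_analysis(
    config: AnalysisConfig,
    phenotypes: Sequence[PhenotypeRecord] | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> ReportBundle:
    """Run the full comparison; inputs from files (config paths) or in memory."""
    if phenotypes is None:
        if config.phenotype_path is None:
            raise ValueError("no phenotypes given (in memory or via config path)")
        phenotypes = read_phenotypes(config.phenotype_path)
    if genotypes is None:
        if config.genotype_path is None:
            raise ValueError("no genotypes given (in memory or via config path)")
        genotypes = read_genotypes(config.genotype_path, config.genotype_format)

    dataset = apply_filters(phenotypes, genotypes)
    screen, extra_terms = _screen_covariates(dataset)
    base_X = build_baseline_design(dataset, extra_terms)
    y = dataset.y
    rc = config.robust_config()

    fit_std = fit_irls(base_X, y) if "standard" in config.estimators else None
    fit_rob = fit_robust(base_X, y, rc) if "robust" in config.estimators else None

    ids = dataset.genotypes.individual_ids
    cook = impact = None
    if fit_std is not None:
        cook = cooks_distance(
            base_X,
            y,
            ids=ids,
            estimator="standard",
            threshold=config.cook_threshold,
            mse_denominator=config.mse_denominator,
            q_convention=config.q_convention,
        )
        flagged = cook.flagged_ids()
        if flagged and "robust" in config.estimators:
            impact = impact_frame(
                exclusion_impact(base_X, y, ids, flagged, config=rc)
            )

    scans: dict[str, ScanResult] = {}
    selected: dict[str, str] = {}
    for est in config.estimators:
        scan = scan_variants(base_X, y, dataset.genotypes, est, rc)
        scans[est] = scan
        selected[est] = str(scan.top(1)["variant_id"].iloc[0])

    cv = None
    if set(config.estimators) == {"standard", "robust"}:
        # each estimator's model carries its own selected SNP, fixed across folds
        vids = [v.variant_id for v in dataset.genotypes.variants]
        cv_std_X = base_X.with_column(
            dataset.genotypes.dosages[:, vids.index(selected["standard"])].astype(float),
            f"snp:{selected['standard']}",
        )
        cv_rob_X = base_X.with_column(
            dataset.genotypes.dosages[:, vids.index(selected["robust"])].astype(float),
            f"snp:{selected['robust']}",
        )
        from .evaluate import auc_trapezoid, idi, loocv_probabilities, metrics_at_cutoff

        ps = loocv_probabilities(cv_std_X, y, "standard")
        pr = loocv_probabilities(cv_rob_X, y, "robust", rc)
        ok = ~(np.isnan(ps) | np.isnan(pr))
        cv = CVResult(
            probs_standard=ps, probs_robust=pr, y=y, cutoffs=config.cutoffs
        )
        cv.metrics_standard = [metrics_at_cutoff(ps[ok], y[ok], c) for c in config.cutoffs]
        cv.metrics_robust = [metrics_at_cutoff(pr[ok], y[ok], c) for c in config.cutoffs]
        cv.auc_standard = auc_trapezoid(ps[ok], y[ok])
        cv.auc_robust = auc_trapezoid(pr[ok], y[ok])
        cv.idi = idi(pr[ok], ps[ok], y[ok])

    age_odds = odds_by_age_quartile(dataset.age, y).to_frame()
    metadata = {
        "config_hash": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
        "n_individuals": len(dataset.phenotypes),
        "n_variants": dataset.genotypes.n_variants,
        "baseline_terms": base_X.column_names,
        "selected_variants": selected,
    }
    bundle = ReportBundle(
        dataset=dataset,
        screen=screen,
        baseline_terms=base_X.column_names,
        fit_standard=fit_std,
        fit_robust=fit_rob,
        cook=cook,
        impact=impact,
        scans=scans,
        selected=selected,
        cv=cv,
        age_odds=age_odds,
        metadata=metadata,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
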