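"""Synthetic hypertension-cohort generator.

Emulates the kind of sample the pipeline targets — a modest cohort
(~130 unrelated individuals) genotyped at a few hundred biallelic SNPs —
with fully known ground truth:

* genotypes drawn under Hardy-Weinberg equilibrium with MAFs uniform on a
  configurable range, no linkage disequilibrium between variants;
* ages from a truncated normal (mean 52, sd 15, range [20, 95]), matching a
  middle-aged cohort with a median age near 52;
* disease status from a logistic model in age plus a small set of causal
  SNPs; the intercept is calibrated numerically (not per draw) so that the
  expected prevalence hits a target of 33% with an age odds ratio of 1.085
  per year;
* gender and smoking simulated independent of outcome, so a chi-square
  screen correctly excludes them from the baseline model;
* planted outliers: the oldest individuals are forced normotensive and the
  youngest forced hypertensive — the label-flip-at-age-extremes phenotype
  that influence diagnostics should recover;
* missingness injected both as background per-call dropout (exercising the
  variant-completeness filter) and as a few high-missingness individuals
  constructed to exceed the 5% exclusion threshold;
* optional longitudinal copies (up to 4 measurements per individual, ages
  advancing one year per visit, first visit occasionally incomplete) to
  exercise first-available-measurement reduction.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats

from .ingest import (
    MISSING,
    GenotypeMatrix,
    PhenotypeRecord,
    VariantRecord,
)

__all__ = [
    "SimulationSpec",
    "TruthLog",
    "simulate_genotypes",
    "simulate_phenotypes",
    "plant_outliers",
    "inject_missingness",
    "generate_cohort",
    "calibrate_intercept",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Full parameterization of a synthetic cohort.

    ``age_or`` is the per-year odds ratio of disease (1.085 default);
    ``causal_variants`` maps variant indices to log odds ratios per allele
    copy, each drawn at ``causal_maf``.  The intercept is derived from
    ``prevalence_target`` unless ``intercept`` is given explicitly.
    """

    n_individuals: int = 130
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    age_mean: float = 52.0
    age_sd: float = 15.0
    age_min: float = 20.0
    age_max: float = 95.0
    age_or: float = 1.085
    prevalence_target: float = 0.33
    intercept: float | None = None
    causal_variants: tuple[tuple[int, float], ...] = ((0, 0.8),)
    causal_maf: float = 0.3
    n_outliers: int = 4
    outlier_mechanism: str = "label_flip_extreme_age"
    missing_individual_rate: float = 0.02
    missing_variant_rate: float = 0.001
    longitudinal_copies: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for rate in (self.missing_individual_rate, self.missing_variant_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missingness rates must lie in [0, 1]")
        for idx, _ in self.causal_variants:
            if not 0 <= idx < self.n_variants:
                raise ValueError(f"causal variant index {idx} out of range")
        if not 1 <= self.longitudinal_copies <= 4:
            raise ValueError("longitudinal_copies must be in 1..4")
        if self.n_outliers > self.n_individuals:
            raise ValueError("cannot plant more outliers than individuals")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")

    @property
    def beta_age(self) -> float:
        return math.log(self.age_or)

    def resolved_intercept(self) -> float:
        if self.intercept is not None:
            return self.intercept
        return calibrate_intercept(
            self.prevalence_target,
            self.beta_age,
            self.age_mean,
            self.age_sd,
            self.age_min,
            self.age_max,
            tuple(lor for _, lor in self.causal_variants),
            self.causal_maf,
        )


@dataclass
class TruthLog:
    """Ground truth of a generated cohort: the recovery-test surface."""

    causal_variants: list[tuple[str, float]]
    planted_outliers: list[tuple[str, int, int]]  # (id, pre_label, post_label)
    beta_intercept: float
    beta_age: float


def _age_distribution(spec: SimulationSpec) -> stats.rv_continuous:
    a = (spec.age_min - spec.age_mean) / spec.age_sd
    b = (spec.age_max - spec.age_mean) / spec.age_sd
    return stats.truncnorm(a, b, loc=spec.age_mean, scale=spec.age_sd)


@lru_cache(maxsize=64)
def calibrate_intercept(
    prevalence: float,
    beta_age: float,
    age_mean: float,
    age_sd: float,
    age_min: float,
    age_max: float,
    causal_lors: tuple[float, ...],
    causal_maf: float,
) -> float:
    """Intercept such that the model's expected prevalence equals the target.

    The expectation integrates the inverse-logit risk over the truncated
    normal age distribution and enumerates Hardy-Weinberg genotype
    probabilities of the causal variants.  Deterministic (quadrature, no
    Monte Carlo), so the same parameters always yield the same intercept.
    """
    a = (age_min - age_mean) / age_sd
    b = (age_max - age_mean) / age_sd
    age_rv = stats.truncnorm(a, b, loc=age_mean, scale=age_sd)
    f = causal_maf
    hwe = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])

    combos: list[tuple[float, float]] = [(0.0, 1.0)]  # (genetic score, probability)
    for lor in causal_lors:
        combos = [
            (score + lor * g, prob * hwe[g])
            for score, prob in combos
            for g in (0, 1, 2)
        ]

    def expected_prevalence(beta0: float) -> float:
        total = 0.0
        for score, prob in combos:
            val, _ = integrate.quad(
                lambda age: age_rv.pdf(age)
                / (1.0 + np.exp(-(beta0 + beta_age * age + score))),
                age_min,
                age_max,
                limit=200,
            )
            total += prob * val
        return total

    return float(
        optimize.brentq(lambda b0: expected_prevalence(b0) - prevalence, -30.0, 30.0)
    )


def simulate_genotypes(spec: SimulationSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """HWE genotypes; causal columns use ``causal_maf``, others a uniform MAF.

    Columns that come out monomorphic are redrawn (guaranteeing polymorphic
    output for any reasonable n), so the filter pipeline never removes a
    causal variant for monomorphism.
    """
    rng = rng or np.random.default_rng(spec.seed)
    causal_idx = {idx for idx, _ in spec.causal_variants}
    n, m = spec.n_individuals, spec.n_variants
    dosages = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        for _ in range(1000):
            f = (
                spec.causal_maf
                if j in causal_idx
                else rng.uniform(*spec.maf_range)
            )
            probs = [(1 - f) ** 2, 2 * f * (1 - f), f**2]
            col = rng.choice(3, size=n, p=probs).astype(np.int8)
            counts = np.bincount(col, minlength=3)
            if counts.sum() - counts.max() >= 2:  # survives the polymorphism filter
                break
        dosages[:, j] = col
    width = len(str(m))
    variants = [
        VariantRecord(
            variant_id=f"snp{j:0{width}d}",
            chromosome="3",
            position=1000 * (j + 1),
            ref_allele="A",
            alt_allele="G",
        )
        for j in range(m)
    ]
    ids = [f"ind{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, variants)


def simulate_phenotypes(
    G: GenotypeMatrix,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> list[PhenotypeRecord]:
    """Draw disease status from the logistic model; covariates are null.

    Gender and smoking are independent of the outcome by construction, so a
    correct chi-square screen excludes them.  Returns one record per
    individual per longitudinal copy (ages advance a year per visit; with
    more than one copy, a small fraction of first visits lack an age so the
    first *available* measurement is a later one).
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    n = G.n_individuals
    ages = _age_distribution(spec).rvs(size=n, random_state=rng)
    beta0 = spec.resolved_intercept()
    eta = beta0 + spec.beta_age * ages
    for idx, lor in spec.causal_variants:
        eta = eta + lor * G.dosages[:, idx].astype(float)
    prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    status = (rng.uniform(size=n) < prob).astype(int)
    gender = rng.choice(["F", "M"], size=n)
    smoking = rng.choice(["no", "yes"], size=n, p=[0.75, 0.25])

    records: list[PhenotypeRecord] = []
    for i in range(n):
        incomplete_first = (
            spec.longitudinal_copies > 1 and rng.uniform() < 0.1
        )
        for k in range(1, spec.longitudinal_copies + 1):
            records.append(
                PhenotypeRecord(
                    individual_id=G.individual_ids[i],
                    hypertension=int(status[i]),
                    age=None if (k == 1 and incomplete_first) else float(ages[i]) + (k - 1),
                    gender=str(gender[i]),
                    smoking=str(smoking[i]),
                    measurement_index=k,
                )
            )
    return records


def plant_outliers(
    records: list[PhenotypeRecord],
    spec: SimulationSpec,
) -> tuple[list[PhenotypeRecord], list[tuple[str, int, int]]]:
    """Force label flips at the age extremes, mimicking clinical outliers.

    Three quarters (rounded up) of the planted outliers are the oldest
    individuals set normotensive (elderly unaffected); the rest are the
    youngest individuals set hypertensive (early-onset cases).  Returns the
    modified records plus a provenance log of (id, pre, post) labels.
    """
    if spec.outlier_mechanism not in ("label_flip_extreme_age", "extreme_age_injection"):
        raise ValueError(f"unknown outlier mechanism {spec.outlier_mechanism!r}")
    if spec.n_outliers == 0:
        return list(records), []
    first_age: dict[str, float] = {}
    for r in records:
        if r.age is not None and r.individual_id not in first_age:
            first_age[r.individual_id] = r.age
    n_young = spec.n_outliers // 4
    n_old = spec.n_outliers - n_young
    if spec.outlier_mechanism == "extreme_age_injection":
        return _inject_extreme_age(records, first_age, n_old, n_young, spec)
    by_age = sorted(first_age, key=first_age.__getitem__)
    targets: dict[str, int] = {}
    for iid in by_age[-n_old:] if n_old else []:
        targets[iid] = 0
    for iid in by_age[:n_young] if n_young else []:
        targets[iid] = 1
    provenance: list[tuple[str, int, int]] = []
    out: list[PhenotypeRecord] = []
    logged: set[str] = set()
    for r in records:
        if r.individual_id in targets:
            post = targets[r.individual_id]
            if r.individual_id not in logged:
                provenance.append((r.individual_id, int(r.hypertension), post))
                logged.add(r.individual_id)
            out.append(replace(r, hypertension=post))
        else:
            out.append(r)
    return out, provenance


def _inject_extreme_age(
    records: list[PhenotypeRecord],
    first_age: dict[str, float],
    n_old: int,
    n_young: int,
    spec: SimulationSpec,
) -> tuple[list[PhenotypeRecord], list[tuple[str, int, int]]]:
    """Move the age-extreme individuals to the boundary of the age range.

    Unlike the label-flip mechanism this also relocates the outliers' ages to
    the extremes of the permitted range (the oldest to age_max, age_max - 1,
    ..., the youngest to age_min), so the planted records are more extreme
    than any naturally drawn individual of the same phenotype.
    """
    by_age = sorted(first_age, key=first_age.__getitem__)
    targets: dict[str, tuple[float, int]] = {}
    for k, iid in enumerate(reversed(by_age[-n_old:] if n_old else [])):
        targets[iid] = (spec.age_max - k, 0)
    for k, iid in enumerate(by_age[:n_young] if n_young else []):
        targets[iid] = (spec.age_min + k, 1)
    provenance: list[tuple[str, int, int]] = []
    out: list[PhenotypeRecord] = []
    logged: set[str] = set()
    for r in records:
        if r.individual_id in targets:
            new_age, post = targets[r.individual_id]
            if r.individual_id not in logged:
                provenance.append((r.individual_id, int(r.hypertension), post))
                logged.add(r.individual_id)
            out.append(replace(r, hypertension=post, age=new_age))
        else:
            out.append(r)
    return out, provenance


def inject_missingness(
    G: GenotypeMatrix,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Mask genotype calls to exercise the missingness filters.

    Background dropout masks each call independently at
    ``missing_variant_rate``.  Additionally, ``missing_individual_rate``
    (as a fraction of the cohort, at least one individual when the rate is
    positive) of individuals get 8% of their calls masked at random —
    constructed to exceed the 5% exclusion threshold, with randomized
    positions.
    """
    rng = rng or np.random.default_rng(spec.seed + 2)
    dosages = G.dosages.copy()
    n, m = dosages.shape
    if spec.missing_variant_rate > 0:
        mask = rng.uniform(size=dosages.shape) < spec.missing_variant_rate
        dosages[mask] = MISSING
    if spec.missing_individual_rate > 0 and m >= 13:
        n_high = max(1, round(spec.missing_individual_rate * n))
        high = rng.choice(n, size=min(n_high, n), replace=False)
        k = math.ceil(0.08 * m)
        for i in high:
            cols = rng.choice(m, size=k, replace=False)
            dosages[i, cols] = MISSING
    return GenotypeMatrix(dosages, list(G.individual_ids), list(G.variants))


def generate_cohort(
    spec: SimulationSpec,
) -> tuple[list[PhenotypeRecord], GenotypeMatrix, TruthLog]:
    """Compose genotype, phenotype, outlier and missingness generation.

    Returns raw (unfiltered) phenotype records including longitudinal
    copies, the genotype matrix with injected missingness, and the truth
    log recording causal variants, planted outliers and true coefficients.
    """
    rng = np.random.default_rng(spec.seed)
    G_clean = simulate_genotypes(spec, rng)
    records = simulate_phenotypes(G_clean, spec, rng)
    records, provenance = plant_outliers(records, spec)
    G = inject_missingness(G_clean, spec, rng)
    truth = TruthLog(
        causal_variants=[
            (G.variants[idx].variant_id, lor) for idx, lor in spec.causal_variants
        ],
        planted_outliers=provenance,
        beta_intercept=spec.resolved_intercept(),
        beta_age=spec.beta_age,
    )
    return records, G, truth
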