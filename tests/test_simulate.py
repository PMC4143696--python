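"""Synthetic cohort generator: HWE, calibration, outliers, missingness."""

import numpy as np
import pytest
from scipy import stats

from roblogit.glm import DesignMatrix, fit_irls
from roblogit.ingest import apply_filters, first_measurement
from roblogit.simulate import (
    SimulationSpec,
    generate_cohort,
    inject_missingness,
    plant_outliers,
    simulate_genotypes,
    simulate_phenotypes,
)

CLEAN = dict(missing_individual_rate=0.0, missing_variant_rate=0.0)


class TestSimulateGenotypes:
    def test_hwe_dosage_frequencies_at_half(self):
        spec = SimulationSpec(
            n_individuals=4000, n_variants=1, maf_range=(0.5, 0.5),
            causal_variants=(), seed=5, **CLEAN,
        )
        G = simulate_genotypes(spec)
        freqs = np.bincount(G.dosages[:, 0], minlength=3) / 4000
        # HWE at f=0.5: (0.25, 0.5, 0.25); 3 binomial SDs
        for observed, expected in zip(freqs, (0.25, 0.5, 0.25)):
            sd = np.sqrt(expected * (1 - expected) / 4000)
            assert abs(observed - expected) < 3 * sd

    def test_no_monomorphic_columns(self):
        spec = SimulationSpec(
            n_individuals=40, n_variants=100, maf_range=(0.05, 0.1),
            causal_variants=(), seed=8, **CLEAN,
        )
        G = simulate_genotypes(spec)
        for j in range(G.n_variants):
            counts = np.bincount(G.dosages[:, j], minlength=3)
            assert counts.sum() - counts.max() >= 2

    def test_deterministic_under_fixed_seed(self):
        spec = SimulationSpec(seed=11, n_variants=50, **CLEAN)
        a = simulate_genotypes(spec)
        b = simulate_genotypes(spec)
        assert np.array_equal(a.dosages, b.dosages)

    def test_different_seed_changes_genotypes(self):
        a = simulate_genotypes(SimulationSpec(seed=1, n_variants=50, **CLEAN))
        b = simulate_genotypes(SimulationSpec(seed=2, n_variants=50, **CLEAN))
        assert not np.array_equal(a.dosages, b.dosages)


class TestSimulatePhenotypes:
    def test_prevalence_calibrated_to_one_third(self):
        prevs = []
        for seed in range(100):
            spec = SimulationSpec(seed=seed, n_variants=2, n_outliers=0, **CLEAN)
            G = simulate_genotypes(spec)
            recs = simulate_phenotypes(G, spec)
            prevs.append(np.mean([r.hypertension for r in recs]))
        prevs = np.array(prevs)
        assert 0.23 <= prevs.mean() <= 0.43
        assert np.mean((prevs >= 0.23) & (prevs <= 0.43)) >= 0.9

    def test_age_range_and_median_match_target_population(self):
        spec = SimulationSpec(n_individuals=2000, n_variants=2, n_outliers=0,
                              seed=4, **CLEAN)
        recs = simulate_phenotypes(simulate_genotypes(spec), spec)
        ages = np.array([r.age for r in recs])
        assert ages.min() >= 20 and ages.max() <= 95
        assert abs(np.median(ages) - 52) < 2

    def test_generating_coefficients_recovered_at_large_n(self):
        spec = SimulationSpec(n_individuals=2000, n_variants=2, n_outliers=0,
                              seed=7, **CLEAN)
        G = simulate_genotypes(spec)
        recs = simulate_phenotypes(G, spec)
        y = np.array([r.hypertension for r in recs], dtype=float)
        age = np.array([r.age for r in recs])
        snp = G.dosages[:, 0].astype(float)
        X = DesignMatrix(np.column_stack([np.ones(2000), age, snp]),
                         ["intercept", "age", "snp"])
        fit = fit_irls(X, y)
        se = fit.se()
        assert abs(fit.beta[1] - spec.beta_age) < 3 * se[1]
        assert abs(fit.beta[2] - 0.8) < 3 * se[2]

    def test_null_effects_give_half_prevalence(self):
        spec = SimulationSpec(n_individuals=3000, n_variants=2, n_outliers=0,
                              age_or=1.0, prevalence_target=0.5, seed=13, **CLEAN)
        recs = simulate_phenotypes(simulate_genotypes(spec), spec)
        prev = np.mean([r.hypertension for r in recs])
        assert abs(prev - 0.5) < 3 * np.sqrt(0.25 / 3000)

    def test_age_quartile_odds_monotone_at_large_n(self):
        from roblogit.evaluate import odds_by_age_quartile

        spec = SimulationSpec(n_individuals=2000, n_variants=2, n_outliers=0,
                              seed=3, **CLEAN)
        G = simulate_genotypes(spec)
        recs = simulate_phenotypes(G, spec)
        y = np.array([r.hypertension for r in recs], dtype=float)
        ages = np.array([r.age for r in recs])
        t = odds_by_age_quartile(ages, y)
        assert all(a < b for a, b in zip(t.odds, t.odds[1:]))


class TestPlantOutliers:
    def test_zero_outliers_is_identity(self):
        spec = SimulationSpec(seed=1, n_variants=2, n_outliers=0, **CLEAN)
        recs = simulate_phenotypes(simulate_genotypes(spec), spec)
        out, prov = plant_outliers(recs, spec)
        assert out == recs and prov == []

    def test_provenance_logs_exactly_n_outliers_with_labels(self):
        spec = SimulationSpec(seed=1, n_variants=2, n_outliers=4, **CLEAN)
        recs = simulate_phenotypes(simulate_genotypes(spec), spec)
        out, prov = plant_outliers(recs, spec)
        assert len(prov) == 4
        post = {iid: p for iid, _, p in prov}
        assert sorted(post.values()) == [0, 0, 0, 1]  # 3 elderly, 1 young
        by_id = {r.individual_id: r for r in out}
        for iid, _, p in prov:
            assert by_id[iid].hypertension == p

    def test_planted_ids_have_larger_cook_distances_in_distribution(self):
        from roblogit.influence import cooks_distance
        from roblogit.pipeline import build_baseline_design

        planted_d, other_d = [], []
        for seed in range(20):
            spec = SimulationSpec(seed=seed, n_variants=2, **CLEAN)
            records, G, truth = generate_cohort(spec)
            ds = apply_filters(records, G)
            ids = ds.genotypes.individual_ids
            planted = {o[0] for o in truth.planted_outliers}
            rep = cooks_distance(build_baseline_design(ds), ds.y, ids=ids)
            for iid, d in zip(ids, rep.cook_d):
                (planted_d if iid in planted else other_d).append(d)
        u = stats.mannwhitneyu(planted_d, other_d, alternative="greater")
        assert u.pvalue < 1e-10


class TestInjectMissingness:
    def test_zero_rates_are_identity(self):
        spec = SimulationSpec(seed=2, n_variants=40, **CLEAN)
        G = simulate_genotypes(spec)
        G2 = inject_missingness(G, spec)
        assert np.array_equal(G.dosages, G2.dosages)

    def test_high_missingness_individual_constructed_above_threshold(self):
        spec = SimulationSpec(seed=2, n_variants=500,
                              missing_individual_rate=0.02, missing_variant_rate=0.0)
        G = simulate_genotypes(spec)
        G2 = inject_missingness(G, spec)
        frac = G2.missing_mask().mean(axis=1)
        assert (frac > 0.05).sum() >= 1

    def test_background_masking_rate_within_binomial_bounds(self):
        spec = SimulationSpec(seed=6, n_variants=500,
                              missing_individual_rate=0.0, missing_variant_rate=0.01)
        G = simulate_genotypes(spec)
        G2 = inject_missingness(G, spec)
        n_cells = G2.dosages.size
        masked = int(G2.missing_mask().sum())
        expected = 0.01 * n_cells
        sd = np.sqrt(n_cells * 0.01 * 0.99)
        assert abs(masked - expected) < 3 * sd


class TestGenerateCohort:
    def test_default_cohort_survives_filters_with_invariants(self):
        records, G, truth = generate_cohort(SimulationSpec(seed=1))
        ds = apply_filters(records, G)
        assert not ds.genotypes.missing_mask().any()
        assert all(r.complete for r in ds.phenotypes)
        assert truth.beta_age == pytest.approx(np.log(1.085))

    def test_longitudinal_copies_reduce_to_one_record_each(self):
        spec = SimulationSpec(seed=9, n_variants=5, longitudinal_copies=4, **CLEAN)
        records, G, truth = generate_cohort(spec)
        kept, dropped = first_measurement(records)
        assert len(kept) + len(dropped) == spec.n_individuals
        assert len({r.individual_id for r in kept}) == len(kept)

    def test_truth_log_names_causal_variant_column(self):
        spec = SimulationSpec(seed=3, n_variants=10, causal_variants=((4, 0.6),), **CLEAN)
        _, G, truth = generate_cohort(spec)
        assert truth.causal_variants == [(G.variants[4].variant_id, 0.6)]

    def test_fully_deterministic_end_to_end(self):
        a = generate_cohort(SimulationSpec(seed=42, n_variants=30))
        b = generate_cohort(SimulationSpec(seed=42, n_variants=30))
        assert np.array_equal(a[1].dosages, b[1].dosages)
        assert a[0] == b[0]
        assert a[2].planted_outliers == b[2].planted_outliers
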