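"""Generate the synthetic hypertension cohort used by the downstream steps.

Writes a VCF of Hardy-Weinberg genotypes, a longitudinal-style phenotype
TSV (hypertension status, age, gender, smoking) and a truth log recording
the causal variant, the planted extreme-age outliers and the generating
coefficients, under results/cohort/.
"""

import sys
from pathlib import Path

import pandas as pd

from roblogit.ingest import write_vcf
from roblogit.simulate import SimulationSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = SimulationSpec(seed=seed)
    records, genotypes, truth = generate_cohort(spec)

    write_vcf(genotypes, OUT / "genotypes.vcf")
    pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "hypertension": [r.hypertension for r in records],
            "age": [r.age for r in records],
            "gender": [r.gender for r in records],
            "smoking": [r.smoking for r in records],
            "measurement_index": [r.measurement_index for r in records],
        }
    ).to_csv(OUT / "phenotypes.tsv", sep="\t", index=False, na_rep="NA")
    rows = [("coefficient", "intercept", truth.beta_intercept),
            ("coefficient", "age", truth.beta_age)]
    rows += [("causal_variant", vid, lor) for vid, lor in truth.causal_variants]
    rows += [(f"planted_outlier", iid, f"{pre}->{post}")
             for iid, pre, post in truth.planted_outliers]
    pd.DataFrame(rows, columns=["kind", "id", "value"]).to_csv(
        OUT / "truth.tsv", sep="\t", index=False
    )

    n_cases = sum(r.hypertension for r in records)
    print(f"cohort: {spec.n_individuals} individuals x {spec.n_variants} variants, "
          f"{n_cases} cases ({100 * n_cases / spec.n_individuals:.1f}%)")
    print(f"causal variant: {truth.causal_variants}")
    print(f"planted outliers: {[o[0] for o in truth.planted_outliers]}")
    print(f"wrote {OUT}/genotypes.vcf, phenotypes.tsv, truth.tsv")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
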