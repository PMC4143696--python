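"""Scan every variant on top of the age baseline, under both estimators.

The standard scan ranks variants by the drop in deviance; the robust scan
by the quasi-deviance Lambda_QM.  The two rankings need not agree in the
presence of outliers.  QQ coordinates of the per-variant p-values are
written for both scans, and the pairwise genotypic r-squared between the
two top-ranked variants is reported.
"""

from pathlib import Path

import pandas as pd

from roblogit.pipeline import build_baseline_design
from roblogit.scan import pairwise_r2, qq_points, scan_variants

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "baseline_step", Path(__file__).resolve().parent / "03_baseline_models.py"
)
_baseline = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_baseline)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = _baseline.load_filtered()
    X = build_baseline_design(dataset)
    out = ROOT / "scan"
    out.mkdir(parents=True, exist_ok=True)

    tops = {}
    for est in ("standard", "robust"):
        res = scan_variants(X, dataset.y, dataset.genotypes, est)
        res.table.to_csv(out / f"scan_{est}.tsv", sep="\t", index=False)
        pd.DataFrame(qq_points(res), columns=["expected", "observed"]).to_csv(
            out / f"qq_{est}.tsv", sep="\t", index=False
        )
        top = res.top(1).iloc[0]
        tops[est] = top["variant_id"]
        print(f"{est} scan: top variant {top['variant_id']} "
              f"(statistic {top['statistic']:.2f}, p = {top['p']:.2e})")

    vids = [v.variant_id for v in dataset.genotypes.variants]
    g1 = dataset.genotypes.dosages[:, vids.index(tops["standard"])]
    g2 = dataset.genotypes.dosages[:, vids.index(tops["robust"])]
    if tops["standard"] == tops["robust"]:
        print("both scans selected the same variant")
    else:
        print(f"pairwise r^2 between the two selections: {pairwise_r2(g1, g2):.3f}")
    truth = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t")
    causal = truth.loc[truth["kind"] == "causal_variant", "id"].tolist()
    print(f"true causal variant(s): {causal}")


if __name__ == "__main__":
    main()
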