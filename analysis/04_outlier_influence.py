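"""Cook's-distance outlier diagnostics and exclusion-impact analysis.

Exact leave-one-out Cook's distances on the age-only baseline identify
individuals whose hypertension profile departs from the age trend (elderly
unaffected, young affected).  For each flagged individual both estimators
are refitted without them; the percent change of the excess risk (OR - 1)
per year of age quantifies how strongly each estimator leaned on that
observation.
"""

from pathlib import Path

import pandas as pd

from roblogit.influence import cooks_distance, exclusion_impact, impact_frame
from roblogit.pipeline import build_baseline_design

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
    ids = dataset.genotypes.individual_ids

    report = cooks_distance(X, dataset.y, ids=ids, threshold=0.05)
    flagged = report.flagged_ids()
    out = ROOT / "influence"
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / "cook_distances.tsv", sep="\t", index=False)

    print(f"{len(flagged)} individuals exceed the Cook's-distance threshold 0.05")
    truth = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t")
    planted = set(truth.loc[truth["kind"] == "planted_outlier", "id"])
    for iid in flagged:
        i = ids.index(iid)
        mark = " (planted)" if iid in planted else ""
        print(f"  {iid}: D = {report.cook_d[i]:.3f}, age = {X.values[i, 1]:.1f}, "
              f"status = {int(dataset.y[i])}{mark}")

    if flagged:
        rows = exclusion_impact(X, dataset.y, ids, flagged)
        frame = impact_frame(rows)
        frame.to_csv(out / "exclusion_impact.tsv", sep="\t", index=False)
        print("\nexcess-risk change upon exclusion (standard vs robust):")
        for _, r in frame.iterrows():
            print(f"  {r['excluded_id']}: {r['pct_change_standard']:+.1f}% vs "
                  f"{r['pct_change_robust']:+.1f}%")


if __name__ == "__main__":
    main()
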