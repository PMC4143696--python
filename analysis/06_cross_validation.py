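"""Leave-one-out cross-validated clinical performance of the age+SNP models.

Each estimator carries its own scan-selected variant in a fixed age+SNP
model; LOOCV probabilities feed the per-cutoff concordance, sensitivity,
specificity and clinical net benefit table (cutoffs 0.0 to 1.0 in steps of
0.1), the overall AUCs, and the integrated discrimination improvement of
the robust over the standard model.  The descriptive odds of hypertension
per age quartile are written alongside.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from roblogit.evaluate import (
    CVResult,
    DEFAULT_CUTOFFS,
    auc_trapezoid,
    idi,
    loocv_probabilities,
    metrics_at_cutoff,
    odds_by_age_quartile,
)
from roblogit.pipeline import build_baseline_design
from roblogit.robust import RobustConfig

import importlib.util

_spec = importlib.util.spec_from_file_location(
    "baseline_step", Path(__file__).resolve().parent / "03_baseline_models.py"
)
_baseline = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_baseline)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = _baseline.load_filtered()
    base_X = build_baseline_design(dataset)
    y = dataset.y
    vids = [v.variant_id for v in dataset.genotypes.variants]

    selected = {}
    for est in ("standard", "robust"):
        scan = pd.read_csv(ROOT / "scan" / f"scan_{est}.tsv", sep="\t")
        selected[est] = scan.sort_values("rank")["variant_id"].iloc[0]

    designs = {
        est: base_X.with_column(
            dataset.genotypes.dosages[:, vids.index(vid)].astype(float), f"snp:{vid}"
        )
        for est, vid in selected.items()
    }
    ps = loocv_probabilities(designs["standard"], y, "standard")
    pr = loocv_probabilities(designs["robust"], y, "robust", RobustConfig())
    ok = ~(np.isnan(ps) | np.isnan(pr))
    cv = CVResult(probs_standard=ps, probs_robust=pr, y=y)
    cv.metrics_standard = [metrics_at_cutoff(ps[ok], y[ok], c) for c in DEFAULT_CUTOFFS]
    cv.metrics_robust = [metrics_at_cutoff(pr[ok], y[ok], c) for c in DEFAULT_CUTOFFS]
    cv.auc_standard = auc_trapezoid(ps[ok], y[ok])
    cv.auc_robust = auc_trapezoid(pr[ok], y[ok])
    cv.idi = idi(pr[ok], ps[ok], y[ok])

    out = ROOT / "cv"
    out.mkdir(parents=True, exist_ok=True)
    cv.to_frame().to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
    odds_by_age_quartile(dataset.age, y).to_frame().to_csv(
        out / "age_odds.tsv", sep="\t", index=False
    )

    print(f"age+SNP models: standard uses {selected['standard']}, "
          f"robust uses {selected['robust']}")
    print("cutoff  conc_std  NB_std  conc_rob  NB_rob")
    for ms, mr in zip(cv.metrics_standard, cv.metrics_robust):
        nb_s = "-" if np.isnan(ms.net_benefit) else f"{ms.net_benefit:.2f}"
        nb_r = "-" if np.isnan(mr.net_benefit) else f"{mr.net_benefit:.2f}"
        print(f"  {ms.cutoff:.1f}   {ms.concordance_n:3d} ({ms.concordance_pct:.1f}%)  "
              f"{nb_s:>5}   {mr.concordance_n:3d} ({mr.concordance_pct:.1f}%)  {nb_r:>5}")
    print(f"LOOCV AUC: standard {cv.auc_standard:.3f}, robust {cv.auc_robust:.3f}; "
          f"IDI {cv.idi:+.3f}")
    t = odds_by_age_quartile(dataset.age, y)
    print("odds of hypertension per age quartile:",
          ", ".join(f"{lbl}: {o:.2f}" for lbl, o in zip(t.labels(), t.odds)))


if __name__ == "__main__":
    main()
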