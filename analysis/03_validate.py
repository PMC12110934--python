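"""Validate both MFC methods against the molecular reference.

Reads results/cohort_measurements.csv (from 02_simulate_and_quantify.py),
computes concordance and error rates per method, the chi-square method
comparison on the partial-expression samples, empirical ROC curves with
Youden-optimal cut-offs, and the therapy- and tracking-marker-stratified
summaries. Writes validation_report.json and roc_curves.csv under results/.
"""

import json
from pathlib import Path

import pandas as pd

from mrdflow import stratified_validation, validate_results
from mrdflow.cli import _jsonable

RESULTS = Path(__file__).resolve().parent.parent / "results"


def _drop_curves(node) -> None:
    """Strip per-threshold ROC coordinates from a report tree in place."""
    if isinstance(node, dict):
        for key in ("thresholds", "fpr", "tpr"):
            node.pop(key, None)
        for value in node.values():
            _drop_curves(value)
    elif isinstance(node, list):
        for value in node:
            _drop_curves(value)


def main() -> None:
    results = pd.read_csv(RESULTS / "cohort_measurements.csv")
    report = validate_results(results)

    print("overall (molecular-excluded samples dropped):")
    curves = []
    for method, blk in report["methods"].items():
        c = blk["confusion"]
        line = (f"  {method:>8}: n={blk['n']}  concordance {c.concordance_pct:.1f}%  "
                f"FP {c.false_pos_pct:.1f}%  FN {c.false_neg_pct:.1f}%  "
                f"sens {c.sensitivity_pct:.1f}%  spec {c.specificity_pct:.1f}%")
        roc = blk["roc"]
        if roc is not None:
            line += (f"  AUC {roc.auc:.2f} (±{roc.auc_se:.2f})  "
                     f"Youden cut-off {roc.optimal_cutoff:.3f}%")
            curves.append(pd.DataFrame({
                "method": method, "threshold": roc.thresholds,
                "fpr": roc.fpr, "tpr": roc.tpr,
            }))
        print(line)
    if "partial_class" in report:
        chi2 = report["partial_class"]["chi2"]
        print(f"partial-expression method comparison: chi2={chi2.chi2_statistic:.2f} "
              f"p={chi2.p_value:.4f}")

    strata = {
        name: stratified_validation(results[results["molecular_call"] != "excluded"], name)
        for name in ("therapy", "tracking_marker")
    }
    payload = {"overall": _jsonable(report), "strata": _jsonable(strata)}
    _drop_curves(payload)  # curve coordinates live in roc_curves.csv
    (RESULTS / "validation_report.json").write_text(json.dumps(payload, indent=2))
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(RESULTS / "roc_curves.csv", index=False)
    print(f"report written to {RESULTS / 'validation_report.json'}")


if __name__ == "__main__":
    main()
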