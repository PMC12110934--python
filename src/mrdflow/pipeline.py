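"""End-to-end orchestration: LAIP catalog -> gating -> quantification ->
molecular reference -> validation, over a synthetic or user-supplied cohort.

The per-sample results table is the package's central exchange format: one
row per sample x method with the MFC measurement, both interpretive calls
(default and therapy-specific), the molecular reference, ground-truth
columns when the cohort is synthetic, and QC flags.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .cohort_model import Marker, ThresholdConfig
from .gating_engine import (
    GatingConfig,
    TemplateFitError,
    apply_template,
    fit_template,
    marker_threshold,
    preprocess,
)
from .laip_catalog import classify_patient
from .molecular_mrd import classify_molecular, compute_ratio, qc_filter
from .mrd_quantification import (
    DFN_METHOD,
    LAIP_METHOD,
    choose_methods,
    classify_mfc,
    quantify_dfn_method,
    quantify_laip_method,
)
from .synthetic_data import SyntheticCohort
from .validation_stats import compare_methods, confusion, roc_analysis, _as_bool

__all__ = ["run_cohort", "validate_results"]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "sample_id", "patient_id", "therapy", "tracking_marker", "expression_class",
    "method", "cd45_events", "terminal_events", "laip_positive_events",
    "mrd_pct", "mfc_call", "mfc_call_therapy", "npm1_ratio_pct",
    "molecular_qc_pass", "molecular_call", "total_blast_pct",
    "true_level_pct", "true_mrd_pct", "qc_flags",
]


def run_cohort(
    cohort: SyntheticCohort,
    thresholds: ThresholdConfig | None = None,
    gating: GatingConfig | None = None,
) -> pd.DataFrame:
    """Quantify every follow-up sample of a cohort with both MFC methods.

    For each patient a template is fitted on the diagnosis sample; each
    follow-up is gated with the stored template, quantified with the
    LAIP-method (and the DfN-method when the LAIP is partially expressed),
    and paired with its molecular NPM1 measurement.
    """
    thresholds = thresholds or ThresholdConfig()
    gating = gating or GatingConfig()
    rows: list[dict] = []

    for pi, profile in enumerate(cohort.profiles):
        laip_profile = classify_patient(profile, thresholds)
        tracking = laip_profile.tracking_marker
        diagnosis, _ = cohort.diagnosis(pi)
        diagnosis = preprocess(diagnosis, gating)
        try:
            template = fit_template(
                diagnosis, profile, thresholds, gating, tracking_marker=tracking
            )
        except TemplateFitError as exc:
            logger.warning("patient %s: template fit failed (%s)", profile.patient_id, exc)
            continue
        methods = choose_methods(laip_profile)

        sample_rows = cohort.manifest.index[
            cohort.manifest["patient_index"] == pi
        ]
        for ridx in sample_rows:
            fs = cohort.followup(int(ridx))
            events = preprocess(fs.events, gating)
            counts = apply_template(
                template, events, min_events=thresholds.min_events, config=gating
            )
            control_mask = np.zeros(events.n_events, dtype=bool)
            control_mask[counts.indices[template.control_gate_id]] = True

            # total progenitor+blast burden (CD117+ share of WBC) for the
            # "true MRD" restriction stratifier
            cd117_cut = marker_threshold(events, Marker.CD117, control_mask, gating)
            wbc_idx = counts.indices[template.wbc_gate_id]
            cd117_t = events.transformed("CD117")[wbc_idx]
            total_blast_pct = (
                100.0 * float((cd117_t > cd117_cut).sum()) / len(wbc_idx)
                if len(wbc_idx)
                else float("nan")
            )

            molecular = qc_filter(
                compute_ratio(fs.npm1_copies, fs.abl1_copies, fs.sample_id), thresholds
            )
            mol_call = (
                classify_molecular(molecular, thresholds)
                if molecular.qc_pass
                else "excluded"
            )

            measurements = [quantify_laip_method(counts, template, fs.sample_id)]
            if DFN_METHOD in methods:
                cutoff = marker_threshold(events, tracking, control_mask, gating)
                measurements.append(
                    quantify_dfn_method(
                        counts, events, tracking, cutoff, template, fs.sample_id
                    )
                )
            for m in measurements:
                rows.append(
                    {
                        "sample_id": fs.sample_id,
                        "patient_id": fs.patient_id,
                        "therapy": fs.therapy.value,
                        "tracking_marker": tracking.value,
                        "expression_class": laip_profile.expression_class,
                        "method": m.method,
                        "cd45_events": m.cd45_events,
                        "terminal_events": m.terminal_events,
                        "laip_positive_events": m.laip_positive_events,
                        "mrd_pct": m.mrd_pct,
                        "mfc_call": classify_mfc(m, fs.therapy, thresholds, "default"),
                        "mfc_call_therapy": classify_mfc(
                            m, fs.therapy, thresholds, "therapy_specific"
                        ),
                        "npm1_ratio_pct": molecular.ratio_pct,
                        "molecular_qc_pass": molecular.qc_pass,
                        "molecular_call": mol_call,
                        "total_blast_pct": total_blast_pct,
                        "true_level_pct": fs.true_level_pct,
                        "true_mrd_pct": fs.truth.true_mrd_pct,
                        "qc_flags": ";".join(m.qc_flags),
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def validate_results(results: pd.DataFrame, call_column: str = "mfc_call") -> dict:
    """Concordance, method comparison and ROC blocks from a results table.

    Molecular-excluded samples are dropped from every denominator (logged).
    The method-vs-method comparison and ROC are restricted to samples from
    partial-expression patients, where both methods were actually run.
    """
    usable = results[results["molecular_call"] != "excluded"]
    n_dropped = results["sample_id"].nunique() - usable["sample_id"].nunique()
    if n_dropped:
        logger.info("dropped %d molecular-excluded samples from validation", n_dropped)

    report: dict = {"n_excluded": int(n_dropped), "methods": {}}
    for method, sub in usable.groupby("method"):
        summary = confusion(sub[call_column], sub["molecular_call"])
        ref = _as_bool(sub["molecular_call"])
        roc = (
            roc_analysis(sub["mrd_pct"].to_numpy(), ref)
            if 0 < ref.sum() < len(ref)
            else None
        )
        report["methods"][method] = {"n": len(sub), "confusion": summary, "roc": roc}

    partial = usable[usable["expression_class"] == "partial"]
    by_method = {m: s for m, s in partial.groupby("method")}
    if LAIP_METHOD in by_method and DFN_METHOD in by_method:
        a = confusion(
            by_method[DFN_METHOD][call_column], by_method[DFN_METHOD]["molecular_call"]
        )
        b = confusion(
            by_method[LAIP_METHOD][call_column], by_method[LAIP_METHOD]["molecular_call"]
        )
        report["partial_class"] = {
            "dfn_confusion": a,
            "laip_confusion": b,
            "chi2": compare_methods(a, b),
        }
    return report
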