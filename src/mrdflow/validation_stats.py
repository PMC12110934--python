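"""Validation of MFC-MRD calls against the molecular reference standard.

Confusion summaries treat the molecular NPM1 call as truth: a false
positive is an MFC-positive / molecular-negative sample. Method concordance
is compared by a Pearson chi-square on the method x concordant/discordant
table; accuracy by an empirical ROC whose AUC standard error follows
Hanley & McNeil and whose operating point maximizes Youden's J
(sensitivity + specificity - 1), ties broken toward higher specificity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionSummary",
    "ROCResult",
    "MethodComparison",
    "confusion",
    "compare_methods",
    "roc_analysis",
    "stratified_validation",
]

logger = logging.getLogger(__name__)

STRATIFIERS = ("therapy", "tracking_marker", "blast_lt_1pct", "npm1_ratio_lt_1")


@dataclass(frozen=True)
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def concordant(self) -> int:
        return self.tp + self.tn

    @property
    def concordance_pct(self) -> float:
        return 100.0 * self.concordant / self.n if self.n else float("nan")

    @property
    def false_pos_pct(self) -> float:
        return 100.0 * self.fp / self.n if self.n else float("nan")

    @property
    def false_neg_pct(self) -> float:
        return 100.0 * self.fn / self.n if self.n else float("nan")

    @property
    def sensitivity_pct(self) -> float:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else float("nan")

    @property
    def specificity_pct(self) -> float:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else float("nan")

    @property
    def ppv_pct(self) -> float:
        called = self.tp + self.fp
        return 100.0 * self.tp / called if called else float("nan")

    @property
    def npv_pct(self) -> float:
        called = self.tn + self.fn
        return 100.0 * self.tn / called if called else float("nan")


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    p_value: float
    optimal_cutoff: float
    optimal_sens_pct: float
    optimal_spec_pct: float


@dataclass(frozen=True)
class MethodComparison:
    chi2_statistic: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]


def _as_bool(calls) -> np.ndarray:
    arr = np.asarray(calls)
    if arr.dtype == bool:
        return arr
    out = np.empty(arr.shape, dtype=bool)
    for i, v in enumerate(arr.ravel()):
        s = str(v).lower()
        if s not in ("positive", "negative"):
            raise ValueError(f"unexpected call value: {v!r}")
        out.ravel()[i] = s == "positive"
    return out


def confusion(mfc_calls, reference_calls) -> ConfusionSummary:
    """Cross-tabulate MFC calls against the molecular reference.

    Excluded molecular samples must be dropped before calling; the two
    sequences must cover the same samples in the same order.
    """
    mfc = _as_bool(mfc_calls)
    ref = _as_bool(reference_calls)
    if mfc.shape != ref.shape:
        raise ValueError("mismatched sample sets between MFC and reference calls")
    return ConfusionSummary(
        tp=int((mfc & ref).sum()),
        fp=int((mfc & ~ref).sum()),
        tn=int((~mfc & ~ref).sum()),
        fn=int((~mfc & ref).sum()),
    )


def compare_methods(a: ConfusionSummary, b: ConfusionSummary) -> MethodComparison:
    """Pearson chi-square (no continuity correction) on the 2x2 table
    [[concordant_a, discordant_a], [concordant_b, discordant_b]]."""
    if a.n != b.n:
        raise ValueError("method summaries must cover the same number of samples")
    table = (
        (a.concordant, a.n - a.concordant),
        (b.concordant, b.n - b.concordant),
    )
    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero marginal); statistic set to 0")
        return MethodComparison(0.0, 1.0, table)
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return MethodComparison(float(stat), float(p), table)


def roc_analysis(mrd_values, reference_labels) -> ROCResult:
    """Empirical ROC of a quantitative MRD readout against the reference.

    Candidate cutoffs are the observed values; a sample is called positive
    when its value is strictly above the cutoff (the package-wide
    convention). AUC by the trapezoidal rule (equivalently the tie-corrected
    Mann-Whitney statistic); SE and the 95% CI by the Hanley-McNeil
    formulas; the p-value tests AUC = 0.5 by the normal approximation to
    the Mann-Whitney statistic.
    """
    values = np.asarray(mrd_values, dtype=float)
    labels = _as_bool(reference_labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: both reference classes must be present")

    thresholds = np.unique(values)  # ascending
    # rule "value > t": tpr/fpr per candidate cutoff
    pos_sorted = np.sort(values[labels])
    neg_sorted = np.sort(values[~labels])
    tpr = 1.0 - np.searchsorted(pos_sorted, thresholds, side="right") / n_pos
    fpr = 1.0 - np.searchsorted(neg_sorted, thresholds, side="right") / n_neg

    # AUC via the Mann-Whitney statistic with tie correction (equals the
    # trapezoid over the full empirical curve)
    ranks = stats.rankdata(values)
    auc = float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    se_null = float(np.sqrt((n_pos + n_neg + 1) / (12 * n_pos * n_neg)))
    z = (auc - 0.5) / se_null
    p_value = float(2 * stats.norm.sf(abs(z)))

    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # ties in J resolved toward higher specificity (lower fpr = higher cutoff)
    best_idx = int(best[np.argmin(fpr[best])])
    return ROCResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        auc_se=se,
        auc_ci95=ci,
        p_value=p_value,
        optimal_cutoff=float(thresholds[best_idx]),
        optimal_sens_pct=100.0 * float(tpr[best_idx]),
        optimal_spec_pct=100.0 * float(1 - fpr[best_idx]),
    )


_REQUIRED_COLUMNS = {
    "sample_id", "method", "mrd_pct", "mfc_call", "molecular_call",
}


def stratified_validation(
    results: pd.DataFrame, stratifier: str
) -> dict[str, dict[str, dict]]:
    """Repeat confusion + ROC per stratum and per method.

    ``results`` holds one row per sample x method with the MFC and molecular
    calls; molecular-excluded samples must already be dropped. Returns
    ``{stratum: {method: {"n", "confusion", "roc"}}}``; strata with a single
    reference class skip ROC (logged, roc=None).
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier: {stratifier!r}")
    missing = _REQUIRED_COLUMNS - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")

    if stratifier == "therapy":
        groups = results.groupby("therapy", sort=True)
    elif stratifier == "tracking_marker":
        groups = results.groupby("tracking_marker", sort=True)
    elif stratifier == "blast_lt_1pct":
        key = np.where(results["total_blast_pct"] < 1.0, "blast_lt_1pct", "blast_ge_1pct")
        groups = results.groupby(key, sort=True)
    else:
        key = np.where(results["npm1_ratio_pct"] < 1.0, "npm1_lt_1", "npm1_ge_1")
        groups = results.groupby(key, sort=True)

    report: dict[str, dict[str, dict]] = {}
    for stratum, frame in groups:
        report[str(stratum)] = {}
        for method, sub in frame.groupby("method", sort=True):
            summary = confusion(sub["mfc_call"], sub["molecular_call"])
            ref = _as_bool(sub["molecular_call"])
            if ref.all() or not ref.any():
                logger.info(
                    "stratum %s / method %s has a single reference class; ROC skipped",
                    stratum, method,
                )
                roc = None
            else:
                roc = roc_analysis(sub["mrd_pct"].to_numpy(), ref)
            report[str(stratum)][str(method)] = {
                "n": len(sub),
                "confusion": summary,
                "roc": roc,
            }
    return report
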