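"""NPM1-mutant / ABL1 molecular MRD from triplicate RT-qPCR copy numbers.

The ratio is 100 * mean(NPM1-mutant copies) / mean(ABL1 copies); samples
with a mean ABL1 copy number below 10,000 are excluded (insufficient RNA
quality), and positivity is a ratio strictly above 0.01%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_model import ThresholdConfig

__all__ = [
    "MolecularMeasurement",
    "compute_ratio",
    "qc_filter",
    "classify_molecular",
    "process_molecular_table",
]


@dataclass(frozen=True)
class MolecularMeasurement:
    sample_id: str
    npm1_copies: tuple[float, float, float]
    abl1_copies: tuple[float, float, float]
    npm1_mean: float
    abl1_mean: float
    ratio_pct: float
    qc_pass: bool | None = None
    call: str | None = None
    qc_flags: tuple[str, ...] = ()


def compute_ratio(
    npm1: Sequence[float], abl1: Sequence[float], sample_id: str = ""
) -> MolecularMeasurement:
    """Arithmetic replicate means and the percent NPM1-mutated ratio."""
    npm1 = tuple(float(x) for x in npm1)
    abl1 = tuple(float(x) for x in abl1)
    if len(npm1) != 3 or len(abl1) != 3:
        raise ValueError("three replicates are required for each gene")
    if any(x < 0 for x in npm1 + abl1):
        raise ValueError("copy numbers must be non-negative")
    npm1_mean = float(np.mean(npm1))
    abl1_mean = float(np.mean(abl1))
    if abl1_mean == 0:
        raise ValueError("undefined ratio: mean ABL1 copy number is zero")
    return MolecularMeasurement(
        sample_id=sample_id,
        npm1_copies=npm1,
        abl1_copies=abl1,
        npm1_mean=npm1_mean,
        abl1_mean=abl1_mean,
        ratio_pct=100.0 * npm1_mean / abl1_mean,
    )


def qc_filter(
    measurement: MolecularMeasurement, thresholds: ThresholdConfig | None = None
) -> MolecularMeasurement:
    """Exclude samples with fewer than 10,000 mean ABL1 copies.

    A replicate coefficient of variation above 50% (either gene) adds a
    warning flag only; it never excludes the sample.
    """
    thresholds = thresholds or ThresholdConfig()
    flags = list(measurement.qc_flags)
    for gene, reps, mean in (
        ("npm1", measurement.npm1_copies, measurement.npm1_mean),
        ("abl1", measurement.abl1_copies, measurement.abl1_mean),
    ):
        if mean > 0 and float(np.std(reps, ddof=1)) / mean > 0.5:
            flags.append(f"high_replicate_cv_{gene}")
    passed = measurement.abl1_mean >= thresholds.abl1_min_copies
    return replace(
        measurement,
        qc_pass=passed,
        call=None if passed else "excluded",
        qc_flags=tuple(flags),
    )


def classify_molecular(
    measurement: MolecularMeasurement, thresholds: ThresholdConfig | None = None
) -> str:
    """Positive when the ratio is strictly above 0.01%."""
    thresholds = thresholds or ThresholdConfig()
    if measurement.qc_pass is False:
        raise ValueError("cannot classify an excluded (QC-failed) sample")
    return (
        "positive"
        if measurement.ratio_pct > thresholds.npm1_positivity_ratio_pct
        else "negative"
    )


def process_molecular_table(
    table: pd.DataFrame, thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Process a replicate CSV (sample_id, npm1_rep1..3, abl1_rep1..3).

    Appends npm1_mean, abl1_mean, ratio_pct, qc_pass and call columns.
    """
    thresholds = thresholds or ThresholdConfig()
    out = table.copy()
    means_n, means_a, ratios, qcs, calls = [], [], [], [], []
    for _, row in table.iterrows():
        m = compute_ratio(
            [row[f"npm1_rep{i}"] for i in (1, 2, 3)],
            [row[f"abl1_rep{i}"] for i in (1, 2, 3)],
            sample_id=str(row["sample_id"]),
        )
        m = qc_filter(m, thresholds)
        means_n.append(m.npm1_mean)
        means_a.append(m.abl1_mean)
        ratios.append(m.ratio_pct)
        qcs.append(m.qc_pass)
        calls.append(m.call if not m.qc_pass else classify_molecular(m, thresholds))
    out["npm1_mean"] = means_n
    out["abl1_mean"] = means_a
    out["ratio_pct"] = ratios
    out["qc_pass"] = qcs
    out["call"] = calls
    return out
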