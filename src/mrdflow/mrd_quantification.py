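"""The two competing MFC-MRD quantification methods and the MRD call.

LAIP-method: every event in the terminal gate of the patient-specific
template counts as residual disease. LAIP-based DfN-method: only terminal
events positive for the patient's tracking aberrant lineage marker count.
Both are expressed as a percent of CD45+ leukocytes; by construction the
DfN value can never exceed the LAIP value on the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort_model import Marker, TherapyLabel, ThresholdConfig
from .gating_engine import EventTable, GateCounts, GatingTemplate
from .laip_catalog import PatientLAIPProfile

__all__ = [
    "LAIP_METHOD",
    "DFN_METHOD",
    "MFCMeasurement",
    "quantify_laip_method",
    "quantify_dfn_method",
    "classify_mfc",
    "choose_methods",
]

LAIP_METHOD = "LAIP"
DFN_METHOD = "LAIP_DfN"


@dataclass(frozen=True)
class MFCMeasurement:
    sample_id: str
    method: str
    cd45_events: int
    terminal_events: int
    laip_positive_events: int
    mrd_pct: float
    call: str | None = None
    threshold_used: float | None = None
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (
            0 <= self.laip_positive_events <= self.terminal_events <= self.cd45_events
        ):
            raise ValueError(
                "event counts must nest: LAIP+ <= terminal <= CD45+"
            )


def _measurement(
    sample_id: str,
    method: str,
    cd45: int,
    terminal: int,
    counted: int,
    qc_flags: tuple[str, ...],
) -> MFCMeasurement:
    if cd45 == 0:
        raise ValueError("undefined measurement: zero CD45+ events")
    return MFCMeasurement(
        sample_id=sample_id,
        method=method,
        cd45_events=cd45,
        terminal_events=terminal,
        laip_positive_events=counted,
        mrd_pct=100.0 * counted / cd45,
        qc_flags=qc_flags,
    )


def quantify_laip_method(
    counts: GateCounts, template: GatingTemplate, sample_id: str = ""
) -> MFCMeasurement:
    """All terminal-gate events, as a percent of CD45+ leukocytes."""
    terminal = counts.counts[template.terminal_gate_id]
    return _measurement(
        sample_id,
        LAIP_METHOD,
        counts.counts[template.wbc_gate_id],
        terminal,
        terminal,
        tuple(counts.qc_flags),
    )


def quantify_dfn_method(
    counts: GateCounts,
    events: EventTable,
    tracking: Marker,
    cutoff: float,
    template: GatingTemplate,
    sample_id: str = "",
) -> MFCMeasurement:
    """Terminal-gate events positive for the tracking marker, percent of CD45+.

    ``cutoff`` is the positivity threshold on the transformed scale, derived
    from the sample's own internal negative control.
    """
    if tracking.value not in events.data.columns:
        raise ValueError(f"tracking channel {tracking.value} missing from sample")
    terminal_idx = counts.indices[template.terminal_gate_id]
    intensities = events.transformed(tracking.value)[terminal_idx]
    positive = int((intensities > cutoff).sum())
    return _measurement(
        sample_id,
        DFN_METHOD,
        counts.counts[template.wbc_gate_id],
        len(terminal_idx),
        positive,
        tuple(counts.qc_flags),
    )


def classify_mfc(
    measurement: MFCMeasurement,
    therapy: TherapyLabel | None = None,
    thresholds: ThresholdConfig | None = None,
    mode: str = "default",
) -> str:
    """Positive/negative call for an MFC measurement (strictly above cutoff).

    ``default`` mode applies the single interpretive threshold (0.035% of
    CD45+ cells). ``therapy_specific`` applies the ROC-derived cut-offs:
    0.034% post-chemotherapy, 0.095% post-Ven+HMA; post-allo-SCT samples
    have no dedicated cut-off and fall back to the default threshold.
    """
    thresholds = thresholds or ThresholdConfig()
    if mode == "default":
        cutoff = thresholds.mfc_positivity_pct
    elif mode == "therapy_specific":
        if not isinstance(therapy, TherapyLabel):
            raise ValueError(f"unknown therapy for therapy-specific mode: {therapy!r}")
        cutoff = {
            TherapyLabel.POST_CHT: thresholds.cht_cutoff_pct,
            TherapyLabel.POST_VENHMA: thresholds.venhma_cutoff_pct,
            TherapyLabel.POST_ALLOSCT: thresholds.mfc_positivity_pct,
        }[therapy]
    else:
        raise ValueError(f"unknown classification mode: {mode!r}")
    return "positive" if measurement.mrd_pct > cutoff else "negative"


def choose_methods(profile: PatientLAIPProfile | None) -> set[str]:
    """Which quantification methods to run for a patient.

    Total LAIP expression at diagnosis: the template already contains only
    tracking-positive cells, so the LAIP-method alone is used. Partial
    expression: both methods run and are compared. No qualifying LAIP: the
    patient is ineligible for MFC-MRD (empty set).
    """
    if profile is None or not profile.laips:
        return set()
    if profile.expression_class == "total":
        return {LAIP_METHOD}
    return {LAIP_METHOD, DFN_METHOD}
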