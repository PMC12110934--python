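"""LAIP eligibility, tracking-marker selection, and expression classification.

A LAIP (leukemia-associated immunophenotype) is defined here on aberrant
lineage markers only (CD4, CD7, CD56, CD25): a marker qualifies when at
least 20% of the patient's AML cells express it at diagnosis. The single
tracking marker used for the DfN filter is the qualifying marker with the
highest diagnostic expression. Patients whose tracking marker covers >= 90%
of AML cells are "total" expression (LAIP-method only); 20-90% is "partial"
(both quantification methods run and are compared).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort_model import (
    ABERRANT_LINEAGE_MARKERS,
    DiagnosisProfile,
    Marker,
    ThresholdConfig,
)

__all__ = [
    "LAIPDefinition",
    "PatientLAIPProfile",
    "NoLAIPError",
    "identify_laips",
    "select_tracking_marker",
    "classify_expression",
    "classify_patient",
    "stratify_cohort",
]

# Tie-break preference when two qualifying markers share the maximal
# expression: more specific markers first (CD25 and CD56 track residual
# disease with the fewest false calls, CD4 with the most).
_SPECIFICITY_ORDER = (Marker.CD25, Marker.CD56, Marker.CD7, Marker.CD4)


class NoLAIPError(ValueError):
    """Raised when a patient has no qualifying aberrant lineage marker."""


@dataclass(frozen=True)
class LAIPDefinition:
    marker: Marker
    expression_pct: float

    def __post_init__(self) -> None:
        if self.marker not in ABERRANT_LINEAGE_MARKERS:
            raise ValueError(f"{self.marker} is not an aberrant lineage marker")


@dataclass(frozen=True)
class PatientLAIPProfile:
    patient_id: str
    laips: tuple[LAIPDefinition, ...]
    tracking_marker: Marker
    expression_class: str  # "total" | "partial"
    tracking_expression_pct: float
    total_mrd: int = 0


def identify_laips(
    profile: DiagnosisProfile, thresholds: ThresholdConfig | None = None
) -> list[LAIPDefinition]:
    """Qualifying aberrant lineage markers, sorted descending by expression.

    The eligibility threshold is inclusive (>= 20% of AML cells): diagnostic
    profiles with a marker at exactly 20% are counted as LAIPs.
    """
    thresholds = thresholds or ThresholdConfig()
    found = [
        LAIPDefinition(marker, float(profile.expression[marker]))
        for marker in ABERRANT_LINEAGE_MARKERS
        if marker in profile.expression
        and profile.expression[marker] >= thresholds.laip_min_expression_pct
    ]
    found.sort(key=lambda d: (-d.expression_pct, _SPECIFICITY_ORDER.index(d.marker)))
    return found


def select_tracking_marker(laips: list[LAIPDefinition]) -> Marker:
    """The qualifying marker with the highest diagnostic expression.

    Ties are broken by specificity (CD25 > CD56 > CD7 > CD4).
    """
    if not laips:
        raise NoLAIPError("no qualifying LAIP: patient ineligible for MFC-MRD")
    best = max(
        laips,
        key=lambda d: (d.expression_pct, -_SPECIFICITY_ORDER.index(d.marker)),
    )
    return best.marker


def classify_expression(
    tracking_pct: float, thresholds: ThresholdConfig | None = None
) -> str:
    """"total" when the tracking marker covers >= 90% of AML cells, else "partial"."""
    thresholds = thresholds or ThresholdConfig()
    if tracking_pct < thresholds.laip_min_expression_pct:
        raise ValueError(
            f"tracking expression {tracking_pct}% is below the LAIP minimum "
            f"({thresholds.laip_min_expression_pct}%)"
        )
    return "total" if tracking_pct >= thresholds.total_expression_min_pct else "partial"


def classify_patient(
    profile: DiagnosisProfile, thresholds: ThresholdConfig | None = None
) -> PatientLAIPProfile:
    """Full LAIP classification of one diagnostic profile."""
    thresholds = thresholds or ThresholdConfig()
    laips = identify_laips(profile, thresholds)
    tracking = select_tracking_marker(laips)
    tracking_pct = float(profile.expression[tracking])
    return PatientLAIPProfile(
        patient_id=profile.patient_id,
        laips=tuple(laips),
        tracking_marker=tracking,
        expression_class=classify_expression(tracking_pct, thresholds),
        tracking_expression_pct=tracking_pct,
        total_mrd=profile.total_mrd,
    )


def stratify_cohort(
    profiles: list[DiagnosisProfile], thresholds: ThresholdConfig | None = None
) -> pd.DataFrame:
    """Patient and MRD-sample counts per expression class and tracking marker.

    Returns one row per stratum with columns ``stratum``, ``n_patients``,
    ``n_samples``. Strata are the two expression classes plus, within the
    partial class, one stratum per tracking marker.
    """
    thresholds = thresholds or ThresholdConfig()
    classified = [classify_patient(p, thresholds) for p in profiles]
    rows = []
    for cls in ("total", "partial"):
        members = [c for c in classified if c.expression_class == cls]
        rows.append(
            {
                "stratum": cls,
                "n_patients": len(members),
                "n_samples": sum(c.total_mrd for c in members),
            }
        )
    partial = [c for c in classified if c.expression_class == "partial"]
    for marker in _SPECIFICITY_ORDER:
        members = [c for c in partial if c.tracking_marker is marker]
        rows.append(
            {
                "stratum": f"partial/{marker.value}",
                "n_patients": len(members),
                "n_samples": sum(c.total_mrd for c in members),
            }
        )
    return pd.DataFrame(rows)
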