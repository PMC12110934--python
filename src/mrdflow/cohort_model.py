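"""Shared domain types, fixed thresholds, and the packaged diagnosis cohort.

The cohort fixture describes 25 NPM1-mutated AML patients: for each patient
the percentage of leukemic (AML) cells among white blood cells at diagnosis,
the percentage of AML cells positive for each panel marker, and the number of
follow-up MRD samples acquired under each therapy (intensive chemotherapy,
venetoclax + hypomethylating agents, allogeneic stem-cell transplant).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "Marker",
    "MarkerCategory",
    "TherapyLabel",
    "DiagnosisProfile",
    "ThresholdConfig",
    "ABERRANT_LINEAGE_MARKERS",
    "FLUORESCENCE_CHANNELS",
    "SCATTER_CHANNELS",
    "PANEL_CHANNELS",
    "load_table1_fixture",
    "write_fixture",
    "sum_samples_by_therapy",
]


class MarkerCategory(str, enum.Enum):
    SCATTER = "scatter"
    BACKBONE = "backbone"
    MYELOID = "myeloid"
    ABERRANT_LINEAGE = "aberrant-lineage"
    ASYNCHRONOUS = "asynchronous"
    OVEREXPRESSION = "overexpression"


class Marker(str, enum.Enum):
    """Controlled vocabulary of panel channels.

    Aberrant lineage markers (CD4, CD7, CD56, CD25) are the only markers
    eligible to define a LAIP and to serve as the DfN tracking marker.
    CD123 (overexpression) is recorded at diagnosis but never used for MRD:
    its background in normal marrow exceeds the interpretive threshold.
    """

    CD45 = "CD45"
    CD34 = "CD34"
    CD117 = "CD117"
    HLA_DR = "HLA-DR"
    CD13 = "CD13"
    CD33 = "CD33"
    CD4 = "CD4"
    CD7 = "CD7"
    CD56 = "CD56"
    CD25 = "CD25"
    CD15 = "CD15"
    CD11B = "CD11b"
    CD123 = "CD123"
    FSC_A = "FSC-A"
    FSC_H = "FSC-H"
    SSC_A = "SSC-A"

    @property
    def category(self) -> MarkerCategory:
        return _MARKER_CATEGORY[self]

    @property
    def tracking_eligible(self) -> bool:
        return self.category is MarkerCategory.ABERRANT_LINEAGE


_MARKER_CATEGORY: dict[Marker, MarkerCategory] = {
    Marker.FSC_A: MarkerCategory.SCATTER,
    Marker.FSC_H: MarkerCategory.SCATTER,
    Marker.SSC_A: MarkerCategory.SCATTER,
    Marker.CD45: MarkerCategory.BACKBONE,
    Marker.CD34: MarkerCategory.BACKBONE,
    Marker.CD117: MarkerCategory.BACKBONE,
    Marker.HLA_DR: MarkerCategory.BACKBONE,
    Marker.CD13: MarkerCategory.MYELOID,
    Marker.CD33: MarkerCategory.MYELOID,
    Marker.CD4: MarkerCategory.ABERRANT_LINEAGE,
    Marker.CD7: MarkerCategory.ABERRANT_LINEAGE,
    Marker.CD56: MarkerCategory.ABERRANT_LINEAGE,
    Marker.CD25: MarkerCategory.ABERRANT_LINEAGE,
    Marker.CD15: MarkerCategory.ASYNCHRONOUS,
    Marker.CD11B: MarkerCategory.ASYNCHRONOUS,
    Marker.CD123: MarkerCategory.OVEREXPRESSION,
}

ABERRANT_LINEAGE_MARKERS: tuple[Marker, ...] = (
    Marker.CD4,
    Marker.CD7,
    Marker.CD56,
    Marker.CD25,
)

SCATTER_CHANNELS: tuple[str, ...] = ("FSC-A", "FSC-H", "SSC-A")
FLUORESCENCE_CHANNELS: tuple[str, ...] = (
    "CD45", "CD34", "CD117", "HLA-DR", "CD13", "CD33",
    "CD4", "CD7", "CD56", "CD25", "CD15", "CD123",
)
#: every channel a sample event table must carry
PANEL_CHANNELS: tuple[str, ...] = SCATTER_CHANNELS + FLUORESCENCE_CHANNELS


class TherapyLabel(str, enum.Enum):
    """Closed vocabulary of therapy settings for follow-up MRD samples."""

    POST_CHT = "post_CHT"
    POST_VENHMA = "post_VenHMA"
    POST_ALLOSCT = "post_alloSCT"


# fixture column name per therapy
_THERAPY_COLUMNS = {
    TherapyLabel.POST_CHT: "n_post_cht",
    TherapyLabel.POST_VENHMA: "n_post_venhma",
    TherapyLabel.POST_ALLOSCT: "n_post_allosct",
}

# marker columns stored in the fixture, in file order
_FIXTURE_MARKERS = (
    "CD34", "CD117", "CD33", "CD13", "HLA-DR",
    "CD4", "CD7", "CD56", "CD25", "CD15", "CD123",
)


@dataclass(frozen=True)
class DiagnosisProfile:
    """One patient's diagnostic immunophenotype and follow-up sample counts.

    ``expression`` maps each marker to the percent of AML cells positive for
    it at diagnosis (AML+ cells / total AML cells, 0-100). ``aml_pct_of_wbc``
    is the leukemic burden at diagnosis as a percent of CD45+ leukocytes.
    """

    patient_id: str
    aml_pct_of_wbc: float
    expression: Mapping[Marker, float]
    mrd_counts: Mapping[TherapyLabel, int]
    n_laip_reported: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.aml_pct_of_wbc <= 100.0:
            raise ValueError(f"aml_pct_of_wbc out of [0, 100]: {self.aml_pct_of_wbc}")
        for marker, pct in self.expression.items():
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"expression[{marker}] out of [0, 100]: {pct}")
        for therapy, n in self.mrd_counts.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"mrd_counts[{therapy}] must be a non-negative integer")

    @property
    def total_mrd(self) -> int:
        return int(sum(self.mrd_counts.values()))


@dataclass(frozen=True)
class ThresholdConfig:
    """All fixed decision thresholds, on the percent (0-100) scale.

    mfc_positivity_pct
        Default MFC-MRD interpretive threshold: a sample is positive when
        residual LAIP+ cells exceed this percent of CD45+ leukocytes.
    cht_cutoff_pct, venhma_cutoff_pct
        Therapy-specific ROC-derived cut-offs for post-chemotherapy and
        post-Ven+HMA samples.
    npm1_positivity_ratio_pct
        Molecular positivity: NPM1-mutated/ABL1 ratio strictly above this.
    laip_min_expression_pct
        Minimum diagnostic expression for an aberrant lineage marker to
        count as a LAIP (inclusive).
    total_expression_min_pct
        Tracking-marker expression at or above this percent of AML cells is
        "total" expression; below it (but >= laip_min) is "partial".
    abl1_min_copies
        Molecular QC: samples with a lower mean ABL1 copy number are excluded.
    min_events
        Target CD45+ acquisition; fewer events raises a QC flag only.
    """

    mfc_positivity_pct: float = 0.035
    cht_cutoff_pct: float = 0.034
    venhma_cutoff_pct: float = 0.095
    npm1_positivity_ratio_pct: float = 0.01
    laip_min_expression_pct: float = 20.0
    total_expression_min_pct: float = 90.0
    abl1_min_copies: int = 10_000
    min_events: int = 500_000

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if value <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value}")
        if self.total_expression_min_pct <= self.laip_min_expression_pct:
            raise ValueError(
                "total_expression_min_pct must exceed laip_min_expression_pct"
            )

    @classmethod
    def from_file(cls, path: str | Path, **overrides: float) -> "ThresholdConfig":
        """Load thresholds from a YAML/JSON mapping, then apply overrides."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        return replace(cls(**data), **overrides)


def _fixture_path() -> Path:
    return Path(resources.files("mrdflow").joinpath("data/table1.csv"))  # type: ignore[arg-type]


def load_table1_fixture(path: str | Path | None = None) -> list[DiagnosisProfile]:
    """Load the packaged 25-patient diagnosis cohort.

    Returns one :class:`DiagnosisProfile` per patient, in cohort order.
    Raises a :class:`RuntimeError` if the fixture is missing or malformed.
    """
    src = Path(path) if path is not None else _fixture_path()
    try:
        table = pd.read_csv(src)
    except (FileNotFoundError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise RuntimeError(f"diagnosis cohort fixture unreadable: {src}") from exc
    required = {"patient_id", "n_total", "n_laip", "aml_pct", *_FIXTURE_MARKERS,
                *_THERAPY_COLUMNS.values()}
    missing = required - set(table.columns)
    if missing:
        raise RuntimeError(f"diagnosis cohort fixture missing columns: {sorted(missing)}")

    profiles: list[DiagnosisProfile] = []
    for _, row in table.iterrows():
        counts = {t: int(row[col]) for t, col in _THERAPY_COLUMNS.items()}
        if sum(counts.values()) != int(row["n_total"]):
            raise RuntimeError(
                f"fixture row {row['patient_id']}: therapy counts do not sum to n_total"
            )
        profiles.append(
            DiagnosisProfile(
                patient_id=str(int(row["patient_id"])),
                aml_pct_of_wbc=float(row["aml_pct"]),
                expression={Marker(m): float(row[m]) for m in _FIXTURE_MARKERS},
                mrd_counts=counts,
                n_laip_reported=int(row["n_laip"]),
            )
        )
    return profiles


def write_fixture(profiles: list[DiagnosisProfile], path: str | Path) -> None:
    """Write profiles in the fixture's on-disk CSV format (round-trippable)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"patient_id": int(p.patient_id)}
        for therapy, col in _THERAPY_COLUMNS.items():
            row[col] = p.mrd_counts.get(therapy, 0)
        row["n_total"] = p.total_mrd
        row["n_laip"] = p.n_laip_reported
        row["aml_pct"] = _fmt_pct(p.aml_pct_of_wbc)
        for m in _FIXTURE_MARKERS:
            row[m] = _fmt_pct(p.expression[Marker(m)])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _fmt_pct(x: float) -> object:
    return int(x) if float(x).is_integer() else float(x)


def sum_samples_by_therapy(
    profiles: list[DiagnosisProfile],
) -> dict[TherapyLabel, int]:
    """Total follow-up MRD sample counts per therapy across the cohort."""
    totals = {t: 0 for t in TherapyLabel}
    for p in profiles:
        for t in TherapyLabel:
            totals[t] += int(p.mrd_counts.get(t, 0))
    return totals
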