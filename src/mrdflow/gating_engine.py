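"""Patient-specific hierarchical gating: template construction and replay.

The analysis template is built once, on the diagnosis sample, as a rooted
chain of 2-D gates (P1 singlets, P2 CD45+ leukocytes, P3 CD45-dim/SSC-low
blasts, P4.. sequential phenotype gates) plus a lymphocyte side-gate used as
the internal negative control for marker thresholds. At follow-up the stored
geometry is applied verbatim; every gate is a convex polygon in transformed
coordinates (asinh with cofactor 150 for fluorescence, linear for scatter).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_model import (
    DiagnosisProfile,
    FLUORESCENCE_CHANNELS,
    Marker,
    PANEL_CHANNELS,
    SCATTER_CHANNELS,
    TherapyLabel,
    ThresholdConfig,
)

__all__ = [
    "ASINH_COFACTOR",
    "EventTable",
    "GateNode",
    "GatingTemplate",
    "GateCounts",
    "GatingConfig",
    "TemplateFitError",
    "transform_channel",
    "preprocess",
    "marker_threshold",
    "fit_template",
    "apply_template",
    "panel_overlap_qc",
]

ASINH_COFACTOR = 150.0


def transform_channel(values: np.ndarray, channel: str) -> np.ndarray:
    """Gating-scale coordinates: asinh(x/150) for fluorescence, linear scatter."""
    values = np.asarray(values, dtype=float)
    if channel in SCATTER_CHANNELS:
        return values
    return np.arcsinh(values / ASINH_COFACTOR)


@dataclass
class EventTable:
    """Per-event scatter/fluorescence matrix with sample metadata.

    ``data`` holds one row per event and one column per panel channel, in
    arbitrary compensated fluorescence units. ``flags`` (set by
    :func:`preprocess`) records doublet/debris membership without dropping
    events, so preprocessing stays auditable.
    """

    data: pd.DataFrame
    sample_id: str = ""
    patient_id: str = ""
    therapy: TherapyLabel | None = None
    timepoint: str = ""
    flags: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing panel channels: {missing}")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    def transformed(self, channel: str) -> np.ndarray:
        return transform_channel(self.data[channel].to_numpy(), channel)

    @property
    def clean_mask(self) -> np.ndarray:
        """Events that are neither doublets nor debris (requires preprocess)."""
        if self.flags is None:
            raise ValueError("event table not preprocessed: no doublet/debris flags")
        return ~(self.flags["doublet"].to_numpy() | self.flags["debris"].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path, **meta) -> "EventTable":
        return cls(data=pd.read_csv(path), **meta)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class GatingConfig:
    """Tunables of the gating heuristics (documented defaults, not claims
    about any particular cytometer)."""

    debris_fsc_max: float = 30_000.0
    debris_ssc_max: float = 40_000.0
    doublet_band_nsd: float = 3.0          # robust SDs around the singlet FSC-A/FSC-H ratio
    control_min_events: int = 100          # internal negative control size floor
    control_percentile: float = 99.0       # positivity cutoff percentile on the control
    gate_quantiles: tuple[float, float] = (0.001, 0.999)
    gate_margin: float = 0.10              # box expansion as a fraction of the span
    blast_candidate_floor: float = 0.02    # min blast fraction of WBC for a template fit
    blast_min_candidates: int = 50


class TemplateFitError(RuntimeError):
    """Raised when the diagnosis sample cannot support a template (no blasts)."""


# ---------------------------------------------------------------------------
# geometry


def _points_in_convex_polygon(
    px: np.ndarray, py: np.ndarray, vertices: list[tuple[float, float]]
) -> np.ndarray:
    """Membership test for a convex polygon with ordered vertices."""
    verts = np.asarray(vertices, dtype=float)
    if len(verts) < 3:
        raise ValueError("gate geometry needs at least 3 vertices")
    # polygon orientation via the shoelace sum, so vertex order (CW/CCW) is free
    rolled = np.roll(verts, -1, axis=0)
    area2 = float(np.sum(verts[:, 0] * rolled[:, 1] - rolled[:, 0] * verts[:, 1]))
    orient = 1.0 if area2 >= 0 else -1.0
    inside = np.ones(len(px), dtype=bool)
    for i in range(len(verts)):
        x0, y0 = verts[i]
        x1, y1 = verts[(i + 1) % len(verts)]
        cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
        inside &= (orient * cross) >= 0
    return inside


def _rect(x0: float, x1: float, y0: float, y1: float) -> list[tuple[float, float]]:
    return [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]


@dataclass(frozen=True)
class GateNode:
    gate_id: str
    parent: str | None
    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("gate geometry needs at least 3 vertices")

    def membership(self, events: EventTable) -> np.ndarray:
        px = events.transformed(self.x_channel)
        py = events.transformed(self.y_channel)
        return _points_in_convex_polygon(px, py, list(self.vertices))


@dataclass
class GatingTemplate:
    """Ordered gate hierarchy fitted at diagnosis, replayed at follow-up."""

    patient_id: str
    nodes: list[GateNode]
    wbc_gate_id: str
    terminal_gate_id: str
    control_gate_id: str
    tracking_marker: Marker | None = None
    asinh_cofactor: float = ASINH_COFACTOR
    diagnosis_cutoffs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.gate_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gate ids")
        by_id = {n.gate_id: n for n in self.nodes}
        for target in (self.terminal_gate_id, self.control_gate_id):
            node, seen = by_id[target], set()
            while node.parent is not None:
                if node.gate_id in seen:
                    raise ValueError("gate parent chain contains a cycle")
                seen.add(node.gate_id)
                node = by_id[node.parent]
        # the WBC gate must sit on the path from root to the terminal gate
        node = by_id[self.terminal_gate_id]
        path = {node.gate_id}
        while node.parent is not None:
            node = by_id[node.parent]
            path.add(node.gate_id)
        if self.wbc_gate_id not in path:
            raise ValueError("WBC gate is not on the path to the terminal gate")

    def node(self, gate_id: str) -> GateNode:
        return next(n for n in self.nodes if n.gate_id == gate_id)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "patient_id": self.patient_id,
            "wbc_gate_id": self.wbc_gate_id,
            "terminal_gate_id": self.terminal_gate_id,
            "control_gate_id": self.control_gate_id,
            "tracking_marker": self.tracking_marker.value if self.tracking_marker else None,
            "transform": {"type": "asinh", "cofactor": self.asinh_cofactor,
                          "linear_channels": list(SCATTER_CHANNELS)},
            "diagnosis_cutoffs": self.diagnosis_cutoffs,
            "nodes": [
                {
                    "gate_id": n.gate_id,
                    "parent": n.parent,
                    "x_channel": n.x_channel,
                    "y_channel": n.y_channel,
                    "vertices": [list(v) for v in n.vertices],
                    "description": n.description,
                }
                for n in self.nodes
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GatingTemplate":
        text = Path(source).read_text() if isinstance(source, Path) else source
        payload = json.loads(text)
        nodes = [
            GateNode(
                gate_id=n["gate_id"],
                parent=n["parent"],
                x_channel=n["x_channel"],
                y_channel=n["y_channel"],
                vertices=tuple(tuple(v) for v in n["vertices"]),
                description=n.get("description", ""),
            )
            for n in payload["nodes"]
        ]
        return cls(
            patient_id=payload["patient_id"],
            nodes=nodes,
            wbc_gate_id=payload["wbc_gate_id"],
            terminal_gate_id=payload["terminal_gate_id"],
            control_gate_id=payload["control_gate_id"],
            tracking_marker=Marker(payload["tracking_marker"])
            if payload.get("tracking_marker")
            else None,
            asinh_cofactor=payload["transform"]["cofactor"],
            diagnosis_cutoffs=payload.get("diagnosis_cutoffs", {}),
        )


@dataclass
class GateCounts:
    counts: dict[str, int]
    indices: dict[str, np.ndarray]
    qc_flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# operations


def preprocess(events: EventTable, config: GatingConfig | None = None) -> EventTable:
    """Flag doublets and debris without dropping events.

    Doublets: a robust through-origin relation FSC-A = s * FSC-H is fitted on
    the sample itself (s = median ratio); events whose scale-normalized
    residual exceeds ``doublet_band_nsd`` robust SDs are flagged. Debris: the
    low-FSC/low-SSC region.
    """
    config = config or GatingConfig()
    for ch in SCATTER_CHANNELS:
        if ch not in events.data.columns:
            raise ValueError(f"missing scatter channel: {ch}")
    n = events.n_events
    if n == 0:
        flags = pd.DataFrame({"doublet": [], "debris": []}, dtype=bool)
        return replace(events, flags=flags)

    fsc_a = events.data["FSC-A"].to_numpy(dtype=float)
    fsc_h = events.data["FSC-H"].to_numpy(dtype=float)
    ssc_a = events.data["SSC-A"].to_numpy(dtype=float)

    ratio = fsc_a / np.maximum(fsc_h, 1e-9)
    slope = float(np.median(ratio))
    resid = ratio - slope
    mad = float(np.median(np.abs(resid)))
    # floor guards the degenerate zero-spread case (exact FSC-A/FSC-H relation)
    band = max(config.doublet_band_nsd * 1.4826 * mad, 1e-6 * abs(slope))
    doublet = np.abs(resid) > band

    debris = (fsc_a < config.debris_fsc_max) & (ssc_a < config.debris_ssc_max)

    flags = pd.DataFrame({"doublet": doublet, "debris": debris & ~doublet})
    return replace(events, flags=flags)


def marker_threshold(
    events: EventTable,
    marker: Marker | str,
    control: GateNode | np.ndarray,
    config: GatingConfig | None = None,
) -> float:
    """Positivity cutoff for one marker from the internal negative control.

    The cutoff is the 99th percentile of the control population's transformed
    intensity. A control population below ``control_min_events`` events
    triggers a warning and a fallback to the global percentile.
    """
    config = config or GatingConfig()
    channel = marker.value if isinstance(marker, Marker) else marker
    values = events.transformed(channel)
    mask = control.membership(events) if isinstance(control, GateNode) else np.asarray(control, bool)
    selected = values[mask]
    if selected.size < config.control_min_events:
        warnings.warn(
            f"negative control for {channel} has only {selected.size} events; "
            "falling back to the global percentile",
            stacklevel=2,
        )
        selected = values
    if selected.size == 0:
        raise ValueError(f"no events available to threshold {channel}")
    return float(np.percentile(selected, config.control_percentile))


def _quantile_box(
    x: np.ndarray, y: np.ndarray, config: GatingConfig
) -> list[tuple[float, float]]:
    """Axis-aligned box covering the central mass of (x, y), with margin."""
    qlo, qhi = config.gate_quantiles
    x0, x1 = np.quantile(x, [qlo, qhi])
    y0, y1 = np.quantile(y, [qlo, qhi])
    mx = config.gate_margin * max(x1 - x0, 1e-6)
    my = config.gate_margin * max(y1 - y0, 1e-6)
    return _rect(x0 - mx, x1 + mx, y0 - my, y1 + my)


def fit_template(
    diagnosis: EventTable,
    profile: DiagnosisProfile,
    thresholds: ThresholdConfig | None = None,
    config: GatingConfig | None = None,
    tracking_marker: Marker | None = None,
) -> GatingTemplate:
    """Build the patient-specific sequential gating template at diagnosis.

    The blast region is located data-driven from the diagnosis sample (the
    CD117+ CD45-dim cluster); each subsequent 2-D gate is drawn wide enough
    to retain the whole leukemic population regardless of aberrant-marker
    status, mirroring a template that clusters total, partial and absent
    marker expression.
    """
    thresholds = thresholds or ThresholdConfig()
    config = config or GatingConfig()
    if diagnosis.flags is None:
        diagnosis = preprocess(diagnosis, config)

    clean = diagnosis.clean_mask
    if clean.sum() == 0:
        raise TemplateFitError("diagnosis sample has no usable events")

    fsc_a = diagnosis.data["FSC-A"].to_numpy(dtype=float)
    fsc_h = diagnosis.data["FSC-H"].to_numpy(dtype=float)

    # P1: singlet band around the robust FSC-A ~ FSC-H relation
    ratio = fsc_a / np.maximum(fsc_h, 1e-9)
    slope = float(np.median(ratio))
    mad = float(np.median(np.abs(ratio - slope)))
    halfwidth = max(config.doublet_band_nsd * 1.4826 * mad, 1e-6 * slope)
    h_max = float(fsc_h.max()) * 1.5 + 1.0
    p1 = GateNode(
        "P1", None, "FSC-H", "FSC-A",
        vertices=(
            (0.0, 0.0),
            (h_max, (slope - halfwidth) * h_max),
            (h_max, (slope + halfwidth) * h_max),
            (0.0, 0.0 + 1e-6),
        ),
        description="singlets (FSC-A vs FSC-H)",
    )

    cd45 = diagnosis.transformed("CD45")
    ssc = diagnosis.transformed("SSC-A")
    debris_mask = diagnosis.flags["debris"].to_numpy()

    # P2: CD45+ leukocytes; cutoff from the debris region as negative control.
    # A robust location+scale rule keeps the cutoff stable when a few intact
    # cells leak into the scatter-defined debris region.
    if debris_mask.sum() >= config.control_min_events:
        ref = cd45[debris_mask]
        med = float(np.median(ref))
        mad = float(np.median(np.abs(ref - med)))
        cd45_cut = med + 3.5 * 1.4826 * mad
    else:  # no debris present: separate the two main CD45 density modes
        cd45_cut = _valley_threshold(cd45)
    cd45_hi = float(cd45.max()) + 1.0
    ssc_hi = float(ssc.max()) * 1.5 + 1.0
    p2 = GateNode(
        "P2", "P1", "CD45", "SSC-A",
        vertices=tuple(_rect(cd45_cut, cd45_hi, 0.0, ssc_hi)),
        description="WBC: CD45+ leukocytes",
    )

    in_p1 = p1.membership(diagnosis)
    in_p2 = in_p1 & p2.membership(diagnosis) & ~debris_mask
    if in_p2.sum() == 0:
        raise TemplateFitError("no CD45+ leukocytes found at diagnosis")

    # C1: lymphocyte side-gate (CD45-bright, SSC-low) = internal negative control
    wbc_cd45 = cd45[in_p2]
    wbc_ssc = ssc[in_p2]
    # the CD45-brightest few percent with low side scatter are lymphocyte-pure
    # even on heavily infiltrated marrows (blasts and CD117+ progenitors are
    # CD45-dim); purity matters because a percentile cutoff on the control is
    # sensitive to even 1% contamination by antigen-positive cells
    lymph_cd45_lo = float(np.percentile(wbc_cd45, 96))
    lymph_ssc_hi = float(np.percentile(wbc_ssc, 50))
    c1 = GateNode(
        "C1", "P2", "CD45", "SSC-A",
        vertices=tuple(_rect(lymph_cd45_lo, cd45_hi, 0.0, lymph_ssc_hi)),
        description="lymphocytes (internal negative control)",
    )
    control_mask = in_p2 & c1.membership(diagnosis)

    # blast candidates: CD117+ CD45+ events outside the lymphocyte gate
    cutoffs = {
        m.value: marker_threshold(diagnosis, m, control_mask, config)
        for m in (Marker.CD117, Marker.CD34, Marker.CD4, Marker.CD7,
                  Marker.CD56, Marker.CD25)
    }
    cd117 = diagnosis.transformed("CD117")
    seeds = in_p2 & ~control_mask & (cd117 > cutoffs["CD117"])
    n_wbc = int(in_p2.sum())
    if seeds.sum() < config.blast_min_candidates or (
        seeds.sum() / n_wbc < config.blast_candidate_floor
    ):
        raise TemplateFitError(
            f"blast recovery below floor: {int(seeds.sum())} candidate events "
            f"({100 * seeds.sum() / n_wbc:.3f}% of WBC)"
        )

    # P3 blast region in (CD45, SSC): located from the CD117+ seed events.
    # Upper edges use a one-sided robust rule (median + k * lower MAD) so the
    # few CD117-dim lymphocyte/granulocyte tail events that leak into the
    # seeds cannot stretch the gate toward the mature populations.
    def robust_hi(x: np.ndarray) -> float:
        med = float(np.median(x))
        lower = np.abs(x[x <= med] - med)
        return med + 4.5 * 1.4826 * float(np.median(lower))

    qlo = config.gate_quantiles[0]
    seed_cd45 = cd45[seeds]
    seed_ssc = ssc[seeds]
    cd45_lo = float(np.quantile(seed_cd45, qlo))
    ssc_lo = float(np.quantile(seed_ssc, qlo))
    cd45_hi_b = robust_hi(seed_cd45)
    ssc_hi_b = robust_hi(seed_ssc)
    m45 = config.gate_margin * max(cd45_hi_b - cd45_lo, 1e-6)
    mssc = config.gate_margin * max(ssc_hi_b - ssc_lo, 1e-6)
    p3 = GateNode(
        "P3", "P2", "CD45", "SSC-A",
        vertices=tuple(_rect(cd45_lo - m45, cd45_hi_b, 0.0, ssc_hi_b + mssc)),
        description="blasts: CD45-dim, SSC-low",
    )

    # phenotype gates P4..P8 are drawn around ALL events of the blast region
    # (not only CD117+ seeds) so partial or absent expression of any marker —
    # including CD34/CD117 themselves — stays inside the template
    members = in_p2 & p3.membership(diagnosis)

    def box(xc: str, yc: str) -> tuple[tuple[float, float], ...]:
        x = diagnosis.transformed(xc)[members]
        y = diagnosis.transformed(yc)[members]
        return tuple(_quantile_box(x, y, config))

    chain = [
        ("P4", "P3", "CD34", "CD117", "progenitor phenotype (CD34/CD117)"),
        ("P5", "P4", "CD13", "CD33", "myeloid markers"),
        ("P6", "P5", "HLA-DR", "CD15", "backbone/asynchronous markers"),
        ("P7", "P6", "CD4", "CD7", "aberrant lineage markers (all expression levels)"),
        ("P8", "P7", "CD56", "CD25", "aberrant lineage markers (all expression levels)"),
    ]
    nodes = [p1, p2, c1, p3]
    for gate_id, parent, xc, yc, desc in chain:
        nodes.append(GateNode(gate_id, parent, xc, yc, vertices=box(xc, yc),
                              description=desc))

    return GatingTemplate(
        patient_id=profile.patient_id,
        nodes=nodes,
        wbc_gate_id="P2",
        terminal_gate_id="P8",
        control_gate_id="C1",
        tracking_marker=tracking_marker,
        diagnosis_cutoffs=cutoffs,
    )


def _valley_threshold(values: np.ndarray, bins: int = 100) -> float:
    """Threshold at the histogram valley between the two dominant modes."""
    hist, edges = np.histogram(values, bins=bins)
    smooth = np.convolve(hist, np.ones(5) / 5, mode="same")
    peaks = [
        i for i in range(1, bins - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > 0
    ]
    if len(peaks) < 2:
        return float(np.quantile(values, 0.01))
    top = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    valley = top[0] + int(np.argmin(smooth[top[0]:top[1] + 1]))
    return float(edges[valley])


def apply_template(
    template: GatingTemplate,
    events: EventTable,
    min_events: int | None = None,
    config: GatingConfig | None = None,
) -> GateCounts:
    """Replay the stored gate hierarchy on a (preprocessed) sample.

    Counts nest along the hierarchy. A CD45+ count below ``min_events``
    (default: the 500,000-cell acquisition target) adds a low-event QC flag;
    the sample is still quantified.
    """
    config = config or GatingConfig()
    if min_events is None:
        min_events = ThresholdConfig().min_events
    missing = [c for c in PANEL_CHANNELS if c not in events.data.columns]
    if missing:
        raise ValueError(f"channel mismatch: sample lacks {missing}")
    if events.flags is None:
        events = preprocess(events, config)

    debris = events.flags["debris"].to_numpy() if events.n_events else np.zeros(0, bool)
    root_mask = ~debris
    masks: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    indices: dict[str, np.ndarray] = {}
    for node in template.nodes:
        parent_mask = masks[node.parent] if node.parent is not None else root_mask
        if events.n_events == 0:
            mask = np.zeros(0, dtype=bool)
        else:
            mask = parent_mask & node.membership(events)
        masks[node.gate_id] = mask
        counts[node.gate_id] = int(mask.sum())
        indices[node.gate_id] = np.flatnonzero(mask)

    qc_flags = []
    if counts[template.wbc_gate_id] < min_events:
        qc_flags.append("low_events")
    return GateCounts(counts=counts, indices=indices, qc_flags=qc_flags)


def panel_overlap_qc(
    terminal_fraction_a: float, terminal_fraction_b: float, rel_tol: float = 0.20
) -> bool:
    """Cross-check of the two MRD tubes: terminal fractions must agree.

    Returns True (pass) when the relative difference between the two tubes'
    terminal-gate fractions is within ``rel_tol``.
    """
    hi = max(terminal_fraction_a, terminal_fraction_b)
    if hi == 0:
        return True
    return abs(terminal_fraction_a - terminal_fraction_b) / hi <= rel_tol
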