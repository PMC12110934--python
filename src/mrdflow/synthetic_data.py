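"""Synthetic bone-marrow cytometry samples with paired molecular replicates.

The generator emulates the statistical structure the MRD analysis assumes:
a CD45+ leukocyte compartment (lymphocytes, granulocytes, normal CD117+
progenitors, leukemic blasts) plus debris and doublets; per-channel
log-normal intensities on the raw scale; latent per-event Bernoulli marker
positivity (partial aberrant expression on blasts, a small LAIP+ background
on normal progenitors); and triplicate RT-qPCR copy numbers whose expected
NPM1-mutant/ABL1 ratio is proportional to the true leukemic fraction.

Every sample carries ground-truth labels so downstream gating and
quantification can be scored without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import (
    ABERRANT_LINEAGE_MARKERS,
    DiagnosisProfile,
    FLUORESCENCE_CHANNELS,
    Marker,
    TherapyLabel,
)
from .gating_engine import EventTable

__all__ = [
    "PopulationSpec",
    "SimulationConfig",
    "MolecularCoupling",
    "TruthLabels",
    "FollowupSample",
    "SyntheticCohort",
    "make_config",
    "simulate_sample",
    "simulate_diagnosis_from_profile",
    "simulate_molecular",
    "simulate_cohort",
]

WBC_POPULATIONS = ("lymphocytes", "granulocytes", "normal_progenitors", "blasts")

# two-component fluorescence model (raw-scale log-normal): negative events sit
# at autofluorescence level, positive events around the stained level
NEGATIVE_COMPONENT = (40.0, 0.45)   # (median, log-scale sigma)
POSITIVE_COMPONENT = (1200.0, 0.40)

# per-population (median, sigma) for scatter and CD45; CD45 is modelled as a
# single component per population (dim on blasts, bright on lymphocytes)
_BASE_CHANNEL_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "lymphocytes": {"FSC-A": (60_000, 0.15), "SSC-A": (15_000, 0.20), "CD45": (5_000, 0.30)},
    "granulocytes": {"FSC-A": (75_000, 0.15), "SSC-A": (65_000, 0.20), "CD45": (1_800, 0.30)},
    "normal_progenitors": {"FSC-A": (55_000, 0.18), "SSC-A": (20_000, 0.25), "CD45": (2_000, 0.35)},
    "blasts": {"FSC-A": (55_000, 0.18), "SSC-A": (18_000, 0.25), "CD45": (500, 0.35)},
    "debris": {"FSC-A": (10_000, 0.40), "SSC-A": (8_000, 0.50), "CD45": (30, 0.50)},
}

# baseline marker positivity per population (fraction of the population);
# blasts are overridden from the diagnosis profile, progenitor aberrant
# markers from the configured normal-marrow background
_BASE_POSITIVITY: dict[str, dict[Marker, float]] = {
    "lymphocytes": {},
    "granulocytes": {Marker.CD13: 1.0, Marker.CD33: 1.0, Marker.CD15: 1.0},
    "normal_progenitors": {
        Marker.CD34: 0.70, Marker.CD117: 1.0, Marker.CD13: 1.0,
        Marker.CD33: 1.0, Marker.HLA_DR: 1.0, Marker.CD15: 0.05,
        Marker.CD123: 0.10,
    },
    "blasts": {
        Marker.CD34: 0.80, Marker.CD117: 1.0, Marker.CD13: 1.0,
        Marker.CD33: 1.0, Marker.HLA_DR: 1.0,
    },
    "debris": {},
}

#: normal/regenerating-marrow LAIP+ background, percent of WBC per marker.
#: Values sit inside the reference range measured on control marrows
#: (0-0.034% of WBC): CD4 is the least specific aberrancy, CD25 the most.
DEFAULT_BACKGROUND_LAIP_PCT: dict[Marker, float] = {
    Marker.CD4: 0.020,
    Marker.CD7: 0.010,
    Marker.CD56: 0.005,
    Marker.CD25: 0.002,
}

_FSC_H_SLOPE = 0.95      # singlet FSC-H = slope * FSC-A with tight noise
_FSC_H_SIGMA = 0.03


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    fraction: float
    channel_params: Mapping[str, tuple[float, float]]
    marker_positive_fraction: Mapping[Marker, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, f in self.marker_positive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: positive fraction for {m} out of [0,1]")


@dataclass(frozen=True)
class SimulationConfig:
    n_events: int
    seed: int
    populations: tuple[PopulationSpec, ...]
    true_leukemic_fraction: float
    laip_expression_fraction: Mapping[Marker, float] = field(default_factory=dict)
    background_laip_pct: Mapping[Marker, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_LAIP_PCT)
    )
    doublet_rate: float = 0.03
    debris_rate: float = 0.05

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")


@dataclass(frozen=True)
class MolecularCoupling:
    """Links the true leukemic fraction to expected RT-qPCR copy numbers.

    With the defaults, expected ratio_pct = 0.3 * true leukemic percent: a
    sample at the 0.035% flow threshold sits just above the 0.01% molecular
    positivity threshold, so the two assays agree in expectation.
    """

    copies_per_fraction: float = 30_000.0
    abl1_mean_copies: float = 100_000.0
    replicate_cv: float = 0.15

    def __post_init__(self) -> None:
        if min(self.copies_per_fraction, self.abl1_mean_copies, self.replicate_cv) <= 0:
            raise ValueError("all molecular coupling parameters must be positive")


@dataclass
class TruthLabels:
    """Ground truth for one simulated sample."""

    population: np.ndarray                 # per-event population name ("doublet" for doublets)
    marker_positive: pd.DataFrame          # per-event latent positivity (bool, one col/marker)
    true_mrd_pct: float                    # blasts as percent of singlet WBC events

    def __post_init__(self) -> None:
        if len(self.population) != len(self.marker_positive):
            raise ValueError("label count must equal event count")


def make_config(
    n_events: int,
    seed: int,
    true_leukemic_fraction: float,
    laip_expression_fraction: Mapping[Marker, float] | None = None,
    background_laip_pct: Mapping[Marker, float] | None = None,
    progenitor_fraction: float = 0.004,
    doublet_rate: float = 0.03,
    debris_rate: float = 0.05,
    blast_positivity: Mapping[Marker, float] | None = None,
) -> SimulationConfig:
    """Assemble a :class:`SimulationConfig` from high-level knobs.

    ``true_leukemic_fraction`` and ``progenitor_fraction`` are proportions of
    the CD45+ (WBC) compartment; the remaining WBC events split 35/65 between
    lymphocytes and granulocytes.
    """
    if not 0.0 <= true_leukemic_fraction <= 1.0:
        raise ValueError("true_leukemic_fraction must lie in [0, 1]")
    background = dict(DEFAULT_BACKGROUND_LAIP_PCT if background_laip_pct is None
                      else background_laip_pct)
    laip = dict(laip_expression_fraction or {})

    wbc_share = 1.0 - debris_rate
    rest = 1.0 - true_leukemic_fraction - progenitor_fraction
    if rest < 0:
        raise ValueError("leukemic + progenitor fractions exceed 1")
    wbc_fractions = {
        "lymphocytes": 0.35 * rest,
        "granulocytes": 0.65 * rest,
        "normal_progenitors": progenitor_fraction,
        "blasts": true_leukemic_fraction,
    }

    populations = []
    for name in WBC_POPULATIONS + ("debris",):
        positivity = dict(_BASE_POSITIVITY[name])
        if name == "blasts":
            if blast_positivity is not None:
                positivity.update(blast_positivity)
            positivity.update(laip)
        if name == "normal_progenitors":
            # convert %-of-WBC background rates into within-population rates
            for marker, pct in background.items():
                rate = 0.0 if progenitor_fraction == 0 else min(
                    (pct / 100.0) / progenitor_fraction, 1.0
                )
                positivity[marker] = rate
        fraction = debris_rate if name == "debris" else wbc_share * wbc_fractions[name]
        populations.append(
            PopulationSpec(
                name=name,
                fraction=fraction,
                channel_params=_BASE_CHANNEL_PARAMS[name],
                marker_positive_fraction=positivity,
            )
        )
    return SimulationConfig(
        n_events=n_events,
        seed=seed,
        populations=tuple(populations),
        true_leukemic_fraction=true_leukemic_fraction,
        laip_expression_fraction=laip,
        background_laip_pct=background,
        doublet_rate=doublet_rate,
        debris_rate=debris_rate,
    )


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    return median * np.exp(rng.normal(0.0, sigma, n))


def _draw_singlets(
    rng: np.random.Generator, config: SimulationConfig, counts: Sequence[int]
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Draw singlet events population by population."""
    frames, pop_labels, positives = [], [], []
    markers = [Marker(ch) for ch in FLUORESCENCE_CHANNELS if ch != "CD45"]
    for spec, n in zip(config.populations, counts):
        if n == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        for ch in ("FSC-A", "SSC-A", "CD45"):
            median, sigma = spec.channel_params[ch]
            cols[ch] = _lognormal(rng, median, sigma, n)
        cols["FSC-H"] = _FSC_H_SLOPE * cols["FSC-A"] * np.exp(
            rng.normal(0.0, _FSC_H_SIGMA, n)
        )
        pos_frame: dict[str, np.ndarray] = {}
        for marker in markers:
            frac = float(spec.marker_positive_fraction.get(marker, 0.0))
            if frac >= 1.0:
                is_pos = np.ones(n, dtype=bool)
            elif frac <= 0.0:
                is_pos = np.zeros(n, dtype=bool)
            else:
                is_pos = rng.random(n) < frac
            neg = _lognormal(rng, *NEGATIVE_COMPONENT, n)
            pos = _lognormal(rng, *POSITIVE_COMPONENT, n)
            cols[marker.value] = np.where(is_pos, pos, neg)
            pos_frame[marker.value] = is_pos
        frames.append(pd.DataFrame(cols))
        positives.append(pd.DataFrame(pos_frame))
        pop_labels.append(np.full(n, spec.name))
    if not frames:
        empty_cols = {ch: np.zeros(0) for ch in ("FSC-A", "FSC-H", "SSC-A")}
        empty_cols.update({ch: np.zeros(0) for ch in FLUORESCENCE_CHANNELS})
        empty_pos = {m.value: np.zeros(0, bool) for m in markers}
        return pd.DataFrame(empty_cols), np.zeros(0, dtype="<U20"), pd.DataFrame(empty_pos)
    return (
        pd.concat(frames, ignore_index=True),
        np.concatenate(pop_labels),
        pd.concat(positives, ignore_index=True),
    )


def simulate_sample(
    config: SimulationConfig, sample_id: str = "", **meta
) -> tuple[EventTable, TruthLabels]:
    """Simulate one acquisition: event table plus ground-truth labels.

    Doublets are synthesized by summing two WBC singlets' area signals while
    keeping FSC-H near the larger singlet, so the FSC-A vs FSC-H gate can
    separate them. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_doublets = int(round(config.doublet_rate * config.n_events))
    n_singlets = config.n_events - n_doublets

    fractions = np.array([p.fraction for p in config.populations])
    counts = rng.multinomial(n_singlets, fractions) if n_singlets > 0 else np.zeros(
        len(fractions), dtype=int
    )
    data, pops, positive = _draw_singlets(rng, config, counts)

    # doublets: pairs drawn from the cellular (non-debris) populations
    if n_doublets > 0:
        cellular = [p for p in config.populations if p.name != "debris"]
        cell_fracs = np.array([p.fraction for p in cellular])
        cell_fracs = cell_fracs / cell_fracs.sum()
        pair_counts = rng.multinomial(2 * n_doublets, cell_fracs)
        cfg_pairs = SimulationConfig(
            n_events=2 * n_doublets,
            seed=config.seed,
            populations=tuple(
                PopulationSpec(p.name, f, p.channel_params, p.marker_positive_fraction)
                for p, f in zip(cellular, cell_fracs)
            ),
            true_leukemic_fraction=config.true_leukemic_fraction,
            doublet_rate=0.0,
            debris_rate=0.0,
        )
        comp, _, _ = _draw_singlets(rng, cfg_pairs, pair_counts)
        a = comp.iloc[:n_doublets].reset_index(drop=True)
        b = comp.iloc[n_doublets:].reset_index(drop=True)
        doublet = a + b
        doublet["FSC-H"] = _FSC_H_SLOPE * np.maximum(
            a["FSC-A"], b["FSC-A"]
        ) * np.exp(rng.normal(0.0, _FSC_H_SIGMA, n_doublets))
        data = pd.concat([data, doublet], ignore_index=True)
        pops = np.concatenate([pops, np.full(n_doublets, "doublet")])
        positive = pd.concat(
            [positive, pd.DataFrame(False, index=range(n_doublets),
                                    columns=positive.columns)],
            ignore_index=True,
        )

    wbc = np.isin(pops, WBC_POPULATIONS)
    n_blasts = int((pops == "blasts").sum())
    true_mrd_pct = 100.0 * n_blasts / wbc.sum() if wbc.sum() else 0.0

    order = ["FSC-A", "FSC-H", "SSC-A", *FLUORESCENCE_CHANNELS]
    events = EventTable(data=data[order], sample_id=sample_id, **meta)
    labels = TruthLabels(population=pops, marker_positive=positive,
                         true_mrd_pct=true_mrd_pct)
    return events, labels


def simulate_diagnosis_from_profile(
    profile: DiagnosisProfile,
    n_events: int = 100_000,
    seed: int = 0,
    **knobs,
) -> tuple[EventTable, TruthLabels]:
    """Simulate a diagnosis acquisition matching a patient's immunophenotype.

    Blasts occupy the profile's AML percent of the WBC compartment and every
    marker's positive fraction among blasts follows the diagnostic
    expression percentages.
    """
    blast_positivity = {m: pct / 100.0 for m, pct in profile.expression.items()}
    config = make_config(
        n_events=n_events,
        seed=seed,
        true_leukemic_fraction=profile.aml_pct_of_wbc / 100.0,
        blast_positivity=blast_positivity,
        **knobs,
    )
    return simulate_sample(config, sample_id=f"dx_{profile.patient_id}",
                           patient_id=profile.patient_id, timepoint="diagnosis")


def simulate_molecular(
    true_fraction: float,
    coupling: MolecularCoupling | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Triplicate NPM1-mutant and ABL1 copy numbers for one sample.

    Replicates carry log-normal error at the configured CV on top of Poisson
    counting noise; a truly negative sample yields exactly zero NPM1 copies.
    """
    coupling = coupling or MolecularCoupling()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(coupling.replicate_cv ** 2)))

    mu_npm1 = coupling.copies_per_fraction * true_fraction
    if mu_npm1 <= 0:
        npm1 = np.zeros(3)
    else:
        lam = mu_npm1 * np.exp(rng.normal(0.0, sigma, 3) - sigma ** 2 / 2)
        npm1 = rng.poisson(lam).astype(float)
    lam_abl = coupling.abl1_mean_copies * np.exp(
        rng.normal(0.0, sigma, 3) - sigma ** 2 / 2
    )
    abl1 = np.round(lam_abl)
    return npm1, abl1


@dataclass
class FollowupSample:
    sample_id: str
    patient_id: str
    therapy: TherapyLabel
    true_level_pct: float          # configured true MRD level (percent of WBC)
    events: EventTable
    truth: TruthLabels
    npm1_copies: np.ndarray
    abl1_copies: np.ndarray


@dataclass
class SyntheticCohort:
    """Lazy cohort: the manifest is materialized, events are generated on
    demand so a full 125-sample cohort never sits in memory at once.

    Per-sample seeds derive from the master seed by a counter scheme
    (``SeedSequence([master, patient_index, sample_index])``), so any sample
    is reproducible in isolation.
    """

    seed: int
    profiles: list[DiagnosisProfile]
    manifest: pd.DataFrame
    n_events: int
    diagnosis_n_events: int
    coupling: MolecularCoupling
    progenitor_range: tuple[float, float]

    def _seed(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *key]))

    def diagnosis(self, patient_index: int) -> tuple[EventTable, TruthLabels]:
        profile = self.profiles[patient_index]
        sub = int(self._seed(patient_index, 0).integers(2 ** 31))
        return simulate_diagnosis_from_profile(
            profile, n_events=self.diagnosis_n_events, seed=sub
        )

    def followup(self, row_index: int) -> FollowupSample:
        row = self.manifest.iloc[row_index]
        profile = self.profiles[int(row["patient_index"])]
        sub = int(
            self._seed(int(row["patient_index"]), int(row["sample_index"]) + 1).integers(2 ** 31)
        )
        blast_positivity = {m: p / 100.0 for m, p in profile.expression.items()}
        config = make_config(
            n_events=self.n_events,
            seed=sub,
            true_leukemic_fraction=row["true_level_pct"] / 100.0,
            blast_positivity=blast_positivity,
            progenitor_fraction=float(row["progenitor_fraction"]),
        )
        events, truth = simulate_sample(
            config,
            sample_id=str(row["sample_id"]),
            patient_id=profile.patient_id,
            therapy=TherapyLabel(row["therapy"]),
            timepoint="followup",
        )
        npm1, abl1 = simulate_molecular(
            truth.true_mrd_pct / 100.0, self.coupling,
            self._seed(int(row["patient_index"]), int(row["sample_index"]) + 1, 7),
        )
        return FollowupSample(
            sample_id=str(row["sample_id"]),
            patient_id=profile.patient_id,
            therapy=TherapyLabel(row["therapy"]),
            true_level_pct=float(row["true_level_pct"]),
            events=events,
            truth=truth,
            npm1_copies=npm1,
            abl1_copies=abl1,
        )


def simulate_cohort(
    n_patients: int = 25,
    samples_per_patient: int = 5,
    therapy_mix: Mapping[TherapyLabel, float] | None = None,
    seed: int = 0,
    profiles: list[DiagnosisProfile] | None = None,
    n_events: int = 120_000,
    diagnosis_n_events: int = 80_000,
    negative_fraction: float = 0.32,
    level_range_pct: tuple[float, float] = (0.01, 2.0),
    progenitor_range: tuple[float, float] = (0.0005, 0.008),
    coupling: MolecularCoupling | None = None,
) -> SyntheticCohort:
    """Plan a paired MFC + molecular cohort with known ground truth.

    Each patient contributes one diagnosis sample and ``samples_per_patient``
    follow-ups whose true MRD levels are 0 with probability
    ``negative_fraction`` and otherwise log-uniform over ``level_range_pct``
    (percent of WBC). Therapies are drawn from ``therapy_mix``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if profiles is None:
        from .cohort_model import load_table1_fixture

        base = load_table1_fixture()
        profiles = [base[i % len(base)] for i in range(n_patients)]
    else:
        profiles = list(profiles)[:n_patients]
    if len(profiles) < n_patients:
        raise ValueError("not enough diagnosis profiles for the requested cohort")

    if therapy_mix is None:
        therapy_mix = {
            TherapyLabel.POST_CHT: 62 / 125,
            TherapyLabel.POST_VENHMA: 58 / 125,
            TherapyLabel.POST_ALLOSCT: 5 / 125,
        }
    labels = list(therapy_mix.keys())
    probs = np.array([therapy_mix[t] for t in labels], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(np.random.SeedSequence([seed, 999_983]))
    lo, hi = level_range_pct
    rows = []
    for pi in range(n_patients):
        for si in range(samples_per_patient):
            negative = rng.random() < negative_fraction
            level = 0.0 if negative else float(
                np.exp(rng.uniform(np.log(lo), np.log(hi)))
            )
            therapy = labels[int(rng.choice(len(labels), p=probs))]
            prog = float(np.exp(rng.uniform(*np.log(progenitor_range))))
            rows.append(
                {
                    "sample_id": f"pt{profiles[pi].patient_id}_s{si + 1}",
                    "patient_index": pi,
                    "patient_id": profiles[pi].patient_id,
                    "sample_index": si,
                    "therapy": therapy.value,
                    "true_level_pct": level,
                    "truly_negative": negative,
                    "progenitor_fraction": prog,
                }
            )
    return SyntheticCohort(
        seed=seed,
        profiles=profiles,
        manifest=pd.DataFrame(rows),
        n_events=n_events,
        diagnosis_n_events=diagnosis_n_events,
        coupling=coupling or MolecularCoupling(),
        progenitor_range=progenitor_range,
    )
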