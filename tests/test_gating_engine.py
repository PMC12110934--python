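import numpy as np
import pandas as pd
import pytest

import mrdflow as mf
from mrdflow.cohort_model import Marker, PANEL_CHANNELS
from mrdflow.gating_engine import (
    GateNode,
    GatingTemplate,
    TemplateFitError,
    _points_in_convex_polygon,
    transform_channel,
)
from mrdflow.synthetic_data import make_config


def _blank_table(n=0):
    data = pd.DataFrame({ch: np.zeros(n) for ch in PANEL_CHANNELS})
    return mf.EventTable(data=data)


class TestGeometry:
    def test_convex_polygon_membership_independent_of_vertex_order(self):
        square_ccw = [(0, 0), (2, 0), (2, 2), (0, 2)]
        square_cw = list(reversed(square_ccw))
        px = np.array([1.0, 3.0, -0.1, 2.0])
        py = np.array([1.0, 1.0, 1.0, 2.0])
        expected = np.array([True, False, False, True])  # edges inclusive
        assert (_points_in_convex_polygon(px, py, square_ccw) == expected).all()
        assert (_points_in_convex_polygon(px, py, square_cw) == expected).all()

    def test_gate_needs_three_vertices(self):
        with pytest.raises(ValueError):
            GateNode("G", None, "CD45", "SSC-A", vertices=((0, 0), (1, 1)))

    def test_scatter_channels_stay_linear_fluorescence_asinh(self):
        x = np.array([0.0, 150.0, 1500.0])
        assert (transform_channel(x, "FSC-A") == x).all()
        np.testing.assert_allclose(transform_channel(x, "CD45"), np.arcsinh(x / 150.0))


class TestPreprocess:
    def test_flags_injected_doublets(self):
        cfg = make_config(n_events=40_000, seed=2, true_leukemic_fraction=0.05,
                          doublet_rate=0.05)
        events, truth = mf.simulate_sample(cfg)
        events = mf.preprocess(events)
        dbl = truth.population == "doublet"
        assert events.flags["doublet"].to_numpy()[dbl].mean() >= 0.95

    def test_flags_injected_debris(self):
        cfg = make_config(n_events=40_000, seed=2, true_leukemic_fraction=0.05)
        events, truth = mf.simulate_sample(cfg)
        events = mf.preprocess(events)
        deb = truth.population == "debris"
        assert events.flags["debris"].to_numpy()[deb].mean() >= 0.95

    def test_clean_table_has_zero_flags(self):
        n = 1_000
        fsc = np.linspace(50_000, 90_000, n)
        data = pd.DataFrame({ch: np.full(n, 1_000.0) for ch in PANEL_CHANNELS})
        data["FSC-A"] = fsc
        data["FSC-H"] = fsc * 0.95  # exact singlet relation: zero-width band
        data["SSC-A"] = np.full(n, 50_000.0)
        events = mf.preprocess(mf.EventTable(data=data))
        assert not events.flags["doublet"].any()
        assert not events.flags["debris"].any()

    def test_empty_table(self):
        events = mf.preprocess(_blank_table(0))
        assert events.flags is not None and len(events.flags) == 0

    def test_missing_scatter_channel_is_an_input_error(self):
        table = _blank_table(5)
        table.data = table.data.drop(columns=["FSC-H"])
        with pytest.raises(ValueError):
            mf.preprocess(table)


class TestMarkerThreshold:
    def test_about_one_percent_of_control_exceeds_cutoff(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame({ch: np.zeros(10_000) for ch in PANEL_CHANNELS})
        data["CD7"] = rng.lognormal(np.log(40), 0.45, 10_000)
        events = mf.EventTable(data=data)
        cutoff = mf.marker_threshold(events, Marker.CD7, np.ones(10_000, bool))
        exceed = (events.transformed("CD7") > cutoff).mean()
        assert exceed == pytest.approx(0.01, abs=0.003)

    def test_constant_control_returns_that_constant(self):
        data = pd.DataFrame({ch: np.full(200, 100.0) for ch in PANEL_CHANNELS})
        events = mf.EventTable(data=data)
        cutoff = mf.marker_threshold(events, Marker.CD4, np.ones(200, bool))
        assert cutoff == pytest.approx(np.arcsinh(100 / 150))

    def test_small_control_warns_and_falls_back_to_global(self):
        data = pd.DataFrame({ch: np.full(500, 100.0) for ch in PANEL_CHANNELS})
        events = mf.EventTable(data=data)
        mask = np.zeros(500, bool)
        mask[:10] = True
        with pytest.warns(UserWarning):
            mf.marker_threshold(events, Marker.CD4, mask)

    def test_separated_positives_called_positive(self, pt8_diagnosis, pt8_template):
        events, truth = pt8_diagnosis
        c1 = pt8_template.node("C1")
        cutoff = mf.marker_threshold(events, Marker.CD25, c1)
        blasts = truth.population == "blasts"
        pos = truth.marker_positive["CD25"].to_numpy() & blasts
        called = events.transformed("CD25")[pos] > cutoff
        assert called.mean() >= 0.95


class TestTemplate:
    def test_terminal_gate_recovers_blasts_at_diagnosis(self, pt8_diagnosis, pt8_template):
        events, truth = pt8_diagnosis
        counts = mf.apply_template(pt8_template, events, min_events=500_000)
        mask = np.zeros(events.n_events, bool)
        mask[counts.indices["P8"]] = True
        blasts = truth.population == "blasts"
        assert mask[blasts].mean() >= 0.95

    def test_terminal_fraction_matches_aml_percent(self, pt8, pt8_diagnosis, pt8_template):
        events, _ = pt8_diagnosis
        counts = mf.apply_template(pt8_template, events, min_events=500_000)
        fraction = 100 * counts.counts["P8"] / counts.counts["P2"]
        p = pt8.aml_pct_of_wbc / 100
        sd = 100 * np.sqrt(p * (1 - p) / counts.counts["P2"])
        # template background (progenitors, rare mature-cell leak) only adds
        assert fraction == pytest.approx(pt8.aml_pct_of_wbc, abs=3 * sd + 1.0)

    def test_no_blasts_fails_template_fit(self, pt8):
        cfg = make_config(n_events=40_000, seed=3, true_leukemic_fraction=0.0)
        events, _ = mf.simulate_sample(cfg)
        with pytest.raises(TemplateFitError):
            mf.fit_template(mf.preprocess(events), pt8)

    def test_template_round_trips_through_json(self, pt8_template, tmp_path):
        path = tmp_path / "template.json"
        pt8_template.to_json(path)
        loaded = GatingTemplate.from_json(path)
        assert loaded.patient_id == pt8_template.patient_id
        assert loaded.tracking_marker == pt8_template.tracking_marker
        assert [n.gate_id for n in loaded.nodes] == [n.gate_id for n in pt8_template.nodes]
        for a, b in zip(loaded.nodes, pt8_template.nodes):
            assert a.vertices == b.vertices

    def test_wbc_gate_must_lie_on_terminal_path(self, pt8_template):
        with pytest.raises(ValueError):
            GatingTemplate(
                patient_id="x",
                nodes=list(pt8_template.nodes),
                wbc_gate_id="C1",  # side gate, not on the chain to P8
                terminal_gate_id="P8",
                control_gate_id="C1",
            )


class TestApplyTemplate:
    def test_counts_nest_along_the_chain(self, pt8_diagnosis, pt8_template):
        events, _ = pt8_diagnosis
        counts = mf.apply_template(pt8_template, events, min_events=500_000)
        chain = ["P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8"]
        for parent, child in zip(chain, chain[1:]):
            assert counts.counts[child] <= counts.counts[parent]

    def test_empty_table_gives_zero_counts(self, pt8_template):
        counts = mf.apply_template(pt8_template, _blank_table(0))
        assert all(v == 0 for v in counts.counts.values())

    def test_low_event_acquisition_flagged_not_rejected(self, pt8_diagnosis, pt8_template):
        events, _ = pt8_diagnosis
        counts = mf.apply_template(pt8_template, events, min_events=500_000)
        assert "low_events" in counts.qc_flags
        counts_ok = mf.apply_template(pt8_template, events, min_events=1_000)
        assert "low_events" not in counts_ok.qc_flags

    def test_channel_mismatch_is_an_input_error(self, pt8_template):
        table = _blank_table(10)
        table.data = table.data.drop(columns=["CD25"])
        with pytest.raises(ValueError):
            mf.apply_template(pt8_template, table)

    def test_deterministic_replay(self, pt8_diagnosis, pt8_template):
        events, _ = pt8_diagnosis
        a = mf.apply_template(pt8_template, events, min_events=500_000)
        b = mf.apply_template(pt8_template, events, min_events=500_000)
        assert a.counts == b.counts

    def test_residual_blasts_captured_at_followup(self, pt8, pt8_template):
        events, truth = mf.simulate_diagnosis_from_profile(pt8, n_events=0, seed=0)
        cfg_level = 0.005
        from mrdflow.synthetic_data import make_config as mk
        cfg = mk(
            n_events=200_000, seed=88, true_leukemic_fraction=cfg_level,
            blast_positivity={m: v / 100 for m, v in pt8.expression.items()},
        )
        events, truth = mf.simulate_sample(cfg)
        counts = mf.apply_template(pt8_template, mf.preprocess(events), min_events=500_000)
        mask = np.zeros(events.n_events, bool)
        mask[counts.indices["P8"]] = True
        blasts = truth.population == "blasts"
        assert mask[blasts].mean() >= 0.90


def test_panel_overlap_qc_tolerance():
    from mrdflow.gating_engine import panel_overlap_qc

    assert panel_overlap_qc(0.50, 0.55)
    assert not panel_overlap_qc(0.50, 0.30)
    assert panel_overlap_qc(0.0, 0.0)
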