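"""Threshold derivation, quadrant assignment, background correction."""

import numpy as np
import pandas as pd
import pytest

from hxfacs.gating import (
    EmptyGateError,
    GateConfig,
    GateThresholds,
    MissingControlError,
    apply_gates,
    derive_thresholds,
    quantify,
)
from hxfacs.simulate import EventTable, SamplePanel, preset_panel, simulate_panel, tumor_mixture


def _tube(fsc=5e4, ssc=3e4, cd45=0.0, egfr_ab=0.0, hx103=0.0, n=None, **cols):
    """Build a minimal EventTable from scalars or arrays."""
    arrays = {"fsc": fsc, "ssc": ssc, "cd45": cd45, "egfr_ab": egfr_ab, "hx103": hx103}
    arrays.update(cols)
    n = n or max(np.size(v) for v in arrays.values())
    data = {k: np.broadcast_to(np.asarray(v, dtype=float), n).copy() for k, v in arrays.items()}
    df = pd.DataFrame(data)
    df.insert(0, "event_id", np.arange(n))
    return EventTable(df)


def _panel(dmso, isotype, stained, blocked, specimen_id="toy"):
    return SamplePanel(
        specimen_id=specimen_id,
        tubes={
            "dmso_control": dmso,
            "isotype_control": isotype,
            "stained": stained,
            "gefitinib_blocked": blocked,
        },
    )


class TestDeriveThresholds:
    def test_quantile_one_takes_control_maximum(self):
        dmso = _tube(hx103=np.arange(1.0, 101.0))
        iso = _tube(egfr_ab=np.arange(1.0, 101.0), n=100)
        panel = _panel(dmso, iso, dmso, dmso)
        th = derive_thresholds(panel, GateConfig())
        assert th.hx103_cut == 100.0
        assert th.egfr_cut == 100.0

    def test_sub_unit_quantile_interpolates(self):
        values = np.arange(1.0, 101.0)
        dmso = _tube(hx103=values)
        iso = _tube(egfr_ab=values, n=100)
        panel = _panel(dmso, iso, dmso, dmso)
        th = derive_thresholds(panel, GateConfig(control_quantile=0.999))
        assert th.hx103_cut == pytest.approx(np.quantile(values, 0.999))

    def test_too_few_control_events(self):
        small = _tube(hx103=np.arange(10.0))
        panel = _panel(small, small, small, small)
        with pytest.raises(MissingControlError):
            derive_thresholds(panel, GateConfig())

    def test_scatter_gate_counts_monotone(self):
        panel = simulate_panel(tumor_mixture(0.5), n_events=2000, seed=8)
        th = derive_thresholds(panel, GateConfig())
        assert 0 < th.n_events_after_cd45 <= th.n_events_after_scatter <= 2000


class TestApplyGates:
    TH = GateThresholds(hx103_cut=10.0, egfr_cut=10.0, cd45_cut=1e9,
                        n_events_after_scatter=4, n_events_after_cd45=4)

    def test_one_event_per_quadrant(self):
        tube = _tube(egfr_ab=np.array([20.0, 20.0, 5.0, 5.0]),
                     hx103=np.array([5.0, 20.0, 20.0, 5.0]))
        gated = apply_gates(tube, self.TH, GateConfig())
        assert sorted(gated["quadrant"]) == ["Q1", "Q2", "Q3", "Q4"]

    def test_all_below_cuts_is_all_q4(self):
        tube = _tube(egfr_ab=np.full(10, 1.0), hx103=np.full(10, 1.0))
        gated = apply_gates(tube, self.TH, GateConfig())
        assert (gated["quadrant"] == "Q4").all()

    def test_tie_with_cut_is_negative(self):
        tube = _tube(egfr_ab=np.array([10.0]), hx103=np.array([10.0]))
        gated = apply_gates(tube, self.TH, GateConfig())
        assert gated["quadrant"].iloc[0] == "Q4"

    def test_empty_gate_names_stage(self):
        tube = _tube(fsc=np.full(5, 1.0))  # everything fails the scatter floor
        with pytest.raises(EmptyGateError, match="scatter"):
            apply_gates(tube, self.TH, GateConfig())
        tube2 = _tube(cd45=np.full(5, 1e6))
        th = GateThresholds(10.0, 10.0, cd45_cut=100.0,
                            n_events_after_scatter=5, n_events_after_cd45=0)
        with pytest.raises(EmptyGateError, match="CD45"):
            apply_gates(tube2, th, GateConfig())


class TestQuantify:
    def test_stained_identical_to_dmso_corrects_to_zero(self):
        rng = np.random.default_rng(0)
        tube = _tube(hx103=rng.uniform(0, 100, 500), egfr_ab=rng.uniform(0, 100, 500))
        panel = _panel(tube, tube, tube, tube)
        result = quantify(panel, GateConfig())
        assert result.egfr_pos == 0.0
        assert result.hx103_pos == 0.0
        assert result.double_pos == 0.0
        # stained MFI equals DMSO MFI: blocking ratio is not evaluable
        assert result.blocking_ratio is None
        assert not result.specificity_pass

    def test_corrected_values_can_be_negative(self):
        rng = np.random.default_rng(3)
        dmso = _tube(hx103=rng.uniform(0, 100, 400), egfr_ab=rng.uniform(0, 100, 400))
        stained = _tube(hx103=rng.uniform(0, 90, 400), egfr_ab=rng.uniform(0, 100, 400))
        panel = _panel(dmso, dmso, stained, stained)
        result = quantify(panel, GateConfig(control_quantile=0.9))
        assert result.hx103_pos < 0
        assert -100 <= result.hx103_pos <= 100

    def test_quadrant_closure_and_bounds(self):
        panel = preset_panel("wt_overexpressing", seed=6, n_events=5000)
        th = derive_thresholds(panel, GateConfig())
        gated = apply_gates(panel.tube("stained"), th, GateConfig())
        shares = gated["quadrant"].value_counts(normalize=True)
        assert shares.sum() == pytest.approx(1.0, abs=1e-9)
        result = quantify(panel)
        assert 0 <= result.raw_double_pos <= result.raw_egfr_pos <= 100
        assert result.raw_double_pos <= result.raw_hx103_pos

    def test_quantify_is_idempotent(self):
        panel = preset_panel("mutant_high", seed=2, n_events=5000)
        assert quantify(panel) == quantify(panel)

    def test_mutant_high_preset_double_pos_and_blocking(self):
        result = quantify(preset_panel("mutant_high", seed=1, n_events=20000))
        assert result.double_pos >= 80
        assert result.blocking_ratio is not None and result.blocking_ratio >= 0.8
        assert result.specificity_pass

    def test_blocked_tube_reduces_double_pos(self):
        # treating the blocked tube as if it were the stained tube must
        # always lower the corrected double-positive percentage
        for seed in (21, 22, 23):
            panel = preset_panel("mutant_high", seed=seed, n_events=10000)
            swapped = SamplePanel(
                panel.specimen_id,
                {**panel.tubes, "stained": panel.tubes["gefitinib_blocked"]},
            )
            assert quantify(swapped).double_pos < quantify(panel).double_pos
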