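import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualtrace import (
    MeasurementTable,
    Route,
    background_total_cd,
    compute_new_accumulation,
    dietary_scaling_factor,
    estimate_background,
    qc_spike_recovery,
    simulate_experiment,
    tracer_specificity,
)
from dualtrace.accounting import NewAccumulation
from dualtrace.errors import MissingControlError

from .test_core import make_design, make_row


def table_from_rows(rows, design=None):
    return MeasurementTable(pd.DataFrame(rows), design or make_design())


class TestEstimateBackground:
    def test_hand_mean(self):
        rows = [
            make_row(mussel_id=f"m{i}", cd112_ugg_dw=v)
            for i, v in enumerate([1.45, 1.52, 1.59])
        ]
        bg = estimate_background(table_from_rows(rows), "waterborne")
        assert bg.mean == pytest.approx(1.52)
        assert bg.n == 3

    def test_single_value(self):
        bg = estimate_background(
            table_from_rows([make_row(cd112_ugg_dw=1.5)]), "waterborne"
        )
        assert bg.mean == 1.5
        assert bg.sd == 0.0

    def test_missing_control(self):
        rows = [make_row(group="T1")]
        with pytest.raises(MissingControlError):
            estimate_background(table_from_rows(rows), "waterborne")

    def test_per_day_means_retained(self, noisefree_table):
        bg = estimate_background(noisefree_table, "dietary")
        assert set(bg.per_day) == {10, 20, 30}
        assert all(v == pytest.approx(0.87) for v in bg.per_day.values())

    def test_tracer_spec_accepted(self, paper_config, noisefree_table):
        bg = estimate_background(noisefree_table, paper_config.tracer("waterborne"))
        assert bg.tracer == "Cd112"
        assert bg.mean == pytest.approx(1.52)


class TestDietaryScalingFactor:
    @pytest.mark.parametrize(
        "feeding,day,expected", [(3, 24, 8.0), (24, 24, 1.0), (6, 24, 4.0)]
    )
    def test_values(self, feeding, day, expected):
        assert dietary_scaling_factor(feeding, day) == expected

    @pytest.mark.parametrize("feeding,day", [(0, 24), (-1, 24), (25, 24), (3, 0)])
    def test_domain_errors(self, feeding, day):
        with pytest.raises(ValueError):
            dietary_scaling_factor(feeding, day)


class TestComputeNewAccumulation:
    def make_table(self, w_exposed, d_exposed, w_ctrl=1.52, d_ctrl=0.87):
        rows = [
            make_row(mussel_id="c1", cd112_ugg_dw=w_ctrl, cd113_ugg_dw=d_ctrl),
            make_row(group="T1", mussel_id="e1", cd112_ugg_dw=w_exposed,
                     cd113_ugg_dw=d_exposed),
        ]
        return table_from_rows(rows)

    def make_config(self, paper_config, design):
        return dataclasses.replace(paper_config, design=design)

    def test_hand_values(self, paper_config):
        table = self.make_table(5.00, 1.37)
        config = self.make_config(paper_config, table.design)
        cells = compute_new_accumulation(table, config)
        by_route = {c.route: c for c in cells}
        assert by_route[Route.WATERBORNE].mean == pytest.approx(3.48)  # 5.00 - 1.52
        assert by_route[Route.DIETARY].mean == pytest.approx(4.0)  # 8 * (1.37 - 0.87)

    def test_exposed_equal_control_gives_zero(self, paper_config):
        table = self.make_table(1.52, 0.87)
        config = self.make_config(paper_config, table.design)
        for cell in compute_new_accumulation(table, config):
            assert cell.mean == pytest.approx(0.0)
            assert not cell.flagged_negative

    def test_negative_cells_flagged_not_clipped(self, paper_config):
        table = self.make_table(1.0, 0.5)
        config = self.make_config(paper_config, table.design)
        for cell in compute_new_accumulation(table, config):
            assert cell.flagged_negative
            assert cell.mean < 0

    def test_noisefree_recovers_influx_times_t(
        self, paper_config, noisefree_table, paper_truth
    ):
        cells = compute_new_accumulation(noisefree_table, paper_config)
        for cell in cells:
            rate = (
                paper_truth.influx_w[cell.group]
                if cell.route is Route.WATERBORNE
                else paper_truth.influx_d[cell.group]
            )
            assert cell.mean == pytest.approx(rate * cell.day, abs=1e-10)

    @given(scale=st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None)
    def test_linearity_under_scaling(self, scale, paper_config, noisy_table):
        base = compute_new_accumulation(noisy_table, paper_config)
        df = noisy_table.data.copy()
        df["cd112_ugg_dw"] *= scale
        df["cd113_ugg_dw"] *= scale
        scaled_cells = compute_new_accumulation(
            MeasurementTable(df, noisy_table.design), paper_config
        )
        for a, b in zip(base, scaled_cells):
            assert b.mean == pytest.approx(scale * a.mean, rel=1e-9, abs=1e-12)

    def test_scaling_order_invariance(self):
        # S * (exposed - control) == (S * exposed) - (S * control)
        rng = np.random.default_rng(0)
        exposed, control, S = rng.uniform(0, 10, 50), rng.uniform(0, 10, 50), 8.0
        np.testing.assert_allclose(
            S * (exposed - control), S * exposed - S * control, rtol=1e-12
        )

    def test_time_matched_control_option(self, paper_config, noisy_table):
        pooled = compute_new_accumulation(noisy_table, paper_config)
        matched = compute_new_accumulation(
            noisy_table, paper_config, time_matched_control=True
        )
        assert len(pooled) == len(matched)
        assert any(
            a.mean != pytest.approx(b.mean) for a, b in zip(pooled, matched)
        )

    def test_purity_correction_scales_up(self, paper_config, noisefree_table):
        plain = compute_new_accumulation(noisefree_table, paper_config)
        corrected = compute_new_accumulation(
            noisefree_table, paper_config, purity_correction=True
        )
        for a, b in zip(plain, corrected):
            purity = paper_config.tracer(a.route).spike_purity
            assert b.mean == pytest.approx(a.mean / purity, rel=1e-9, abs=1e-12)


class TestNewAccumulationType:
    def test_stats_derived_from_values(self):
        cell = NewAccumulation("T1", 10, "Cd112", Route.WATERBORNE, (1.0, 2.0, 3.0))
        assert cell.mean == pytest.approx(2.0)
        assert cell.sd == pytest.approx(1.0)
        assert not cell.flagged_negative

    def test_flag_iff_negative_mean(self):
        neg = NewAccumulation("T1", 10, "Cd112", Route.WATERBORNE, (-2.0, 1.0))
        assert neg.flagged_negative
        pos = NewAccumulation("T1", 10, "Cd112", Route.WATERBORNE, (-0.5, 1.0))
        assert not pos.flagged_negative


class TestQcOps:
    def test_specificity_hand_value(self):
        frac, ok = tracer_specificity(2.5, 0.02)
        assert frac == pytest.approx(2.5 / 2.52)
        assert ok

    def test_specificity_symmetry_fail(self):
        frac, ok = tracer_specificity(1.0, 1.0)
        assert frac == 0.5 and not ok

    def test_specificity_pure(self):
        frac, ok = tracer_specificity(1.0, 0.0)
        assert frac == 1.0 and ok

    def test_specificity_both_zero(self):
        with pytest.raises(ValueError):
            tracer_specificity(0.0, 0.0)

    @pytest.mark.parametrize(
        "measured,certified,dev,ok",
        [(95, 100, 0.05, True), (111, 100, 0.11, False), (100, 100, 0.0, True)],
    )
    def test_spike_recovery(self, measured, certified, dev, ok):
        deviation, passed = qc_spike_recovery(measured, certified)
        assert deviation == pytest.approx(dev)
        assert passed is ok

    def test_spike_recovery_domain(self):
        with pytest.raises(ValueError):
            qc_spike_recovery(95, 0)


class TestBackgroundTotalCd:
    def test_hand_divisions(self):
        assert background_total_cd(1.52, 0.2413) == pytest.approx(6.2992, abs=1e-3)
        assert background_total_cd(0.87, 0.1222) == pytest.approx(7.1195, abs=1e-3)

    def test_zero_conc(self):
        assert background_total_cd(0.0, 0.5) == 0.0

    @pytest.mark.parametrize("abundance", [0.0, 1.0, -0.2, 2.0])
    def test_domain(self, abundance):
        with pytest.raises(ValueError):
            background_total_cd(1.0, abundance)
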