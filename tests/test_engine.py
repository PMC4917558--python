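import math

import numpy as np
import pytest

from crossmodal import (
    ConfigError,
    NoFlipError,
    apply_parameter,
    base_config,
    builtin_scenarios,
    closed_form_disparity,
    find_flip,
    read_config,
    run_scenario,
    summarize_trace,
    sweep_grid,
    write_config,
    write_trace,
)

DEG = math.pi / 180.0


class TestRunScenario:
    def test_small_disparity_yields_common_cause(self):
        trace = run_scenario(base_config(1.83))
        assert trace["sameness"].iloc[-1] == 1
        assert trace["sim"].iloc[-1] > 0.5

    def test_large_disparity_yields_separate_causes(self):
        trace = run_scenario(base_config(21.7))
        assert trace["sameness"].iloc[-1] == 0

    def test_colocated_stimuli_keep_similarity_at_one(self):
        trace = run_scenario(base_config(0.0))
        assert (trace["sim"] == 1.0).all()
        assert (trace["dist"] == 0.0).all()

    def test_trace_shape_and_invariants(self, spatial_cfg):
        trace = run_scenario(spatial_cfg)
        n_expected = int(round(spatial_cfg.grid.t_end / spatial_cfg.grid.dt)) + 1
        assert len(trace) == n_expected
        # similarity never recovers within a trial
        assert (np.diff(trace["sim"].to_numpy()) <= 1e-12).all()
        # decision-result rows are a partition of unity
        dr_sum = trace[["dr_v", "dr_a", "dr_av"]].sum(axis=1)
        assert np.allclose(dr_sum, 1.0, atol=1e-12)

    def test_memory_holds_after_offset(self, spatial_cfg):
        trace = run_scenario(spatial_cfg)
        after = trace[trace["t"] > 0.5 + 1e-9]
        assert after["ech_mv"].nunique() == 1
        assert float(after["ech_mv"].iloc[0]) == pytest.approx(9.0)
        assert after["ech_ma"].nunique() == 1
        assert float(after["ech_ma"].iloc[0]) == pytest.approx(16.0)

    def test_deterministic(self, spatial_cfg):
        t1 = run_scenario(spatial_cfg)
        t2 = run_scenario(spatial_cfg)
        assert t1.equals(t2)

    def test_ventriloquism_execution_at_weighted_average(self):
        """Common cause: the fused target, at the reliability-weighted
        average position, is the one released for execution."""
        cfg = base_config(1.83)
        trace = run_scenario(cfg)
        last = trace.iloc[-1]
        assert last["dr_av"] > 0.99
        assert last["ech_exav"] == pytest.approx(
            last["dr_av"] * (9.0 + 1.83 / 2), rel=1e-3
        )
        assert abs(last["ech_exv"]) < 0.2


class TestClosedFormOracle:
    @pytest.mark.parametrize("name", sorted(builtin_scenarios()))
    def test_discrete_stepper_matches_analytic_disparity(self, name):
        cfg = builtin_scenarios()[name]
        trace = run_scenario(cfg)
        oracle = closed_form_disparity(cfg)
        tol = cfg.params.k_int * math.pi * cfg.grid.dt
        for t, disp in zip(trace["t"], trace["disp"]):
            assert abs(disp - oracle(t)) <= tol

    def test_synchronous_final_value(self):
        # 10 deg apart for 0.3 s: disp = k * dist * duration
        cfg = base_config(10.0)
        oracle = closed_form_disparity(cfg)
        assert oracle(1.0) == pytest.approx(21 * 10 * DEG * 0.3, rel=1e-9)
        # sits essentially at the similarity threshold
        assert 1 - math.tanh(0.5 * oracle(1.0)) == pytest.approx(0.4997, abs=5e-4)

    def test_lone_stimulus_accumulates_distance_to_origin(self):
        cfg = base_config(7.0)
        d = cfg.model_dump()
        d["auditory"]["reliability"] = 0.0
        d["auditory"]["onset"] = 0.6  # auditory arrives after visual is gone
        d["auditory"]["duration"] = 0.05
        cfg = type(cfg).model_validate(d)
        oracle = closed_form_disparity(cfg)
        # during [0.2, 0.5) only the visual stimulus has been stored
        assert oracle(0.5) == pytest.approx(21 * 9 * DEG * 0.3, rel=1e-9)

    def test_flat_before_onset_and_after_offset(self, spatial_cfg):
        oracle = closed_form_disparity(spatial_cfg)
        assert oracle(0.0) == 0.0
        assert oracle(0.19) == 0.0
        assert oracle(0.6) == oracle(0.99)


class TestFindFlip:
    def test_spatial_flip_near_ten_degrees(self):
        res = find_flip(base_config(), "sd", 1.0, 22.0)
        assert res.flip_value == pytest.approx(10.0, abs=0.1)
        assert res.hi - res.lo <= 0.01

    def test_temporal_flip_near_hundred_milliseconds(self):
        res = find_flip(base_config(7.0), "onset_delay", 0.0, 0.25)
        assert res.flip_value == pytest.approx(0.10, abs=0.005)

    def test_duration_flip_near_four_hundred_milliseconds(self):
        res = find_flip(base_config(7.5), "duration", 0.25, 0.55)
        assert res.flip_value == pytest.approx(0.40, abs=0.005)

    def test_no_flip_raises(self):
        with pytest.raises(NoFlipError):
            find_flip(base_config(), "sd", 1.0, 2.0)

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ConfigError):
            apply_parameter(base_config(), "frequency", 1.0)

    def test_dt_refinement_stability(self):
        """Halving the grid step moves the flip by less than the bisection
        tolerance."""
        res_coarse = find_flip(base_config(dt=0.001), "sd", 1.0, 22.0)
        res_fine = find_flip(base_config(dt=0.0005), "sd", 1.0, 22.0)
        assert abs(res_coarse.flip_value - res_fine.flip_value) < 0.01 + 0.01

    @pytest.mark.parametrize("duration", [0.2, 0.3, 0.4, 0.5])
    def test_reciprocal_law_flip_sd_times_duration_constant(self, duration):
        """For synchronous equal-duration trials the flip disparity scales as
        1/duration: sd* x D = 2 atanh(th) / k_int."""
        cfg = base_config(duration=duration)
        res = find_flip(cfg, "sd", 1.0, 22.0)
        expected = math.degrees(2 * math.atanh(0.5) / 21.0)
        assert res.flip_value * duration == pytest.approx(expected, rel=0.02)


class TestSweepGrid:
    def test_small_spatial_disparity_is_robust_to_delay(self):
        table = sweep_grid(base_config(), [1.83], [0.0, 0.05, 0.1, 0.15, 0.2, 0.25])
        assert (table["sameness"] == 1).all()

    def test_large_disparities_break_binding(self):
        table = sweep_grid(base_config(), [21.7], [0.25])
        assert (table["sameness"] == 0).all()

    def test_single_cell_matches_run_scenario(self):
        table = sweep_grid(base_config(), [7.0], [0.0])
        trace = run_scenario(base_config(7.0))
        assert table["sim_final"].iloc[0] == pytest.approx(trace["sim"].iloc[-1])
        assert table["sameness"].iloc[0] == trace["sameness"].iloc[-1]

    def test_final_similarity_monotone_in_both_axes(self):
        sds = [2.0, 6.0, 10.0, 14.0, 18.0]
        dts = [0.0, 0.05, 0.10, 0.15, 0.20]
        table = sweep_grid(base_config(), sds, dts)
        grid = table.pivot(index="sd", columns="dt", values="sim_final")
        vals = grid.to_numpy()
        assert (np.diff(vals, axis=0) <= 1e-9).all()  # down each column
        assert (np.diff(vals, axis=1) <= 1e-9).all()  # along each row

    def test_empty_axis_rejected(self):
        with pytest.raises(ConfigError):
            sweep_grid(base_config(), [], [0.0])


class TestReliabilitySelection:
    @pytest.mark.parametrize("rel_a", [0.2, 0.4, 0.6, 0.8])
    def test_more_reliable_modality_wins_when_causes_separate(self, rel_a):
        cfg = base_config(15.0, rel_a=rel_a)  # sim ends well below threshold
        trace = run_scenario(cfg)
        last = trace.iloc[-1]
        assert last["sameness"] == 0
        if rel_a > 0.5:
            assert last["dr_a"] > 0.99
            assert last["dr_v"] < 0.01
        else:
            assert last["dr_v"] > 0.99
            assert last["dr_a"] < 0.01

    def test_multisensory_dv_crosses_threshold_mid_trial(self):
        cfg = base_config(15.0, rel_a=0.2)
        trace = run_scenario(cfg)
        below = trace[trace["dv_av"] < 0.5]
        assert below["t"].iloc[0] == pytest.approx(0.4, abs=0.005)

    def test_reliability_tie_reported(self):
        cfg = base_config(15.0, rel_a=0.5)
        s = summarize_trace(run_scenario(cfg), cfg)
        assert s.winner == "visual" and s.tied


class TestConfigIO:
    def test_round_trip_equality(self, tmp_path):
        for name, cfg in builtin_scenarios().items():
            p = tmp_path / f"{name}.json"
            write_config(cfg, p)
            assert read_config(p) == cfg

    def test_trace_csv_row_count(self, tmp_path, spatial_cfg):
        trace = run_scenario(spatial_cfg)
        out = tmp_path / "trace.csv"
        write_trace(trace, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(trace) + 1  # header + rows

    def test_unknown_key_named_in_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(
            '{"visual": {"onset": 0.2, "duration": 0.3, "ech_deg": 9, '
            '"loudness": 3}, '
            '"auditory": {"onset": 0.2, "duration": 0.3, "ech_deg": 16}}'
        )
        with pytest.raises(ConfigError, match="loudness"):
            read_config(p)

    def test_missing_stimulus_named_in_error(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"visual": {"onset": 0.2, "duration": 0.3, "ech_deg": 9}}')
        with pytest.raises(ConfigError, match="auditory"):
            read_config(p)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(Exception, match="extends past"):
            base_config(7.0, onset=0.9, duration=0.3)

    def test_report_time_changes_categorical_outcome(self):
        """Forcing the report before the evidence has accumulated keeps the
        default common-cause decision."""
        d = base_config(15.0, rel_a=0.2).model_dump()
        d["report_time"] = 0.3  # before the similarity crosses threshold
        cfg = base_config(15.0).__class__.model_validate(d)
        early = summarize_trace(run_scenario(cfg), cfg)
        assert early.sameness == 1 and early.winner == "av"
        d["report_time"] = None
        cfg_late = cfg.__class__.model_validate(d)
        late = summarize_trace(run_scenario(cfg_late), cfg_late)
        assert late.sameness == 0 and late.winner == "visual"
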