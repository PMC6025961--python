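"""Simulator invariants: reporter kinetics, carbon bookkeeping, switching
statistics, queue behaviour and determinism."""

import math

import numpy as np
import pandas as pd
import pytest

import metaswitch as ms
from metaswitch.lineage import detect_events_per_cell, mother_traces
from metaswitch.params import CellState, ScenarioConfig


class TestReporterUpdate:
    def test_off_state_with_zero_basal_production_stays_dark(self, params):
        p = params.evolve(beta_off=0.0)
        cell = CellState(cell_id=0, F_sucC=0.0, F_alsS=0.0)
        out = ms.reporter_update(cell, dt=30.0, params=p)
        assert out.F_sucC == 0.0 and out.F_alsS == 0.0

    def test_on_state_steady_level_is_production_over_growth(self, params):
        r = params.r_base  # off-state growth rate used for both reporters
        cell = CellState(cell_id=0, sucC_state=True,
                         F_sucC=params.beta_on / (params.r_base * params.penalty_sucC),
                         F_alsS=params.beta_off / (params.r_base * params.penalty_sucC))
        growth = params.r_base * params.penalty_sucC
        out = ms.reporter_update(cell, dt=100.0, params=params)
        assert out.F_sucC == pytest.approx(params.beta_on / growth, rel=1e-12)
        assert out.F_alsS == pytest.approx(params.beta_off / growth, rel=1e-12)
        del r

    def test_decay_after_switch_off_follows_closed_form(self, params):
        """After leaving the on state, F relaxes toward beta_off/r with
        e-folding time 1/r (dilution only, no degradation)."""
        r = params.r_base
        f0 = 9000.0
        cell = CellState(cell_id=0, F_sucC=f0, F_alsS=f0)
        t, dt = 0.0, 3.0
        state = cell
        for _ in range(200):
            state = ms.reporter_update(state, dt=dt, params=params)
            t += dt
            fstar = params.beta_off / r
            expected = fstar + (f0 - fstar) * math.exp(-r * t)
            assert state.F_sucC == pytest.approx(expected, rel=1e-6)

    def test_non_positive_dt_rejected(self, params):
        with pytest.raises(ValueError):
            ms.reporter_update(CellState(cell_id=0), dt=0.0, params=params)


class TestBatchEnvironment:
    def test_zero_founders_leave_environment_constant(self, params):
        cfg = ms.batch_scenario(seed=0, n_founders=0, duration=120.0)
        res = ms.simulate_batch(params, cfg)
        env = res.env
        for col in ("glucose_mM", "malate_mM", "acetate_mM", "acetoin_mM"):
            assert env[col].nunique() == 1

    def test_carbon_bookkeeping_closes(self, batch_result):
        """Produced - consumed acetate equals the net concentration change,
        and acetoin output is exactly half the acetate drawn down."""
        env = batch_result.env
        net = env["acetate_mM"].iloc[-1] - env["acetate_mM"].iloc[0]
        balance = batch_result.acetate_produced - batch_result.acetate_consumed
        assert balance == pytest.approx(net, rel=1e-8, abs=1e-10)
        assert env["acetoin_mM"].iloc[-1] == pytest.approx(
            0.5 * batch_result.acetate_consumed, rel=1e-8)

    def test_comK_null_abolishes_acetate_buildup(self, params, batch_result):
        cfg = ms.batch_scenario(seed=1, comK_null=True)
        ko = ms.simulate_batch(params, cfg)
        wt_peak = batch_result.env["acetate_mM"].max()
        assert ko.env["acetate_mM"].max() < wt_peak
        assert ko.env["acetate_mM"].max() <= 0.5 * wt_peak

    def test_alsS_null_stops_acetate_consumption_and_acetoin(self, params):
        res = ms.simulate_batch(params, ms.batch_scenario(seed=4, alsS_null=True))
        assert res.acetate_consumed == 0.0
        assert res.env["acetoin_mM"].max() == 0.0
        assert np.all(np.diff(res.env["acetate_mM"].to_numpy()) >= -1e-12)

    def test_wrong_mode_rejected(self, params):
        with pytest.raises(ValueError):
            ms.simulate_batch(params, ms.pad_scenario(seed=0))


class TestScenarioConfig:
    def test_frame_interval_must_divide_duration(self):
        with pytest.raises(ValueError, match="divide"):
            ScenarioConfig(mode="batch", duration=100.0, frame_interval=12.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            ScenarioConfig(mode="chemostat", duration=120.0)

    def test_knockouts_zero_the_right_rates(self, params):
        cfg = ScenarioConfig(mode="batch", duration=120.0, comK_null=True,
                             alsS_null=True)
        p = cfg.apply_knockouts(params)
        assert p.k_on_sucC == 0.0 and p.c_A == 0.0

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            ms.default_params(k_on_sucC=-1.0)
        with pytest.raises(ValueError):
            ms.default_params(penalty_alsS=1.5)
        with pytest.raises(ValueError):
            ms.default_params(y_acetoin=0.0)
        with pytest.raises(ValueError):
            ms.default_params(h_alsS=0.5)


class TestMotherMachine:
    def test_zero_channels_give_empty_table(self, params):
        cfg = ms.mother_machine_scenario(seed=0, n_channels=0, duration=120.0)
        lin = ms.simulate_mother_machine(params, cfg)
        assert len(lin) == 0
        assert list(lin.columns)[:2] == ["cell_id", "parent_id"]

    def test_channel_capacity_below_one_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            ms.mother_machine_scenario(seed=0, n_channels=4,
                                       channel_capacity=0, duration=120.0)

    def test_absorbing_off_state_shows_no_events(self):
        p, cfg = ms.alsS_mother_machine(seed=5, n_channels=6, duration=720.0)
        p = p.evolve(k_on_sucC=0.0, k0_alsS=0.0, kmax_alsS=0.0)
        lin = ms.simulate_mother_machine(p, cfg)
        assert lin["state_sucC"].sum() == 0
        assert lin["state_alsS"].sum() == 0
        for col in ("state_sucC", "state_alsS"):
            ev = detect_events_per_cell(lin, col, 0.5, 12.0)
            assert len(ev) == 0

    def test_mother_persists_with_one_record_per_channel_per_frame(self, mm_lineage):
        mothers = mm_lineage[mm_lineage["parent_id"] == -1]
        counts = mothers.groupby(["channel_id", "frame"]).size()
        n_channels = mm_lineage["channel_id"].nunique()
        n_frames = mm_lineage["frame"].nunique()
        assert (counts == 1).all()
        assert len(counts) == n_channels * n_frames

    def test_queue_never_exceeds_capacity_and_washes_out(self, mm_lineage):
        cap = mm_lineage.attrs["config"].channel_capacity
        per_frame = mm_lineage.groupby(["channel_id", "frame"]).size()
        assert per_frame.max() <= cap
        assert (mm_lineage["fate"] == "washed_out").any()

    def test_episode_durations_are_exponential_with_configured_mean(self):
        """Completed alsS episodes on mother traces average 1/k_off."""
        p, cfg = ms.alsS_mother_machine(seed=21, n_channels=120,
                                        duration=5760.0)
        p = p.evolve(k_off_alsS=1 / 252.0)
        lin = ms.simulate_mother_machine(p, cfg)
        ev = detect_events_per_cell(
            lin[lin["parent_id"] == -1], "state_alsS", 0.5, 12.0)
        done = ev[~ev["censored"]]
        assert len(done) >= 300
        corrected = done["dwell_min"].mean() + 6.0
        assert corrected == pytest.approx(252.0, rel=0.10)

    def test_occupancy_matches_telegraph_balance(self, mm_lineage):
        """Time-averaged on-fraction approaches k_on/(k_on+k_off) within
        3 Monte-Carlo standard errors of a two-state Markov chain."""
        p = mm_lineage.attrs["params"]
        cfg = mm_lineage.attrs["config"]
        k_on = p.k_on_alsS(cfg.media_acetate)
        k_off = p.k_off_alsS
        target = k_on / (k_on + k_off)
        mothers = mother_traces(mm_lineage)
        states = np.concatenate(
            [tr["state_alsS"].to_numpy() for tr in mothers.values()])
        T = states.size * cfg.frame_interval
        tau = 1.0 / (k_on + k_off)
        se = math.sqrt(2 * target * (1 - target) * tau / T)
        assert abs(states.mean() - target) < 3 * se


class TestPad:
    def test_single_founder_without_division_is_one_lineage(self, params):
        p = params.evolve(L_div=math.inf)
        cfg = ms.pad_scenario(seed=0, n_founders=1, duration=240.0)
        res = ms.simulate_pad(p, cfg)
        assert res.lineage["cell_id"].nunique() == 1
        assert (res.lineage["parent_id"] == -1).all()

    def test_deterministic_doubling_gives_eight_cells(self):
        """No noise, no switching, division every 60 min, 180 min -> 2^3."""
        p = ms.default_params(growth_cv=0.0, div_cv=0.0, meas_cv=0.0,
                              k_on_sucC=0.0, k0_alsS=0.0, kmax_alsS=0.0,
                              K_carbon=0.0, r_base=math.log(2) / 60.0)
        cfg = ms.pad_scenario(seed=0, duration=180.0, n_founders=1,
                              acetate=0.0)
        res = ms.simulate_pad(p, cfg)
        last = res.lineage[res.lineage["frame"] == res.lineage["frame"].max()]
        assert len(last) == 8

    def test_growth_recovers_as_acetate_is_detoxified(self, pad_result, params):
        """Population elongation over the first 2 h is slower than over the
        last 2 h once alsS+ cells have drawn the acetate down."""
        env = pad_result.env
        t = env["t_min"].to_numpy()
        logB = np.log(env["biomass"].to_numpy())

        def rate(mask):
            return np.polyfit(t[mask], logB[mask], 1)[0]

        assert rate(t <= 120.0) < rate(t >= t[-1] - 120.0)
        assert env["acetate_mM"].iloc[-1] < env["acetate_mM"].iloc[0]

    def test_without_detox_acetate_and_growth_stay_low(self, params, pad_result):
        res = ms.simulate_pad(params, ms.pad_scenario(seed=2, alsS_null=True))
        assert res.env["acetate_mM"].iloc[-1] >= \
            pad_result.env["acetate_mM"].iloc[-1]
        assert res.env["biomass"].iloc[-1] < pad_result.env["biomass"].iloc[-1]


class TestDeterminism:
    def test_same_seed_same_tables(self):
        p, cfg = ms.alsS_mother_machine(seed=7, n_channels=4, duration=480.0)
        a = ms.simulate_mother_machine(p, cfg)
        b = ms.simulate_mother_machine(p, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        p, cfg7 = ms.alsS_mother_machine(seed=7, n_channels=4, duration=480.0)
        _, cfg8 = ms.alsS_mother_machine(seed=8, n_channels=4, duration=480.0)
        a = ms.simulate_mother_machine(p, cfg7)
        b = ms.simulate_mother_machine(p, cfg8)
        assert not a["f_alsS"].equals(b["f_alsS"])

    def test_batch_snapshots_deterministic(self, params):
        cfg = ms.batch_scenario(seed=11, duration=120.0, n_founders=30)
        a = ms.simulate_batch(params, cfg)
        b = ms.simulate_batch(params, cfg)
        for sa, sb in zip(a.snapshots, b.snapshots):
            assert np.array_equal(sa.values, sb.values)
        pd.testing.assert_frame_equal(a.env, b.env)
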