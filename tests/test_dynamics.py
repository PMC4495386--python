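"""Windowed integration, averaged-nest construction, and overlap metrics."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nestquorum.model import ColonyState, NestSchedule, PhaseParams, ScenarioConfig
from nestquorum.dynamics import (
    Trajectory,
    averaged_nest,
    compare,
    integrate_windowed,
    nest_population,
    quorum_time,
)
from nestquorum import presets


def _constant_scenario(**kwargs):
    base = dict(
        nest1=NestSchedule.constant(presets.CONSTANT_MEDIOCRE),
        nest2=NestSchedule.constant(presets.CONSTANT_MEDIOCRE),
    )
    base.update(kwargs)
    return ScenarioConfig(**base)


class TestIntegration:
    def test_no_rates_no_motion(self):
        frozen = PhaseParams(0.0, 0.0)
        cfg = _constant_scenario(nest1=NestSchedule.constant(frozen),
                                 nest2=NestSchedule.constant(frozen),
                                 mu=0.0, phi1=0.0, phi2=0.0,
                                 initial=ColonyState(X=12.0, P=30.0))
        traj = integrate_windowed(cfg)
        assert np.allclose(traj.states, traj.states[0], atol=1e-12)

    def test_isolated_assessors_decay_exponentially(self):
        # with no discovery, assessors of nest 1 leave at rate k + rho
        cfg = _constant_scenario(mu=0.0, initial=ColonyState(Z1=5.0))
        traj = integrate_windowed(cfg)
        k, rho = presets.CONSTANT_MEDIOCRE.k, presets.CONSTANT_MEDIOCRE.rho
        expected = 5.0 * math.exp(-(k + rho) * 60.0)
        assert traj.component("Z1")[60] == pytest.approx(expected, rel=1e-8)
        assert expected == pytest.approx(0.93187, abs=1e-4)

    def test_grid_and_boundaries(self):
        traj = integrate_windowed(presets.scenario("t25"))
        assert traj.times[0] == 0.0 and traj.times[-1] == 180.0
        assert np.all(np.diff(traj.times) == 1.0)
        # quality switches at 2.5 and 10 within every cycle
        assert 2.5 in traj.window_boundaries and 12.5 in traj.window_boundaries
        assert np.all(traj.states >= 0.0)

    @pytest.mark.parametrize("name", ["t25", "t50", "t75"])
    def test_conservation_along_trajectory(self, name):
        traj = integrate_windowed(presets.scenario(name))
        assert np.abs(traj.active_total - traj.active_total[0]).max() < 1e-6
        assert np.abs(traj.passive_total - traj.passive_total[0]).max() < 1e-6

    def test_population_bookkeeping_closes(self):
        traj = integrate_windowed(presets.scenario("t50"))
        total = (nest_population(traj, 1) + nest_population(traj, 2)
                 + traj.component("X") + traj.component("P"))
        assert np.allclose(total, total[0], atol=1e-6)

    def test_quorum_crossing_is_located_and_logged(self):
        # the magnified 75% preset attains quorum in the fluctuating nest
        traj = integrate_windowed(presets.scenario("magnified_t75"))
        assert len(traj.quorum_events) == 1
        nest, t_ev = traj.quorum_events[0]
        assert nest == 2
        y2 = traj.component("Y2")
        assert y2[int(math.floor(t_ev))] <= 7.0 + 1e-6
        assert y2.max() > 7.0
        # carried items appear only after the crossing
        b2 = traj.component("B2")
        assert b2[int(math.floor(t_ev))] == pytest.approx(0.0, abs=1e-9)
        assert b2[-1] > 1.0


class TestNestPopulation:
    def test_definition_and_index_check(self):
        traj = integrate_windowed(presets.scenario("t25"))
        pop = nest_population(traj, 2)
        manual = (traj.component("Z2") + traj.component("Y2")
                  + traj.component("B2"))
        assert np.array_equal(pop, manual)
        # pre-quorum there is nothing carried, so population is Z + Y
        assert np.allclose(pop, traj.component("Z2") + traj.component("Y2"))
        with pytest.raises(ValueError):
            nest_population(traj, 3)


class TestAveragedNest:
    def test_quarter_good_time_weighted_means(self):
        sched = NestSchedule(good=PhaseParams(0.024, 0.004),
                             poor=PhaseParams(0.016, 0.012), good_fraction=0.25)
        avg = averaged_nest(sched)
        assert avg.is_constant
        assert avg.good.k == pytest.approx(0.018, abs=1e-15)
        # 0.25 * 0.004 + 0.75 * 0.012
        assert avg.good.rho == pytest.approx(0.010, abs=1e-15)

    def test_constant_schedule_passes_through(self):
        sched = NestSchedule.constant(PhaseParams(0.02, 0.008))
        assert averaged_nest(sched).good == sched.good

    def test_half_good_average_equals_mediocre(self):
        sched = NestSchedule(good=presets.FLUCT_GOOD, poor=presets.FLUCT_POOR,
                             good_fraction=0.5)
        avg = averaged_nest(sched).good
        assert avg == presets.CONSTANT_MEDIOCRE


def _synthetic_ramp_trajectory():
    times = np.arange(0.0, 181.0)
    states = np.zeros((len(times), 8))
    states[:, 5] = times / 10.0  # Y2 ramps up linearly
    return Trajectory(times=times, states=states)


class TestQuorumTime:
    def test_subthreshold_trajectory_has_no_event(self):
        traj = integrate_windowed(presets.scenario("t25"))
        assert quorum_time(traj, 7.0) is None
        assert traj.quorum_events == []

    def test_constructed_crossing(self):
        traj = _synthetic_ramp_trajectory()
        assert quorum_time(traj, 7.0) == pytest.approx(71.0, abs=1.0)

    def test_threshold_below_range_triggers_immediately(self):
        traj = _synthetic_ramp_trajectory()
        assert quorum_time(traj, -1.0) <= traj.times[1]


class TestCompare:
    def test_identical_series(self):
        a = np.linspace(0, 5, 50)
        m = compare(a, a)
        assert m.sup_norm == 0.0 and m.rms == 0.0

    def test_constant_offset(self):
        a = np.linspace(0, 5, 50)
        m = compare(a, a + 0.3)
        assert m.sup_norm == pytest.approx(0.3)
        assert m.rms == pytest.approx(0.3)

    def test_symmetry_and_norm_ordering(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=80), rng.normal(size=80)
        m1, m2 = compare(a, b), compare(b, a)
        assert m1.sup_norm == m2.sup_norm and m1.rms == m2.rms
        assert m1.sup_norm >= m1.rms >= 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare(np.zeros(5), np.zeros(6))


class TestHomogenization:
    @pytest.mark.parametrize("name", ["t25", "t50", "t75"])
    def test_fluctuating_matches_averaged_nest(self, name):
        cfg = presets.scenario(name)
        cfg_avg = replace(cfg, nest2=averaged_nest(cfg.nest2))
        pop_fn = nest_population(integrate_windowed(cfg), 2)
        pop_an = nest_population(integrate_windowed(cfg_avg), 2)
        assert compare(pop_fn, pop_an).sup_norm < presets.overlap_tolerance(name)

    def test_faster_fluctuation_tightens_overlap(self):
        cfg_avg = replace(presets.scenario("t25"),
                          nest2=averaged_nest(presets.scenario("t25").nest2))
        pop_an = nest_population(integrate_windowed(cfg_avg), 2)
        sups = []
        for period in (10.0, 5.0):
            pop_fn = nest_population(
                integrate_windowed(presets.scenario("t25", period=period)), 2)
            sups.append(compare(pop_fn, pop_an).sup_norm)
        assert sups[1] < sups[0]

    def test_constant_nest_unaffected_by_partner(self):
        cfg = presets.scenario("t25")
        cfg_avg = replace(cfg, nest2=averaged_nest(cfg.nest2))
        pop_cn_fn = nest_population(integrate_windowed(cfg), 1)
        pop_cn_an = nest_population(integrate_windowed(cfg_avg), 1)
        assert compare(pop_cn_fn, pop_cn_an).sup_norm < presets.overlap_tolerance("t25")

    def test_half_good_fluctuating_nest_tracks_constant_nest(self):
        traj = integrate_windowed(presets.scenario("t50"))
        m = compare(nest_population(traj, 1), nest_population(traj, 2))
        assert m.sup_norm < presets.overlap_tolerance("t50")

    def test_treatment_ordering_of_final_populations(self):
        finals = [nest_population(integrate_windowed(presets.scenario(n)), 2)[-1]
                  for n in ("t25", "t50", "t75")]
        assert finals[0] < finals[1] < finals[2]


class TestTrajectoryOutput:
    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        traj = integrate_windowed(presets.scenario("t50"))
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["time_min", "X", "Z1", "Y1", "B1",
                                    "Z2", "Y2", "B2", "P", "pop1", "pop2"]
        assert len(df) == 181
        assert df["pop2"].iloc[-1] == pytest.approx(
            nest_population(traj, 2)[-1])

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            presets.scenario("t99")
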