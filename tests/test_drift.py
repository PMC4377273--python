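"""Drift simulation: release arithmetic, advection, growth, conservation."""

import numpy as np
import pytest

import larvamatch as lm
from larvamatch.drift import DriftState, step

from conftest import make_uniform_fields


class TestReleases:
    def test_default_schedule_eleven_grounds_total(self):
        particles = lm.generate_releases(lm.ReleaseSchedule(), lm.default_grounds())
        assert len(particles) == 69_300

    def test_single_ground_default_schedule(self):
        ground = lm.default_grounds()[:1]
        particles = lm.generate_releases(lm.ReleaseSchedule(), ground)
        assert len(particles) == 6_300  # 300 particles x 21 release dates

    def test_degenerate_schedule_single_release(self):
        sched = lm.ReleaseSchedule(period=61)
        particles = lm.generate_releases(sched, lm.default_grounds()[:1])
        assert len(particles) == 300
        assert np.all(particles.release_day == 0)

    def test_release_dates_span_march_april(self):
        days = lm.ReleaseSchedule().release_days
        assert days[0] == 0 and days[-1] == 60 and len(days) == 21

    def test_particles_start_as_eggs_at_ground(self):
        grounds = lm.default_grounds()
        particles = lm.generate_releases(lm.ReleaseSchedule(jitter_km=0.0), grounds)
        p = particles[0]
        assert p.stage == "egg" and p.age == 0
        g = {g.id: g for g in grounds}[p.origin_ground]
        assert (p.x, p.y) == (g.x, g.y)

    def test_empty_grounds_rejected(self):
        with pytest.raises(ValueError, match="ground"):
            lm.generate_releases(lm.ReleaseSchedule(), [])

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            lm.ReleaseSchedule(start_day=10, end_day=5)


def _single_particle_state(x, y, release_day=0, mass=np.nan, day=0):
    return DriftState(
        day=day,
        x=np.array([float(x)]),
        y=np.array([float(y)]),
        mass=np.array([float(mass)]),
        release_day=np.array([release_day]),
        origin_ground=np.array([1]),
        exited=np.zeros(1, dtype=bool),
    )


class TestStep:
    def test_zero_velocity_positions_unchanged_ages_advance(self, tiny_fields):
        st = _single_particle_state(30.0, 100.0)
        step(st, tiny_fields, lm.DriftConfig())
        assert (st.x[0], st.y[0]) == (30.0, 100.0)
        assert st.day == 1 and st.age[0] == 1

    @pytest.mark.parametrize("integration", ["euler", "rk2"])
    def test_uniform_flow_closed_form_advection(self, integration):
        fields = make_uniform_fields(v=10.0)
        st = _single_particle_state(30.0, 50.0)
        cfg = lm.DriftConfig(integration=integration)
        for _ in range(10):
            step(st, fields, cfg)
        assert st.y[0] == pytest.approx(50.0 + 10 * 10.0, abs=1e-9)
        assert st.x[0] == pytest.approx(30.0, abs=1e-9)

    def test_growth_matches_exponential_closed_form_at_reference_sst(self):
        cfg = lm.DriftConfig(egg_duration=3)
        fields = make_uniform_fields(v=0.0, sst=cfg.t_ref)
        st = _single_particle_state(30.0, 50.0)
        n_days = 20
        for _ in range(n_days):
            step(st, fields, cfg)
        grown_days = n_days - cfg.egg_duration
        expected = cfg.initial_mass * np.exp(cfg.growth_rate_ref * grown_days)
        assert st.mass[0] == pytest.approx(expected, rel=1e-12)

    def test_growth_faster_in_warm_water(self):
        cfg = lm.DriftConfig(egg_duration=0)
        warm = make_uniform_fields(v=0.0, sst=cfg.t_ref + 5)
        cold = make_uniform_fields(v=0.0, sst=cfg.t_ref - 5)
        sw, sc = _single_particle_state(30, 50), _single_particle_state(30, 50)
        sw.mass[0] = sc.mass[0] = cfg.initial_mass
        for _ in range(10):
            step(sw, warm, cfg)
            step(sc, cold, cfg)
        assert sw.mass[0] > sc.mass[0]

    def test_land_policy_hold_keeps_particle_off_land(self):
        fields = make_uniform_fields(v=0.0)
        off = ~fields.land_mask
        fields.u[:, off] = -30.0  # strong onshore flow
        st = _single_particle_state(5.0, 50.0)
        step(st, fields, lm.DriftConfig(land_policy="hold"))
        assert st.x[0] >= 0.0

    def test_open_boundary_clamps_and_flags(self):
        fields = make_uniform_fields(v=50.0, ny=12)
        st = _single_particle_state(30.0, 110.0)
        step(st, fields, lm.DriftConfig())
        assert st.y[0] <= fields.grid.y_max
        assert st.exited[0]

    def test_day_outside_coverage_rejected(self, tiny_fields):
        st = _single_particle_state(30.0, 50.0, day=tiny_fields.n_days)
        with pytest.raises(ValueError, match="coverage"):
            step(st, tiny_fields, lm.DriftConfig())

    def test_timestep_must_divide_day(self):
        with pytest.raises(ValueError, match="timestep"):
            lm.DriftConfig(timestep=0.3)
        lm.DriftConfig(timestep=0.25)  # valid


def _small_run(integration="euler", timestep=1.0, v=8.0, seed=0):
    fields = make_uniform_fields(v=v, ny=60, n_days=40)
    sched = lm.ReleaseSchedule(end_day=12, period=3, particles_per_release=20, seed=seed)
    cfg = lm.DriftConfig(integration=integration, timestep=timestep)
    return lm.run_simulation(fields, sched, lm.default_grounds()[:3], cfg)


class TestRunSimulation:
    def test_particle_count_conserved_every_day(self):
        history = _small_run()
        released = np.sort(history.release_day)
        for day in history.days:
            assert history.n_alive(int(day)) == int(np.sum(released <= day))

    def test_full_count_after_release_window(self, scenario_run):
        history = scenario_run("matched_wave")["history"]
        expected = 50 * 21 * 11
        assert history.n_particles == expected
        for day in (61, 100, 183):
            assert history.n_alive(day) == expected

    def test_determinism_identical_histories(self):
        a, b = _small_run(seed=5), _small_run(seed=5)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.mass, b.mass)

    def test_stage_transition_exactly_once_at_egg_duration(self):
        history = _small_run()
        egg = lm.DriftConfig().egg_duration
        for day in history.days:
            age = int(day) - history.release_day
            larvae = history.stage_mask(int(day), "larva")
            np.testing.assert_array_equal(larvae, (age >= egg))
            assert not np.any(larvae & (age < egg))

    def test_mass_nondecreasing_and_undefined_for_eggs(self):
        history = _small_run()
        egg = lm.DriftConfig().egg_duration
        for i in range(0, history.n_particles, 7):
            rel = history.release_day[i]
            m = history.mass[:, i]
            age = history.days - rel
            assert np.all(np.isnan(m[(age >= 0) & (age < egg)]))
            larval = m[age >= egg]
            assert np.all(np.diff(larval) >= 0)
            assert larval[0] == lm.DriftConfig().initial_mass

    def test_euler_halving_timestep_shrinks_error_roughly_linearly(self):
        # smooth sheared field: v depends on x through the jet profile
        grid = lm.GridSpec(nx=20, ny=80, n_days=30)
        fields = lm.make_coastal_fields(grid, lm.OceanParams(jet_speed=10.0, eddy_amplitude=0.0))
        # give the flow an offshore component so trajectories cross the shear
        fields.u[:, ~fields.land_mask] = 2.0

        def final_y(ts):
            st = _single_particle_state(10.0, 50.0)
            cfg = lm.DriftConfig(timestep=ts)
            for day in range(20):
                st.day = day
                step(st, fields, cfg)
            return st.y[0]

        ref = final_y(0.125)
        err_1 = abs(final_y(1.0) - ref)
        err_05 = abs(final_y(0.5) - ref)
        assert err_05 < err_1
        assert err_05 == pytest.approx(err_1 / 2, rel=0.5)

    def test_history_frame_round_trip(self):
        history = _small_run()
        frame = history.to_frame(days=[0, 5, 10, 20])
        back = lm.ParticleHistory.from_frame(frame, lm.DriftConfig().egg_duration)
        for day in (0, 5, 10, 20):
            k1, k2 = history.day_index(day), back.day_index(day)
            alive = history.alive_mask(day)
            np.testing.assert_allclose(
                np.sort(history.x[k1, alive]), np.sort(back.x[k2, back.alive_mask(day)])
            )
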