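"""Lagrangian tracker: time-step rule, diffusivity, interpolation, advection,
boundary rules, vertical migration, release scheduling and full integration."""

import numpy as np
import pytest

from mpaconnect.geo import haversine_km
from mpaconnect.grids import ValidationError
from mpaconnect.synth import SyntheticDomainConfig, synth_flow
from mpaconnect.tracker import (ACTIVE, LOST, STANDSTILL, CoverageError,
                                SimulationConfig, advect_step,
                                apply_boundaries, choose_time_step,
                                horizontal_diffusivity, interpolate_velocity,
                                random_walk_velocity, release_cohort,
                                run_simulation, vertical_migration_step)
from conftest import make_grid, uniform_field, square_mpa


class TestTimeStepRule:
    @pytest.mark.parametrize("cell,vmax,expected", [
        (6000.0, 0.5, 12000.0),   # the 6 km / 0.5 m/s end of the admissible band
        (8000.0, 0.5, 16000.0),   # the 8 km end
        (1.0, 1.0, 1.0),
    ])
    def test_bound(self, cell, vmax, expected):
        assert choose_time_step(cell, vmax) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            choose_time_step(0.0, 1.0)
        with pytest.raises(ValidationError):
            choose_time_step(1000.0, -0.1)


class TestDiffusivity:
    def test_powers_of_ten(self):
        assert horizontal_diffusivity(1e-9, 1000.0) == pytest.approx(10.0)

    def test_high_precision_value(self):
        # eps^(1/3) * l^(4/3) evaluated independently for l = 7 km
        assert horizontal_diffusivity(1e-9, 7000.0) == pytest.approx(
            133.9051827940672, rel=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            horizontal_diffusivity(0.0, 1000.0)


class TestRandomWalk:
    def test_zero_kh_is_zero(self):
        rng = np.random.default_rng(0)
        u, v = random_walk_velocity(0.0, 7200.0, rng, n=100)
        assert np.all(u == 0) and np.all(v == 0)

    def test_bound_and_variance(self):
        rng = np.random.default_rng(1)
        kh, dt = 10.0, 7200.0
        bound = np.sqrt(2 * kh / dt)
        assert bound == pytest.approx(0.0527, abs=1e-4)
        u, v = random_walk_velocity(kh, dt, rng, n=100_000)
        assert np.abs(u).max() <= bound and np.abs(v).max() <= bound
        # Var(delta) = 1/3 -> component variance = (1/3) * 2 kh / dt
        assert u.var() == pytest.approx(2 * kh / dt / 3, rel=0.05)
        assert v.var() == pytest.approx(2 * kh / dt / 3, rel=0.05)


class TestInterpolation:
    def test_constant_field(self):
        grid = make_grid()
        f = uniform_field(grid, n_days=2, u=0.2)
        u, v, w = interpolate_velocity(f, grid, [3.3], [41.7], [5.0], 0)
        assert u[0] == pytest.approx(0.2)
        assert v[0] == 0.0 and w[0] == 0.0

    def test_node_identity_and_midpoint(self):
        grid = make_grid(res=0.5, depths=(1.0,))
        f = uniform_field(grid, n_days=1, u=0.0)
        iy, ix = 3, 4
        f.u[0, 0, iy, ix + 1] = 0.4  # neighbor east of the node
        lon0, lat0 = grid.lon_axis[ix], grid.lat_axis[iy]
        u, _, _ = interpolate_velocity(f, grid, [lon0], [lat0], [1.0], 0)
        assert u[0] == pytest.approx(0.0)
        u, _, _ = interpolate_velocity(f, grid, [grid.lon_axis[ix + 1]], [lat0], [1.0], 0)
        assert u[0] == pytest.approx(0.4)
        mid = 0.5 * (lon0 + grid.lon_axis[ix + 1])
        u, _, _ = interpolate_velocity(f, grid, [mid], [lat0], [1.0], 0)
        assert u[0] == pytest.approx(0.2)


class TestAdvection:
    def test_closed_form_step(self):
        # 0.1 m/s eastward for 7200 s = 720 m; at the equator that is
        # 720 / 111194.93 degrees of longitude
        lon, lat, dep = advect_step(0.0, 0.0, 1.0, 0.1, 0.0, 0.0, 7200.0)
        assert float(lon) == pytest.approx(0.00647511556, rel=1e-6)
        assert float(lat) == 0.0 and float(dep) == 1.0

    def test_zero_velocity_is_identity(self):
        lon, lat, dep = advect_step(3.0, 42.0, 0.2, 0.0, 0.0, 0.0, 7200.0)
        assert (float(lon), float(lat), float(dep)) == (3.0, 42.0, 0.2)

    def test_polar_guard(self):
        with pytest.raises(ValidationError, match="poleward"):
            advect_step(0.0, 89.9, 1.0, 0.1, 0.0, 0.0, 7200.0)


class TestBoundaries:
    def test_outside_box_is_lost(self, sea_grid):
        lon, lat, dep, st = apply_boundaries(
            [9.9], [42.0], [10.5], [42.0], [1.0], [ACTIVE], sea_grid)
        assert st[0] == LOST

    def test_surface_reflection(self, sea_grid):
        _, _, dep, st = apply_boundaries(
            [5.0], [42.0], [5.0], [42.0], [-0.05], [ACTIVE], sea_grid)
        assert dep[0] == pytest.approx(0.05)
        assert st[0] == ACTIVE

    def test_depth_clamped_to_deepest_level(self, sea_grid):
        _, _, dep, _ = apply_boundaries(
            [5.0], [42.0], [5.0], [42.0], [5000.0], [ACTIVE], sea_grid)
        assert dep[0] == sea_grid.depth_levels[-1]

    def test_standstill_freezes_at_last_sea_position(self):
        grid = make_grid(res=0.25, land_rows=2)
        cfg = SimulationConfig(pld_days=10.0, n_events=1, larvae_per_event=20,
                               kh=0.0, seed=3)
        # jet aimed at the northern coast
        f = uniform_field(grid, n_days=12, u=0.0, v=0.3)
        mpa = square_mpa(1, 5.0, 43.1, half=0.08)
        traj = run_simulation(f, grid, [mpa], cfg)
        assert np.all(traj.status == STANDSTILL)
        # frozen on the last sea row, south of the land band
        coast_lat = grid.lat_edges[-3]
        assert np.all(traj.final_lat < coast_lat)
        assert np.all(traj.final_lat > coast_lat - 0.3)


class TestVerticalMigration:
    def test_triggers(self, sea_grid):
        cfg = SimulationConfig(vertical_migration=True)
        # crossing 20:00 forces night depth
        d = vertical_migration_step([30.0], [5.0], [42.0],
                                    t_s=19.5 * 3600, dt_s=7200, cfg=cfg,
                                    grid=sea_grid)
        assert d[0] == pytest.approx(0.2)
        # crossing 08:00 forces day depth
        d = vertical_migration_step([0.2], [5.0], [42.0],
                                    t_s=7.5 * 3600, dt_s=7200, cfg=cfg,
                                    grid=sea_grid)
        assert d[0] == pytest.approx(50.0)

    def test_day_depth_capped_over_shallow_column(self):
        grid = make_grid(bathy=30.0, depths=(0.5, 10.0, 25.0, 60.0))
        cfg = SimulationConfig(vertical_migration=True)
        d = vertical_migration_step([0.2], [5.0], [42.0],
                                    t_s=7.5 * 3600, dt_s=7200, cfg=cfg,
                                    grid=grid)
        # deepest level midpoint above the 30 m seafloor
        assert d[0] == pytest.approx(25.0)

    def test_flag_off_is_identity(self, sea_grid):
        cfg = SimulationConfig(vertical_migration=False)
        d = vertical_migration_step([7.7], [5.0], [42.0], 19.5 * 3600, 7200,
                                    cfg, sea_grid)
        assert d[0] == 7.7


class TestRelease:
    def test_counts_and_depth(self, sea_grid):
        cfg = SimulationConfig(n_events=1, larvae_per_event=1000)
        rng = np.random.default_rng(0)
        cohort = release_cohort([square_mpa(1, 5.0, 42.0)], cfg, sea_grid, rng)
        assert len(cohort["lon"]) == 1000
        assert np.all(cohort["depth"] == 0.2)

    def test_default_schedule_gives_10000_per_mpa(self, sea_grid):
        cfg = SimulationConfig()  # 10 events x 1000 larvae
        rng = np.random.default_rng(0)
        mpas = [square_mpa(i, 2.0 * i, 42.0) for i in (1, 2)]
        cohort = release_cohort(mpas, cfg, sea_grid, rng)
        assert len(cohort["lon"]) == 20000
        assert np.all(np.unique(cohort["release_day"]) ==
                      np.arange(0, 30, 3))

    def test_release_points_inside_polygon(self, sea_grid):
        import shapely
        mpa = square_mpa(1, 5.0, 42.0, half=0.2)
        cfg = SimulationConfig(n_events=2, larvae_per_event=50)
        cohort = release_cohort([mpa], cfg, sea_grid, np.random.default_rng(1))
        assert shapely.intersects_xy(mpa.polygon, cohort["lon"], cohort["lat"]).all()


class TestRunSimulation:
    def test_stationary_without_flow_or_diffusion(self, sea_grid):
        cfg = SimulationConfig(pld_days=5.0, n_events=2, larvae_per_event=25,
                               kh=0.0, seed=0)
        f = uniform_field(sea_grid, n_days=10, u=0.0)
        traj = run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0)], cfg)
        np.testing.assert_array_equal(traj.final_lon, traj.release_lon)
        np.testing.assert_array_equal(traj.final_lat, traj.release_lat)

    def test_deterministic_under_seed(self, sea_grid):
        cfg = SimulationConfig(pld_days=3.0, n_events=1, larvae_per_event=30,
                               seed=7)
        f = uniform_field(sea_grid, n_days=5, u=0.05)
        a = run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0)], cfg)
        b = run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0)], cfg)
        np.testing.assert_array_equal(a.final_lon, b.final_lon)
        np.testing.assert_array_equal(a.final_lat, b.final_lat)

    @pytest.mark.parametrize("pld,expected_km", [(20, 172.8), (30, 259.2), (40, 345.6)])
    def test_uniform_flow_closed_form(self, pld, expected_km):
        grid = make_grid(lon0=0.0, lon1=10.0, lat0=40.0, lat1=44.0, res=0.25)
        cfg = SimulationConfig(pld_days=float(pld), n_events=1,
                               larvae_per_event=40, kh=0.0, seed=0)
        f = uniform_field(grid, n_days=pld + 2, u=0.1)
        traj = run_simulation(f, grid, [square_mpa(1, 1.0, 42.0)], cfg)
        d = haversine_km(traj.release_lon, traj.release_lat,
                         traj.final_lon, traj.final_lat)
        assert np.median(d) == pytest.approx(expected_km, rel=0.005)

    def test_solid_rotation_returns_to_start(self):
        # one full 30-day rotation with dt = T/1200 returns each particle
        # to its start within 1% of the orbit circumference
        grid = make_grid(lon0=-3, lon1=3, lat0=-3, lat1=3, res=0.125,
                         depths=(0.5, 10.0))
        cfg_flow = SyntheticDomainConfig(
            lon_min=-3, lon_max=3, lat_min=-3, lat_max=3,
            resolution_deg=0.125, coast_width_deg=0.0, n_mpas=1,
            flow_kind="solid_rotation", rotation_period_days=30.0)
        f = synth_flow(cfg_flow, grid, 32)
        cfg = SimulationConfig(pld_days=30.0, dt_s=2160.0, n_events=1,
                               larvae_per_event=20, kh=0.0, seed=0)
        mpa = square_mpa(1, 1.0, 0.0, half=0.05)
        traj = run_simulation(f, grid, [mpa], cfg)
        r_km = haversine_km(traj.release_lon, traj.release_lat, 0.0, 0.0)
        err_km = haversine_km(traj.release_lon, traj.release_lat,
                              traj.final_lon, traj.final_lat)
        circumference = 2 * np.pi * r_km
        assert np.all(traj.status == ACTIVE)
        assert np.all(err_km <= 0.01 * circumference)

    def test_diffusion_law_msd(self, sea_grid):
        # zero flow, kh > 0: mean displacement ~ 0 and
        # 2-D MSD = (4/3) kh t within 10% over >= 1000 particles
        kh, days = 20.0, 10.0
        cfg = SimulationConfig(pld_days=days, n_events=1,
                               larvae_per_event=1200, kh=kh, seed=42)
        f = uniform_field(sea_grid, n_days=int(days) + 2, u=0.0)
        traj = run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0, half=0.01)], cfg)
        m_per_deg = 111194.9266
        dx = (traj.final_lon - traj.release_lon) * m_per_deg * np.cos(np.radians(42.0))
        dy = (traj.final_lat - traj.release_lat) * m_per_deg
        t = days * 86400.0
        msd = float(np.mean(dx ** 2 + dy ** 2))
        assert msd == pytest.approx(4.0 / 3.0 * kh * t, rel=0.10)
        sigma = np.sqrt(2.0 / 3.0 * kh * t)
        assert abs(dx.mean()) < 5 * sigma / np.sqrt(len(dx))
        assert abs(dy.mean()) < 5 * sigma / np.sqrt(len(dy))

    def test_particle_conservation_statuses(self, sea_grid):
        cfg = SimulationConfig(pld_days=5.0, n_events=3, larvae_per_event=30,
                               seed=0)
        f = uniform_field(sea_grid, n_days=15, u=0.3)
        traj = run_simulation(f, sea_grid, [square_mpa(1, 9.0, 42.0)], cfg)
        n = (traj.status == ACTIVE).sum() + (traj.status == LOST).sum() \
            + (traj.status == STANDSTILL).sum()
        assert n == traj.n_particles

    def test_coverage_error(self, sea_grid):
        cfg = SimulationConfig(pld_days=30.0, n_events=10)
        f = uniform_field(sea_grid, n_days=20, u=0.0)
        with pytest.raises(CoverageError):
            run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0)], cfg)

    def test_inadmissible_dt_rejected(self, sea_grid):
        cfg = SimulationConfig(pld_days=2.0, dt_s=86400.0, n_events=1,
                               larvae_per_event=5)
        f = uniform_field(sea_grid, n_days=5, u=1.0)
        with pytest.raises(ValidationError, match="admissible"):
            run_simulation(f, sea_grid, [square_mpa(1, 5.0, 42.0)], cfg)

    def test_daily_records(self, sea_grid):
        cfg = SimulationConfig(pld_days=3.0, n_events=1, larvae_per_event=10,
                               kh=0.0, seed=0)
        f = uniform_field(sea_grid, n_days=5, u=0.1)
        traj = run_simulation(f, sea_grid, [square_mpa(1, 2.0, 42.0)], cfg,
                              record_trajectories=True)
        assert np.all(np.diff(traj.record_times_s) == 86400.0)
        assert traj.traj_lon.shape == (len(traj.record_times_s), 10)


def test_vertical_migration_reduces_dispersal_in_sheared_flow():
    """Diel migration spends half the day in the weaker deep flow, so median
    dispersal must drop relative to passive surface transport."""
    grid = make_grid(res=0.25, depths=(0.5, 10.0, 30.0, 60.0, 120.0))
    cfg_flow = SyntheticDomainConfig(lon_min=0, lon_max=10, lat_min=40,
                                     lat_max=44, resolution_deg=0.25,
                                     coast_width_deg=0.0, n_mpas=1,
                                     flow_kind="uniform",
                                     flow_amplitude_ms=0.15,
                                     vertical_decay_m=50.0)
    f = synth_flow(cfg_flow, grid, 14)
    base = dict(pld_days=10.0, n_events=1, larvae_per_event=60, kh=0.0, seed=5)
    mpa = square_mpa(1, 1.5, 42.0)
    passive = run_simulation(f, grid, [mpa], SimulationConfig(**base))
    vm = run_simulation(f, grid, [mpa],
                        SimulationConfig(vertical_migration=True, **base))
    dp = np.median(haversine_km(passive.release_lon, passive.release_lat,
                                passive.final_lon, passive.final_lat))
    dv = np.median(haversine_km(vm.release_lon, vm.release_lat,
                                vm.final_lon, vm.final_lat))
    assert dv < dp
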