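import numpy as np
import pytest

from bloomweb import (
    BloomStack,
    EnvResponse,
    GridSpec,
    allocate_effort,
    build_scenario_grid,
    default_env_responses,
    gen_blooms,
    gen_drivers,
    habitat_capacity,
    movement_step,
    run_simulation,
    simulate_cell,
)
from bloomweb.spatial import CAPACITY_FLOOR

from conftest import make_uniform_drivers


class TestHabitatCapacity:
    def test_product_and_floor(self):
        r1 = EnvResponse("sst", midpoint=20.0, slope=100.0, ref=None)
        # saturated logistic -> response 1
        assert habitat_capacity({"sst": 30.0}, [r1]) == pytest.approx(1.0)
        assert habitat_capacity({"sst": 30.0}, [], foraging=0.0) == CAPACITY_FLOOR
        # two responses at 0.8 and 0.5 multiply to 0.4
        assert habitat_capacity({}, [], foraging=1.0) == 1.0

    def test_normalised_response_is_one_at_reference(self):
        r = EnvResponse("sbt", midpoint=21.0, slope=0.5, ref=23.0)
        assert r.value(23.0) == pytest.approx(1.0)
        assert r.value(18.0) < 1.0

    def test_two_known_responses_multiply(self):
        vals = np.array([0.8, 0.5])

        class Fixed:
            variable = "sst"

            def __init__(self, v):
                self.v = v

            def value(self, x):
                return self.v

        cap = habitat_capacity({"sst": 0.0}, [Fixed(0.8), Fixed(0.5)])
        assert cap == pytest.approx(0.4)
        assert vals.prod() == pytest.approx(0.4)


class TestMovement:
    def test_uniform_field_unchanged_exactly(self, grid6):
        B = np.full((grid6.n_water, 2), 3.7)
        cap = np.full((grid6.n_water, 2), 0.8)
        out = movement_step(B, cap, np.array([300.0, 3.0]), 1.0, grid6)
        assert np.array_equal(out, B)

    def test_mass_conserved_on_random_fields(self, grid6):
        rng = np.random.default_rng(1)
        for _ in range(20):
            B = rng.uniform(0.01, 10.0, (grid6.n_water, 3))
            cap = rng.uniform(CAPACITY_FLOOR, 1.0, (grid6.n_water, 3))
            out = movement_step(B, cap, np.array([300.0, 30.0, 3.0]), 1.0, grid6)
            np.testing.assert_allclose(out.sum(0), B.sum(0), rtol=1e-12)
            assert (out >= 0).all()

    def test_biomass_accumulates_in_the_good_cell(self):
        mask = np.ones((2, 3), dtype=bool)
        mask[0, 1] = False
        mask[0, 2] = False
        g = GridSpec(2, 3, 5.0, mask)  # two water cells, horizontally adjacent
        B = np.full((2, 1), 1.0)
        cap = np.array([[1.0], [CAPACITY_FLOOR]])
        prev = B[0, 0]
        for _ in range(40):
            B = movement_step(B, cap, np.array([30.0]), 1.0, g)
            assert B[0, 0] > prev
            prev = B[0, 0]

    def test_outflow_capped_below_total(self, grid6):
        B = np.full((grid6.n_water, 1), 1.0)
        cap = np.full((grid6.n_water, 1), CAPACITY_FLOOR)  # maximal emigration
        out = movement_step(B, cap, np.array([3000.0]), 1.0, grid6)
        assert (out > 0).all()  # at most 95 % leaves any cell


class TestEffortAllocation:
    def test_uniform_biomass_zero_cost_uniform_effort(self):
        B = np.full((10, 2), 1.5)
        prices = np.array([[1.0, 0.0]])
        eff = allocate_effort(B, prices)
        np.testing.assert_allclose(eff, 1.0)

    def test_single_profitable_cell_takes_all_effort(self):
        B = np.zeros((4, 1))
        B[2, 0] = 5.0
        eff = allocate_effort(B, np.array([[1.0]]))
        np.testing.assert_allclose(eff[:, 0], [0, 0, 4.0, 0])

    def test_proportional_split(self):
        B = np.array([[3.0], [1.0]])
        eff = allocate_effort(B, np.array([[1.0]]))
        np.testing.assert_allclose(eff[:, 0] / eff[:, 0].sum(), [0.75, 0.25])

    def test_unprofitable_fleet_falls_back_to_uniform(self):
        B = np.full((5, 1), 1.0)
        eff = allocate_effort(B, np.array([[1.0]]), cost=np.full(5, 99.0))
        np.testing.assert_allclose(eff, 1.0)


class TestRunSimulation:
    def test_uniform_equilibrium_persists_spatially(self, model10):
        grid = GridSpec.regular(6, 6)
        drv = make_uniform_drivers(grid, 12)
        env = default_env_responses(model10, drv)
        st = run_simulation(
            model10, grid, drv, n_months=24, spinup_months=0, env_responses=env
        )
        assert st.stable
        drift = np.abs(st.B / model10.B[None, None, :] - 1).max()
        assert drift < 1e-3
        # spatial uniformity preserved by symmetry
        assert np.abs(st.B[-1].std(axis=0)).max() < 1e-10

    def test_one_cell_grid_matches_single_cell_oracle(self, model8, one_cell_grid):
        grid = one_cell_grid
        drv = gen_drivers(grid, 30, seed=12)
        env = default_env_responses(model8, drv)
        st = run_simulation(
            model8, grid, drv, n_months=18, spinup_months=12, env_responses=env
        )
        water = grid.water_mask
        chl = drv.data["chlorophyll"][:, water][:, 0]
        cap = np.ones((30, model8.n_groups))
        for i, name in enumerate(model8.names):
            for r in env.get(name, []):
                cap[:, i] *= r.value(drv.data[r.variable][:, water][:, 0])
        traj = simulate_cell(
            model8,
            n_months=18,
            spinup_months=12,
            chl_rel=chl / chl.mean(),
            capacity=np.maximum(cap, CAPACITY_FLOOR),
        )
        rel = np.abs(st.B[:, 0, :] - traj) / np.maximum(np.abs(traj), 1e-300)
        assert rel.max() < 1e-8

    def test_zero_bloom_scenarios_equal_baseline(self, model8):
        grid = GridSpec.regular(5, 5)
        drv = gen_drivers(grid, 18, seed=4)
        env = default_env_responses(model8, drv)
        zeros = BloomStack.zeros(grid, 1)
        base = run_simulation(
            model8, grid, drv, n_months=12, spinup_months=6, env_responses=env
        )
        scen = build_scenario_grid(model8.names[4])
        for s in (scen[0], scen[30], scen[85], scen[140]):
            st = run_simulation(
                model8,
                grid,
                drv,
                blooms=zeros,
                scenario=s,
                n_months=12,
                spinup_months=6,
                env_responses=env,
            )
            assert np.abs(st.B - base.B).max() <= 1e-12

    def test_bloom_kill_recorded_and_routed_to_detritus(self, model8):
        grid = GridSpec.regular(6, 6)
        drv = make_uniform_drivers(grid, 36)
        blooms = gen_blooms(grid, 1, severe_years=[0], seed=3)
        scen = [s for s in build_scenario_grid(model8.names[4]) if s.foraging is None][0]
        st = run_simulation(
            model8,
            grid,
            drv,
            blooms=blooms,
            scenario=scen,
            n_months=12,
            spinup_months=6,
            env_responses={},
        )
        assert st.loss.sum() > 0
        assert (st.loss >= 0).all()
        # only consumers are targeted in the all-consumer block
        for i in np.nonzero(~model8.is_consumer)[0]:
            assert st.loss[:, :, i].sum() == 0

    def test_instability_is_flagged_not_silent(self, model8):
        grid = GridSpec.regular(4, 4)
        drv = make_uniform_drivers(grid, 12)
        exploded = model8.copy()
        exploded.landings *= 400.0  # absurd catchability crashes harvested stocks
        st = run_simulation(
            exploded, grid, drv, n_months=24, spinup_months=0, env_responses={}
        )
        assert not st.stable
        assert "reason" in st.diagnostics

    def test_netcdf_roundtrip_shape(self, tmp_path, model8):
        grid = GridSpec.regular(4, 4)
        drv = make_uniform_drivers(grid, 12)
        st = run_simulation(model8, grid, drv, n_months=12, spinup_months=0, env_responses={})
        p = tmp_path / "traj.nc"
        st.to_netcdf(p)
        import xarray as xr

        ds = xr.open_dataset(p, engine="scipy")
        assert ds["biomass"].shape == (12, 4, 4, model8.n_groups)
        ds.close()
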