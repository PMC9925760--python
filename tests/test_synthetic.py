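import numpy as np
import pytest
from scipy import stats

from bloomweb import (
    BloomStack,
    GridSpec,
    SurveyDesign,
    check_balance,
    gen_blooms,
    gen_drivers,
    gen_foodweb,
    gen_surveys,
)
from bloomweb.foodweb import TRAITS


class TestFoodwebGenerator:
    def test_balance_holds_to_solver_tolerance(self, model10):
        rep = check_balance(model10)
        assert rep["residual"].abs().max() < 1e-9
        assert ((model10.EE >= 0) & (model10.EE <= 1)).all()

    def test_diets_sum_to_one(self, model10):
        rows = model10.DC.sum(axis=1)
        np.testing.assert_allclose(rows[model10.is_consumer], 1.0, atol=1e-12)

    def test_seeded_determinism_bit_identical(self):
        a = gen_foodweb(12, 2, seed=7)
        b = gen_foodweb(12, 2, seed=7)
        assert a.names == b.names
        for attr in ("B", "PB", "QB", "EE", "DC", "landings", "M0base", "dispersal"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_tags_fleets_and_minimum_structure(self, model10):
        assert set(model10.trait) <= set(TRAITS)
        assert model10.is_producer.sum() >= 1
        assert model10.is_detritus.sum() == 1
        assert model10.is_consumer.sum() >= 2
        # every fleet lands at least one group
        assert (model10.landings.sum(axis=1) > 0).all()

    def test_minimal_four_group_web(self):
        m = gen_foodweb(4, 1, seed=1)
        assert m.n_groups == 4
        assert check_balance(m)["balanced"].all()

    def test_rejects_impossible_configuration(self):
        with pytest.raises(ValueError):
            gen_foodweb(3, 1, seed=0)


class TestDriverGenerator:
    def test_seasonality_and_static_fields(self, grid6):
        d = gen_drivers(grid6, 24, seed=3)
        water = grid6.water_mask
        # depth and rugosity identical across months
        assert np.array_equal(d.data["depth"][0][water], d.data["depth"][13][water])
        assert np.array_equal(d.data["rugosity"][0][water], d.data["rugosity"][20][water])
        # same calendar month differs only by the (bounded) noise term
        diff = d.data["sst"][1][water] - d.data["sst"][13][water]
        seasonal = d.data["sst"][1][water] - d.data["sst"][7][water]
        assert np.abs(diff).max() < np.abs(seasonal).mean()

    def test_depth_increases_offshore(self, grid6):
        d = gen_drivers(grid6, 12, seed=3)
        water = grid6.water_mask
        rho = stats.spearmanr(
            grid6.coast_distance[water], d.data["depth"][0][water]
        ).statistic
        assert rho > 0

    def test_determinism_and_no_gaps_on_water(self, grid6):
        a = gen_drivers(grid6, 12, seed=9)
        b = gen_drivers(grid6, 12, seed=9)
        for v in a.data:
            assert np.array_equal(a.data[v][:, grid6.water_mask], b.data[v][:, grid6.water_mask])
            assert np.isfinite(a.data[v][:, grid6.water_mask]).all()

    def test_too_short_stack_rejected(self, grid6):
        with pytest.raises(ValueError):
            gen_drivers(grid6, 6, seed=0)


class TestBloomGenerator:
    def test_no_severe_years_stay_below_ceiling(self):
        g = GridSpec.regular(10, 10)
        b = gen_blooms(g, 3, severe_years=[], seed=4, normal_amp=(1e4, 8e4))
        # background + superposed kernels stays well under the severe range
        assert b.x.max() < 2e5

    def test_severe_year_footprint_strictly_greatest(self):
        g = GridSpec.regular(10, 10)
        b = gen_blooms(g, 4, severe_years=[2], seed=4)
        areas = [b.footprint_area(y, 1e5) for y in range(4)]
        assert areas[2] == max(areas)
        assert all(areas[2] > a for y, a in enumerate(areas) if y != 2)
        q90 = [np.quantile(b.x[12 * y : 12 * (y + 1)][:, g.water_mask], 0.9) for y in range(4)]
        assert q90[2] == max(q90)

    def test_land_is_zero_water_at_least_background(self):
        g = GridSpec.regular(8, 8)
        b = gen_blooms(g, 2, severe_years=[1], seed=0)
        assert (b.x[:, g.land_mask] == 0).all()
        assert (b.x[:, g.water_mask] >= b.background).all()

    def test_quiet_months_exactly_background(self):
        g = GridSpec.regular(8, 8)
        b = gen_blooms(g, 2, seed=1)
        # winter/spring months away from the peak window are untouched
        quiet = b.x[1][g.water_mask]
        assert np.all(quiet == b.background)

    def test_coastal_exceeds_offshore_when_active(self):
        g = GridSpec.regular(12, 12)
        b = gen_blooms(g, 3, severe_years=[1], seed=5)
        cd = g.coast_distance[g.water_mask]
        coastal = cd <= np.quantile(cd, 0.3)
        for t in range(b.n_months):
            xw = b.x[t][g.water_mask]
            if xw.max() > b.background:
                assert xw[coastal].mean() >= xw[~coastal].mean()

    def test_determinism_and_bad_years_rejected(self):
        g = GridSpec.regular(6, 6)
        assert np.array_equal(gen_blooms(g, 2, seed=3).x, gen_blooms(g, 2, seed=3).x)
        with pytest.raises(ValueError):
            gen_blooms(g, 2, severe_years=[5], seed=0)

    def test_zeros_stack_is_all_zero(self):
        g = GridSpec.regular(5, 5)
        z = BloomStack.zeros(g, 2)
        assert z.x.sum() == 0


class _FakeState:
    """Minimal trajectory stand-in for survey sampling."""

    def __init__(self, grid, names, B):
        self.grid = grid
        self.group_names = names
        self.B = B


@pytest.fixture()
def flat_state(grid6):
    B = np.full((3, grid6.n_water, 2), 0.0)
    B[:, :, 0] = 2.0
    B[:, :, 1] = 0.5
    return _FakeState(grid6, ["a", "b"], B)


class TestSurveyGenerator:
    def test_zero_error_reproduces_cell_biomass(self, flat_state, grid6):
        cells = list(zip(*grid6.water_rc))[:5]
        d = SurveyDesign(timesteps=[0, 2], groups=["a", "b"], cells=cells, sigma=0.0)
        tab = gen_surveys(flat_state, d, seed=1)
        assert np.allclose(tab["observed"], 2.5)
        assert np.allclose(tab["observed"], tab["true_biomass"])

    def test_fixed_seed_identical_tables(self, flat_state, grid6):
        cells = list(zip(*grid6.water_rc))[:5]
        d = SurveyDesign(timesteps=[1], groups=["a"], cells=cells, sigma=0.4)
        t1 = gen_surveys(flat_state, d, seed=11)
        t2 = gen_surveys(flat_state, d, seed=11)
        assert t1.equals(t2)

    def test_mean_corrected_error_is_unbiased(self, grid6):
        # 500 stations on uniform biomass: mean within 3 SE of the truth
        B = np.full((1, grid6.n_water, 1), 3.0)
        st = _FakeState(grid6, ["a"], B)
        cells = list(zip(*grid6.water_rc))
        sigma = 0.3
        reps = int(np.ceil(500 / len(cells)))
        obs = []
        for k in range(reps):
            d = SurveyDesign(timesteps=[0], groups=["a"], cells=cells, sigma=sigma)
            obs.append(gen_surveys(st, d, seed=100 + k)["observed"].to_numpy())
        obs = np.concatenate(obs)[:500]
        se = obs.std(ddof=1) / np.sqrt(len(obs))
        assert abs(obs.mean() - 3.0) < 3 * se

    def test_design_outside_grid_rejected(self, flat_state):
        d = SurveyDesign(timesteps=[0], groups=["a"], cells=[(99, 99)])
        with pytest.raises(ValueError):
            gen_surveys(flat_state, d, seed=0)
        d_land = SurveyDesign(timesteps=[0], groups=["a"], cells=[(0, 0)])
        with pytest.raises(ValueError):
            gen_surveys(flat_state, d_land, seed=0)
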