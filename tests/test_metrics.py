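import numpy as np
import pandas as pd
import pytest

from bloomweb import (
    FoodWebModel,
    GridSpec,
    before_after_in_out,
    community_aggregate,
    ecosystem_indicators,
    mortality_index,
    rmse_log,
    screen_scenarios,
)
from bloomweb.spatial import SpatialState


def toy_model(n=3, harvested=(1,), traits=None):
    names = [f"g{i}" for i in range(n)]
    m = FoodWebModel(
        names=names,
        group_type=["producer"] + ["consumer"] * (n - 1),
        B=np.ones(n),
        PB=np.full(n, 2.0),
        QB=np.r_[0.0, np.full(n - 1, 8.0)],
        EE=np.full(n, 0.5),
        BA=np.zeros(n),
        DC=np.vstack([np.zeros(n)] + [np.eye(n)[0]] * (n - 1)),
        landings=[[1.0 if i in harvested else 0.0 for i in range(n)]],
        fleet_names=["f"],
    )
    if traits is not None:
        m.trait = np.asarray(traits, dtype=object)
    return m


def make_state(grid, model, B, loss=None, catch=None):
    T = B.shape[0]
    return SpatialState(
        grid=grid,
        model=model,
        months=T,
        spinup_months=0,
        B=B,
        loss=np.zeros_like(B) if loss is None else loss,
        catch=np.zeros((T, B.shape[1], 1, B.shape[2])) if catch is None else catch,
        capacity=np.ones_like(B),
    )


@pytest.fixture()
def uniform_state(grid6):
    model = toy_model()
    B = np.full((24, grid6.n_water, 3), 2.0)
    return make_state(grid6, model, B)


class TestEcosystemIndicators:
    def test_uniform_biomass_gives_summed_constant(self, uniform_state):
        ind = ecosystem_indicators(uniform_state)
        assert len(ind) == 2
        np.testing.assert_allclose(ind["B_T"], 6.0)  # 3 groups × 2 each
        np.testing.assert_allclose(ind["B_har"], 2.0)
        np.testing.assert_allclose(ind["B_loss"], 0.0)

    def test_hand_built_two_cell_two_month_sums(self):
        mask = np.ones((2, 3), dtype=bool)
        mask[0, 1] = False
        mask[0, 2] = False
        grid = GridSpec(2, 3, 5.0, mask)  # 2 water cells
        model = toy_model(n=2)
        B = np.zeros((12, 2, 2))
        B[:, 0, 0], B[:, 1, 0] = 1.0, 3.0  # group 0 spatial mean 2
        B[:, 0, 1], B[:, 1, 1] = 2.0, 2.0  # group 1 spatial mean 2
        loss = np.zeros_like(B)
        loss[3, :, 1] = 0.5  # one month, both cells, group 1
        catch = np.zeros((12, 2, 1, 2))
        catch[:, :, 0, 1] = 0.1  # per month per cell
        st = make_state(grid, model, B, loss=loss, catch=catch)
        ind = ecosystem_indicators(st)
        assert ind.loc[0, "B_T"] == pytest.approx(4.0)
        assert ind.loc[0, "B_har"] == pytest.approx(2.0)
        assert ind.loc[0, "B_loss"] == pytest.approx(0.5)
        assert ind.loc[0, "C_T"] == pytest.approx(12 * 0.1)

    def test_juveniles_excluded(self, grid6):
        model = toy_model()
        model.juvenile[2] = True
        B = np.full((12, grid6.n_water, 3), 2.0)
        ind = ecosystem_indicators(make_state(grid6, model, B))
        np.testing.assert_allclose(ind["B_T"], 4.0)

    def test_indicator_linearity_over_group_partition(self, grid6):
        model = toy_model()
        rng = np.random.default_rng(5)
        B = rng.uniform(0.5, 2.0, (12, grid6.n_water, 3))
        st = make_state(grid6, model, B)
        full = ecosystem_indicators(st)["B_T"].to_numpy()
        parts = []
        for keep in range(3):
            B_part = np.zeros_like(B)
            B_part[:, :, keep] = B[:, :, keep]
            parts.append(ecosystem_indicators(make_state(grid6, model, B_part))["B_T"].to_numpy())
        np.testing.assert_allclose(sum(parts), full, rtol=1e-12)


class TestMortalityIndex:
    def test_zero_loss_zero_index(self, uniform_state):
        assert (mortality_index(uniform_state, "g1") == 0).all()

    def test_uniform_single_month_kill_equals_proportion(self, grid6):
        model = toy_model()
        S = grid6.n_water
        b = 2.0
        B = np.full((12, S, 3), b)
        loss = np.zeros_like(B)
        loss[5, :, 1] = 0.1 * b  # A = 0.1 everywhere, one month
        st = make_state(grid6, model, B, loss=loss)
        idx = mortality_index(st, "g1")
        assert idx.iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_ratio_invariant_under_joint_scaling(self, grid6):
        model = toy_model()
        rng = np.random.default_rng(2)
        B = rng.uniform(1, 3, (12, grid6.n_water, 3))
        loss = 0.05 * B
        st1 = make_state(grid6, model, B, loss=loss)
        st2 = make_state(grid6, model, 2 * B, loss=2 * loss)
        pd.testing.assert_series_equal(mortality_index(st1, "g2"), mortality_index(st2, "g2"))

    def test_zero_biomass_reported_missing(self, grid6):
        model = toy_model()
        B = np.zeros((12, grid6.n_water, 3))
        st = make_state(grid6, model, B)
        assert mortality_index(st, "g0").isna().all()


class TestCommunityAggregate:
    def test_single_class_equals_total(self, grid6):
        model = toy_model(traits=["demersal"] * 3)
        B = np.full((12, grid6.n_water, 3), 1.5)
        agg = community_aggregate(make_state(grid6, model, B))
        assert agg["class"].nunique() == 1
        np.testing.assert_allclose(agg["biomass"], 4.5)

    def test_two_class_split_matches_hand_sums(self, grid6):
        model = toy_model(traits=["producer", "demersal", "upper_tl_pelagic"])
        B = np.full((12, grid6.n_water, 3), 1.0)
        B[:, :, 2] = 3.0
        agg = community_aggregate(make_state(grid6, model, B))
        vals = agg.groupby("class")["biomass"].first()
        assert vals["demersal"] == pytest.approx(1.0)
        assert vals["upper_tl_pelagic"] == pytest.approx(3.0)
        assert vals["producer"] == pytest.approx(1.0)


class TestScreening:
    @pytest.fixture()
    def runs(self):
        rng = np.random.default_rng(8)
        return pd.DataFrame(
            {
                "scenario_id": [f"S{i:03d}" for i in range(40)],
                "loss_rate": rng.uniform(0.3, 1.3, 40),
                "rmse": rng.uniform(0.05, 0.5, 40),
            }
        )

    def test_matches_brute_force_filter(self, runs):
        accepted = screen_scenarios(runs, mu=0.77, sd=0.12, rmse_tol=0.10)
        rmin = runs["rmse"].min()
        brute = sorted(
            row["scenario_id"]
            for _, row in runs.iterrows()
            if abs(row["loss_rate"] - 0.77) <= 0.24 and row["rmse"] <= 1.10 * rmin
        )
        assert accepted == brute

    def test_perfect_run_accepted_outlier_rejected(self, runs):
        runs.loc[0, ["loss_rate", "rmse"]] = 0.77, runs["rmse"].min()
        runs.loc[1, "loss_rate"] = 0.77 + 3 * 0.12
        runs.loc[1, "rmse"] = runs["rmse"].min()
        accepted = screen_scenarios(runs)
        assert "S000" in accepted and "S001" not in accepted

    def test_idempotent_and_order_independent(self, runs):
        a = screen_scenarios(runs)
        shuffled = runs.sample(frac=1.0, random_state=1)
        assert screen_scenarios(shuffled) == a
        assert screen_scenarios(runs.loc[runs["scenario_id"].isin(a)] if a else runs) is not None

    def test_empty_run_set_rejected(self):
        with pytest.raises(ValueError):
            screen_scenarios(pd.DataFrame(columns=["scenario_id", "loss_rate", "rmse"]))


class TestRmseLog:
    def test_zero_for_proportional_series(self):
        x = np.array([1.0, 2.0, 4.0])
        assert rmse_log(5 * x, x) == pytest.approx(0.0, abs=1e-12)

    def test_positive_for_shape_mismatch(self):
        assert rmse_log(np.array([1.0, 2.0]), np.array([2.0, 1.0])) > 0


class TestBeforeAfterInOut:
    def test_identical_strata_zero_change(self, uniform_state):
        cells = list(zip(*uniform_state.grid.water_rc))[:6]
        df = before_after_in_out(uniform_state, ["g0"], ([0], cells), ([0], cells))
        assert df["pct_change"].iloc[1] == pytest.approx(0.0)

    def test_constant_field_zero_se(self, uniform_state):
        cells = list(zip(*uniform_state.grid.water_rc))
        df = before_after_in_out(uniform_state, ["g0", "g1"], ([0], cells), ([5], cells))
        np.testing.assert_allclose(df["se"], 0.0)
        np.testing.assert_allclose(df["mean"], 4.0)

    def test_imposed_half_kill_recovered(self, grid6):
        model = toy_model()
        B = np.full((2, grid6.n_water, 3), 2.0)
        inside = [rc for i, rc in enumerate(zip(*grid6.water_rc)) if i < 8]
        flat = {rc: i for i, rc in enumerate(zip(*grid6.water_rc))}
        for rc in inside:
            B[1, flat[rc], :] *= 0.5  # 50 % killed inside the bloom polygon
        st = make_state(grid6, model, B)
        outside = [rc for rc in zip(*grid6.water_rc) if rc not in inside]
        df = before_after_in_out(
            st, ["g0"], ([1], outside), ([1], inside), labels=("outside", "inside")
        )
        assert df["pct_change"].iloc[1] == pytest.approx(-50.0)
        df2 = before_after_in_out(st, ["g0"], ([0], inside), ([1], inside))
        assert df2["pct_change"].iloc[1] == pytest.approx(-50.0)

    def test_empty_stratum_rejected(self, uniform_state):
        with pytest.raises(ValueError):
            before_after_in_out(uniform_state, ["g0"], ([0], []), ([0], [(1, 1)]))
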