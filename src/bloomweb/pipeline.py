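"""End-to-end orchestration: generate inputs, run the scenario ensemble,
calibrate, compute metrics, screen, and validate — from one config.

Every stage draws its randomness from a child seed spawned from the master
seed, so a config (plus the code version) determines every output.  Ensemble
members are pure functions of (inputs, scenario), so serial and parallel
execution produce identical results.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .calibration import Parameter, SimulationRunner, iterate_fit, oat_sensitivity
from .grid import GridSpec
from .redtide import build_scenario_grid, scenario_table
from .spatial import default_env_responses, run_simulation
from .synthetic import (
    BloomStack,
    SurveyDesign,
    gen_blooms,
    gen_drivers,
    gen_foodweb,
    gen_surveys,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; fully serialisable."""

    seed: int = 0
    n_rows: int = 15
    n_cols: int = 15
    cell_width_km: float = 5.0
    n_groups: int = 10
    n_fleets: int = 2
    n_years: int = 4
    severe_years: list[int] = field(default_factory=lambda: [2])
    spinup_months: int = 24
    background_conc: float = 1e3
    scenario_subset: str = "all"  # all | mortality_only | with_foraging | single_target
    max_scenarios: int | None = None
    target_group: str | None = None  # default: first harvested consumer
    substeps: int = 4
    workers: int = 1
    calibrate: bool = False
    calibration_max_iter: int = 2
    calibration_top_k: int = 3
    calibration_candidates: int = 8
    screen_mu: float = 0.77
    screen_sd: float = 0.12
    screen_rmse_tol: float = 0.10
    bloom_threshold: float = 1e5
    save_trajectories: bool = False
    out_dir: str = "bloomweb_run"

    @property
    def n_months(self) -> int:
        return 12 * self.n_years

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _child_seeds(seed: int, n: int = 6) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_inputs(config: RunConfig):
    """Grid, food web, drivers and blooms for a config (stage 1)."""
    s_web, s_drv, s_blm, *_ = _child_seeds(config.seed)
    grid = GridSpec.regular(config.n_rows, config.n_cols, config.cell_width_km)
    model = gen_foodweb(config.n_groups, config.n_fleets, seed=s_web)
    total_months = config.spinup_months + config.n_months
    drivers = gen_drivers(grid, max(12, total_months), seed=s_drv)
    blooms = gen_blooms(
        grid,
        config.n_years,
        severe_years=config.severe_years,
        seed=s_blm,
        background=config.background_conc,
    )
    return grid, model, drivers, blooms


def pick_target_group(model, config: RunConfig) -> str:
    if config.target_group:
        return config.target_group
    harvested = [
        model.names[i]
        for i in range(model.n_groups)
        if model.harvested[i] and model.is_consumer[i]
    ]
    if not harvested:
        raise ValueError("no harvested consumer to target")
    demersal = [
        g for g in harvested if model.trait[model.index(g)] in ("demersal", "reef_associated")
    ]
    return (demersal or harvested)[0]


def select_scenarios(scenarios, config: RunConfig):
    subset = config.scenario_subset
    if subset == "mortality_only":
        sel = [s for s in scenarios if s.foraging is None]
    elif subset == "with_foraging":
        sel = [s for s in scenarios if s.foraging is not None]
    elif subset == "single_target":
        sel = [s for s in scenarios if s.target != "all_consumers"]
    else:
        sel = list(scenarios)
    if config.max_scenarios:
        sel = sel[: config.max_scenarios]
    return sel


def _run_one(args):
    (model, grid, drivers, blooms, scenario, config, env_responses) = args
    state = run_simulation(
        model,
        grid,
        drivers,
        blooms=blooms,
        scenario=scenario,
        n_months=config.n_months,
        spinup_months=config.spinup_months,
        env_responses=env_responses,
        substeps=config.substeps,
    )
    return scenario.id if scenario else "baseline", state


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run all stages; returns the artifact directory."""
    out = Path(out_dir or config.out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "trajectories").mkdir(exist_ok=True)

    grid, model, drivers, blooms = generate_inputs(config)
    target = pick_target_group(model, config)
    env_responses = default_env_responses(model, drivers)
    scenarios = build_scenario_grid(target)
    selected = select_scenarios(scenarios, config)

    # --- inputs -------------------------------------------------------
    model.to_csv_dir(out / "inputs")
    drivers.to_dataset().to_netcdf(out / "inputs" / "drivers.nc", engine="scipy")
    blooms.to_dataset().to_netcdf(out / "inputs" / "blooms.nc", engine="scipy")
    blooms.events.to_csv(out / "inputs" / "bloom_events.csv", index=False)
    scenario_table(scenarios).to_csv(out / "scenarios.csv", index=False)

    # --- baseline + ensemble -------------------------------------------
    jobs = [(model, grid, drivers, blooms, None, config, env_responses)]
    jobs += [(model, grid, drivers, blooms, s, config, env_responses) for s in selected]
    if config.workers > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as ex:
            results = list(ex.map(_run_one, jobs))
    else:
        results = [_run_one(j) for j in jobs]
    states = dict(results)
    baseline = states["baseline"]

    stability = {sid: bool(st.stable) for sid, st in states.items()}
    if config.save_trajectories:
        for sid, st in states.items():
            st.to_netcdf(out / "trajectories" / f"{sid}.nc")

    # --- indicators (unstable runs recorded but excluded) ---------------
    ind_rows = []
    base_ind = M.ecosystem_indicators(baseline)
    for sid, st in states.items():
        if not st.stable:
            continue
        ind = M.ecosystem_indicators(st)
        for _, row in ind.iterrows():
            y = int(row["year"])
            for metric in ("B_T", "B_har", "B_loss", "C_T"):
                base_val = float(base_ind.loc[base_ind["year"] == y, metric].iloc[0])
                ind_rows.append(
                    {
                        "scenario_id": sid,
                        "year": y,
                        "metric": metric,
                        "value": float(row[metric]),
                        "delta_vs_baseline": float(row[metric]) - base_val,
                    }
                )
    pd.DataFrame(ind_rows).to_csv(out / "indicators.csv", index=False)

    # --- calibration ----------------------------------------------------
    if config.calibrate:
        runner = SimulationRunner(
            model,
            grid,
            drivers,
            env_responses=env_responses,
            n_months=min(24, config.n_months),
            spinup_months=min(12, config.spinup_months),
            substeps=config.substeps,
        )
        from .dynamics import simulate_cell

        ref_monthly = simulate_cell(
            model,
            n_months=runner.n_months,
            spinup_months=runner.spinup_months,
        )
        ref = ref_monthly  # runner scores on the monthly domain-mean series
        params = [
            Parameter("vulnerability", model.names[i])
            for i in range(model.n_groups)
            if model.is_consumer[i]
        ] + [
            Parameter("dispersal", model.names[i])
            for i in range(model.n_groups)
            if not model.is_detritus[i]
        ]
        ranked = oat_sensitivity(runner, params, ref)
        top = [
            Parameter(row["kind"], row["group"])
            for _, row in ranked.head(config.calibration_top_k).iterrows()
        ]
        fit = iterate_fit(
            runner,
            ref,
            top,
            n_candidates=config.calibration_candidates,
            max_iter=config.calibration_max_iter,
        )
        fit.records.to_csv(out / "calibration_log.csv", index=False)
    else:
        pd.DataFrame(
            columns=["iteration", "parameter", "candidate", "pbias", "LL", "accepted"]
        ).to_csv(out / "calibration_log.csv", index=False)

    # --- screening -------------------------------------------------------
    *_, s_survey, s_obs = _child_seeds(config.seed)
    severe = config.severe_years[0] if config.severe_years else 0
    # observed index: survey-sampled baseline trajectory of the target group
    design = SurveyDesign(
        timesteps=[12 * y + 9 for y in range(config.n_years)],
        groups=[target],
        cells=[tuple(rc) for rc in zip(*baseline.grid.water_rc)][:: max(1, grid.n_water // 50)],
        sigma=0.2,
    )
    obs_tab = gen_surveys(baseline, design, seed=s_obs)
    obs_index = obs_tab.groupby("timestep")["observed"].mean().to_numpy()
    screen_rows = []
    for sid, st in states.items():
        if sid == "baseline" or not st.stable:
            continue
        rate = M.mortality_index(st, target).iloc[severe]
        sim_index = st.annual_mean()[:, model.index(target)]
        screen_rows.append(
            {
                "scenario_id": sid,
                "loss_rate": float(rate),
                "rmse": M.rmse_log(sim_index, obs_index),
            }
        )
    screening = pd.DataFrame(
        screen_rows, columns=["scenario_id", "loss_rate", "rmse"]
    )
    screening["accepted"] = False
    if len(screening):
        accepted = M.screen_scenarios(
            screening, mu=config.screen_mu, sd=config.screen_sd, rmse_tol=config.screen_rmse_tol
        )
        screening["accepted"] = screening["scenario_id"].isin(accepted)
    screening.to_csv(out / "screening.csv", index=False)

    # --- validation: before/after inside the severe-year bloom footprint --
    val_rows = []
    scen_states = [st for sid, st in states.items() if sid != "baseline" and st.stable]
    if scen_states and len(blooms.events):
        st = scen_states[0]
        year = severe
        months = range(12 * year, 12 * (year + 1))
        footprint = blooms.x[12 * year : 12 * (year + 1)].max(axis=0) > config.bloom_threshold
        inside = [
            (r, c) for r, c in zip(*grid.water_rc) if footprint[r, c]
        ]
        outside = [(r, c) for r, c in zip(*grid.water_rc) if not footprint[r, c]]
        peak = max(months, key=lambda t: blooms.x[t].sum())
        before_t, after_t = [max(0, 12 * year)], [min(st.B.shape[0] - 1, peak + 1)]
        groups = [model.names[i] for i in range(model.n_groups) if model.is_consumer[i]]
        if inside:
            ba = M.before_after_in_out(st, groups, (before_t, inside), (after_t, inside))
            ba["comparison"] = "before_after"
            val_rows.append(ba)
            if outside:
                io = M.before_after_in_out(
                    st, groups, (after_t, outside), (after_t, inside), labels=("outside", "inside")
                )
                io["comparison"] = "in_out"
                val_rows.append(io)
    (
        pd.concat(val_rows)
        if val_rows
        else pd.DataFrame(
            columns=["stratum", "mean", "se", "n_cells", "pct_change", "comparison"]
        )
    ).to_csv(out / "validation.csv", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "target_group": target,
        "n_scenarios_run": len(selected),
        "stability": stability,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
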