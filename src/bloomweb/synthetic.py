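"""Synthetic inputs: balanced food webs, driver rasters, bloom maps, surveys.

Everything the pipeline consumes is generated here with controllable seeds,
emulating the shapes and qualitative behaviour of shelf-ecosystem inputs: a
small mass-balanced food web with trait/taxon tags and fishing fleets;
monthly environmental rasters (depth, rugosity, SST, SBT, SSS, chlorophyll)
with a seasonal cycle, smooth spatial gradients and seeded noise; monthly
*K. brevis*-like bloom concentration maps that are coastal, patchy and
autumn-peaked with occasional severe years; and survey-like point samples
with lognormal observation error.

All generators are pure functions of their arguments: the same seed always
returns bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .foodweb import FoodWebModel
from .grid import GridSpec
from .massbalance import UnbalancedWebError, solve_balance

__all__ = [
    "DriverStack",
    "BloomStack",
    "SurveyDesign",
    "InfeasibleFoodWebError",
    "gen_foodweb",
    "gen_drivers",
    "gen_blooms",
    "gen_surveys",
]

DRIVER_VARS = ("depth", "rugosity", "sst", "sbt", "sss", "chlorophyll")

# name pools per trophic tier, cycled deterministically
_T1_NAMES = ["zooplankton", "benthic_grazers", "small_forage_fish", "shrimp"]
_T2_NAMES = ["demersal_fish", "reef_fish", "squid", "large_crabs", "mullet"]
_T3_NAMES = ["grouper", "coastal_sharks", "king_mackerel", "marine_mammals_grp"]


class InfeasibleFoodWebError(RuntimeError):
    """Parameter draws could not produce a balanced web within the retry budget."""


# ----------------------------------------------------------------------
@dataclass
class DriverStack:
    """Monthly environmental rasters aligned to a :class:`GridSpec`.

    ``data[var]`` has shape ``(n_months, n_rows, n_cols)`` with NaN on land.
    Static variables (depth, rugosity) are identical across months.
    """

    grid: GridSpec
    data: dict[str, np.ndarray]
    n_months: int

    def water_series(self, var: str) -> np.ndarray:
        """(n_months, n_water) view of one variable over water cells."""
        return self.data[var][:, self.grid.water_mask]

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": np.arange(self.n_months),
            "row": np.arange(self.grid.n_rows),
            "col": np.arange(self.grid.n_cols),
        }
        return xr.Dataset(
            {v: (("time", "row", "col"), a) for v, a in self.data.items()},
            coords=coords,
            attrs={"cell_width_km": self.grid.cell_width_km},
        )


@dataclass
class BloomStack:
    """Monthly bloom-concentration rasters (cells·L⁻¹) plus an event log."""

    grid: GridSpec
    x: np.ndarray  # (n_months, n_rows, n_cols); 0 on land
    severity: np.ndarray  # per-year scalar
    events: pd.DataFrame  # year, months, centroid, peak concentration
    background: float

    @property
    def n_months(self) -> int:
        return self.x.shape[0]

    @property
    def n_years(self) -> int:
        return self.x.shape[0] // 12

    def footprint_area(self, year: int, threshold: float) -> int:
        """Number of cell-months in a year with concentration above threshold."""
        sl = self.x[12 * year : 12 * (year + 1)]
        return int((sl > threshold).sum())

    @classmethod
    def zeros(cls, grid: GridSpec, n_years: int) -> "BloomStack":
        """An all-zero stack (used for no-forcing baseline equivalence runs)."""
        x = np.zeros((12 * n_years, grid.n_rows, grid.n_cols))
        return cls(
            grid=grid,
            x=x,
            severity=np.zeros(n_years),
            events=pd.DataFrame(
                columns=["year", "peak_month", "row", "col", "amplitude", "sigma_cells"]
            ),
            background=0.0,
        )

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"kbrevis": (("time", "row", "col"), self.x)},
            coords={
                "time": np.arange(self.n_months),
                "row": np.arange(self.grid.n_rows),
                "col": np.arange(self.grid.n_cols),
            },
            attrs={"units": "cells/L", "background": self.background},
        )


@dataclass
class SurveyDesign:
    """Which timesteps, stations and groups a synthetic survey samples."""

    timesteps: list[int]
    groups: list[str]
    cells: list[tuple[int, int]] | None = None
    polygon: object | None = None  # shapely geometry in km coordinates
    sigma: float = 0.3  # lognormal observation error sd (log scale)
    mean_corrected: bool = True


# ----------------------------------------------------------------------
def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 2.0) -> np.ndarray:
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    s = z.std()
    return z / s if s > 0 else z


def gen_foodweb(
    n_groups: int,
    n_fleets: int = 1,
    seed: int = 0,
    max_attempts: int = 30,
) -> FoodWebModel:
    """Generate a mass-balanced food web with trait/taxon tags and fleets.

    The web has one detritus pool, ≥1 producer and ≥2 consumers arranged in
    up to three trophic tiers.  Biomasses are set top-down from drawn
    ecotrophic-efficiency targets so the snapshot balances by construction;
    draws whose implied parameters leave plausible ranges are rejected and
    redrawn up to ``max_attempts`` times.
    """
    if n_groups < 4:
        raise ValueError("need n_groups >= 4 (producer, detritus, 2 consumers)")
    if n_fleets < 1:
        raise ValueError("need n_fleets >= 1")
    rng = np.random.default_rng(seed)

    n_det = 1
    n_prod = max(1, n_groups // 6)
    n_cons = n_groups - n_det - n_prod

    for _attempt in range(max_attempts):
        model = _draw_foodweb(rng, n_prod, n_cons, n_fleets)
        if model is not None:
            return model
    raise InfeasibleFoodWebError(
        f"no balanced web for n_groups={n_groups} after {max_attempts} draws"
    )


def _draw_foodweb(rng, n_prod, n_cons, n_fleets):
    # --- tier layout -------------------------------------------------
    if n_cons == 2:
        tiers = [1, 1]
    else:
        n_t1 = max(1, int(round(n_cons * 0.45)))
        n_t3 = max(1, int(round(n_cons * 0.25)))
        n_t2 = n_cons - n_t1 - n_t3
        if n_t2 < 1:
            n_t2, n_t3 = 1, max(1, n_cons - n_t1 - 1)
        tiers = [n_t1, n_t2, n_t3]

    names: list[str] = []
    gtype: list[str] = []
    tier_of: list[int] = []
    for p in range(n_prod):
        names.append("phytoplankton" if p == 0 else f"benthic_algae_{p}")
        gtype.append("producer")
        tier_of.append(0)
    pools = [_T1_NAMES, _T2_NAMES, _T3_NAMES]
    for k, nt in enumerate(tiers, start=1):
        for j in range(nt):
            pool = pools[k - 1]
            base = pool[j % len(pool)]
            suffix = "" if j < len(pool) else f"_{j // len(pool) + 1}"
            names.append(base + suffix)
            gtype.append("consumer")
            tier_of.append(k)
    names.append("detritus")
    gtype.append("detritus")
    tier_of.append(-1)

    n = len(names)
    tier_of = np.array(tier_of)
    gtype_arr = np.array(gtype, dtype=object)
    det = n - 1
    producers = np.nonzero(gtype_arr == "producer")[0]
    cons_idx = np.nonzero(gtype_arr == "consumer")[0]

    # --- rates -------------------------------------------------------
    QB = np.zeros(n)
    PB = np.zeros(n)
    qb_scale = {1: 15.0, 2: 8.0, 3: 4.0}
    for i in cons_idx:
        QB[i] = qb_scale[tier_of[i]] * np.exp(rng.normal(0.0, 0.25))
        ge = rng.uniform(0.15, 0.3)
        PB[i] = ge * QB[i]
    PB[producers] = rng.uniform(60.0, 160.0, size=len(producers))

    # --- diets -------------------------------------------------------
    DC = np.zeros((n, n))
    max_tier = tier_of.max()
    for j in cons_idx:
        k = tier_of[j]
        if k == 1:
            prey = list(producers) + [det]
            w = rng.dirichlet(np.ones(len(prey)) * 2.0)
            w[-1] *= rng.uniform(0.1, 0.5)  # modest detritivory
        else:
            prey = [i for i in cons_idx if tier_of[i] == k - 1]
            if k == 3:
                prey = prey + [i for i in cons_idx if tier_of[i] == 1]
            w = rng.dirichlet(np.ones(len(prey)) * 2.0)
        w = w / w.sum()
        DC[j, prey] = w

    # --- harvest selection ------------------------------------------
    upper = [i for i in cons_idx if tier_of[i] >= min(2, max_tier)]
    harvested = list(upper)
    extra = [i for i in cons_idx if i not in harvested]
    hi = 0
    while len(harvested) < n_fleets and hi < len(extra):
        harvested.append(extra[hi])
        hi += 1
    if len(harvested) < n_fleets:
        return None
    h = np.zeros(n)
    for i in harvested:
        h[i] = rng.uniform(0.05, 0.15)

    ee_target = np.zeros(n)
    ee_target[cons_idx] = rng.uniform(0.55, 0.9, size=len(cons_idx))
    ee_target[producers] = rng.uniform(0.5, 0.85, size=len(producers))
    ee_target = np.maximum(ee_target, h + 0.3)  # keep EE - h bounded away from 0
    if (ee_target > 0.95).any():
        ee_target = np.minimum(ee_target, 0.95)

    # --- biomasses, top-down so EE targets hold exactly ---------------
    B = np.zeros(n)
    B[det] = np.exp(rng.normal(np.log(30.0), 0.3))
    top = max_tier
    for i in cons_idx:
        if tier_of[i] == top:
            B[i] = np.exp(rng.normal(np.log(0.25), 0.35))
    M = lambda: QB[:, None] * DC  # noqa: E731
    for k in range(top - 1, 0, -1):
        pred_flow = B @ M()  # predators above tier k already have B
        for i in cons_idx:
            if tier_of[i] == k:
                demand = pred_flow[i]
                B[i] = demand / (PB[i] * (ee_target[i] - h[i]))
    pred_flow = B @ M()
    for i in producers:
        B[i] = pred_flow[i] / (PB[i] * ee_target[i])

    if not np.all(np.isfinite(B)) or (B[:-1] <= 0).any():
        return None
    if (B > 800.0).any() or (B[list(cons_idx) + list(producers)] < 1e-4).any():
        return None

    Y = h * B * PB
    landings = np.zeros((n_fleets, n))
    fleet_names = [f"fleet_{f + 1}" for f in range(n_fleets)]
    for k, i in enumerate(sorted(harvested)):
        f = k % n_fleets
        landings[f, i] = Y[i]
    # optionally share large catches across a second fleet
    for i in sorted(harvested):
        f_owner = int(np.nonzero(landings[:, i] > 0)[0][0]) if landings[:, i].any() else 0
        if n_fleets > 1 and rng.random() < 0.3:
            f2 = (f_owner + 1) % n_fleets
            share = rng.uniform(0.2, 0.5)
            landings[f2, i] = landings[f_owner, i] * share
            landings[f_owner, i] *= 1.0 - share

    # --- tags ---------------------------------------------------------
    model = FoodWebModel(
        names=names,
        group_type=gtype_arr,
        B=B,
        PB=PB,
        QB=QB,
        EE=np.full(n, np.nan),
        BA=np.zeros(n),
        DC=DC,
        landings=landings,
        fleet_names=fleet_names,
    )
    try:
        model = solve_balance(model)
    except UnbalancedWebError:
        return None

    tl = model.trophic_levels()
    trait = np.empty(n, dtype=object)
    taxon = np.empty(n, dtype=object)
    for i in range(n):
        if gtype_arr[i] == "producer":
            trait[i], taxon[i] = "producer", "primary_producers"
        elif gtype_arr[i] == "detritus":
            trait[i], taxon[i] = "detritus", "detritus"
        else:
            pelagic = rng.random() < 0.5
            if tl[i] >= 3.2:
                trait[i] = "upper_tl_pelagic" if pelagic else "reef_associated"
                taxon[i] = rng.choice(["fishes", "elasmobranchs", "marine_mammals"])
            elif tl[i] >= 2.5:
                trait[i] = "lower_tl_pelagic" if pelagic else "demersal"
                taxon[i] = rng.choice(["fishes", "cephalopods"])
            else:
                trait[i] = "lower_tl_pelagic" if pelagic else "benthic_invertebrate"
                taxon[i] = "fishes" if pelagic else "invertebrates"
    disp = np.empty(n)
    for i in range(n):
        t = trait[i]
        if t in ("producer", "detritus", "benthic_invertebrate"):
            disp[i] = 3.0
        elif t in ("demersal", "reef_associated"):
            disp[i] = 30.0
        else:  # pelagic traits; planktonic low-TL pools stay slow
            disp[i] = 3.0 if tl[i] < 2.5 else 300.0
    model.trait = trait
    model.taxon = taxon
    model.dispersal = disp
    model.harvested = model.landings.sum(axis=0) > 0
    return model


# ----------------------------------------------------------------------
def gen_drivers(
    grid: GridSpec,
    n_months: int,
    seed: int = 0,
    noise_sd: float = 0.3,
) -> DriverStack:
    """Monthly driver rasters: seasonal cycle + smooth gradient + seeded noise.

    Depth increases with distance from the coast; SST/SBT/SSS/chlorophyll
    follow a 12-month sinusoid on top of smooth spatial structure.  Fields on
    land are NaN.
    """
    if n_months < 12:
        raise ValueError("n_months must be >= 12")
    rng = np.random.default_rng(seed)
    R, C = grid.n_rows, grid.n_cols
    land = grid.land_mask
    cd = grid.coast_distance
    lat = np.linspace(1.0, -1.0, R)[:, None] * np.ones((1, C))  # north-south

    depth = 5.0 + 1.8 * cd + 3.0 * _smooth_noise(rng, (R, C))
    depth = np.clip(depth, 1.0, None)
    rugosity = np.clip(0.5 + 0.3 * _smooth_noise(rng, (R, C)), 0.05, None)

    data = {v: np.empty((n_months, R, C)) for v in DRIVER_VARS}
    for t in range(n_months):
        month = t % 12
        phase = 2.0 * np.pi * (month - 4) / 12.0
        sst = 25.0 + 4.0 * np.sin(phase) + 0.8 * lat + noise_sd * _smooth_noise(rng, (R, C))
        sbt = 23.5 + 2.5 * np.sin(phase) - 0.03 * depth + 0.5 * lat + noise_sd * _smooth_noise(rng, (R, C))
        sss = 35.0 - 1.5 * np.exp(-cd / 25.0) + 0.1 * noise_sd * _smooth_noise(rng, (R, C))
        chl_phase = 2.0 * np.pi * (month - 8) / 12.0
        chl = (0.4 + 2.5 * np.exp(-cd / 30.0)) * (1.0 + 0.3 * np.sin(chl_phase))
        chl = np.clip(chl + 0.2 * noise_sd * _smooth_noise(rng, (R, C)), 0.05, None)
        data["sst"][t] = sst
        data["sbt"][t] = sbt
        data["sss"][t] = sss
        data["chlorophyll"][t] = chl
        data["depth"][t] = depth
        data["rugosity"][t] = rugosity
    for v in DRIVER_VARS:
        data[v][:, land] = np.nan
    return DriverStack(grid=grid, data=data, n_months=n_months)


# ----------------------------------------------------------------------
def gen_blooms(
    grid: GridSpec,
    n_years: int,
    severe_years: list[int] | tuple[int, ...] = (),
    seed: int = 0,
    background: float = 1e3,
    peak_months: tuple[int, ...] = (7, 8, 9, 10),
    normal_amp: tuple[float, float] = (1e4, 8e4),
    severe_amp: tuple[float, float] = (2e6, 8e6),
) -> BloomStack:
    """Coastal, patchy, autumn-peaked bloom maps with occasional severe years.

    Blooms are superposed Gaussian spatial kernels anchored at near-shore
    cells, modulated by a within-year temporal envelope centred on a peak
    month (0-based month-of-year; the default window is Aug–Nov).  Severe
    years draw larger amplitudes, wider kernels and longer durations, so both
    their 90th-percentile concentration and their footprint area exceed
    non-severe years.  Months with no active bloom are exactly the background
    concentration on water cells; land is always 0.
    """
    severe_years = sorted(set(int(y) for y in severe_years))
    if any(y < 0 or y >= n_years for y in severe_years):
        raise ValueError("severe_years must lie within the simulated years")
    rng = np.random.default_rng(seed)
    R, C = grid.n_rows, grid.n_cols
    water = grid.water_mask
    cd_w = grid.coast_distance[water]
    coastal_cut = np.quantile(cd_w, 0.25)
    coastal_cells = np.array(
        [(r, c) for r, c in zip(*grid.water_rc) if grid.coast_distance[r, c] <= coastal_cut]
    )
    rr, cc = np.indices((R, C))

    x = np.zeros((12 * n_years, R, C))
    x[:, water] = background
    severity = np.zeros(n_years)
    rows = []
    for y in range(n_years):
        severe = y in severe_years
        n_events = int(rng.integers(1, 3)) if severe else int(rng.integers(1, 3))
        for _ in range(n_events):
            if severe:
                amp = np.exp(rng.uniform(np.log(severe_amp[0]), np.log(severe_amp[1])))
                sigma = rng.uniform(1.8, 3.0)
                dur = rng.uniform(2.5, 4.0)
            else:
                amp = np.exp(rng.uniform(np.log(normal_amp[0]), np.log(normal_amp[1])))
                sigma = rng.uniform(1.0, 2.0)
                dur = rng.uniform(1.5, 2.5)
            r0, c0 = coastal_cells[rng.integers(len(coastal_cells))]
            p = rng.choice(peak_months)
            kernel = np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))
            for month in range(12):
                wt = np.exp(-((month - p) ** 2) / (2.0 * (dur / 2.0) ** 2))
                if wt < 0.05:
                    continue  # keep off-season months exactly at background
                x[12 * y + month] += amp * wt * kernel
            severity[y] += amp
            rows.append(
                {
                    "year": y,
                    "peak_month": int(p),
                    "row": int(r0),
                    "col": int(c0),
                    "amplitude": amp,
                    "sigma_cells": sigma,
                }
            )
    x[:, ~water] = 0.0
    events = pd.DataFrame(rows)
    return BloomStack(
        grid=grid, x=x, severity=severity, events=events, background=background
    )


# ----------------------------------------------------------------------
def gen_surveys(state, design: SurveyDesign, seed: int = 0) -> pd.DataFrame:
    """Station-level synthetic survey samples of model biomass.

    Observed abundance = (summed biomass of the sampled groups in the
    station's cell) × lognormal observation error.  With
    ``design.mean_corrected`` the multiplier is exp(N(0, σ²) − σ²/2), so the
    sample mean is an unbiased estimate of model biomass.
    """
    rng = np.random.default_rng(seed)
    grid: GridSpec = state.grid
    cells = design.cells
    if cells is None:
        if design.polygon is None:
            raise ValueError("design needs cells or a polygon")
        from shapely.geometry import Point

        w = grid.cell_width_km
        cells = [
            (r, c)
            for r, c in zip(*grid.water_rc)
            if design.polygon.contains(Point((c + 0.5) * w, (r + 0.5) * w))
        ]
        if not cells:
            raise ValueError("polygon contains no water-cell centres")
    flat_index = np.full((grid.n_rows, grid.n_cols), -1, dtype=int)
    flat_index[grid.water_mask] = np.arange(grid.n_water)
    gi = [state.group_names.index(g) for g in design.groups]
    rows = []
    for t in design.timesteps:
        if t < 0 or t >= state.B.shape[0]:
            raise ValueError(f"timestep {t} outside the recorded trajectory")
        for r, c in cells:
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ValueError(f"cell ({r}, {c}) outside the grid")
            s = flat_index[r, c]
            if s < 0:
                raise ValueError(f"cell ({r}, {c}) is on land")
            true = float(state.B[t, s, gi].sum())
            if design.sigma > 0:
                eps = rng.normal(0.0, design.sigma)
                if design.mean_corrected:
                    eps -= design.sigma**2 / 2.0
                obs = true * np.exp(eps)
            else:
                obs = true
            rows.append(
                {
                    "timestep": t,
                    "row": r,
                    "col": c,
                    "x_km": (c + 0.5) * grid.cell_width_km,
                    "y_km": (r + 0.5) * grid.cell_width_km,
                    "observed": obs,
                    "true_biomass": true,
                }
            )
    return pd.DataFrame(rows)
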