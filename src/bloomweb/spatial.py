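"""Gridded ecosystem model: per-cell trophic dynamics + movement + effort.

Every water cell runs the shared foraging-arena kernel; on top of that the
grid model adds

* habitat capacity — per cell and group, the product of environmental
  response functions (and, under a bloom scenario, the sublethal foraging
  response), floored at 1e-4; capacity shrinks the foraging arena and biases
  movement;
* donor-controlled dispersal between rook (4-neighbour) cells with
  reflecting boundaries; the per-edge flux is
  ``(D·dt/(4L)) · (ρ0 + (1 - capacity_donor)) · capacity_neighbour · B_donor``
  so reduced capacity increases emigration and more suitable neighbours
  attract more of the outflow; total per-step outflow is capped below 95 %
  of the donor cell's biomass and mass is conserved exactly;
* gravity-model fishing effort — each fleet's fixed total effort is spread
  over cells proportional to profitability (biomass value of its target
  groups minus a spatial cost), falling back to uniform when no cell is
  profitable;
* a spin-up period with forcing off during which domain totals are relaxed
  multiplicatively toward the balanced baseline (time constant 6 months);
* episodic bloom mortality, applied as a discrete kill at the start of each
  month: loss = A(x)·B is removed, recorded, and routed to detritus.

Per-timestep order of operations (fixed): (1) update drivers, capacity and
the fishing-effort map, (2) apply red-tide mortality and record the loss,
(3) trophic-dynamics sub-steps, (4) movement, (5) effort reallocation for
the next step and catch accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.special import expit

from .dynamics import Dynamics
from .foodweb import FoodWebModel
from .grid import GridSpec
from .redtide import Scenario
from .synthetic import BloomStack, DriverStack

__all__ = [
    "EnvResponse",
    "default_env_responses",
    "habitat_capacity",
    "movement_step",
    "allocate_effort",
    "run_simulation",
    "SpatialState",
    "CAPACITY_FLOOR",
]

CAPACITY_FLOOR = 1e-4
BASE_MOVE_FRAC = 0.1  # baseline mixing share of the dispersal propensity
MAX_OUTFLOW = 0.95
STABILITY_BOUNDS = (1e-4, 100.0)  # domain-total biomass relative to baseline


@dataclass(frozen=True)
class EnvResponse:
    """Logistic environmental preference, normalised to 1 at a reference.

    ``value(x) = min(1, expit(slope·direction·(x - midpoint)) / r_ref)``
    where ``r_ref`` is the raw logistic at ``ref``.  With ``ref=None`` the
    raw logistic is used.  Values map any driver value into [0, 1].
    """

    variable: str
    midpoint: float
    slope: float
    direction: int = 1
    ref: float | None = None

    def value(self, x):
        raw = expit(self.slope * self.direction * (np.asarray(x, dtype=float) - self.midpoint))
        if self.ref is not None:
            r0 = expit(self.slope * self.direction * (self.ref - self.midpoint))
            raw = np.minimum(raw / r0, 1.0)
        return raw


def default_env_responses(
    model: FoodWebModel, drivers: DriverStack, slope: float = 0.5
) -> dict[str, list[EnvResponse]]:
    """Trait-based assignment: bottom temperature for demersal/reef/benthic
    groups, surface temperature for pelagic groups; responses are normalised
    at the domain-and-time mean of the driver so baseline capacity is 1."""
    water = drivers.grid.water_mask
    refs = {v: float(np.nanmean(drivers.data[v][:, water])) for v in ("sst", "sbt")}
    out: dict[str, list[EnvResponse]] = {}
    for i, name in enumerate(model.names):
        t = model.trait[i]
        if t in ("demersal", "reef_associated", "benthic_invertebrate"):
            var = "sbt"
        elif t in ("upper_tl_pelagic", "lower_tl_pelagic"):
            var = "sst"
        else:
            out[name] = []
            continue
        ref = refs[var]
        out[name] = [
            EnvResponse(variable=var, midpoint=ref - 2.0, slope=slope, direction=1, ref=ref)
        ]
    return out


def habitat_capacity(driver_values: dict, responses: list[EnvResponse], foraging=1.0, floor: float = CAPACITY_FLOOR):
    """Capacity = max(floor, Π environmental responses × foraging response)."""
    cap = np.asarray(foraging, dtype=float)
    for r in responses:
        cap = cap * r.value(driver_values[r.variable])
    return np.maximum(cap, floor)


# ----------------------------------------------------------------------
def movement_step(
    B: np.ndarray,
    capacity: np.ndarray,
    D: np.ndarray,
    dt_months: float,
    grid: GridSpec,
    neighbor_idx: np.ndarray | None = None,
    base_frac: float = BASE_MOVE_FRAC,
    max_outflow: float = MAX_OUTFLOW,
) -> np.ndarray:
    """Donor-controlled dispersal on the water lattice; conserves mass.

    ``B`` and ``capacity`` are (n_water, n_groups) (or (n_water,) for a
    single group); ``D`` is the per-group dispersal rate in km·year⁻¹.
    """
    single = B.ndim == 1
    if single:
        B = B[:, None]
        capacity = capacity[:, None]
        D = np.atleast_1d(D)
    if neighbor_idx is None:
        neighbor_idx = grid.neighbor_indices()
    coef = D[None, :] * (dt_months / 12.0) / (4.0 * grid.cell_width_km)
    propensity = coef * (base_frac + (1.0 - capacity))  # per-edge donor rate

    # cap each edge at max_outflow/4 so the total per-cell outflow stays
    # below max_outflow regardless of how many neighbours a cell has, and
    # uniform fields remain exactly unchanged (symmetric edge coefficients)
    edge_cap = max_outflow / 4.0
    out_total = np.zeros_like(B)
    inflow = np.zeros_like(B)
    for d in range(4):
        nb = neighbor_idx[d]
        valid = nb >= 0
        w = np.zeros_like(capacity)
        w[valid] = capacity[nb[valid]]
        k = np.minimum(propensity * w, edge_cap)
        flux = k * B
        out_total += flux
        np.add.at(inflow, nb[valid], flux[valid])
    B_new = B - out_total + inflow
    return B_new[:, 0] if single else B_new


def allocate_effort(
    B: np.ndarray,
    prices: np.ndarray,
    cost: np.ndarray | None = None,
    total_effort: float | None = None,
) -> np.ndarray:
    """Gravity-model effort map: effort ∝ max(0, Σ price·B − cost).

    ``B`` is (n_water, n_groups), ``prices`` (n_fleets, n_groups), ``cost``
    (n_water,) or (n_water, n_fleets).  Each fleet's effort sums to
    ``total_effort`` (default: number of water cells, so uniform effort is
    1 per cell — the baseline of the catchability calibration).  A fleet
    with no profitable cell spreads its effort uniformly.
    """
    S = B.shape[0]
    total = float(S) if total_effort is None else float(total_effort)
    prof = B @ prices.T  # (S, F)
    if cost is not None:
        cost = np.asarray(cost, dtype=float)
        prof = prof - (cost[:, None] if cost.ndim == 1 else cost)
    prof = np.clip(prof, 0.0, None)
    sums = prof.sum(axis=0)
    effort = np.empty_like(prof)
    for f in range(prof.shape[1]):
        if sums[f] > 0:
            effort[:, f] = prof[:, f] * (total / sums[f])
        else:
            effort[:, f] = total / S
    return effort


def default_prices(model: FoodWebModel) -> np.ndarray:
    """Unit price for every group a fleet lands, zero otherwise."""
    return (model.landings > 0).astype(float)


# ----------------------------------------------------------------------
@dataclass
class SpatialState:
    """Recorded post-spin-up trajectory of a gridded run."""

    grid: GridSpec
    model: FoodWebModel
    months: int
    spinup_months: int
    B: np.ndarray  # (T, n_water, n)
    loss: np.ndarray  # (T, n_water, n) biomass killed by bloom forcing
    catch: np.ndarray  # (T, n_water, n_fleets, n)
    capacity: np.ndarray  # (T, n_water, n)
    stable: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def group_names(self) -> list[str]:
        return self.model.names

    def biomass_map(self, t: int, group: str) -> np.ndarray:
        return self.grid.unflatten(self.B[t, :, self.model.index(group)])

    def domain_mean(self) -> np.ndarray:
        """(T, n) spatial mean biomass (t·km⁻²) per month."""
        return self.B.mean(axis=1)

    def annual_mean(self) -> np.ndarray:
        """(Y, n) annual mean of the domain-mean biomass."""
        T = (self.months // 12) * 12
        return self.domain_mean()[:T].reshape(-1, 12, self.B.shape[2]).mean(axis=1)

    def to_netcdf(self, path: str | Path) -> None:
        T = self.B.shape[0]
        full = np.stack([self.grid.unflatten(self.B[t]) for t in range(T)])
        ds = xr.Dataset(
            {
                "biomass": (("time", "row", "col", "group"), full.astype(np.float32)),
                "loss": (
                    ("time", "row", "col", "group"),
                    np.stack([self.grid.unflatten(self.loss[t]) for t in range(T)]).astype(
                        np.float32
                    ),
                ),
            },
            coords={
                "time": np.arange(T),
                "row": np.arange(self.grid.n_rows),
                "col": np.arange(self.grid.n_cols),
                "group": list(self.model.names),
            },
            attrs={
                "spinup_months": self.spinup_months,
                "stable": int(self.stable),
                "cell_width_km": self.grid.cell_width_km,
            },
        )
        ds.to_netcdf(path, engine="scipy")


def run_simulation(
    model: FoodWebModel,
    grid: GridSpec,
    drivers: DriverStack,
    blooms: BloomStack | None = None,
    scenario: Scenario | None = None,
    n_months: int = 36,
    spinup_months: int = 24,
    vmult=None,
    dispersal_mult: np.ndarray | dict[str, float] | None = None,
    env_responses: dict[str, list[EnvResponse]] | None = None,
    prices: np.ndarray | None = None,
    cost: np.ndarray | None = None,
    substeps: int = 4,
    base_move_frac: float = BASE_MOVE_FRAC,
    nudge_tau_months: float = 6.0,
    stability_bounds: tuple[float, float] = STABILITY_BOUNDS,
) -> SpatialState:
    """Run the gridded model and record the post-spin-up trajectory.

    Blooms (and the scenario forcing they drive) are off during spin-up;
    bloom month 0 is the first recorded month.  Driver months are indexed
    cyclically if the driver stack is shorter than the run.  A run whose
    domain-total biomass for any group leaves ``stability_bounds`` × baseline
    (or turns non-finite) is flagged unstable and truncated.
    """
    dyn = Dynamics(model, vmult=vmult)
    n = model.n_groups
    S = grid.n_water
    water = grid.water_mask
    nb_idx = grid.neighbor_indices()

    D = model.dispersal.astype(float).copy()
    if isinstance(dispersal_mult, dict):
        for g, m in dispersal_mult.items():
            D[model.index(g)] *= m
    elif dispersal_mult is not None:
        D = D * np.asarray(dispersal_mult, dtype=float)

    if env_responses is None:
        env_responses = {}
    if prices is None:
        prices = default_prices(model)

    Td = drivers.n_months
    chl = np.stack([drivers.data["chlorophyll"][t][water] for t in range(Td)])
    chl_base = chl.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chl_rel_all = np.where(chl_base > 0, chl / np.where(chl_base > 0, chl_base, 1.0), 1.0)

    # environmental part of capacity, cached per driver month
    env_cap_cache: dict[int, np.ndarray] = {}

    def env_capacity(td: int) -> np.ndarray:
        if td not in env_cap_cache:
            cap = np.ones((S, n))
            for i, name in enumerate(model.names):
                for r in env_responses.get(name, []):
                    cap[:, i] *= r.value(drivers.data[r.variable][td][water])
            env_cap_cache[td] = cap
        return env_cap_cache[td]

    targets = np.zeros(n, dtype=bool)
    if scenario is not None:
        for i, name in enumerate(model.names):
            targets[i] = scenario.applies_to(name, bool(model.is_consumer[i]))

    B = np.tile(model.B, (S, 1))
    B0_tot = model.B * S
    effort = np.ones((S, model.n_fleets))
    ones_m0 = np.ones((S, n))

    total = spinup_months + n_months
    rec_B = np.zeros((n_months, S, n))
    rec_loss = np.zeros((n_months, S, n))
    rec_catch = np.zeros((n_months, S, model.n_fleets, n))
    rec_cap = np.ones((n_months, S, n))
    stable = True
    diagnostics: dict = {}

    for t in range(total):
        td = t % Td
        rec = t - spinup_months

        # (1) drivers, capacity (effort comes from the previous step)
        cap = env_capacity(td).copy()
        x_t = None
        if blooms is not None and rec >= 0:
            bt = rec % blooms.n_months
            x_t = blooms.x[bt][water]
            if scenario is not None and scenario.foraging is not None:
                phi = scenario.foraging.value(x_t)
                cap[:, targets] *= phi[:, None]
        np.maximum(cap, CAPACITY_FLOOR, out=cap)

        # (2) episodic mortality: discrete kill, loss routed to detritus
        if x_t is not None and scenario is not None:
            A = scenario.mortality.proportion_killed(x_t)
            loss = A[:, None] * B * targets[None, :]
            B = B - loss
            if dyn.det is not None:
                B[:, dyn.det] += loss.sum(axis=1)
            if rec >= 0:
                rec_loss[rec] = loss

        # (3) trophic dynamics
        try:
            B, catch_m = dyn.advance_month(
                B, cap, chl_rel_all[td], ones_m0, effort, substeps=substeps
            )
        except FloatingPointError:
            stable = False
            diagnostics["reason"] = "non-finite biomass"
            diagnostics["month"] = t
            break

        # (4) movement
        B = movement_step(B, cap, D, 1.0, grid, neighbor_idx=nb_idx, base_frac=base_move_frac)

        # spin-up: relax domain totals toward the baseline
        if t < spinup_months and nudge_tau_months > 0:
            tot = B.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(tot > 0, B0_tot / np.where(tot > 0, tot, 1.0), 1.0)
            B = B * ratio[None, :] ** (1.0 / nudge_tau_months)

        # (5) effort reallocation for the next step; catch accounting
        effort = allocate_effort(B, prices, cost)

        tot = B.sum(axis=0)
        lo, hi = stability_bounds
        bad = (tot < lo * B0_tot) | (tot > hi * B0_tot) | ~np.isfinite(tot)
        if bad.any():
            stable = False
            diagnostics["reason"] = "biomass outside stability bounds"
            diagnostics["month"] = t
            diagnostics["groups"] = [model.names[i] for i in np.nonzero(bad)[0]]
            if rec >= 0:
                rec_B[rec] = B
                rec_catch[rec] = catch_m
                rec_cap[rec] = cap
            break

        if rec >= 0:
            rec_B[rec] = B
            rec_catch[rec] = catch_m
            rec_cap[rec] = cap

    return SpatialState(
        grid=grid,
        model=model,
        months=n_months,
        spinup_months=spinup_months,
        B=rec_B,
        loss=rec_loss,
        catch=rec_catch,
        capacity=rec_cap,
        stable=stable,
        diagnostics=diagnostics,
    )
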