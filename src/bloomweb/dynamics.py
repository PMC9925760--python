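"""Foraging-arena trophic dynamics for well-mixed cells.

Consumption follows the classical foraging-arena closure: only a vulnerable
fraction of prey biomass is exposed to predation, with the exchange rate set
by a per-predator vulnerability multiplier v (v -> 1 is donor control,
large v approaches mass action)::

    Q = a·v·B_prey·B_pred / (2·v + a·B_pred)

The search rate ``a`` is calibrated so that at the balanced baseline (all
biomasses at their snapshot values, habitat capacity 1) every flow equals
its Ecopath value B_pred·QB_pred·DC — making the balanced snapshot an exact
fixed point of the dynamics.  Habitat capacity scales the search rate (a
smaller foraging arena).

Biomass rates per group:

    dB/dt = production - predation - fishing - other mortality (+ detritus terms)

with production = GE·ΣQ_in for consumers (growth efficiency GE = PB/QB held
at baseline), a chlorophyll-forced saturating term for producers, and a
detritus pool receiving unassimilated consumption (default fraction 0.2)
plus all other-mortality deaths, closed by a constant export/import flux
fixed at the baseline residual.

Integration uses (by default) 4 sub-steps per month with gains explicit and
losses semi-implicit (a Patankar-type positivity-preserving scheme), so
biomass never goes negative even for stiff loss rates.  The same vectorised
kernel drives both the single-cell model and every cell of the spatial
model, which is what makes the two trajectories equivalent on a one-cell
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .foodweb import FoodWebModel

__all__ = [
    "Dynamics",
    "CellState",
    "consumption",
    "producer_growth",
    "step_cell",
    "simulate_cell",
]

V_FLOOR = 1.01  # vulnerability multipliers at/below 1 have no free arena flux
UNASSIM_DEFAULT = 0.2
CHL_F_BOUNDS = (0.1, 10.0)
PRODUCER_NU = 3.0  # producer self-limitation shape (max P/B = (1+ν)·PB)


def consumption(b_prey, b_pred, a, v, capacity=1.0):
    """Foraging-arena flow Q = a_eff·v·B_prey·B_pred/(2v + a_eff·B_pred).

    ``capacity`` scales the search rate ``a`` (shrinks the arena).  The flow
    is bounded by the arena supply v·B_prey and tends to the mass-action
    limit a_eff·B_prey·B_pred/2 as v grows.
    """
    a_eff = np.asarray(a, dtype=float) * capacity
    num = a_eff * v * b_prey * b_pred
    den = 2.0 * np.asarray(v, dtype=float) + a_eff * b_pred
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out if out.ndim else float(out)


def producer_growth(B, PB, chl_rel=1.0, capacity=1.0, B0=None, nu=PRODUCER_NU):
    """Producer production PB·B·f(chl)·capacity·g(B), f clipped to [0.1, 10].

    ``chl_rel`` is the local chlorophyll anomaly relative to its baseline,
    so f = 1 under baseline forcing.  ``g(B) = (1+ν)/(1+ν·B/B0)`` is a
    self-limitation term (g(B0) = 1, so production = PB·B at baseline) that
    raises per-capita production as the stock is grazed down — the analogue
    of a maximum P/B ratio of (1+ν)·PB — and keeps producers from collapsing
    under sustained negative forcing.  ``B0=None`` disables it.
    """
    f = np.clip(chl_rel, *CHL_F_BOUNDS)
    g = 1.0 if B0 is None else (1.0 + nu) / (1.0 + nu * np.asarray(B) / B0)
    out = np.asarray(PB, dtype=float) * B * f * capacity * g
    return out if np.ndim(out) else float(out)


@dataclass
class CellState:
    """State of one well-mixed cell."""

    B: np.ndarray  # (n,) t·km⁻²
    m0mult: np.ndarray = None  # (n,) total multiplier on M0base, default 1
    capacity: np.ndarray = None  # (n,) in (0, 1]
    effort: np.ndarray = None  # (n_fleets,), baseline 1

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        n = self.B.shape[0]
        if self.m0mult is None:
            self.m0mult = np.ones(n)
        if self.capacity is None:
            self.capacity = np.ones(n)


class Dynamics:
    """Pre-computed rate constants + the vectorised sub-step kernel.

    Arrays passed to :meth:`step` have a leading cell axis ``S`` (use S=1
    for a single cell).
    """

    def __init__(
        self,
        model: FoodWebModel,
        vmult: np.ndarray | dict[str, float] | None = None,
        unassim: float = UNASSIM_DEFAULT,
    ):
        self.model = model
        n = model.n_groups
        self.n = n
        vm = np.full(n, 2.0)
        if isinstance(vmult, dict):
            for g, v in vmult.items():
                vm[model.index(g)] = v
        elif vmult is not None:
            vm = np.asarray(vmult, dtype=float).copy()
        vm = np.maximum(vm, V_FLOOR)
        self.vmult = vm
        self.unassim = unassim

        B0, QB, PB = model.B, model.QB, model.PB
        self.B0 = B0.copy()
        self.PB = PB.copy()
        self.GE = np.where(QB > 0, PB / np.where(QB > 0, QB, 1.0), 0.0)
        self.is_producer = model.is_producer
        self.is_consumer = model.is_consumer

        # baseline flows Q0[j, i] = B0_j·QB_j·DC_ji and arena constants
        Q0 = (B0 * QB)[:, None] * model.DC
        link = Q0 > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            vrate = np.where(link, vm[:, None] * Q0 / np.where(B0 > 0, B0, 1.0)[None, :], 0.0)
            a = np.where(
                link,
                2.0 * vrate / (np.where(B0 > 0, B0, 1.0)[:, None] * (vm[:, None] - 1.0)),
                0.0,
            )
        self.Q0 = Q0
        self.link = link
        self.vrate = vrate
        self.a = a

        # fishing: catchability per fleet/group so baseline effort 1 gives Y
        with np.errstate(divide="ignore", invalid="ignore"):
            self.q = np.where(B0 > 0, model.landings / np.where(B0 > 0, B0, 1.0)[None, :], 0.0)
        self.M0base = np.where(np.isnan(model.M0base), 0.0, model.M0base)

        # detritus closure: constant export (or import) flux at the baseline
        det = np.nonzero(model.is_detritus)[0]
        self.det = int(det[0]) if len(det) else None
        self.det_export_rate = 0.0
        self.det_import = 0.0
        if self.det is not None:
            inflow0 = unassim * Q0.sum() + float(self.M0base @ B0)
            outflow0 = float(Q0[:, self.det].sum())
            r0 = inflow0 - outflow0
            if r0 >= 0 and B0[self.det] > 0:
                self.det_export_rate = r0 / B0[self.det]
            else:
                self.det_import = -r0

    # ------------------------------------------------------------------
    def flows(self, B, cap, chl_rel, m0mult, effort):
        """Instantaneous gain/loss rates (t·km⁻²·yr⁻¹) for cells × groups."""
        S = B.shape[0]
        a_eff = self.a[None, :, :] * cap[:, :, None]  # predator capacity
        num = a_eff * self.vrate[None] * B[:, None, :] * B[:, :, None]
        den = 2.0 * self.vrate[None] + a_eff * B[:, :, None]
        with np.errstate(invalid="ignore"):
            Q = np.where(self.link[None], num / np.where(den > 0, den, 1.0), 0.0)

        gains = np.zeros_like(B)
        cons = self.is_consumer
        gains[:, cons] = self.GE[None, cons] * Q[:, cons, :].sum(axis=2)
        prod = self.is_producer
        f = np.clip(np.asarray(chl_rel, dtype=float), *CHL_F_BOUNDS)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = (1.0 + PRODUCER_NU) / (
                1.0 + PRODUCER_NU * B[:, prod] / np.where(self.B0[prod] > 0, self.B0[prod], 1.0)
            )
        gains[:, prod] = self.PB[None, prod] * B[:, prod] * f[:, None] * cap[:, prod] * g

        pred_loss = Q.sum(axis=1)
        m0_loss = self.M0base[None] * m0mult * B
        catch = self.q[None, :, :] * effort[:, :, None] * B[:, None, :]
        fish_loss = catch.sum(axis=1)

        losses = pred_loss + m0_loss + fish_loss
        if self.det is not None:
            d = self.det
            gains[:, d] = (
                self.unassim * Q.sum(axis=(1, 2))
                + m0_loss.sum(axis=1)
                + self.det_import
            )
            losses[:, d] += self.det_export_rate * B[:, d]
        return gains, losses, catch

    def step(self, B, cap, chl_rel, m0mult, effort, dt):
        """One positivity-preserving sub-step of length ``dt`` years.

        Losses (all proportional to the group's own biomass) are treated
        semi-implicitly (Patankar form)::

            B_new = (B + gains·dt) / (1 + (losses/B)·dt)

        which cannot overshoot below zero however stiff the loss rate, and
        leaves a balanced state (gains = losses) exactly unchanged.  The
        effective loss realised over the sub-step is losses·(B_new/B), and
        the reported catch is scaled accordingly so the per-group budget
        ΔB = gains·dt − effective losses·dt closes to machine precision.
        """
        gains, losses, catch = self.flows(B, cap, chl_rel, m0mult, effort)
        pos = B > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            loss_rate = np.where(pos, losses / np.where(pos, B, 1.0), 0.0)
        B_new = (B + gains * dt) / (1.0 + loss_rate * dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(pos, B_new / np.where(pos, B, 1.0), 0.0)
        catch_dt = catch * (dt * scale[:, None, :])
        return B_new, catch_dt

    def advance_month(self, B, cap, chl_rel, m0mult, effort, substeps: int = 4):
        """Integrate one month; returns (B_new, catch over the month)."""
        dt = 1.0 / (12.0 * substeps)
        catch_acc = 0.0
        for _ in range(substeps):
            B, catch_dt = self.step(B, cap, chl_rel, m0mult, effort, dt)
            catch_acc = catch_acc + catch_dt
        if not np.all(np.isfinite(B)):
            raise FloatingPointError("non-finite biomass during integration")
        return B, catch_acc


def step_cell(state: CellState, dynamics: Dynamics, dt_months: float = 1.0, substeps: int = 4) -> CellState:
    """Advance a single cell by ``dt_months`` (must divide 1 month evenly)."""
    n_sub = max(1, int(round(substeps * dt_months)))
    dt = dt_months / (12.0 * n_sub)
    B = state.B[None, :].copy()
    cap = state.capacity[None, :]
    effort = (
        state.effort[None, :]
        if state.effort is not None
        else np.ones((1, dynamics.model.n_fleets))
    )
    chl = np.ones(1)
    for _ in range(n_sub):
        B, _ = dynamics.step(B, cap, chl, state.m0mult[None, :], effort, dt)
    return CellState(B=B[0], m0mult=state.m0mult.copy(), capacity=state.capacity.copy(),
                     effort=None if state.effort is None else state.effort.copy())


# ----------------------------------------------------------------------
def simulate_cell(
    model: FoodWebModel,
    n_months: int,
    spinup_months: int = 0,
    vmult=None,
    chl_rel: np.ndarray | None = None,
    capacity: np.ndarray | None = None,
    effort: np.ndarray | None = None,
    substeps: int = 4,
    nudge_tau_months: float = 6.0,
) -> np.ndarray:
    """Single-cell trajectory: the well-mixed (Ecosim-like) reference run.

    ``chl_rel`` (total months,) and ``capacity`` (total months, n) supply
    time-varying forcing; defaults are baseline (1 everywhere).  During
    spin-up, biomass is relaxed toward the baseline with the same
    multiplicative nudging the spatial model uses.  Returns the recorded
    post-spin-up monthly biomass, shape (n_months, n).
    """
    dyn = Dynamics(model, vmult=vmult)
    total = spinup_months + n_months
    n = model.n_groups
    B = model.B[None, :].copy()
    eff = np.ones((1, model.n_fleets)) if effort is None else np.asarray(effort)[None, :]
    ones = np.ones((1, n))
    out = np.empty((n_months, n))
    for t in range(total):
        chl = np.ones(1) if chl_rel is None else np.array([chl_rel[t]], dtype=float)
        cap = ones if capacity is None else np.asarray(capacity[t], dtype=float)[None, :]
        B, _ = dyn.advance_month(B, cap, chl, ones, eff, substeps=substeps)
        if t < spinup_months and nudge_tau_months > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(B[0] > 0, model.B / np.where(B[0] > 0, B[0], 1.0), 1.0)
            B = B * ratio[None, :] ** (1.0 / nudge_tau_months)
        if t >= spinup_months:
            out[t - spinup_months] = B[0]
    return out
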