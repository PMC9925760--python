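"""Iterative calibration of vulnerability and dispersal parameters.

The gridded model is calibrated to the single-cell (well-mixed) biomass
trajectory rather than to data: the score is the percent bias

    pbias_i = 100 · Σ_t (sim_t - ref_t) / Σ_t ref_t

summed as |pbias_i| over groups (hydrological PBIAS convention).  A
lognormal log-likelihood is tracked alongside as a diagnostic but is not
optimised.  The routine is one-at-a-time throughout: a sensitivity pass
perturbs each parameter (×2 and ×0.5) and ranks parameters by the induced
change in total |pbias|; the fitting loop then sweeps the ranked parameters,
trying a log-spaced candidate grid for each (20 values by default) and
keeping any candidate that lowers the total |pbias|, until an iteration
produces no improvement.  Acceptance only on improvement makes the
total-|pbias| trajectory non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foodweb import FoodWebModel
from .spatial import run_simulation

__all__ = [
    "Parameter",
    "SimulationRunner",
    "pbias",
    "total_abs_pbias",
    "loglik",
    "oat_sensitivity",
    "candidate_grid",
    "iterate_fit",
    "FitResult",
]

VULN_RANGE = (1.01, 1e4)
DISP_RANGE = (0.1, 10.0)


@dataclass(frozen=True)
class Parameter:
    """A calibration handle: a predator's vulnerability multiplier or a
    group's dispersal multiplier."""

    kind: str  # "vulnerability" | "dispersal"
    group: str

    def __post_init__(self):
        if self.kind not in ("vulnerability", "dispersal"):
            raise ValueError("kind must be 'vulnerability' or 'dispersal'")

    @property
    def id(self) -> str:
        return f"{self.kind}:{self.group}"


def pbias(sim, ref) -> float:
    """Percent bias 100·Σ(sim - ref)/Σref of one series against a reference."""
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if sim.shape != ref.shape:
        raise ValueError("series lengths differ")
    denom = ref.sum()
    if denom == 0:
        raise ValueError("all-zero reference series")
    return float(100.0 * (sim - ref).sum() / denom)


def total_abs_pbias(sim: np.ndarray, ref: np.ndarray) -> float:
    """Σ over groups of |pbias|; series are (T, n_groups)."""
    sim = np.atleast_2d(np.asarray(sim, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    return float(sum(abs(pbias(sim[:, i], ref[:, i])) for i in range(sim.shape[1])))


def loglik(sim, ref, sigma: float = 0.3) -> float:
    """Lognormal log-likelihood of the reference given the simulation.

    LL = Σ_t log N(ln ref_t | ln sim_t, σ²); maximal when sim ≡ ref.
    """
    sim = np.asarray(sim, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if (sim <= 0).any() or (ref <= 0).any():
        raise ValueError("series must be positive for the lognormal likelihood")
    resid = np.log(ref) - np.log(sim)
    T = resid.size
    return float(-T * np.log(sigma * np.sqrt(2.0 * np.pi)) - (resid**2).sum() / (2.0 * sigma**2))


# ----------------------------------------------------------------------
class SimulationRunner:
    """Pure-function wrapper: parameter values -> annual biomass (Y, n).

    Freezes everything about a gridded run except the vulnerability and
    dispersal multipliers, so calibration candidates can be evaluated in any
    order (or in parallel) with identical results.  Returns ``None`` for a
    run flagged unstable.
    """

    def __init__(
        self,
        model: FoodWebModel,
        grid,
        drivers,
        env_responses=None,
        n_months: int = 24,
        spinup_months: int = 12,
        substeps: int = 4,
        blooms=None,
        scenario=None,
        base_move_frac: float = 0.1,
    ):
        self.model = model
        self.grid = grid
        self.drivers = drivers
        self.env_responses = env_responses
        self.n_months = n_months
        self.spinup_months = spinup_months
        self.substeps = substeps
        self.blooms = blooms
        self.scenario = scenario
        self.base_move_frac = base_move_frac

    monthly: bool = True  # score on the monthly series (annual when False)

    def run(
        self,
        vulnerability: dict[str, float] | None = None,
        dispersal: dict[str, float] | None = None,
    ) -> np.ndarray | None:
        state = run_simulation(
            self.model,
            self.grid,
            self.drivers,
            blooms=self.blooms,
            scenario=self.scenario,
            n_months=self.n_months,
            spinup_months=self.spinup_months,
            vmult=vulnerability,
            dispersal_mult=dispersal,
            env_responses=self.env_responses,
            substeps=self.substeps,
            base_move_frac=self.base_move_frac,
        )
        if not state.stable:
            return None
        return state.domain_mean() if self.monthly else state.annual_mean()


def _split(values: dict[str, float], params: list[Parameter]) -> tuple[dict, dict]:
    vuln = {p.group: values[p.id] for p in params if p.kind == "vulnerability" and p.id in values}
    disp = {p.group: values[p.id] for p in params if p.kind == "dispersal" and p.id in values}
    return vuln, disp


def default_incumbents(params: list[Parameter]) -> dict[str, float]:
    return {p.id: (2.0 if p.kind == "vulnerability" else 1.0) for p in params}


def oat_sensitivity(
    runner: SimulationRunner,
    params: list[Parameter],
    ref: np.ndarray,
    incumbents: dict[str, float] | None = None,
    factors: tuple[float, ...] = (2.0, 0.5),
) -> pd.DataFrame:
    """Rank parameters by the |Δ total pbias| a ×2 / ×0.5 perturbation causes.

    Unstable perturbed runs are flagged and given the worst rank.
    Deterministic: ties keep the input parameter order.
    """
    incumbents = dict(incumbents or default_incumbents(params))
    vuln0, disp0 = _split(incumbents, params)
    base = runner.run(vulnerability=vuln0, dispersal=disp0)
    if base is None:
        raise RuntimeError("baseline run is unstable; cannot rank parameters")
    tp0 = total_abs_pbias(base, ref)

    rows = []
    for order, p in enumerate(params):
        sens = 0.0
        unstable = False
        for fac in factors:
            trial = dict(incumbents)
            trial[p.id] = incumbents[p.id] * fac
            vuln, disp = _split(trial, params)
            sim = runner.run(vulnerability=vuln, dispersal=disp)
            if sim is None:
                unstable = True
                continue
            sens = max(sens, abs(total_abs_pbias(sim, ref) - tp0))
        rows.append(
            {
                "parameter": p.id,
                "kind": p.kind,
                "group": p.group,
                "sensitivity": -1.0 if unstable and sens == 0.0 else sens,
                "unstable": unstable,
                "order": order,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["sensitivity", "order"], ascending=[False, True], kind="stable"
    )
    return df.reset_index(drop=True)


def candidate_grid(kind: str, n: int = 20) -> np.ndarray:
    """Shared log-spaced candidate values per parameter kind."""
    lo, hi = VULN_RANGE if kind == "vulnerability" else DISP_RANGE
    return np.logspace(np.log10(lo), np.log10(hi), n)


@dataclass
class FitResult:
    params: dict[str, float]
    records: pd.DataFrame
    pbias_path: list[float]
    iterations: int


def iterate_fit(
    runner: SimulationRunner,
    ref: np.ndarray,
    params: list[Parameter],
    incumbents: dict[str, float] | None = None,
    n_candidates: int = 20,
    max_iter: int = 10,
) -> FitResult:
    """Sweep ranked parameters over candidate grids until no improvement.

    Within an iteration each parameter is swept one at a time (others held
    at their incumbents, updated as soon as a candidate is accepted).  A
    candidate is accepted only if it strictly lowers the total |pbias|; ties
    between equally good candidates go to the value closest to the incumbent
    (in log space).  Stops at the first iteration with no accepted change,
    or at ``max_iter``.
    """
    incumbents = dict(incumbents or default_incumbents(params))
    pmap = {p.id: p for p in params}
    vuln, disp = _split(incumbents, params)
    base = runner.run(vulnerability=vuln, dispersal=disp)
    if base is None:
        raise RuntimeError("starting point is unstable")
    tp_cur = total_abs_pbias(base, ref)
    path = [tp_cur]
    records = []

    it = 0
    for it in range(1, max_iter + 1):
        improved = False
        for pid, p in pmap.items():
            grid_vals = candidate_grid(p.kind, n_candidates)
            best_tp, best_val = None, None
            for cand in grid_vals:
                trial = dict(incumbents)
                trial[pid] = float(cand)
                vuln, disp = _split(trial, params)
                sim = runner.run(vulnerability=vuln, dispersal=disp)
                tp = np.inf if sim is None else total_abs_pbias(sim, ref)
                ll = np.nan if sim is None else loglik(sim.ravel(), ref.ravel())
                records.append(
                    {
                        "iteration": it,
                        "parameter": pid,
                        "candidate": float(cand),
                        "pbias": tp,
                        "LL": ll,
                        "accepted": False,
                    }
                )
                closer = (
                    best_val is not None
                    and abs(np.log(cand) - np.log(incumbents[pid]))
                    < abs(np.log(best_val) - np.log(incumbents[pid]))
                )
                if best_tp is None or tp < best_tp - 1e-12 or (tp <= best_tp + 1e-12 and closer):
                    best_tp, best_val = tp, float(cand)
            if best_tp is not None and best_tp < tp_cur - 1e-12:
                incumbents[pid] = best_val
                tp_cur = best_tp
                improved = True
                for r in reversed(records):
                    if r["iteration"] == it and r["parameter"] == pid and r["candidate"] == best_val:
                        r["accepted"] = True
                        break
        path.append(tp_cur)
        if not improved:
            break

    return FitResult(
        params=incumbents,
        records=pd.DataFrame(records),
        pbias_path=path,
        iterations=it,
    )
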