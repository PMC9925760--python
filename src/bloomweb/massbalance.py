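"""Mass balance of the static snapshot.

For every living group *i* the production that is not exported must be
accounted for by predation, catch, and biomass accumulation::

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC_ji + Y_i + BA_i

The remainder, ``M0base_i = PB_i · (1 - EE_i)``, is the baseline "other
mortality" rate — losses to disease, senescence and the environment — which
is the term the episodic red-tide forcing multiplies.

:func:`solve_balance` fills exactly one unknown per group, chosen from
``{B, EE}``; :func:`check_balance` re-evaluates the identity on a fully
specified model and reports per-group residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .foodweb import FoodWebModel

__all__ = ["solve_balance", "check_balance", "UnbalancedWebError"]

TOL = 1e-9


class UnbalancedWebError(ValueError):
    """Raised when the solved snapshot needs EE outside [0, 1]."""

    def __init__(self, groups: list[str], ee: list[float]):
        self.groups = groups
        self.ee = ee
        msg = ", ".join(f"{g} (EE={e:.3f})" for g, e in zip(groups, ee))
        super().__init__(f"unbalanced food web, EE out of [0, 1] for: {msg}")


def solve_balance(
    model: FoodWebModel, unknown: dict[str, str] | None = None
) -> FoodWebModel:
    """Solve the balance identity for one unknown per group.

    Parameters
    ----------
    model
        Partially specified model.  Values of unknown fields are ignored.
    unknown
        Mapping group name -> ``"B"`` or ``"EE"``.  Groups not listed have
        ``EE`` treated as the unknown (the common case).  Detritus is a
        non-living pool: its EE and M0base are fixed at 0 and it may not be
        listed.

    Returns
    -------
    A new :class:`FoodWebModel` with B/EE filled and ``M0base`` computed.
    """
    unknown = dict(unknown or {})
    m = model.copy()
    n = m.n_groups
    for g, kind in unknown.items():
        if g not in m.names:
            raise KeyError(f"unknown group {g!r}")
        if kind not in ("B", "EE"):
            raise ValueError("unknown must be 'B' or 'EE'")
        if m.group_type[m.index(g)] == "detritus":
            raise ValueError("detritus has no balance equation")

    living = ~m.is_detritus
    b_unknown = np.zeros(n, dtype=bool)
    for g, kind in unknown.items():
        if kind == "B":
            b_unknown[m.index(g)] = True

    # Consumption matrix M[j, i] = QB_j · DC_ji (per unit predator biomass).
    M = m.QB[:, None] * m.DC
    Y = m.Y

    if b_unknown.any():
        ui = np.nonzero(b_unknown)[0]
        known = ~b_unknown
        # rows: balance of each B-unknown group; unknowns: their biomasses
        A = np.zeros((len(ui), len(ui)))
        rhs = np.zeros(len(ui))
        for r, i in enumerate(ui):
            A[r, :] = -M[ui, i]
            A[r, r] += m.PB[i] * m.EE[i]
            rhs[r] = Y[i] + m.BA[i] + m.B[known] @ M[known, i]
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular balance system for groups {[m.names[i] for i in ui]}"
            ) from exc
        if (sol <= 0).any():
            bad = [m.names[i] for i, v in zip(ui, sol) if v <= 0]
            raise UnbalancedWebError(bad, [0.0] * len(bad))
        m.B[ui] = sol

    # EE for every living group whose EE was not prescribed as known.
    predation = m.B @ M  # per prey group
    demand = predation + Y + m.BA
    ee_unknown = living & ~b_unknown
    prod = m.B * m.PB
    with np.errstate(divide="ignore", invalid="ignore"):
        ee = np.where(prod > 0, demand / np.where(prod > 0, prod, 1.0), 0.0)
    ee[~ee_unknown] = m.EE[~ee_unknown]
    ee[m.is_detritus] = 0.0
    no_prod_with_demand = ee_unknown & (prod <= 0) & (demand > TOL)
    if no_prod_with_demand.any():
        bad = [m.names[i] for i in np.nonzero(no_prod_with_demand)[0]]
        raise UnbalancedWebError(bad, [np.inf] * len(bad))

    over = living & ((ee > 1.0 + 1e-9) | (ee < -1e-9))
    if over.any():
        idx = np.nonzero(over)[0]
        raise UnbalancedWebError([m.names[i] for i in idx], ee[idx].tolist())

    m.EE = np.clip(ee, 0.0, 1.0)
    m.M0base = np.where(living, m.PB * (1.0 - m.EE), 0.0)
    return m


def check_balance(model: FoodWebModel, tol: float = TOL) -> pd.DataFrame:
    """Per-group residual of production - (predation + catch + BA + M0·B).

    At balance the residual is zero: production splits exactly into the
    consumed/caught/accumulated part (B·PB·EE) and other mortality
    (M0base·B = B·PB·(1-EE)).  Detritus, being non-living, has residual 0
    by convention.
    """
    M = model.QB[:, None] * model.DC
    predation = model.B @ M
    Y = model.Y
    production = model.B * model.PB
    m0_flow = model.M0base * model.B
    residual = production - (predation + Y + model.BA + m0_flow)
    residual = np.where(model.is_detritus, 0.0, residual)
    return pd.DataFrame(
        {
            "group": model.names,
            "production": production,
            "predation": predation,
            "catch": Y,
            "BA": model.BA,
            "m0_flow": m0_flow,
            "residual": residual,
            "balanced": np.abs(residual) <= tol,
        }
    )
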