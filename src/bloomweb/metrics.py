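"""Ecosystem, community and population impact indicators.

Annual indicators from a recorded trajectory: total biomass B_T (t·km⁻²),
harvested-group biomass B_har, biomass lost to bloom forcing B_loss, and
total catch C_T (t·km⁻²·year⁻¹); trait/taxon community aggregates (juvenile
groups excluded); a per-group annual bloom mortality index (loss summed over
months and cells ÷ mean annual domain biomass); ensemble screening against a
loss-rate band and an RMSE tolerance; and the before/after–inside/outside
mean-abundance comparison used to confront predictions with survey-style
observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ecosystem_indicators",
    "mortality_index",
    "community_aggregate",
    "screen_scenarios",
    "rmse_log",
    "before_after_in_out",
]


def _years(T: int) -> int:
    if T < 12:
        raise ValueError("need at least 12 recorded months")
    return T // 12


def ecosystem_indicators(state, include_juveniles: bool = False) -> pd.DataFrame:
    """Annual B_T, B_har, B_loss and C_T for a run.

    Biomass indicators are annual means of the spatial-mean biomass summed
    over (non-juvenile) groups; B_loss sums the spatial-mean monthly kill
    over the year's months and groups; C_T sums the spatial-mean catch over
    the year, fleets and groups.
    """
    model = state.model
    keep = np.ones(model.n_groups, dtype=bool) if include_juveniles else ~model.juvenile
    T = state.B.shape[0]
    Y = _years(T)
    dm = state.B.mean(axis=1)  # (T, n) spatial means
    dl = state.loss.mean(axis=1)
    dc = state.catch.mean(axis=1).sum(axis=1)  # (T, n) summed over fleets
    rows = []
    for y in range(Y):
        sl = slice(12 * y, 12 * (y + 1))
        rows.append(
            {
                "year": y,
                "B_T": dm[sl][:, keep].sum(axis=1).mean(),
                "B_har": dm[sl][:, keep & model.harvested].sum(axis=1).mean(),
                "B_loss": dl[sl][:, keep].sum(),
                "C_T": dc[sl][:, keep].sum(),
            }
        )
    return pd.DataFrame(rows)


def mortality_index(state, group: str) -> pd.Series:
    """Annual bloom mortality rate (year⁻¹) for one group.

    index_y = Σ_{months, cells} loss / (annual mean of the domain-total
    biomass); NaN where the group's biomass is zero.
    """
    g = state.model.index(group)
    T = state.B.shape[0]
    Y = _years(T)
    out = np.empty(Y)
    for y in range(Y):
        sl = slice(12 * y, 12 * (y + 1))
        num = state.loss[sl, :, g].sum()
        den = state.B[sl, :, g].sum(axis=1).mean()
        out[y] = num / den if den > 0 else np.nan
    return pd.Series(out, index=pd.RangeIndex(Y, name="year"), name=group)


def community_aggregate(state, by: str = "trait") -> pd.DataFrame:
    """Annual mean domain-mean biomass per trait or taxon class.

    Juvenile groups are excluded.  Every non-juvenile group must carry a
    class tag (guaranteed by the model container).
    """
    model = state.model
    tags = model.trait if by == "trait" else model.taxon
    keep = ~model.juvenile
    T = state.B.shape[0]
    Y = _years(T)
    dm = state.B.mean(axis=1)
    rows = []
    for cls in sorted(set(tags[keep])):
        members = keep & (tags == cls)
        for y in range(Y):
            sl = slice(12 * y, 12 * (y + 1))
            rows.append(
                {"class": cls, "year": y, "biomass": dm[sl][:, members].sum(axis=1).mean()}
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def rmse_log(sim, obs) -> float:
    """RMSE between two relative indices, on the log scale after mean-centred
    standardisation (both series are scaled out, only shape is compared)."""
    sim = np.asarray(sim, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if (sim <= 0).any() or (obs <= 0).any():
        raise ValueError("indices must be positive")
    a = np.log(sim) - np.log(sim).mean()
    b = np.log(obs) - np.log(obs).mean()
    return float(np.sqrt(np.mean((a - b) ** 2)))


def screen_scenarios(
    runs: pd.DataFrame,
    mu: float = 0.77,
    sd: float = 0.12,
    rmse_tol: float = 0.10,
) -> list[str]:
    """Accepted scenario ids: focal-year loss rate within mu ± 2·sd AND
    RMSE within (1 + rmse_tol) of the lowest RMSE across all runs.

    ``runs`` needs columns ``scenario_id``, ``loss_rate``, ``rmse``.
    Idempotent and order-independent (ids are returned sorted).
    """
    if len(runs) == 0:
        raise ValueError("empty run set")
    rmin = runs["rmse"].min()
    ok = (np.abs(runs["loss_rate"] - mu) <= 2.0 * sd) & (runs["rmse"] <= (1.0 + rmse_tol) * rmin)
    return sorted(runs.loc[ok, "scenario_id"].tolist())


# ----------------------------------------------------------------------
def _stratum_values(state, groups, cells, timesteps) -> np.ndarray:
    grid = state.grid
    flat_index = np.full((grid.n_rows, grid.n_cols), -1, dtype=int)
    flat_index[grid.water_mask] = np.arange(grid.n_water)
    gi = [state.model.index(g) for g in groups]
    s_idx = []
    for r, c in cells:
        s = flat_index[r, c]
        if s < 0:
            raise ValueError(f"cell ({r}, {c}) is land or outside the grid")
        s_idx.append(s)
    if not s_idx:
        raise ValueError("empty stratum")
    vals = state.B[np.asarray(timesteps)][:, s_idx][:, :, gi].sum(axis=2)
    return vals.mean(axis=0)  # per-cell, averaged over the stratum's months


def before_after_in_out(
    state,
    groups: list[str],
    stratum_a: tuple[list[int], list[tuple[int, int]]],
    stratum_b: tuple[list[int], list[tuple[int, int]]],
    labels: tuple[str, str] = ("before", "after"),
) -> pd.DataFrame:
    """Mean ± SE of summed-group biomass in two strata and the % change.

    A stratum is (timesteps, cells); use the same cells with different
    timesteps for before/after, or the same timesteps with different cell
    sets for inside/outside.  % change = 100·(b - a)/a, reported on the
    second row (NaN when the reference mean is zero).
    """
    va = _stratum_values(state, groups, stratum_a[1], stratum_a[0])
    vb = _stratum_values(state, groups, stratum_b[1], stratum_b[0])
    rows = []
    for label, v in zip(labels, (va, vb)):
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        rows.append({"stratum": label, "mean": v.mean(), "se": se, "n_cells": len(v)})
    df = pd.DataFrame(rows)
    ma = va.mean()
    df["pct_change"] = [np.nan, 100.0 * (vb.mean() - ma) / ma if ma != 0 else np.nan]
    return df
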