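"""Lethal and sublethal logistic responses to bloom concentration.

The lethal response gives the proportion of biomass killed in a cell-month
as a logistic function of *K. brevis* concentration x (cells·L⁻¹)::

    A(x) = 1 / (1 + (x / c)^(-b))

with inflection c (A(c) = 0.5) and slope b > 0; A(0) = 0 in the limit.  The
monthly kill converts to an annual instantaneous rate Â = -ln(1 - A)·12 and,
scaled by the group's baseline other mortality, to the multiplier
M0mult = Â / M0base.  The multiplier is additive: effective other mortality
is M0base·(1 + M0mult), so M0mult = 0 recovers the baseline exactly.

The sublethal (foraging) response is a decreasing logistic multiplier on
habitat capacity.  Each mortality inflection c spawns three foraging curves
with inflections at 25/50/75 % of c.  The curve family is log-logistic
(value 1 at x = 0 exactly, 0.5 at its inflection) with the exponent set so
the linear-x slope at the inflection equals the configured slope multiplier
(-5·10⁻⁵ per cells·L⁻¹ by default).

The scenario grid combines 5 inflections × 4 slopes = 20 mortality curves,
plus 3 paired foraging curves for each (60 lethal+sublethal configurations),
for 80 configurations, each applied either to all consumer groups or to a
single named target group: 160 scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "MortalityResponse",
    "ForagingResponse",
    "Scenario",
    "mortality_proportion",
    "annualize",
    "m0_multiplier",
    "build_mortality_library",
    "build_foraging_library",
    "build_scenario_grid",
    "scenario_table",
    "apply_forcing",
    "DEFAULT_INFLECTIONS",
    "DEFAULT_SLOPES",
    "FORAGING_FRACTIONS",
    "FORAGING_SLOPE_MULTIPLIER",
]

# Five inflection concentrations, log-spaced over 10^4.5 .. 10^6.5 cells/L,
# spanning the range where harmful effects of K. brevis are plausible; four
# slope scalars giving visibly distinct steepness on a log-x axis.  Both are
# overridable where the libraries are built.
DEFAULT_INFLECTIONS: tuple[float, ...] = tuple(np.logspace(4.5, 6.5, 5))
DEFAULT_SLOPES: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0)
FORAGING_FRACTIONS: tuple[float, ...] = (0.25, 0.50, 0.75)
FORAGING_SLOPE_MULTIPLIER: float = 5e-5  # |dφ/dx| at the inflection

_A_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class MortalityResponse:
    """Logistic proportion-killed curve: inflection ``c`` (cells·L⁻¹), slope ``b``."""

    c: float
    b: float
    label: str = ""

    def __post_init__(self):
        if self.c <= 0 or self.b <= 0:
            raise ValueError("inflection c and slope b must be positive")

    def proportion_killed(self, x):
        return mortality_proportion(x, self)


@dataclass(frozen=True)
class ForagingResponse:
    """Decreasing log-logistic habitat-capacity multiplier.

    ``inflection`` = fraction × paired mortality inflection; the exponent is
    chosen so |dφ/dx| at the inflection equals ``slope_multiplier``.
    """

    mortality_c: float
    fraction: float
    slope_multiplier: float = FORAGING_SLOPE_MULTIPLIER
    label: str = ""

    @property
    def inflection(self) -> float:
        return self.fraction * self.mortality_c

    @property
    def exponent(self) -> float:
        # log-logistic φ = 1/(1+(x/x0)^k): dφ/dx at x0 is -k/(4·x0)
        return 4.0 * self.inflection * self.slope_multiplier

    def value(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore"):
            out = expit(-self.exponent * np.log(x / self.inflection))
        out = np.where(x == 0.0, 1.0, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class Scenario:
    """One ensemble member: a mortality curve, an optional paired foraging
    curve, and the set of groups the forcing applies to."""

    id: str
    mortality: MortalityResponse
    foraging: ForagingResponse | None
    target: str  # "all_consumers" or a group name

    def applies_to(self, group_name: str, is_consumer: bool) -> bool:
        if self.target == "all_consumers":
            return is_consumer
        return group_name == self.target


# ----------------------------------------------------------------------
def mortality_proportion(x, r: MortalityResponse):
    """Proportion of biomass killed at concentration x; A(0)=0, A(c)=0.5."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("concentration must be >= 0")
    with np.errstate(divide="ignore"):
        a = expit(r.b * np.log(x / r.c))
    a = np.where(x == 0.0, 0.0, a)
    a = np.minimum(a, _A_CLIP)
    return a if a.ndim else float(a)


def annualize(A):
    """Monthly kill proportion -> annual instantaneous rate Â = -ln(1-A)·12."""
    A = np.asarray(A, dtype=float)
    if (A < 0).any() or (A >= 1).any():
        raise ValueError("A must lie in [0, 1); clip before annualizing")
    out = -np.log1p(-A) * 12.0
    return out if out.ndim else float(out)


def m0_multiplier(a_hat, m0base: float):
    """Additional other-mortality multiplier M0mult = Â / M0base.

    The caller composes it additively: effective M0 = M0base·(1 + M0mult).
    Raises for M0base = 0 (a group with EE = 1 has no baseline other
    mortality to scale; apply Â as an absolute additional rate instead).
    """
    if m0base <= 0:
        raise ValueError(
            "M0base is 0 (EE = 1): apply the annualized rate directly instead"
        )
    a_hat = np.asarray(a_hat, dtype=float)
    out = a_hat / m0base
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
def build_mortality_library(
    inflections=DEFAULT_INFLECTIONS, slopes=DEFAULT_SLOPES
) -> list[MortalityResponse]:
    """The mortality-curve library, ordered inflection-major then slope."""
    lib = []
    for ci, c in enumerate(inflections):
        for bi, b in enumerate(slopes):
            lib.append(MortalityResponse(c=float(c), b=float(b), label=f"c{ci + 1}b{bi + 1}"))
    return lib


def build_foraging_library(
    mortality_library: list[MortalityResponse],
    fractions=FORAGING_FRACTIONS,
    slope_multiplier: float = FORAGING_SLOPE_MULTIPLIER,
) -> list[ForagingResponse]:
    """Three foraging curves per distinct mortality inflection level."""
    seen: list[float] = []
    for m in mortality_library:
        if m.c not in seen:
            seen.append(m.c)
    lib = []
    for ci, c in enumerate(seen):
        for fi, f in enumerate(fractions):
            lib.append(
                ForagingResponse(
                    mortality_c=c,
                    fraction=float(f),
                    slope_multiplier=slope_multiplier,
                    label=f"c{ci + 1}f{fi + 1}",
                )
            )
    return lib


def build_scenario_grid(
    target_group: str,
    mortality_library: list[MortalityResponse] | None = None,
    foraging_library: list[ForagingResponse] | None = None,
    fractions=FORAGING_FRACTIONS,
) -> list[Scenario]:
    """The full combinatorial scenario grid.

    20 mortality-only + 60 mortality+foraging configurations, each run once
    applied to all consumers and once applied to ``target_group``: 160
    scenarios with stable ids S001..S160 (all-consumer block first).
    """
    mort = mortality_library or build_mortality_library()
    forag = foraging_library or build_foraging_library(mort, fractions)
    by_c: dict[float, list[ForagingResponse]] = {}
    for f in forag:
        by_c.setdefault(f.mortality_c, []).append(f)

    scenarios: list[Scenario] = []
    k = 0
    for target in ("all_consumers", target_group):
        for m in mort:  # mortality-only block
            k += 1
            scenarios.append(Scenario(id=f"S{k:03d}", mortality=m, foraging=None, target=target))
        for m in mort:  # paired lethal + sublethal block
            for f in by_c[m.c]:
                k += 1
                scenarios.append(
                    Scenario(id=f"S{k:03d}", mortality=m, foraging=f, target=target)
                )
    return scenarios


def scenario_table(scenarios: list[Scenario]) -> pd.DataFrame:
    """One row per scenario, mirroring a supplementary scenario listing."""
    rows = []
    for s in scenarios:
        rows.append(
            {
                "id": s.id,
                "target": s.target,
                "mortality_label": s.mortality.label,
                "inflection_cells_per_l": s.mortality.c,
                "slope": s.mortality.b,
                "foraging_fraction": s.foraging.fraction if s.foraging else np.nan,
                "foraging_inflection": s.foraging.inflection if s.foraging else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def apply_forcing(
    B: float,
    x: float,
    scenario: Scenario,
    group_name: str,
    m0base: float,
    is_consumer: bool = True,
):
    """Forcing triple for one group in one cell-month.

    Returns ``(loss, M0mult, foraging_value)``: the biomass killed
    (loss = A·B), the additional other-mortality multiplier, and the
    habitat-capacity multiplier.  A group outside the scenario's target set
    gets the identity ``(0, 0, 1)``.  If M0base is 0 the annualized rate is
    returned directly in place of the multiplier.
    """
    if not scenario.applies_to(group_name, is_consumer):
        return 0.0, 0.0, 1.0
    A = mortality_proportion(x, scenario.mortality)
    loss = A * B
    a_hat = annualize(A)
    mult = a_hat / m0base if m0base > 0 else a_hat
    phi = scenario.foraging.value(x) if scenario.foraging is not None else 1.0
    return loss, mult, phi
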