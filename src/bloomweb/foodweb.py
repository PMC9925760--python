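"""The static food-web container: one biomass pool per functional group.

A :class:`FoodWebModel` is the Ecopath-style snapshot of the ecosystem: per
group a biomass ``B`` (t·km⁻²), production/biomass ``PB`` (year⁻¹),
consumption/biomass ``QB`` (year⁻¹, zero for producers and detritus), an
ecotrophic efficiency ``EE``, a diet matrix ``DC`` (row = predator, entries
are the fraction of each prey in that predator's diet), per-fleet landings,
and tags (ecological trait, taxon, harvested/juvenile flags) plus a baseline
dispersal rate used by the spatial model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FoodWebModel", "TRAITS", "GROUP_TYPES"]

GROUP_TYPES = ("producer", "consumer", "detritus")

TRAITS = (
    "upper_tl_pelagic",
    "lower_tl_pelagic",
    "demersal",
    "reef_associated",
    "benthic_invertebrate",
    "producer",
    "detritus",
)


@dataclass
class FoodWebModel:
    names: list[str]
    group_type: np.ndarray  # str array in GROUP_TYPES
    B: np.ndarray  # t·km⁻²
    PB: np.ndarray  # year⁻¹
    QB: np.ndarray  # year⁻¹ (0 for producers/detritus)
    EE: np.ndarray  # unitless, may be NaN before balancing
    BA: np.ndarray  # biomass accumulation t·km⁻²·year⁻¹
    DC: np.ndarray  # (n, n), row = predator, rows of consumers sum to 1
    landings: np.ndarray  # (n_fleets, n) t·km⁻²·year⁻¹
    fleet_names: list[str]
    trait: np.ndarray = field(default=None)
    taxon: np.ndarray = field(default=None)
    harvested: np.ndarray = field(default=None)
    juvenile: np.ndarray = field(default=None)
    dispersal: np.ndarray = field(default=None)  # km·year⁻¹
    M0base: np.ndarray = field(default=None)  # year⁻¹, filled by solve_balance

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("B", "PB", "QB", "EE", "BA"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
            if getattr(self, attr).shape != (n,):
                raise ValueError(f"{attr} must have shape ({n},)")
        self.group_type = np.asarray(self.group_type, dtype=object)
        self.DC = np.asarray(self.DC, dtype=float)
        if self.DC.shape != (n, n):
            raise ValueError("DC must be (n, n)")
        self.landings = np.atleast_2d(np.asarray(self.landings, dtype=float))
        if self.landings.shape[1] != n:
            raise ValueError("landings must be (n_fleets, n)")
        if self.trait is None:
            self.trait = np.array(["demersal"] * n, dtype=object)
        else:
            self.trait = np.asarray(self.trait, dtype=object)
        if self.taxon is None:
            self.taxon = np.array(["fishes"] * n, dtype=object)
        else:
            self.taxon = np.asarray(self.taxon, dtype=object)
        if self.harvested is None:
            self.harvested = self.landings.sum(axis=0) > 0
        else:
            self.harvested = np.asarray(self.harvested, dtype=bool)
        if self.juvenile is None:
            self.juvenile = np.zeros(n, dtype=bool)
        else:
            self.juvenile = np.asarray(self.juvenile, dtype=bool)
        if self.dispersal is None:
            self.dispersal = np.full(n, 30.0)
        else:
            self.dispersal = np.asarray(self.dispersal, dtype=float)
        if self.M0base is None:
            self.M0base = np.full(n, np.nan)
        else:
            self.M0base = np.asarray(self.M0base, dtype=float)
        bad = ~np.isin(self.group_type, GROUP_TYPES)
        if bad.any():
            raise ValueError(f"unknown group types: {self.group_type[bad]}")
        if (self.B < 0).any() or (self.PB < 0).any() or (self.QB < 0).any():
            raise ValueError("B, PB, QB must be non-negative")
        rows = self.DC.sum(axis=1)
        cons = self.is_consumer
        if cons.any() and not np.allclose(rows[cons], 1.0, atol=1e-8):
            raise ValueError("consumer diet fractions must sum to 1")

    # ------------------------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.names)

    @property
    def n_fleets(self) -> int:
        return self.landings.shape[0]

    @property
    def is_producer(self) -> np.ndarray:
        return self.group_type == "producer"

    @property
    def is_consumer(self) -> np.ndarray:
        return self.group_type == "consumer"

    @property
    def is_detritus(self) -> np.ndarray:
        return self.group_type == "detritus"

    @property
    def Y(self) -> np.ndarray:
        """Total landings per group (summed over fleets), t·km⁻²·year⁻¹."""
        return self.landings.sum(axis=0)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def copy(self) -> "FoodWebModel":
        return replace(
            self,
            group_type=self.group_type.copy(),
            B=self.B.copy(),
            PB=self.PB.copy(),
            QB=self.QB.copy(),
            EE=self.EE.copy(),
            BA=self.BA.copy(),
            DC=self.DC.copy(),
            landings=self.landings.copy(),
            trait=self.trait.copy(),
            taxon=self.taxon.copy(),
            harvested=self.harvested.copy(),
            juvenile=self.juvenile.copy(),
            dispersal=self.dispersal.copy(),
            M0base=self.M0base.copy(),
            names=list(self.names),
            fleet_names=list(self.fleet_names),
        )

    def trophic_levels(self) -> np.ndarray:
        """TL = 1 for producers/detritus; TL_j = 1 + Σ_i DC_ji · TL_i."""
        n = self.n_groups
        A = np.eye(n)
        cons = self.is_consumer
        A[cons] -= self.DC[cons]
        return np.linalg.solve(A, np.ones(n))

    # ------------------------------------------------------------------
    # CSV round-trip (groups.csv / diet.csv / fleets.csv)
    def to_csv_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        groups = pd.DataFrame(
            {
                "name": self.names,
                "type": self.group_type,
                "B": self.B,
                "PB": self.PB,
                "QB": self.QB,
                "EE": self.EE,
                "BA": self.BA,
                "M0base": self.M0base,
                "trait": self.trait,
                "taxon": self.taxon,
                "harvested": self.harvested,
                "juvenile": self.juvenile,
                "dispersal": self.dispersal,
            }
        )
        groups.to_csv(path / "groups.csv", index=False)
        pred, prey = np.nonzero(self.DC > 0)
        diet = pd.DataFrame(
            {
                "predator": [self.names[j] for j in pred],
                "prey": [self.names[i] for i in prey],
                "fraction": self.DC[pred, prey],
            }
        )
        diet.to_csv(path / "diet.csv", index=False)
        fl, gi = np.nonzero(self.landings > 0)
        fleets = pd.DataFrame(
            {
                "fleet": [self.fleet_names[f] for f in fl],
                "group": [self.names[i] for i in gi],
                "catch": self.landings[fl, gi],
            }
        )
        fleets.to_csv(path / "fleets.csv", index=False)

    @classmethod
    def from_csv_dir(cls, path: str | Path) -> "FoodWebModel":
        path = Path(path)
        groups = pd.read_csv(path / "groups.csv")
        names = groups["name"].tolist()
        n = len(names)
        idx = {g: i for i, g in enumerate(names)}
        DC = np.zeros((n, n))
        diet = pd.read_csv(path / "diet.csv")
        for _, row in diet.iterrows():
            DC[idx[row["predator"]], idx[row["prey"]]] = row["fraction"]
        fleets = pd.read_csv(path / "fleets.csv")
        fleet_names = sorted(fleets["fleet"].unique().tolist())
        landings = np.zeros((len(fleet_names), n))
        fidx = {f: k for k, f in enumerate(fleet_names)}
        for _, row in fleets.iterrows():
            landings[fidx[row["fleet"]], idx[row["group"]]] = row["catch"]
        return cls(
            names=names,
            group_type=groups["type"].to_numpy(dtype=object),
            B=groups["B"].to_numpy(),
            PB=groups["PB"].to_numpy(),
            QB=groups["QB"].to_numpy(),
            EE=groups["EE"].to_numpy(),
            BA=groups["BA"].to_numpy(),
            DC=DC,
            landings=landings,
            fleet_names=fleet_names,
            trait=groups["trait"].to_numpy(dtype=object),
            taxon=groups["taxon"].to_numpy(dtype=object),
            harvested=groups["harvested"].to_numpy(dtype=bool),
            juvenile=groups["juvenile"].to_numpy(dtype=bool),
            dispersal=groups["dispersal"].to_numpy(),
            M0base=groups["M0base"].to_numpy(),
        )
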