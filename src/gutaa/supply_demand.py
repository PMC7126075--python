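"""Dietary amino-acid supply versus metabolic demand.

Gross dietary content of each amino acid (protein fraction × concentration
in protein) is discounted for ileal digestibility and for first-pass
mucosal catabolism — the fraction of an absorbed amino acid consumed by
the intestinal mucosa and its microbiota before reaching the systemic
pool. The net supply, expressed as % of dry food, is compared with
published requirements for rapidly growing mice on the same scale, giving
a unitless supply:demand ratio per amino acid and diet.

Default mucosal-catabolism fractions follow first-pass splanchnic
measurements in non-ruminant mammals fed casein-based diets: Ile 30%,
Leu 40%, Val 40%, Phe 45%, Lys 50%, Thr 60% — threonine, heavily used in
mucin glycoproteins, is the most retained. Digestibility and demand
defaults are literature-typical placeholders; the module validates
completeness of user-supplied tables rather than asserting study values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .endmembers import AAProfile, DietComposition, protein_source_fractions

__all__ = [
    "SupplyParams",
    "DemandTable",
    "experiment_ration",
    "aa_supply",
    "supply_vs_demand",
    "supply_demand_table",
    "DEFAULT_MUCOSAL_CATABOLISM",
    "DEFAULT_DIGESTIBILITY",
    "DEFAULT_DEMAND",
]

DEFAULT_MUCOSAL_CATABOLISM: dict[str, float] = {
    "Ile": 0.30, "Leu": 0.40, "Val": 0.40, "Phe": 0.45, "Lys": 0.50,
    "Thr": 0.60, "Asp": 0.90,
}

# True ileal digestibility of casein-based diets is high; placeholder.
DEFAULT_DIGESTIBILITY: dict[str, float] = {
    aa: 0.91 for aa in ("Thr", "Lys", "Phe", "Val", "Ile", "Leu", "Asp")
}

# Requirements for rapidly growing mice as % of dry food (placeholder
# values in the range of rodent nutrient-requirement tables).
DEFAULT_DEMAND: dict[str, float] = {
    "Thr": 0.60, "Lys": 0.60, "Phe": 0.55, "Val": 0.55, "Ile": 0.45,
    "Leu": 0.75, "Asp": 1.20,
}


def _check_fraction_map(name: str, m: Mapping[str, float]) -> None:
    bad = {aa: v for aa, v in m.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"{name}: fractions outside [0,1]: {bad}")


@dataclass(frozen=True)
class SupplyParams:
    """Discount factors and ration for the supply calculation."""

    digestibility: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIGESTIBILITY))
    mucosal_catabolism: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MUCOSAL_CATABOLISM)
    )
    daily_ration: float = 3.0  # g dry food / day
    experiment_days: int = 120

    def __post_init__(self) -> None:
        _check_fraction_map("digestibility", self.digestibility)
        _check_fraction_map("mucosal_catabolism", self.mucosal_catabolism)


@dataclass(frozen=True)
class DemandTable:
    """Per-AA requirement as % of dry food for rapidly growing mice."""

    demand: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DEMAND))

    def __post_init__(self) -> None:
        bad = {aa: v for aa, v in self.demand.items() if v < 0}
        if bad:
            raise ValueError(f"demand: negative entries {bad}")


def experiment_ration(params: SupplyParams) -> float:
    """Total dry-food intake over the experiment (g)."""
    if params.daily_ration <= 0:
        raise ValueError(f"daily_ration must be positive, got {params.daily_ration}")
    if params.experiment_days < 1:
        raise ValueError(f"experiment_days must be >= 1, got {params.experiment_days}")
    return params.daily_ration * params.experiment_days


def aa_supply(
    diet: DietComposition,
    casein_profile: AAProfile,
    cornmeal_profile: AAProfile,
    params: SupplyParams,
    aa_codes: Iterable[str],
) -> dict[str, float]:
    """Net supply of each amino acid as % of dry food.

    supply_AA = protein_fraction × c̄_AA × digestibility_AA × (1 − catabolism_AA) × 100

    where c̄_AA is the AA concentration in dietary protein averaged over
    casein and cornmeal protein by their protein-mass shares.
    """
    f_cas, f_corn = protein_source_fractions(diet)
    out: dict[str, float] = {}
    for aa in aa_codes:
        try:
            dig = params.digestibility[aa]
        except KeyError:
            raise KeyError(f"digestibility table missing entry for {aa!r}") from None
        try:
            cat = params.mucosal_catabolism[aa]
        except KeyError:
            raise KeyError(f"mucosal catabolism table missing entry for {aa!r}") from None
        try:
            conc = f_cas * casein_profile.concentration[aa] + f_corn * cornmeal_profile.concentration[aa]
        except KeyError as exc:
            raise KeyError(f"AA profile missing concentration for {exc.args[0]!r}") from None
        out[aa] = diet.total_protein_fraction * conc * dig * (1.0 - cat) * 100.0
    return out


def supply_vs_demand(
    supply: Mapping[str, float],
    demand: DemandTable,
    balanced_band: tuple[float, float] = (0.9, 1.1),
) -> pd.DataFrame:
    """Supply:demand ratio and deficit/balanced/surplus call per amino acid.

    AAs with zero demand get a NaN ratio flagged ``undefined``.
    """
    lo, hi = balanced_band
    rows = []
    common = [aa for aa in supply if aa in demand.demand]
    missing = [aa for aa in supply if aa not in demand.demand]
    if missing:
        raise KeyError(f"demand table missing entries for {missing}")
    for aa in common:
        d = demand.demand[aa]
        if d == 0:
            rows.append({"aa": aa, "supply_pct": supply[aa], "demand_pct": d,
                         "ratio": float("nan"), "class": "undefined"})
            continue
        ratio = supply[aa] / d
        cls = "deficit" if ratio < lo else ("surplus" if ratio > hi else "balanced")
        rows.append({"aa": aa, "supply_pct": supply[aa], "demand_pct": d,
                     "ratio": ratio, "class": cls})
    return pd.DataFrame(rows, columns=["aa", "supply_pct", "demand_pct", "ratio", "class"])


def supply_demand_table(
    diets: Iterable[DietComposition],
    casein_profile: AAProfile,
    cornmeal_profile: AAProfile,
    params: SupplyParams,
    demand: DemandTable,
    aa_codes: Iterable[str],
    balanced_band: tuple[float, float] = (0.9, 1.1),
) -> pd.DataFrame:
    """Tidy supply-versus-demand table over treatments × amino acids."""
    aa_codes = list(aa_codes)
    frames = []
    for diet in diets:
        supply = aa_supply(diet, casein_profile, cornmeal_profile, params, aa_codes)
        frame = supply_vs_demand(supply, demand, balanced_band)
        frame.insert(0, "treatment", diet.treatment_label)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
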