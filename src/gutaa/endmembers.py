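"""Dietary and microbial δ¹³C end members for the two-source mixing model.

The experimental diets pair a C₃ protein (casein, δ¹³C ≈ −26.5‰) against
C₄ carbohydrates (sucrose −12.2‰, cornmeal −12.0‰), so the two candidate
carbon sources of a muscle essential amino acid are ~14‰ apart — a natural
label requiring no isotopic enrichment.

Two end members are built per (treatment, amino acid):

* **dietary routing** — the concentration-weighted δ¹³C of that amino acid
  in dietary protein, mixing casein and the protein fraction of cornmeal
  (cornmeal is ~10% protein by weight, and in low-protein diets its
  contribution to the dietary amino-acid pool is substantial);
* **microbial synthesis** — the mass-weighted δ¹³C of the dietary
  carbohydrate pool (sucrose + cornmeal starch) plus a per-compound
  fractionation offset for bacterial de novo synthesis.

Direct routing is taken as isotopically neutral by default (trophic
discrimination of intact amino acids ≈ 0‰); a per-AA routing offset is
exposed for sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .aminoacids import ESSENTIAL_AA

__all__ = [
    "DietComposition",
    "AAProfile",
    "FractionationTable",
    "EndmemberSet",
    "protein_source_fractions",
    "dietary_aa_delta",
    "carbohydrate_pool_delta",
    "microbial_endmember_delta",
    "build_endmember_set",
    "DEFAULT_DIETS",
    "DEFAULT_CASEIN_PROFILE",
    "DEFAULT_CORNMEAL_PROFILE",
    "DEFAULT_FRACTIONATION",
]

_MASS_TOL = 1e-6


@dataclass(frozen=True)
class DietComposition:
    """Mass fractions and source δ¹³C values for one diet treatment.

    ``mass_fraction_other`` absorbs oils, vitamins, fibre, and minerals.
    ``cornmeal_carb_fraction`` optionally overrides the carbohydrate mass
    of cornmeal per gram; by default its non-protein mass is used.
    """

    treatment_label: str
    mass_fraction_casein: float
    mass_fraction_sucrose: float
    mass_fraction_cornmeal: float
    mass_fraction_other: float
    cornmeal_protein_fraction: float = 0.10
    delta_casein: float = -26.5
    delta_sucrose: float = -12.2
    delta_cornmeal: float = -12.0
    cornmeal_carb_fraction: float | None = None

    def __post_init__(self) -> None:
        fracs = (
            self.mass_fraction_casein,
            self.mass_fraction_sucrose,
            self.mass_fraction_cornmeal,
            self.mass_fraction_other,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError(f"{self.treatment_label}: mass fractions must be in [0,1]")
        total = sum(fracs)
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(
                f"{self.treatment_label}: mass fractions sum to {total:.6f}, expected 1"
            )
        if not 0.0 <= self.cornmeal_protein_fraction <= 1.0:
            raise ValueError(f"{self.treatment_label}: cornmeal_protein_fraction not in [0,1]")

    @property
    def protein_mass_casein(self) -> float:
        """Grams of casein protein per gram of diet (casein is pure protein)."""
        return self.mass_fraction_casein

    @property
    def protein_mass_cornmeal(self) -> float:
        """Grams of cornmeal-derived protein per gram of diet."""
        return self.mass_fraction_cornmeal * self.cornmeal_protein_fraction

    @property
    def total_protein_fraction(self) -> float:
        return self.protein_mass_casein + self.protein_mass_cornmeal

    @property
    def carb_mass_cornmeal(self) -> float:
        if self.cornmeal_carb_fraction is not None:
            return self.mass_fraction_cornmeal * self.cornmeal_carb_fraction
        return self.mass_fraction_cornmeal * (1.0 - self.cornmeal_protein_fraction)


@dataclass(frozen=True)
class AAProfile:
    """Per-source amino-acid concentrations.

    ``concentration`` maps 3-letter AA code → grams of that amino acid per
    gram of the unit named by ``unit`` (``"protein"`` or ``"dry_source"``).
    """

    source: str
    concentration: Mapping[str, float]
    unit: str = "protein"

    def __post_init__(self) -> None:
        if self.unit not in ("protein", "dry_source"):
            raise ValueError(f"{self.source}: unit must be 'protein' or 'dry_source'")
        bad = {aa: c for aa, c in self.concentration.items() if c < 0}
        if bad:
            raise ValueError(f"{self.source}: negative concentrations {bad}")


@dataclass(frozen=True)
class FractionationTable:
    """Per-AA Δ¹³C offsets (‰) for microbial synthesis from carbohydrate carbon.

    The offsets appropriate for gut communities come from culture studies
    and are not universal constants; the shipped default (0‰ for every AA)
    is a placeholder meaning "end member equals the carbohydrate pool",
    which callers should override with study-specific values when known.
    """

    offset: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [aa for aa, v in self.offset.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite fractionation offsets for {bad}")

    def require(self, aa_codes: Iterable[str]) -> None:
        missing = [aa for aa in aa_codes if aa not in self.offset]
        if missing:
            raise KeyError(f"fractionation table missing offsets for {missing}")


@dataclass
class EndmemberSet:
    """Per-(treatment, AA) δ¹³C of the two candidate sources.

    ``delta_dietary`` is the routed dietary-protein end member;
    ``delta_microbial`` the carbohydrate-fed microbial-synthesis one. Both
    maps cover the same keys.
    """

    delta_dietary: dict[tuple[str, str], float] = field(default_factory=dict)
    delta_microbial: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.delta_dietary) != set(self.delta_microbial):
            raise ValueError("dietary and microbial end-member maps cover different keys")

    def require(self, treatment: str, aa: str) -> tuple[float, float]:
        key = (treatment, aa)
        if key not in self.delta_dietary:
            raise KeyError(f"no end members for treatment {treatment!r}, AA {aa!r}")
        return self.delta_dietary[key], self.delta_microbial[key]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: treatment, aa, role, delta."""
        rows = [
            {"treatment": t, "aa": a, "role": "dietary", "delta": d}
            for (t, a), d in sorted(self.delta_dietary.items())
        ] + [
            {"treatment": t, "aa": a, "role": "microbial", "delta": d}
            for (t, a), d in sorted(self.delta_microbial.items())
        ]
        return pd.DataFrame(rows, columns=["treatment", "aa", "role", "delta"])


def protein_source_fractions(diet: DietComposition) -> tuple[float, float]:
    """Split total dietary protein between casein and cornmeal by mass.

    Returns ``(f_casein, f_cornmeal)`` summing to 1. Raises ``ValueError``
    for a protein-free diet.
    """
    m_cas = diet.protein_mass_casein
    m_corn = diet.protein_mass_cornmeal
    total = m_cas + m_corn
    if total <= 0:
        raise ValueError(f"{diet.treatment_label}: diet contains no protein")
    f_corn = m_corn / total
    return 1.0 - f_corn, f_corn


def dietary_aa_delta(
    diet: DietComposition,
    casein_profile: AAProfile,
    cornmeal_profile: AAProfile,
    aa_codes: Iterable[str] = ESSENTIAL_AA,
    routing_offset: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Concentration-weighted dietary-protein δ¹³C per amino acid.

    For each AA the two protein sources are mixed in proportion to the
    amount of that amino acid each contributes per gram of diet
    (protein mass × concentration in protein), so an amino acid scarce in
    casein but rich in corn protein leans toward the cornmeal δ¹³C.

    ``routing_offset`` adds an optional per-AA trophic-discrimination term
    (default 0‰: intact routing is isotopically neutral).
    """
    m_cas = diet.protein_mass_casein
    m_corn = diet.protein_mass_cornmeal
    out: dict[str, float] = {}
    undefined: list[str] = []
    for aa in aa_codes:
        try:
            c_cas = casein_profile.concentration[aa]
            c_corn = cornmeal_profile.concentration[aa]
        except KeyError as exc:
            raise KeyError(f"AA profile missing concentration for {exc.args[0]!r}") from None
        w_cas = m_cas * c_cas
        w_corn = m_corn * c_corn
        if w_cas + w_corn <= 0:
            undefined.append(aa)
            continue
        delta = (w_cas * diet.delta_casein + w_corn * diet.delta_cornmeal) / (w_cas + w_corn)
        if routing_offset is not None:
            delta += routing_offset.get(aa, 0.0)
        out[aa] = delta
    if undefined:
        raise ValueError(
            f"{diet.treatment_label}: dietary δ undefined for {undefined} "
            "(zero concentration in both protein sources)"
        )
    return out


def carbohydrate_pool_delta(diet: DietComposition) -> float:
    """Mass-weighted δ¹³C of the dietary carbohydrate pool (sucrose + cornmeal starch)."""
    m_suc = diet.mass_fraction_sucrose
    m_corn = diet.carb_mass_cornmeal
    total = m_suc + m_corn
    if total <= 0:
        raise ValueError(f"{diet.treatment_label}: diet contains no carbohydrate")
    return (m_suc * diet.delta_sucrose + m_corn * diet.delta_cornmeal) / total


def microbial_endmember_delta(
    carb_delta: float,
    table: FractionationTable,
    aa_codes: Iterable[str] = ESSENTIAL_AA,
) -> dict[str, float]:
    """Microbial-synthesis end member: carbohydrate-pool δ plus per-AA offset."""
    aa_codes = list(aa_codes)
    table.require(aa_codes)
    return {aa: carb_delta + table.offset[aa] for aa in aa_codes}


def build_endmember_set(
    diets: Iterable[DietComposition],
    casein_profile: AAProfile,
    cornmeal_profile: AAProfile,
    fractionation: FractionationTable,
    aa_codes: Iterable[str] = ESSENTIAL_AA,
    routing_offset: Mapping[str, float] | None = None,
) -> EndmemberSet:
    """Assemble both end members over the full (treatment, AA) grid."""
    aa_codes = list(aa_codes)
    dietary: dict[tuple[str, str], float] = {}
    microbial: dict[tuple[str, str], float] = {}
    for diet in diets:
        d_diet = dietary_aa_delta(diet, casein_profile, cornmeal_profile, aa_codes, routing_offset)
        d_micro = microbial_endmember_delta(carbohydrate_pool_delta(diet), fractionation, aa_codes)
        for aa in aa_codes:
            dietary[(diet.treatment_label, aa)] = d_diet[aa]
            microbial[(diet.treatment_label, aa)] = d_micro[aa]
    return EndmemberSet(delta_dietary=dietary, delta_microbial=microbial)


def _diet(label: str, protein_pct: float, cornmeal_pct: float) -> DietComposition:
    casein = protein_pct / 100.0 - cornmeal_pct / 100.0 * 0.10
    cornmeal = cornmeal_pct / 100.0
    sucrose = 0.36
    return DietComposition(
        treatment_label=label,
        mass_fraction_casein=round(casein, 6),
        mass_fraction_sucrose=sucrose,
        mass_fraction_cornmeal=cornmeal,
        mass_fraction_other=round(1.0 - casein - sucrose - cornmeal, 6),
    )


# The four experimental diets, labelled protein%:carbohydrate%. Sucrose is
# held at 36% of diet mass; cornmeal varies inversely with casein so that
# total protein (casein + 10% of cornmeal mass) hits the label.
DEFAULT_DIETS: tuple[DietComposition, ...] = (
    _diet("40P:40C", 40.0, 4.0),
    _diet("21P:45C", 21.0, 9.0),
    _diet("12P:55C", 12.0, 19.0),
    _diet("9P:75C", 9.0, 39.0),
)

# Typical amino-acid compositions (g AA per 100 g protein, here as g/g).
# Placeholder literature-typical values for bovine casein and corn protein;
# override with measured compositions where available. Corn protein is
# Lys-poor and Leu-rich relative to casein.
DEFAULT_CASEIN_PROFILE = AAProfile(
    source="casein",
    concentration={
        "Thr": 0.042, "Lys": 0.080, "Phe": 0.052, "Val": 0.066,
        "Ile": 0.054, "Leu": 0.095, "Asp": 0.071,
    },
)
DEFAULT_CORNMEAL_PROFILE = AAProfile(
    source="cornmeal",
    concentration={
        "Thr": 0.038, "Lys": 0.028, "Phe": 0.049, "Val": 0.047,
        "Ile": 0.036, "Leu": 0.123, "Asp": 0.062,
    },
)

# Placeholder: no net fractionation between carbohydrate substrate and
# microbially synthesized AA carbon; study-specific offsets replace these.
DEFAULT_FRACTIONATION = FractionationTable(offset={aa: 0.0 for aa in ESSENTIAL_AA})
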