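"""Two-source mixing: fraction of muscle AA_ESS carbon of microbial origin.

A muscle essential amino acid is modelled as a binary mixture of carbon
directly routed from dietary protein (δ_diet) and carbon synthesized de
novo by gut bacteria from dietary carbohydrate (δ_microbe):

    δ_muscle = (1 − p)·δ_diet + p·δ_microbe
    p = (δ_muscle − δ_diet) / (δ_microbe − δ_diet)

p is estimated per individual mouse and per amino acid, then summarized
per treatment as mean ± SE over individuals. Measurement noise can push a
raw estimate outside [0,1]; raw values are preserved for diagnostics and
clipped values used for reporting (clip-then-average by default, the
order is policy-switchable). Estimation is refused when the two end
members are closer than a separation floor (default 1‰, ~2× a typical
compound-specific measurement SD) because p is then unidentifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .endmembers import EndmemberSet

__all__ = [
    "IsotopeDataset",
    "MixingEstimate",
    "UnidentifiableMixtureError",
    "mixing_fraction",
    "estimate_treatment",
    "estimate_all",
    "contribution_table",
]

DEFAULT_SEPARATION_FLOOR = 1.0  # ‰


class UnidentifiableMixtureError(ValueError):
    """End members too close for the mixing fraction to be identifiable."""


@dataclass
class IsotopeDataset:
    """Long-format per-individual, per-AA muscle δ¹³C measurements."""

    records: pd.DataFrame  # columns: individual_id, treatment, aa, delta_muscle[, sd]

    REQUIRED = ("individual_id", "treatment", "aa", "delta_muscle")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"isotope dataset missing columns {missing}")
        if not np.isfinite(self.records["delta_muscle"].to_numpy(float)).all():
            raise ValueError("non-finite delta_muscle values in isotope dataset")
        dup = self.records.duplicated(subset=["individual_id", "aa"])
        if dup.any():
            pairs = self.records.loc[dup, ["individual_id", "aa"]].to_records(index=False)
            raise ValueError(f"duplicate (individual, aa) measurements: {list(pairs)[:5]}")

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.records["treatment"]))

    @property
    def aa_codes(self) -> list[str]:
        return list(dict.fromkeys(self.records["aa"]))


@dataclass
class MixingEstimate:
    """Microbial-fraction estimate for one (treatment, AA) cell."""

    treatment: str
    aa: str
    raw_fractions: np.ndarray
    clipped_fractions: np.ndarray
    mean: float
    se: float  # NaN when n == 1 (SE undefined from a single mouse)
    n: int
    separation: float  # |δ_microbe − δ_diet|, ‰
    n_clipped_low: int = 0
    n_clipped_high: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("estimate requires at least one individual")
        if np.any(self.clipped_fractions < 0) or np.any(self.clipped_fractions > 1):
            raise ValueError("clipped fractions outside [0,1]")

    @property
    def se_defined(self) -> bool:
        return not math.isnan(self.se)


def mixing_fraction(
    delta_muscle: float,
    delta_diet: float,
    delta_microbe: float,
    separation_floor: float = DEFAULT_SEPARATION_FLOOR,
) -> float:
    """Raw (unclipped) microbial fraction from the two-source balance.

    Raises :class:`UnidentifiableMixtureError` when
    ``|delta_microbe − delta_diet| < separation_floor``.
    """
    sep = abs(delta_microbe - delta_diet)
    if sep < separation_floor:
        raise UnidentifiableMixtureError(
            f"end-member separation {sep:.3g}‰ below floor {separation_floor:g}‰; "
            "mixing fraction unidentifiable"
        )
    return (delta_muscle - delta_diet) / (delta_microbe - delta_diet)


def estimate_treatment(
    dataset: IsotopeDataset,
    endmembers: EndmemberSet,
    treatment: str,
    aa: str,
    clip_order: Literal["clip_then_average", "average_then_clip"] = "clip_then_average",
    separation_floor: float = DEFAULT_SEPARATION_FLOOR,
) -> MixingEstimate:
    """Estimate the microbial fraction for one (treatment, AA) cell.

    Per-individual fractions are computed, clipped to [0,1], and the
    treatment mean and SE (sample SD / √n) taken over individuals after
    clipping (or before, under ``average_then_clip``). With a single
    individual the SE is reported as NaN.
    """
    d_diet, d_micro = endmembers.require(treatment, aa)
    sub = dataset.records
    sub = sub[(sub["treatment"] == treatment) & (sub["aa"] == aa)]
    if sub.empty:
        raise ValueError(f"no measurements for treatment {treatment!r}, AA {aa!r}")
    deltas = sub["delta_muscle"].to_numpy(float)
    raw = np.array(
        [mixing_fraction(d, d_diet, d_micro, separation_floor) for d in deltas]
    )
    clipped = np.clip(raw, 0.0, 1.0)
    n = len(raw)
    pooled = clipped if clip_order == "clip_then_average" else raw
    mean = float(np.mean(pooled))
    se = float(np.std(pooled, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    if clip_order == "average_then_clip":
        mean = float(np.clip(mean, 0.0, 1.0))
    return MixingEstimate(
        treatment=treatment,
        aa=aa,
        raw_fractions=raw,
        clipped_fractions=clipped,
        mean=mean,
        se=se,
        n=n,
        separation=abs(d_micro - d_diet),
        n_clipped_low=int(np.sum(raw < 0)),
        n_clipped_high=int(np.sum(raw > 1)),
    )


def estimate_all(
    dataset: IsotopeDataset,
    endmembers: EndmemberSet,
    clip_order: Literal["clip_then_average", "average_then_clip"] = "clip_then_average",
    separation_floor: float = DEFAULT_SEPARATION_FLOOR,
) -> list[MixingEstimate]:
    """Estimate every (treatment, AA) cell present in the dataset."""
    out = []
    for treatment in dataset.treatments:
        for aa in dataset.aa_codes:
            out.append(
                estimate_treatment(
                    dataset, endmembers, treatment, aa,
                    clip_order=clip_order, separation_floor=separation_floor,
                )
            )
    return out


def contribution_table(estimates: Iterable[MixingEstimate]) -> pd.DataFrame:
    """Tidy results table across treatments × amino acids."""
    rows = [
        {
            "treatment": e.treatment,
            "aa": e.aa,
            "mean": e.mean,
            "se": e.se,
            "n": e.n,
            "separation": e.separation,
            "n_clipped_low": e.n_clipped_low,
            "n_clipped_high": e.n_clipped_high,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=["treatment", "aa", "mean", "se", "n", "separation",
                 "n_clipped_low", "n_clipped_high"],
    )
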