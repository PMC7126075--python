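"""Mass-balance correction of δ¹³C for carbon added during derivatization.

GC-amenable amino-acid derivatives carry reagent carbon, so the measured
δ¹³C of a derivatized amino acid is a carbon-weighted mixture of the amino
acid itself and the added groups:

    (n_AA + n_add) · δ_derivatized = n_AA · δ_AA + n_add · δ_added

Calibration runs a standard of known δ_AA through the same chemistry and
solves for δ_added (which folds in any kinetic fractionation of the
reaction); sample correction then inverts the same balance. Everything is
linear on the ‰ scale — the error of treating δ values as additive is
negligible at natural abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .aminoacids import AminoAcidSpec

__all__ = ["DerivatizationStandard", "calibrate_added_carbon", "correct_derivatization"]


@dataclass(frozen=True)
class DerivatizationStandard:
    """A standard of known δ¹³C measured after derivatization.

    ``delta_known`` is the accepted δ¹³C (‰ vs VPDB) of the underivatized
    amino acid; ``delta_derivatized_measured`` is what the IRMS reports
    for its derivative.
    """

    aa: AminoAcidSpec
    delta_known: float
    delta_derivatized_measured: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_known) and math.isfinite(self.delta_derivatized_measured)):
            raise ValueError(f"{self.aa.code}: standard δ values must be finite")


def calibrate_added_carbon(standard: DerivatizationStandard) -> float:
    """Solve the carbon mass balance of a standard for the added-carbon δ¹³C.

    δ_added = [(n_AA + n_add)·δ_derivatized − n_AA·δ_known] / n_add

    Raises ``ValueError`` when the derivative adds no carbon (the added
    pool is then unobservable and the calibration is undefined).
    """
    aa = standard.aa
    if aa.n_added_carbon == 0:
        raise ValueError(
            f"{aa.code}: derivatization adds no carbon; added-carbon δ is undefined"
        )
    n_tot = aa.n_carbon + aa.n_added_carbon
    return (
        n_tot * standard.delta_derivatized_measured - aa.n_carbon * standard.delta_known
    ) / aa.n_added_carbon


def correct_derivatization(delta_measured: float, aa: AminoAcidSpec, delta_added: float) -> float:
    """Recover the underivatized amino-acid δ¹³C from a derivative measurement.

    δ_AA = [(n_AA + n_add)·δ_measured − n_add·δ_added] / n_AA

    With ``n_added_carbon == 0`` this is the identity. The correction is
    linear in δ_measured with slope (n_AA + n_add)/n_AA > 1, so measurement
    noise is amplified by the same factor.
    """
    if not (math.isfinite(delta_measured) and math.isfinite(delta_added)):
        raise ValueError(f"{aa.code}: non-finite δ input to derivatization correction")
    if aa.n_added_carbon == 0:
        return delta_measured
    n_tot = aa.n_carbon + aa.n_added_carbon
    return (n_tot * delta_measured - aa.n_added_carbon * delta_added) / aa.n_carbon
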