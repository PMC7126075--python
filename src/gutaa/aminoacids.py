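"""Amino-acid identities and per-compound constants.

The six essential amino acids (AA_ESS) tracked here — Thr, Lys, Phe, Val,
Ile, Leu — cannot be synthesized de novo by the mammalian host; any muscle
AA_ESS carbon that does not match dietary protein must have passed through
microbial synthesis. Asp is carried alongside because it is the precursor
of aspartate semialdehyde, the committed intermediate of microbial Thr and
Lys synthesis, and so appears in the supply/demand accounting.

Precursor families group AA_ESS by the glycolytic / TCA-cycle metabolite
from which bacteria build them: Val/Ile/Leu from pyruvate, Thr/Lys from
oxaloacetate, Phe from phosphoenolpyruvate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AminoAcidSpec", "ESSENTIAL_AA", "DEFAULT_AA_SPECS", "get_spec"]

_FAMILIES = {"pyruvate", "oxaloacetate", "phosphoenolpyruvate"}


@dataclass(frozen=True)
class AminoAcidSpec:
    """Identity and carbon bookkeeping for one amino acid.

    Parameters
    ----------
    name : str
        Full name, e.g. ``"valine"``.
    code : str
        Three-letter code, e.g. ``"Val"``.
    n_carbon : int
        Carbons in the underivatized amino acid (≥ 2).
    n_added_carbon : int
        Carbons added by the derivatization reagent. The exact counts for
        the chemistry used in any given study depend on the reagent; these
        defaults are configurable placeholders, not asserted values.
    precursor_family : str
        One of ``pyruvate``, ``oxaloacetate``, ``phosphoenolpyruvate``.
    """

    name: str
    code: str
    n_carbon: int
    n_added_carbon: int
    precursor_family: str

    def __post_init__(self) -> None:
        if self.n_carbon < 2:
            raise ValueError(f"{self.code}: n_carbon must be >= 2, got {self.n_carbon}")
        if self.n_added_carbon < 0:
            raise ValueError(f"{self.code}: n_added_carbon must be >= 0")
        if self.precursor_family not in _FAMILIES:
            raise ValueError(
                f"{self.code}: precursor_family {self.precursor_family!r} "
                f"not in {sorted(_FAMILIES)}"
            )


ESSENTIAL_AA = ("Thr", "Lys", "Phe", "Val", "Ile", "Leu")

# n_added_carbon defaults assume a methoxycarbonyl methyl-ester style
# derivative (placeholder; override per study chemistry via config).
DEFAULT_AA_SPECS: dict[str, AminoAcidSpec] = {
    s.code: s
    for s in [
        AminoAcidSpec("threonine", "Thr", 4, 3, "oxaloacetate"),
        AminoAcidSpec("lysine", "Lys", 6, 4, "oxaloacetate"),
        AminoAcidSpec("phenylalanine", "Phe", 9, 3, "phosphoenolpyruvate"),
        AminoAcidSpec("valine", "Val", 5, 3, "pyruvate"),
        AminoAcidSpec("isoleucine", "Ile", 6, 3, "pyruvate"),
        AminoAcidSpec("leucine", "Leu", 6, 3, "pyruvate"),
        AminoAcidSpec("aspartate", "Asp", 4, 4, "oxaloacetate"),
    ]
}


def get_spec(code: str) -> AminoAcidSpec:
    """Return the default :class:`AminoAcidSpec` for a 3-letter code."""
    try:
        return DEFAULT_AA_SPECS[code]
    except KeyError:
        raise KeyError(
            f"unknown amino acid code {code!r}; known: {sorted(DEFAULT_AA_SPECS)}"
        ) from None
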