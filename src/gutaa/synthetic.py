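"""Synthetic isotope and community datasets with known ground truth.

Every downstream stage (end members → mixing → community statistics) is
exercised against data generated here, so true microbial fractions and
true community structure are known exactly.

The default design mirrors the feeding experiment being emulated: four
diets trading C₃ casein against C₄ carbohydrates (40P:40C, 21P:45C,
12P:55C, 9P:75C), six mice per treatment for muscle isotopes and five for
cecal communities. Muscle δ¹³C is the two-source mixture plus Gaussian
measurement noise (default SD 0.5‰, a typical compound-specific isotope
precision). Cecal communities are Dirichlet-multinomial draws around
treatment-level phylum mixtures in which Firmicutes dominate the two
low-protein diets (82.5% and 66.2% expected abundance) and the two phyla
are nearly even on the high-protein diets — the published community
pattern this generator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aminoacids import ESSENTIAL_AA
from .community import OtuTable
from .endmembers import DEFAULT_DIETS, DietComposition, EndmemberSet
from .mixing import IsotopeDataset

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "CommunityProfile",
    "generate_isotope_dataset",
    "generate_otu_table",
    "generate_full_experiment",
    "DEFAULT_GROUND_TRUTH",
    "DEFAULT_COMMUNITY_PROFILE",
]

# Emulated microbial contributions per (treatment, AA): highest for Val/Ile,
# rising as dietary protein falls (Val 60% / Ile 40% on the low-protein
# diet); Thr and Lys near zero on high-protein diets with a several-fold
# rise below 21% protein; Phe low on the low-protein diet.
_TRUE_P: dict[str, dict[str, float]] = {
    "40P:40C": {"Val": 0.30, "Ile": 0.30, "Leu": 0.15, "Phe": 0.15, "Thr": 0.03, "Lys": 0.03},
    "21P:45C": {"Val": 0.35, "Ile": 0.30, "Leu": 0.15, "Phe": 0.15, "Thr": 0.04, "Lys": 0.04},
    "12P:55C": {"Val": 0.40, "Ile": 0.35, "Leu": 0.20, "Phe": 0.20, "Thr": 0.12, "Lys": 0.12},
    "9P:75C": {"Val": 0.60, "Ile": 0.40, "Leu": 0.25, "Phe": 0.04, "Thr": 0.15, "Lys": 0.15},
}

# Expected phylum mixtures per treatment; Firmicutes fractions follow the
# published relative abundances, the remainder split between Bacteroidetes
# and three minor phyla.
_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Deferribacteres", "Verrucomicrobia")
_PHYLUM_MIX: dict[str, dict[str, float]] = {
    "40P:40C": {"Firmicutes": 0.495, "Bacteroidetes": 0.469, "Proteobacteria": 0.020,
                "Deferribacteres": 0.008, "Verrucomicrobia": 0.008},
    "21P:45C": {"Firmicutes": 0.455, "Bacteroidetes": 0.476, "Proteobacteria": 0.037,
                "Deferribacteres": 0.016, "Verrucomicrobia": 0.016},
    "12P:55C": {"Firmicutes": 0.825, "Bacteroidetes": 0.125, "Proteobacteria": 0.020,
                "Deferribacteres": 0.015, "Verrucomicrobia": 0.015},
    "9P:75C": {"Firmicutes": 0.662, "Bacteroidetes": 0.288, "Proteobacteria": 0.020,
               "Deferribacteres": 0.015, "Verrucomicrobia": 0.015},
}

# Firmicutes spread over ~6x more OTUs than Bacteroidetes, echoing the
# observed OTU richness imbalance.
_N_OTUS = {"Firmicutes": 36, "Bacteroidetes": 6, "Proteobacteria": 3,
           "Deferribacteres": 2, "Verrucomicrobia": 2}
_FAMILIES = {
    "Firmicutes": ("Lactobacillaceae", "Lachnospiraceae", "Ruminococcaceae"),
    "Bacteroidetes": ("Bacteroidaceae", "Porphyromonadaceae", "Rikenellaceae", "S24-7"),
    "Proteobacteria": ("Alcaligenaceae",),
    "Deferribacteres": ("Deferribacteraceae",),
    "Verrucomicrobia": ("Verrucomicrobiaceae",),
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Treatments, replication, amino acids, and the master seed."""

    treatments: Sequence[DietComposition] = DEFAULT_DIETS
    n_individuals_per_treatment: int = 6
    aa_list: Sequence[str] = ESSENTIAL_AA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals_per_treatment < 1:
            raise ValueError("n_individuals_per_treatment must be >= 1")
        if not self.treatments:
            raise ValueError("design needs at least one treatment")
        if not self.aa_list:
            raise ValueError("design needs at least one amino acid")

    def individual_ids(self, treatment: str) -> list[str]:
        return [f"{treatment}_m{i + 1}" for i in range(self.n_individuals_per_treatment)]


@dataclass(frozen=True)
class GroundTruth:
    """Latent microbial fractions and measurement noise used to simulate."""

    p_microbial: Mapping[tuple[str, str], float]
    noise_sd: float = 0.5  # ‰

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.p_microbial.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"ground-truth fractions outside [0,1]: {bad}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CommunityProfile:
    """Treatment-level phylum mixtures and sequencing model."""

    phylum_mixture: Mapping[str, Mapping[str, float]]
    dirichlet_concentration: float = 80.0
    sequencing_depth: int = 20_000
    n_otus_per_phylum: Mapping[str, int] = field(default_factory=lambda: dict(_N_OTUS))

    def __post_init__(self) -> None:
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        for t, mix in self.phylum_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{t}: phylum mixture sums to {total:.6f}, expected 1")


DEFAULT_GROUND_TRUTH = GroundTruth(
    p_microbial={(t, aa): p for t, d in _TRUE_P.items() for aa, p in d.items()},
    noise_sd=0.5,
)
DEFAULT_COMMUNITY_PROFILE = CommunityProfile(phylum_mixture=_PHYLUM_MIX)


def generate_isotope_dataset(
    design: ExperimentDesign,
    truth: GroundTruth,
    endmembers: EndmemberSet,
) -> IsotopeDataset:
    """Simulate per-individual muscle δ¹³C from the two-source mixture.

    δ_muscle = (1−p)·δ_diet + p·δ_microbe + ε,  ε ~ N(0, noise_sd²),
    with p the ground-truth microbial fraction for that (treatment, AA).
    Deterministic given ``design.seed``. Fails with a named pair when an
    end member or truth entry is missing, and hard-asserts that no draw
    strays beyond 10 noise SDs of the mixture value.
    """
    rng = np.random.default_rng([design.seed, 1])
    rows = []
    for diet in design.treatments:
        t = diet.treatment_label
        for ind in design.individual_ids(t):
            for aa in design.aa_list:
                d_diet, d_micro = endmembers.require(t, aa)
                try:
                    p = truth.p_microbial[(t, aa)]
                except KeyError:
                    raise KeyError(
                        f"ground truth missing p_microbial for treatment {t!r}, AA {aa!r}"
                    ) from None
                mix = (1.0 - p) * d_diet + p * d_micro
                eps = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
                delta = mix + eps
                assert abs(delta - mix) <= 10.0 * max(truth.noise_sd, 1e-12) + 1e-12
                rows.append(
                    {"individual_id": ind, "treatment": t, "aa": aa, "delta_muscle": delta}
                )
    return IsotopeDataset(records=pd.DataFrame(rows))


def _taxon_structure(profile: CommunityProfile) -> tuple[list[str], dict[str, tuple[str, str]], dict[str, np.ndarray]]:
    """Fixed within-phylum rank-abundance structure shared by all samples.

    Each phylum's expected mass is split over its OTUs by a geometric
    rank-abundance series (ratio 0.8), a standard idealization of microbial
    abundance distributions; deterministic, no RNG involved.
    """
    taxa: list[str] = []
    taxonomy: dict[str, tuple[str, str]] = {}
    weights: dict[str, np.ndarray] = {}
    for phylum, k in profile.n_otus_per_phylum.items():
        w = 0.8 ** np.arange(k)
        weights[phylum] = w / w.sum()
        fams = _FAMILIES.get(phylum, ("unclassified",))
        for i in range(k):
            tid = f"OTU_{phylum[:4]}_{i + 1:03d}"
            taxa.append(tid)
            taxonomy[tid] = (phylum, fams[i % len(fams)])
    return taxa, taxonomy, weights


def generate_otu_table(
    design: ExperimentDesign,
    profile: CommunityProfile,
    n_individuals: int | None = None,
) -> OtuTable:
    """Simulate a samples × OTU count table with diet-dependent structure.

    Per sample, taxon proportions are drawn from
    Dirichlet(concentration × expected abundances) and counts from a
    multinomial at ``sequencing_depth``, so every row sums to the depth.
    ``n_individuals`` defaults to the design's replication (use 5 for the
    ceca subset of a 6-mouse isotope design); sample ids match the first
    isotope individuals of each treatment.
    """
    n_ind = n_individuals if n_individuals is not None else design.n_individuals_per_treatment
    if n_ind < 1:
        raise ValueError("n_individuals must be >= 1")
    if n_ind > design.n_individuals_per_treatment:
        raise ValueError("ceca sample count exceeds design replication")
    rng = np.random.default_rng([design.seed, 2])
    taxa, taxonomy, weights = _taxon_structure(profile)
    counts: dict[str, np.ndarray] = {}
    group: dict[str, str] = {}
    for diet in design.treatments:
        t = diet.treatment_label
        try:
            mix = profile.phylum_mixture[t]
        except KeyError:
            raise KeyError(f"community profile missing phylum mixture for treatment {t!r}") from None
        expected = np.concatenate(
            [mix.get(ph, 0.0) * weights[ph] for ph in profile.n_otus_per_phylum]
        )
        expected = np.maximum(expected, 1e-9)
        expected /= expected.sum()
        alpha = profile.dirichlet_concentration * expected
        for ind in design.individual_ids(t)[:n_ind]:
            props = rng.dirichlet(alpha)
            counts[ind] = rng.multinomial(profile.sequencing_depth, props)
            group[ind] = t
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=taxa)
    return OtuTable(counts=frame, taxonomy=taxonomy, group=group)


def generate_full_experiment(
    design: ExperimentDesign | None = None,
    truth: GroundTruth | None = None,
    profile: CommunityProfile | None = None,
    endmembers: EndmemberSet | None = None,
    n_ceca_per_treatment: int = 5,
) -> tuple[IsotopeDataset, OtuTable, GroundTruth]:
    """One paired synthetic experiment: isotopes, ceca communities, truth.

    Defaults reproduce the emulated study layout: 4 diets × 6 mice for
    isotopes and 4 × 5 for ceca, with cecal sample ids drawn from the same
    individuals as the isotope dataset. Treatment labels must agree across
    all sub-configurations.
    """
    design = design or ExperimentDesign()
    truth = truth or DEFAULT_GROUND_TRUTH
    profile = profile or DEFAULT_COMMUNITY_PROFILE
    if endmembers is None:
        from .endmembers import (
            DEFAULT_CASEIN_PROFILE,
            DEFAULT_CORNMEAL_PROFILE,
            DEFAULT_FRACTIONATION,
            build_endmember_set,
        )
        endmembers = build_endmember_set(
            design.treatments, DEFAULT_CASEIN_PROFILE, DEFAULT_CORNMEAL_PROFILE,
            DEFAULT_FRACTIONATION, design.aa_list,
        )
    design_labels = {d.treatment_label for d in design.treatments}
    profile_labels = set(profile.phylum_mixture)
    if not design_labels <= profile_labels:
        raise ValueError(
            f"treatment labels inconsistent across sub-configs: design has "
            f"{sorted(design_labels - profile_labels)} missing from community profile"
        )
    isotopes = generate_isotope_dataset(design, truth, endmembers)
    n_ceca = min(n_ceca_per_treatment, design.n_individuals_per_treatment)
    otu = generate_otu_table(design, profile, n_individuals=n_ceca)
    return isotopes, otu, truth
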