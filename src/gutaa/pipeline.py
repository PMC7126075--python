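"""Config-driven orchestration of the full analysis.

Stages: simulate (optional) → end members → mixing → supply/demand →
community statistics. Each stage reads delimited-text inputs (or the
synthetic generator's output), writes tidy TSVs stamped with a hash of the
config, and appends to a run log. A stage whose inputs are absent is
skipped with a logged notice rather than failing the run, so partial
configurations (e.g. isotopes without an OTU table) still produce their
stages' outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import io as gio
from .aminoacids import DEFAULT_AA_SPECS, ESSENTIAL_AA
from .community import (
    OtuTable, anosim, bray_curtis, dbrda, firmicutes_bacteroidetes_ratio, pcoa,
    rank_correlation, relative_abundance, select_axes, shannon_diversity,
)
from .endmembers import (
    DEFAULT_CASEIN_PROFILE, DEFAULT_CORNMEAL_PROFILE, DEFAULT_DIETS,
    DEFAULT_FRACTIONATION, build_endmember_set,
)
from .mixing import IsotopeDataset, contribution_table, estimate_all
from .supply_demand import (
    DEFAULT_DEMAND, DemandTable, SupplyParams, supply_demand_table,
)
from .synthetic import ExperimentDesign, generate_full_experiment

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("gutaa.pipeline")


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_dict``)."""

    seed: int = 0
    out_dir: str = "results"
    permutations: int = 1000
    clip_order: str = "clip_then_average"
    dbrda_direction: str = "aa_response"
    axis_variance_target: float = 0.8
    separation_floor: float = 1.0
    simulate: bool = False
    n_individuals: int = 6
    n_ceca: int = 5
    daily_ration: float = 3.0
    experiment_days: int = 120
    paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = cls(**{k: v for k, v in cfg.items() if k in known})
        if not isinstance(out.seed, int):
            raise ValueError("seed must be an integer")
        return out

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def path(self, key: str) -> Path | None:
        p = self.paths.get(key)
        return Path(p) if p else None


def _load_common(cfg: RunConfig):
    diets = gio.read_diet_table(cfg.path("diet_table")) if cfg.path("diet_table") else list(DEFAULT_DIETS)
    if cfg.path("aa_profiles"):
        profiles = gio.read_aa_profiles(cfg.path("aa_profiles"))
        casein, cornmeal = profiles["casein"], profiles["cornmeal"]
    else:
        casein, cornmeal = DEFAULT_CASEIN_PROFILE, DEFAULT_CORNMEAL_PROFILE
    frac = gio.read_fractionation(cfg.path("fractionation")) if cfg.path("fractionation") else DEFAULT_FRACTIONATION
    return diets, casein, cornmeal, frac


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Report-only validation: returns a list of human-readable violations."""
    report: list[str] = []
    for key, p in cfg.paths.items():
        if p and not Path(p).exists():
            report.append(f"path for {key!r} does not exist: {p}")
    if report:
        return report
    try:
        diets, casein, cornmeal, frac = _load_common(cfg)
    except (ValueError, KeyError) as exc:
        return [f"input tables failed to load: {exc}"]
    for diet in diets:
        total = (diet.mass_fraction_casein + diet.mass_fraction_sucrose
                 + diet.mass_fraction_cornmeal + diet.mass_fraction_other)
        if abs(total - 1.0) > 1e-6:  # unreachable via DietComposition, kept for raw tables
            report.append(f"diet {diet.treatment_label}: mass fractions sum to {total:.4f}")
    for prof in (casein, cornmeal):
        missing = [aa for aa in ESSENTIAL_AA if aa not in prof.concentration]
        if missing:
            report.append(f"profile {prof.source!r} missing AAs: {missing}")
    missing_frac = [aa for aa in ESSENTIAL_AA if aa not in frac.offset]
    if missing_frac:
        report.append(f"fractionation table missing AAs: {missing_frac}")
    iso_path = cfg.path("isotope_dataset")
    if iso_path:
        try:
            dataset = gio.read_isotope_dataset(iso_path)
        except ValueError as exc:
            report.append(f"isotope dataset invalid: {exc}")
        else:
            bad = [aa for aa in dataset.aa_codes if aa not in DEFAULT_AA_SPECS]
            for aa in bad:
                report.append(f"isotope dataset contains unknown AA code {aa!r}")
    if cfg.path("otu_counts") and cfg.path("otu_taxonomy"):
        try:
            gio.read_otu_table(cfg.path("otu_counts"), cfg.path("otu_taxonomy"))
        except ValueError as exc:
            report.append(f"OTU table invalid: {exc}")
    return report


def _community_stats(cfg: RunConfig, otu: OtuTable, dataset: IsotopeDataset | None,
                     out: Path, cfg_hash: str) -> dict[str, Any]:
    rng = np.random.default_rng([cfg.seed, 10])
    phylum = relative_abundance(otu, "phylum")
    gio.write_table(phylum.rename_axis("sample_id"), out / "phylum_abundance.tsv", cfg_hash, index=True)
    family = relative_abundance(otu, "family")
    gio.write_table(family.rename_axis("sample_id"), out / "family_abundance.tsv", cfg_hash, index=True)

    diversity = pd.DataFrame(
        {"sample_id": otu.sample_ids,
         "treatment": [otu.group[s] for s in otu.sample_ids],
         "shannon": [shannon_diversity(otu.counts.loc[s]) for s in otu.sample_ids]}
    )
    gio.write_table(diversity, out / "diversity.tsv", cfg_hash)

    d = bray_curtis(otu.counts)
    gio.write_distance_matrix(d, out / "braycurtis.tsv", cfg_hash)
    r_stat, p_anosim = anosim(d, otu.group, n_perm=cfg.permutations, seed=rng)

    ord_res = pcoa(d)
    coords = pd.DataFrame(
        ord_res.coordinates, index=ord_res.ids,
        columns=[f"PCo{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    ).rename_axis("sample_id")
    gio.write_table(coords, out / "pcoa_coordinates.tsv", cfg_hash, index=True)

    # F:B ratio vs dietary protein (rank of treatment by protein content)
    fb = firmicutes_bacteroidetes_ratio(phylum)
    treatments = [otu.group[s] for s in phylum.index]
    protein_rank = {t: i for i, t in enumerate(dict.fromkeys(treatments))}
    diet_codes = np.array([protein_rank[t] for t in treatments], float)
    fb_vals = fb.to_numpy(float)
    ok = np.isfinite(fb_vals)
    rho, p_rho = rank_correlation(diet_codes[ok], fb_vals[ok], n_perm=cfg.permutations, seed=rng)

    stats = {"anosim_R": r_stat, "anosim_p": p_anosim,
             "spearman_rho_fb_vs_diet": rho, "spearman_p": p_rho}

    rows = [{"statistic": k, "value": v} for k, v in stats.items()]
    if dataset is not None:
        axes = select_axes(ord_res, cfg.axis_variance_target)
        y = (dataset.records.pivot(index="individual_id", columns="aa", values="delta_muscle")
             .reindex(ord_res.ids))
        if y.notna().all().all():
            if cfg.dbrda_direction == "aa_response":
                resp, pred = y.to_numpy(float), axes
            else:
                resp, pred = axes, y.to_numpy(float)
            rda = dbrda(resp, pred, n_perm=cfg.permutations, seed=rng)
            stats["dbrda_r2"] = rda.r2
            stats["dbrda_r2_adjusted"] = rda.r2_adjusted
            rows += [
                {"statistic": "dbrda_r2", "value": rda.r2},
                {"statistic": "dbrda_r2_adjusted", "value": rda.r2_adjusted},
                {"statistic": "dbrda_F", "value": rda.f_stat},
                {"statistic": "dbrda_p", "value": rda.p_perm},
                {"statistic": "dbrda_aic", "value": rda.aic},
                {"statistic": "dbrda_n_axes", "value": rda.n_axes_used},
            ]
        else:
            log.info("db-RDA skipped: isotope data do not cover all ceca samples")
    gio.write_table(pd.DataFrame(rows), out / "community_stats.tsv", cfg_hash)
    return stats


def run_pipeline(cfg: RunConfig | Mapping[str, Any], stages: list[str] | None = None) -> dict[str, Any]:
    """Run the configured stages; returns a summary dict of key results.

    Stage order: simulate, endmembers, mix, supply, community. ``stages``
    restricts the run; by default every stage whose inputs are available
    executes. Deterministic given ``cfg.seed``.
    """
    if not isinstance(cfg, RunConfig):
        cfg = RunConfig.from_dict(cfg)
    want = set(stages) if stages else {"simulate", "endmembers", "mix", "supply", "community"}
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hashed = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    cfg_hash = gio.config_hash(hashed)
    summary: dict[str, Any] = {"config_hash": cfg_hash}

    diets, casein, cornmeal, frac = _load_common(cfg)
    log.info("loaded %d diets; config hash %s", len(diets), cfg_hash)

    endmembers = build_endmember_set(diets, casein, cornmeal, frac, ESSENTIAL_AA)
    if "endmembers" in want:
        gio.write_endmembers(endmembers, out / "endmembers.tsv", cfg_hash)
        log.info("end members written for %d (treatment, AA) cells", len(endmembers.delta_dietary))

    dataset: IsotopeDataset | None = None
    otu: OtuTable | None = None
    if cfg.path("isotope_dataset"):
        dataset = gio.read_isotope_dataset(cfg.path("isotope_dataset"))
    if cfg.path("otu_counts") and cfg.path("otu_taxonomy"):
        otu = gio.read_otu_table(cfg.path("otu_counts"), cfg.path("otu_taxonomy"))
    if cfg.simulate and "simulate" in want and (dataset is None or otu is None):
        design = ExperimentDesign(
            treatments=tuple(diets), n_individuals_per_treatment=cfg.n_individuals,
            seed=cfg.seed,
        )
        sim_iso, sim_otu, truth = generate_full_experiment(
            design, endmembers=endmembers, n_ceca_per_treatment=cfg.n_ceca,
        )
        dataset = dataset or sim_iso
        otu = otu or sim_otu
        gio.write_isotope_dataset(dataset, out / "synthetic_isotopes.tsv", cfg_hash)
        gio.write_otu_table(otu, out / "synthetic_otu_counts.tsv",
                            out / "synthetic_otu_taxonomy.tsv", cfg_hash)
        truth_rows = pd.DataFrame(
            [{"treatment": t, "aa": aa, "p_true": p}
             for (t, aa), p in sorted(truth.p_microbial.items())]
        )
        gio.write_table(truth_rows, out / "synthetic_ground_truth.tsv", cfg_hash)
        log.info("simulated %d isotope records and %d ceca samples",
                 len(dataset.records), len(otu.sample_ids))

    if "mix" in want:
        if dataset is not None:
            estimates = estimate_all(dataset, endmembers, clip_order=cfg.clip_order,
                                     separation_floor=cfg.separation_floor)
            contrib = contribution_table(estimates)
            gio.write_table(contrib, out / "contributions.tsv", cfg_hash)
            summary["contributions"] = contrib
            log.info("mixing: %d (treatment, AA) estimates", len(contrib))
        else:
            log.info("mixing stage skipped: no isotope dataset available")

    if "supply" in want:
        digest = (gio.read_param_table(cfg.path("digestibility"))
                  if cfg.path("digestibility") else None)
        catab = (gio.read_param_table(cfg.path("catabolism"))
                 if cfg.path("catabolism") else None)
        demand_map = (gio.read_param_table(cfg.path("demand"))
                      if cfg.path("demand") else dict(DEFAULT_DEMAND))
        params_kwargs = dict(daily_ration=cfg.daily_ration, experiment_days=cfg.experiment_days)
        if digest is not None:
            params_kwargs["digestibility"] = digest
        if catab is not None:
            params_kwargs["mucosal_catabolism"] = catab
        params = SupplyParams(**params_kwargs)
        aa_all = list(ESSENTIAL_AA) + ["Asp"]
        sd_table = supply_demand_table(diets, casein, cornmeal, params,
                                       DemandTable(demand=demand_map), aa_all)
        gio.write_table(sd_table, out / "supply_demand.tsv", cfg_hash)
        summary["supply_demand"] = sd_table
        log.info("supply/demand: %d rows", len(sd_table))

    if "community" in want:
        if otu is not None:
            summary["community"] = _community_stats(cfg, otu, dataset, out, cfg_hash)
            log.info("community statistics written")
        else:
            log.info("community stage skipped: no OTU table available")

    return summary
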