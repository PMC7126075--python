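"""Delimited-text I/O for every table the pipeline reads or writes.

All on-disk formats are tab-separated with a header row; lines starting
with ``#`` are comments (output tables carry the run's config hash in one).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .community import DistanceMatrix, OtuTable
from .endmembers import AAProfile, DietComposition, EndmemberSet, FractionationTable
from .mixing import IsotopeDataset

__all__ = [
    "read_diet_table", "write_diet_table",
    "read_aa_profiles", "write_aa_profiles",
    "read_fractionation", "write_fractionation",
    "read_param_table", "write_param_table",
    "read_isotope_dataset", "write_isotope_dataset",
    "read_otu_table", "write_otu_table",
    "read_endmembers", "write_endmembers",
    "write_distance_matrix",
    "write_table", "load_config", "config_hash",
]

_SEP = "\t"


def _read(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_SEP, comment="#")


def write_table(frame: pd.DataFrame, path: str | Path, cfg_hash: str | None = None,
                index: bool = False) -> None:
    """Write a tidy TSV, optionally stamped with the run's config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if cfg_hash:
            fh.write(f"# config_sha256={cfg_hash}\n")
        frame.to_csv(fh, sep=_SEP, index=index)


def read_diet_table(path: str | Path) -> list[DietComposition]:
    frame = _read(path)
    diets = []
    for _, row in frame.iterrows():
        kwargs = dict(
            treatment_label=str(row["treatment"]),
            mass_fraction_casein=float(row["casein"]),
            mass_fraction_sucrose=float(row["sucrose"]),
            mass_fraction_cornmeal=float(row["cornmeal"]),
            mass_fraction_other=float(row["other"]),
        )
        for col, attr in [
            ("cornmeal_protein_fraction", "cornmeal_protein_fraction"),
            ("delta_casein", "delta_casein"),
            ("delta_sucrose", "delta_sucrose"),
            ("delta_cornmeal", "delta_cornmeal"),
        ]:
            if col in frame.columns:
                kwargs[attr] = float(row[col])
        diets.append(DietComposition(**kwargs))
    return diets


def write_diet_table(diets: list[DietComposition], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "treatment": d.treatment_label,
                "casein": d.mass_fraction_casein,
                "sucrose": d.mass_fraction_sucrose,
                "cornmeal": d.mass_fraction_cornmeal,
                "other": d.mass_fraction_other,
                "cornmeal_protein_fraction": d.cornmeal_protein_fraction,
                "delta_casein": d.delta_casein,
                "delta_sucrose": d.delta_sucrose,
                "delta_cornmeal": d.delta_cornmeal,
            }
            for d in diets
        ]
    )
    write_table(frame, path)


def read_aa_profiles(path: str | Path) -> dict[str, AAProfile]:
    """Read long-format profiles: columns source, aa, concentration[, unit]."""
    frame = _read(path)
    profiles = {}
    for source, sub in frame.groupby("source"):
        unit = str(sub["unit"].iloc[0]) if "unit" in sub.columns else "protein"
        conc = dict(zip(sub["aa"], sub["concentration"].astype(float)))
        profiles[str(source)] = AAProfile(source=str(source), concentration=conc, unit=unit)
    return profiles


def write_aa_profiles(profiles: Mapping[str, AAProfile], path: str | Path) -> None:
    rows = [
        {"source": p.source, "aa": aa, "concentration": c, "unit": p.unit}
        for p in profiles.values()
        for aa, c in p.concentration.items()
    ]
    write_table(pd.DataFrame(rows), path)


def read_fractionation(path: str | Path) -> FractionationTable:
    frame = _read(path)
    return FractionationTable(offset=dict(zip(frame["aa"], frame["offset"].astype(float))))


def write_fractionation(table: FractionationTable, path: str | Path) -> None:
    rows = [{"aa": aa, "offset": v} for aa, v in table.offset.items()]
    write_table(pd.DataFrame(rows), path)


def read_param_table(path: str | Path, value_col: str = "value") -> dict[str, float]:
    """Read a two-column (aa, value) parameter table keyed by 3-letter code."""
    frame = _read(path)
    return dict(zip(frame["aa"], frame[value_col].astype(float)))


def write_param_table(values: Mapping[str, float], path: str | Path,
                      value_col: str = "value") -> None:
    rows = [{"aa": aa, value_col: v} for aa, v in values.items()]
    write_table(pd.DataFrame(rows), path)


def read_isotope_dataset(path: str | Path) -> IsotopeDataset:
    return IsotopeDataset(records=_read(path))


def write_isotope_dataset(dataset: IsotopeDataset, path: str | Path,
                          cfg_hash: str | None = None) -> None:
    write_table(dataset.records, path, cfg_hash)


def read_otu_table(counts_path: str | Path, taxonomy_path: str | Path,
                   taxa_as_rows: bool = False) -> OtuTable:
    """Read a count table plus taxonomy sidecar (taxon_id, phylum, family).

    The count table has sample rows with columns ``sample_id``,
    ``treatment``, then one column per taxon; ``taxa_as_rows=True`` reads
    the transposed orientation (taxon rows, one column per sample, with a
    separate ``treatment`` row dropped from counts).
    """
    frame = _read(counts_path)
    if taxa_as_rows:
        frame = frame.set_index(frame.columns[0])
        treat = frame.loc["treatment"]
        counts = frame.drop(index="treatment").T.astype(int)
        group = dict(treat)
    else:
        frame = frame.set_index("sample_id")
        group = dict(frame["treatment"])
        counts = frame.drop(columns=["treatment"]).astype(int)
    counts.index.name = None
    counts.columns.name = None
    tax = _read(taxonomy_path)
    taxonomy = {
        str(r["taxon_id"]): (str(r["phylum"]), str(r["family"])) for _, r in tax.iterrows()
    }
    return OtuTable(counts=counts, taxonomy=taxonomy, group=group)


def write_otu_table(table: OtuTable, counts_path: str | Path, taxonomy_path: str | Path,
                    cfg_hash: str | None = None) -> None:
    out = table.counts.copy()
    out.insert(0, "treatment", [table.group[s] for s in out.index])
    out.index.name = "sample_id"
    write_table(out, counts_path, cfg_hash, index=True)
    tax = pd.DataFrame(
        [{"taxon_id": t, "phylum": p, "family": f} for t, (p, f) in table.taxonomy.items()]
    )
    write_table(tax, taxonomy_path)


def read_endmembers(path: str | Path) -> EndmemberSet:
    frame = _read(path)
    dietary, microbial = {}, {}
    for _, row in frame.iterrows():
        key = (str(row["treatment"]), str(row["aa"]))
        if row["role"] == "dietary":
            dietary[key] = float(row["delta"])
        else:
            microbial[key] = float(row["delta"])
    return EndmemberSet(delta_dietary=dietary, delta_microbial=microbial)


def write_endmembers(endmembers: EndmemberSet, path: str | Path,
                     cfg_hash: str | None = None) -> None:
    write_table(endmembers.to_frame(), path, cfg_hash)


def write_distance_matrix(d: DistanceMatrix, path: str | Path,
                          cfg_hash: str | None = None) -> None:
    frame = pd.DataFrame(d.data, index=d.ids, columns=d.ids)
    frame.index.name = "sample_id"
    write_table(frame, path, cfg_hash, index=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a config mapping, stamped into output tables."""
    payload = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
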