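"""Readers and writers for the package's delimited-text formats.

Pedigree: TSV with columns id, sire, dam, family, group (empty or "0" marks an
unknown parent / founder).  Genotypes: CSV with columns id, locus, allele1,
allele2, allele3 (allele3 empty unless trisomic).  Phenotypes: CSV with
columns id, family, group, treatment, tank, weight_g, length_cm.  Simulation
parameters round-trip through a flat YAML config.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .design import SimulationParams
from .pedigree import Pedigree

PEDIGREE_COLUMNS = ["id", "sire", "dam", "family", "group"]
GENOTYPE_COLUMNS = ["id", "locus", "allele1", "allele2", "allele3"]
PHENOTYPE_COLUMNS = ["id", "family", "group", "treatment", "tank", "weight_g", "length_cm"]


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.frame[PEDIGREE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["sire"] = df["sire"].replace("0", "")
    df["dam"] = df["dam"].replace("0", "")
    return Pedigree(df)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes[GENOTYPE_COLUMNS].to_csv(path, index=False)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "locus": str})
    df["allele3"] = df["allele3"].astype("Int64")
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={"id": str, "family": str, "group": str, "treatment": str, "tank": str}
    )


def write_params(params: SimulationParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_params(path: str | Path) -> SimulationParams:
    with open(path) as fh:
        return SimulationParams.from_dict(yaml.safe_load(fh))


def write_summary(summary: dict, path: str | Path) -> None:
    """Structured run summary as JSON (pure aggregation, inputs untouched)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
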