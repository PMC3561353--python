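"""Synthetic breeding-design data: pedigrees, marker genotypes and phenotypes.

Generative model for phenotypes (all on the log10-gram scale):

    log10 W = mu[group, treatment] + tank + a_i + e,
    tank ~ N(0, V_tank)          one draw per physical tank,
    a_parent ~ N(0, V_A[group])  founder breeding values,
    a_offspring = (a_sire + a_dam)/2 + N(0, V_A[family group]/2),
    e ~ N(0, V_E[treatment]).

Raw weight is 10**log10W; fork length is back-computed from weight through
Fulton's condition factor K = 100 W / L^3 with K drawn per fish, so simulated
K and length magnitudes match hatchery-stage salmon.

Marker genotypes mimic a six-locus microsatellite panel: parents are drawn
from per-locus allele frequencies, offspring inherit one allele per parent per
locus, and two artefacts of real genotyping are overlaid — a small per-locus
genotyping-error rate and a ~3% per-individual trisomy rate (a duplicated
parental allele at one locus, so trisomic fish stay parent-compatible).

Each stage draws from its own deterministic substream of the master seed, so
pedigree, genotypes and phenotypes are independently reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import BreedingDesign, DesignError, SimulationParams
from .pedigree import Pedigree

_STAGES = {"pedigree": 1, "parent_genotypes": 2, "offspring_genotypes": 3, "phenotypes": 4}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


def simulate_pedigree(design: BreedingDesign, seed: int = 0) -> Pedigree:
    """Build the full two-generation pedigree implied by the breeding design.

    Farmed family i crosses farmed sire FS_i with farmed dam FD_i, wild family
    i crosses WS_i with WD_i, and hybrid family h reuses farmed dam FD_h and
    wild sire WS_h (maternal/paternal half sibs of the pure families).
    Offspring rows carry the tank each fish is reared in.
    """
    rows: list[dict] = []
    for i in range(design.n_farm_families):
        for pid in (f"FS{i + 1:02d}", f"FD{i + 1:02d}"):
            rows.append(dict(id=pid, sire="", dam="", family="", group="farm", tank=""))
    for i in range(design.n_wild_families):
        for pid in (f"WS{i + 1:02d}", f"WD{i + 1:02d}"):
            rows.append(dict(id=pid, sire="", dam="", family="", group="wild", tank=""))

    crosses = []
    for i in range(design.n_farm_families):
        crosses.append((f"F{i + 1:02d}", f"FS{i + 1:02d}", f"FD{i + 1:02d}", "farm"))
    for i in range(design.n_wild_families):
        crosses.append((f"W{i + 1:02d}", f"WS{i + 1:02d}", f"WD{i + 1:02d}", "wild"))
    for i in range(design.n_hybrid_families):
        # farmed dam x wild sire
        crosses.append((f"H{i + 1:02d}", f"WS{i + 1:02d}", f"FD{i + 1:02d}", "hybrid"))

    counter = 0
    for tank_id, _treatment in design.tanks:
        for family_id, sire, dam, group in crosses:
            for _ in range(design.offspring_per_family_per_tank):
                counter += 1
                rows.append(
                    dict(id=f"O{counter:05d}", sire=sire, dam=dam,
                         family=family_id, group=group, tank=tank_id)
                )
    return Pedigree(pd.DataFrame(rows))


def _genotype_frame(records: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=["id", "locus", "allele1", "allele2", "allele3"])
    df["allele3"] = df["allele3"].astype("Int64")
    return df


def simulate_parent_genotypes(
    pedigree: Pedigree, params: SimulationParams, seed: int = 0
) -> pd.DataFrame:
    """Diploid founder genotypes drawn from the per-locus allele frequencies."""
    rng = _rng(seed, "parent_genotypes")
    founders = pedigree.founders["id"].tolist()
    records = []
    for locus_idx, freqs in enumerate(params.allele_freqs):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.size == 0:
            raise DesignError(f"locus {locus_idx}: empty allele frequency vector")
        draws = rng.choice(freqs.size, size=(len(founders), 2), p=freqs)
        locus = f"L{locus_idx + 1}"
        for pid, (a1, a2) in zip(founders, draws):
            records.append((pid, locus, int(a1), int(a2), pd.NA))
    return _genotype_frame(records)


def simulate_offspring_genotypes(
    pedigree: Pedigree,
    parent_genotypes: pd.DataFrame,
    params: SimulationParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Mendelian offspring genotypes with genotyping error and trisomy overlays.

    Per locus each offspring receives one uniformly chosen allele from each
    parent.  With probability ``trisomy_rate`` an individual duplicates one
    inherited allele at one random locus (three recorded alleles).  With
    probability ``genotyping_error_rate`` per locus, one recorded allele is
    replaced by a random draw from the population allele frequencies.
    """
    rng = _rng(seed, "offspring_genotypes")
    loci = [f"L{i + 1}" for i in range(params.n_loci)]
    parent_alleles: dict[tuple[str, str], list[int]] = {}
    for r in parent_genotypes.itertuples(index=False):
        parent_alleles[(r.id, r.locus)] = [int(r.allele1), int(r.allele2)]

    offspring = pedigree.offspring
    records = []
    for r in offspring.itertuples(index=False):
        genotype: dict[str, list[int]] = {}
        for locus in loci:
            try:
                sire_all = parent_alleles[(r.sire, locus)]
                dam_all = parent_alleles[(r.dam, locus)]
            except KeyError as exc:
                raise DesignError(
                    f"offspring {r.id}: parent genotype missing for {exc.args[0]}"
                ) from None
            genotype[locus] = [
                sire_all[rng.integers(2)],
                dam_all[rng.integers(2)],
            ]
        if rng.random() < params.trisomy_rate:
            locus = loci[rng.integers(len(loci))]
            genotype[locus].append(genotype[locus][rng.integers(2)])
        for locus in loci:
            alleles = genotype[locus]
            if rng.random() < params.genotyping_error_rate:
                freqs = np.asarray(params.allele_freqs[loci.index(locus)], dtype=float)
                alleles[rng.integers(len(alleles))] = int(
                    rng.choice(freqs.size, p=freqs)
                )
            a3 = alleles[2] if len(alleles) == 3 else pd.NA
            records.append((r.id, locus, alleles[0], alleles[1], a3))
    return _genotype_frame(records)


def simulate_breeding_values(
    pedigree: Pedigree, params: SimulationParams, rng: np.random.Generator
) -> pd.Series:
    """Breeding values for every pedigree member on the log10-weight scale."""
    frame = pedigree.frame
    a = pd.Series(0.0, index=frame["id"])
    for r in frame.itertuples(index=False):
        if r.sire == "" and r.dam == "":
            a[r.id] = rng.normal(0.0, np.sqrt(params.v_a[r.group]))
        else:
            mendelian_sd = np.sqrt(params.v_a[r.group] / 2.0)
            a[r.id] = 0.5 * (a[r.sire] + a[r.dam]) + rng.normal(0.0, mendelian_sd)
    return a


def simulate_phenotypes(
    pedigree: Pedigree,
    design: BreedingDesign,
    params: SimulationParams,
    seed: int = 0,
) -> pd.DataFrame:
    """Terminal weight, length and condition factor for every offspring.

    Returns one row per fish: id, family, group, treatment, tank, weight_g,
    length_cm, condition_factor.
    """
    rng = _rng(seed, "phenotypes")
    treatment_of = dict(design.tanks)
    tank_effects = {
        tank: rng.normal(0.0, np.sqrt(params.v_tank)) for tank, _ in design.tanks
    }
    breeding = simulate_breeding_values(pedigree, params, rng)

    offspring = pedigree.offspring
    if (offspring["tank"] == "").any():
        raise DesignError("offspring rows must carry a tank assignment")
    treatments = offspring["tank"].map(treatment_of)
    mu = np.array(
        [params.mu_logw[(g, t)] for g, t in zip(offspring["group"], treatments)]
    )
    resid_sd = np.sqrt(np.array([params.v_e[t] for t in treatments]))
    log_w = (
        mu
        + offspring["tank"].map(tank_effects).to_numpy()
        + breeding[offspring["id"]].to_numpy()
        + rng.normal(0.0, 1.0, len(offspring)) * resid_sd
    )
    weight = 10.0**log_w
    k = rng.normal(params.mean_condition_factor, params.sd_condition_factor, len(offspring))
    k = np.clip(k, 0.5, None)  # condition factors below 0.5 are not biologically plausible
    length = np.cbrt(100.0 * weight / k)
    return pd.DataFrame(
        {
            "id": offspring["id"].to_numpy(),
            "family": offspring["family"].to_numpy(),
            "group": offspring["group"].to_numpy(),
            "treatment": treatments.to_numpy(),
            "tank": offspring["tank"].to_numpy(),
            "weight_g": weight,
            "length_cm": length,
            "condition_factor": k,
        }
    )


def family_parent_table(pedigree: Pedigree) -> pd.DataFrame:
    """One row per family: family_id, sire_id, dam_id (for parentage testing)."""
    off = pedigree.offspring
    fam = off[["family", "sire", "dam"]].drop_duplicates()
    if fam["family"].duplicated().any():
        raise DesignError("a family maps to more than one parental pair")
    return fam.rename(
        columns={"family": "family_id", "sire": "sire_id", "dam": "dam_id"}
    ).reset_index(drop=True)


def simulate_dataset(
    design: BreedingDesign | None = None,
    params: SimulationParams | None = None,
    seed: int = 0,
) -> dict:
    """Run every simulation stage and return all tables keyed by name."""
    design = design or BreedingDesign()
    params = params or SimulationParams()
    pedigree = simulate_pedigree(design, seed)
    parents = simulate_parent_genotypes(pedigree, params, seed)
    offspring_gts = simulate_offspring_genotypes(pedigree, parents, params, seed)
    phenotypes = simulate_phenotypes(pedigree, design, params, seed)
    return {
        "design": design,
        "params": params,
        "pedigree": pedigree,
        "parent_genotypes": parents,
        "offspring_genotypes": offspring_gts,
        "phenotypes": phenotypes,
        "families": family_parent_table(pedigree),
    }
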