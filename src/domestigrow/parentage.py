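"""Exclusion-based parentage assignment for multilocus genotypes.

An offspring is compatible with a candidate parental pair when, at every locus,
its recorded alleles can be explained by Mendelian transmission: one allele
from the sire and one from the dam.  A single incompatible locus excludes the
pair (strict exclusion, as in classic family-assignment programs); a
``max_mismatch_loci`` tolerance can relax this for known genotyping-error
rates.  Ties are never broken: offspring compatible with two or more candidate
families are reported as ambiguous, and offspring compatible with none as
unassigned.

Trisomic loci (three recorded alleles, from a chromosomal duplication) are
treated as compatible when the three alleles can be partitioned as one allele
from one parent plus two alleles (repetition allowed) from the other parent's
genotype — a rule chosen so that true offspring carrying a duplicated parental
allele are never excluded from their own family.  A locus with no recorded
alleles is treated as missing data and matches any parental pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class GenotypeFormatError(ValueError):
    pass


@dataclass(frozen=True)
class MultilocusGenotype:
    """Per-individual allele multisets at each locus (2, or 3 when trisomic)."""

    individual_id: str
    loci: tuple[str, ...]
    alleles: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.loci) != len(self.alleles):
            raise GenotypeFormatError("one allele tuple required per locus")
        for locus, obs in zip(self.loci, self.alleles):
            if len(obs) > 3:
                raise GenotypeFormatError(
                    f"{self.individual_id}@{locus}: more than 3 alleles recorded"
                )

    def locus_alleles(self, locus: str) -> tuple[int, ...]:
        return self.alleles[self.loci.index(locus)]


@dataclass(frozen=True)
class FamilyGenotypes:
    family_id: str
    sire: MultilocusGenotype
    dam: MultilocusGenotype


@dataclass
class AssignmentSummary:
    n_offspring: int = 0
    n_assigned: int = 0
    n_ambiguous: int = 0
    n_unassigned: int = 0
    n_trisomic: int = 0
    reduced_evidence_ids: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_offspring": self.n_offspring,
            "n_assigned": self.n_assigned,
            "n_ambiguous": self.n_ambiguous,
            "n_unassigned": self.n_unassigned,
            "n_trisomic": self.n_trisomic,
            "n_reduced_evidence": len(self.reduced_evidence_ids),
        }


def genotypes_from_frame(frame: pd.DataFrame) -> list[MultilocusGenotype]:
    """Build genotype objects from a long table (id, locus, allele1..allele3)."""
    out = []
    for ind, sub in frame.groupby("id", sort=False):
        loci, alleles = [], []
        for r in sub.itertuples(index=False):
            obs = [r.allele1, r.allele2, getattr(r, "allele3", pd.NA)]
            obs = tuple(int(a) for a in obs if pd.notna(a))
            loci.append(r.locus)
            alleles.append(obs)
        out.append(MultilocusGenotype(str(ind), tuple(loci), tuple(alleles)))
    return out


def locus_compatible(
    offspring_alleles: tuple[int, ...],
    sire_alleles: tuple[int, ...],
    dam_alleles: tuple[int, ...],
) -> bool:
    """Can the offspring's recorded alleles at one locus come from this pair?

    Diploid loci require one allele transmissible by the sire and the other by
    the dam.  Three-allele (trisomic) loci require a partition into one allele
    from one parent and two alleles (with repetition) from the other.  Missing
    data (no recorded alleles) is a wildcard.
    """
    off = tuple(offspring_alleles)
    if len(off) > 3:
        raise GenotypeFormatError("more than 3 alleles recorded at a locus")
    if len(off) == 0:
        return True
    if not sire_alleles or not dam_alleles:
        raise GenotypeFormatError("parental allele sets must be non-empty")
    sire = set(sire_alleles)
    dam = set(dam_alleles)
    if len(off) == 1:
        return off[0] in sire or off[0] in dam
    if len(off) == 2:
        a, b = off
        return (a in sire and b in dam) or (b in sire and a in dam)
    # trisomic: choose which index is the singleton, and which parent gave it
    for single in range(3):
        x = off[single]
        pair = [off[j] for j in range(3) if j != single]
        for p, q in ((sire, dam), (dam, sire)):
            if x in p and pair[0] in q and pair[1] in q:
                return True
    return False


def pair_compatible(
    offspring: MultilocusGenotype,
    sire: MultilocusGenotype,
    dam: MultilocusGenotype,
    max_mismatch_loci: int = 0,
) -> bool:
    mismatches = 0
    for locus, obs in zip(offspring.loci, offspring.alleles):
        if not locus_compatible(obs, sire.locus_alleles(locus), dam.locus_alleles(locus)):
            mismatches += 1
            if mismatches > max_mismatch_loci:
                return False
    return True


def detect_trisomy(genotype: MultilocusGenotype) -> list[str]:
    """Loci at which three alleles were recorded."""
    return [locus for locus, obs in zip(genotype.loci, genotype.alleles) if len(obs) == 3]


def assign_offspring(
    offspring: list[MultilocusGenotype],
    families: list[FamilyGenotypes],
    max_mismatch_loci: int = 0,
) -> tuple[pd.DataFrame, AssignmentSummary]:
    """Test every offspring against every candidate family by exclusion.

    Returns the per-offspring assignment table (id, status, family,
    n_compatible, compatible_families, trisomic_loci) and summary counts.
    Offspring with missing loci are flagged as reduced-evidence assignments.
    """
    ids = [f.family_id for f in families]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate family ids among candidates")

    # Fast path for diploid loci: precompute each family's transmissible
    # unordered allele pairs per locus.
    fast: list[dict[str, frozenset]] = []
    for fam in families:
        per_locus = {}
        for locus in fam.sire.loci:
            s = fam.sire.locus_alleles(locus)
            d = fam.dam.locus_alleles(locus)
            per_locus[locus] = frozenset(
                (a, b) if a <= b else (b, a) for a in s for b in d
            )
        fast.append(per_locus)

    summary = AssignmentSummary()
    rows = []
    for off in offspring:
        compatible = []
        for fam, pairs in zip(families, fast):
            if max_mismatch_loci == 0 and not detect_trisomy(off):
                ok = True
                for locus, obs in zip(off.loci, off.alleles):
                    if len(obs) == 2:
                        key = (obs[0], obs[1]) if obs[0] <= obs[1] else (obs[1], obs[0])
                        if key not in pairs[locus]:
                            ok = False
                            break
                    elif not locus_compatible(
                        obs, fam.sire.locus_alleles(locus), fam.dam.locus_alleles(locus)
                    ):
                        ok = False
                        break
            else:
                ok = pair_compatible(off, fam.sire, fam.dam, max_mismatch_loci)
            if ok:
                compatible.append(fam.family_id)
        trisomic = detect_trisomy(off)
        status = (
            "assigned" if len(compatible) == 1
            else "ambiguous" if len(compatible) >= 2
            else "unassigned"
        )
        summary.n_offspring += 1
        summary.n_trisomic += bool(trisomic)
        setattr(summary, f"n_{status}", getattr(summary, f"n_{status}") + 1)
        if any(len(obs) == 0 for obs in off.alleles):
            summary.reduced_evidence_ids.append(off.individual_id)
        rows.append(
            {
                "id": off.individual_id,
                "status": status,
                "family": compatible[0] if status == "assigned" else pd.NA,
                "n_compatible": len(compatible),
                "compatible_families": ";".join(compatible),
                "trisomic_loci": ";".join(trisomic),
            }
        )
    return pd.DataFrame(rows), summary


def assign_from_frames(
    offspring_genotypes: pd.DataFrame,
    family_table: pd.DataFrame,
    parent_genotypes: pd.DataFrame,
    max_mismatch_loci: int = 0,
) -> tuple[pd.DataFrame, AssignmentSummary]:
    """Frame-level wrapper: genotype tables + (family_id, sire_id, dam_id)."""
    parents = {g.individual_id: g for g in genotypes_from_frame(parent_genotypes)}
    families = []
    for r in family_table.itertuples(index=False):
        try:
            families.append(
                FamilyGenotypes(str(r.family_id), parents[r.sire_id], parents[r.dam_id])
            )
        except KeyError as exc:
            raise ValueError(f"family {r.family_id}: parent {exc.args[0]} not genotyped")
    return assign_offspring(
        genotypes_from_frame(offspring_genotypes), families, max_mismatch_loci
    )
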