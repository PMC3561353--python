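"""Simulator: pedigree structure, genotype draws, phenotype generative model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import domestigrow as dg
from domestigrow.design import REFERENCE_MEAN_WEIGHT_G, REFERENCE_N, REFERENCE_SD_WEIGHT_G
from domestigrow.parentage import genotypes_from_frame, pair_compatible


class TestPedigree:
    def test_study_design_counts_and_halfsib_reuse(self):
        ped = dg.simulate_pedigree(dg.BreedingDesign(), seed=0)
        off = ped.offspring
        assert off["family"].nunique() == 29
        assert len(ped.founders) == 40
        # hybrid families reuse the farmed dam and the wild sire of pure families
        fam = dg.family_parent_table(ped).set_index("family_id")
        for h in range(1, 10):
            assert fam.loc[f"H{h:02d}", "dam_id"] == fam.loc[f"F{h:02d}", "dam_id"]
            assert fam.loc[f"H{h:02d}", "sire_id"] == fam.loc[f"W{h:02d}", "sire_id"]

    def test_minimal_design(self):
        d = dg.BreedingDesign(1, 1, 1, offspring_per_family_per_tank=2,
                              tanks=(("T1", "control"), ("T2", "stress")))
        ped = dg.simulate_pedigree(d, seed=0)
        assert len(ped.founders) == 4
        fam = dg.family_parent_table(ped).set_index("family_id")
        assert fam.loc["H01", "dam_id"] == fam.loc["F01", "dam_id"]
        assert fam.loc["H01", "sire_id"] == fam.loc["W01", "sire_id"]

    def test_overdrawn_hybrids_rejected(self):
        with pytest.raises(dg.DesignError):
            dg.BreedingDesign(2, 2, 3)

    def test_eggs_per_tray(self):
        assert dg.BreedingDesign().eggs_per_tray(50) == 1450


class TestParentGenotypes:
    def test_degenerate_frequencies_all_homozygous(self):
        d = dg.BreedingDesign(2, 2, 0, offspring_per_family_per_tank=1)
        p = dg.SimulationParams(n_loci=1, alleles_per_locus=1,
                                allele_freqs=(np.array([1.0]),))
        ped = dg.simulate_pedigree(d, 0)
        gts = dg.simulate_parent_genotypes(ped, p, 0)
        assert (gts["allele1"] == 0).all() and (gts["allele2"] == 0).all()

    def test_table_shape(self):
        d = dg.BreedingDesign(1, 0, 0, offspring_per_family_per_tank=1)
        p = dg.SimulationParams(n_loci=2, alleles_per_locus=4)
        gts = dg.simulate_parent_genotypes(dg.simulate_pedigree(d, 0), p, 0)
        assert len(gts) == 2 * 2  # 2 parents x 2 loci

    def test_homozygosity_matches_allele_frequencies(self):
        # with k equifrequent alleles, P(homozygous) = sum p^2 = 1/k
        d = dg.BreedingDesign(1250, 1250, 0, offspring_per_family_per_tank=0)
        p = dg.SimulationParams(n_loci=6, alleles_per_locus=10)
        gts = dg.simulate_parent_genotypes(dg.simulate_pedigree(d, 0), p, seed=123)
        hom = (gts["allele1"] == gts["allele2"]).groupby(gts["locus"]).mean()
        n_per_locus = 5000
        tol = 4 * np.sqrt(0.1 * 0.9 / n_per_locus)
        assert np.all(np.abs(hom - 0.1) < tol)


class TestOffspringGenotypes:
    @pytest.fixture()
    def tiny(self):
        d = dg.BreedingDesign(1, 1, 1, offspring_per_family_per_tank=10,
                              tanks=(("T1", "control"),))
        return d, dg.simulate_pedigree(d, 0)

    def test_forced_inheritance(self, tiny):
        d, ped = tiny
        parents = ped.founders["id"]
        # sires homozygous 0/0, dams homozygous 1/1 at a single locus
        rows = [
            (pid, "L1", 0 if pid[1] == "S" else 1, 0 if pid[1] == "S" else 1, pd.NA)
            for pid in parents
        ]
        pgts = pd.DataFrame(rows, columns=["id", "locus", "allele1", "allele2", "allele3"])
        p = dg.SimulationParams(n_loci=1, alleles_per_locus=2,
                                genotyping_error_rate=0.0, trisomy_rate=0.0)
        gts = dg.simulate_offspring_genotypes(ped, pgts, p, 0)
        assert set(map(tuple, gts[["allele1", "allele2"]].to_numpy())) == {(0, 1)}

    def test_trisomy_rate_one_marks_exactly_one_locus(self, tiny):
        d, ped = tiny
        p = dg.SimulationParams(trisomy_rate=1.0, genotyping_error_rate=0.0)
        pgts = dg.simulate_parent_genotypes(ped, p, 0)
        gts = dg.simulate_offspring_genotypes(ped, pgts, p, 0)
        per_ind = gts.groupby("id")["allele3"].apply(lambda s: s.notna().sum())
        assert (per_ind == 1).all()

    def test_missing_parent_errors(self, tiny):
        d, ped = tiny
        p = dg.SimulationParams()
        pgts = dg.simulate_parent_genotypes(ped, p, 0).iloc[:3]
        with pytest.raises(dg.DesignError):
            dg.simulate_offspring_genotypes(ped, pgts, p, 0)

    def test_trisomic_count_within_binomial_interval(self):
        d = dg.BreedingDesign()  # 29 families x 4 tanks x 19 ~ study scale
        p = dg.SimulationParams(trisomy_rate=70 / 2256, genotyping_error_rate=0.0)
        ped = dg.simulate_pedigree(d, 0)
        pgts = dg.simulate_parent_genotypes(ped, p, 2)
        gts = dg.simulate_offspring_genotypes(ped, pgts, p, seed=2)
        n = len(ped.offspring)
        n_tri = gts.groupby("id")["allele3"].apply(lambda s: s.notna().any()).sum()
        lo, hi = sps.binom.ppf([0.025, 0.975], n, 70 / 2256)
        assert lo <= n_tri <= hi

    def test_mendelian_consistency_without_artefacts(self, tiny):
        # error and trisomy rates 0 => every offspring compatible with its parents
        d, ped = tiny
        p = dg.SimulationParams(genotyping_error_rate=0.0, trisomy_rate=0.0)
        pgts = dg.simulate_parent_genotypes(ped, p, 3)
        gts = dg.simulate_offspring_genotypes(ped, pgts, p, 3)
        parents = {g.individual_id: g for g in genotypes_from_frame(pgts)}
        fam = dg.family_parent_table(ped).set_index("family_id")
        truth = ped.offspring.set_index("id")["family"]
        for off in genotypes_from_frame(gts):
            f = truth[off.individual_id]
            assert pair_compatible(off, parents[fam.loc[f, "sire_id"]],
                                   parents[fam.loc[f, "dam_id"]])


class TestPhenotypes:
    def test_zero_variance_collapse(self):
        d = dg.BreedingDesign(2, 2, 1, offspring_per_family_per_tank=3)
        p = dg.SimulationParams(v_a={g: 0.0 for g in dg.GROUPS},
                                v_e={t: 0.0 for t in dg.TREATMENTS}, v_tank=0.0)
        ph = dg.simulate_phenotypes(dg.simulate_pedigree(d, 0), d, p, 0)
        for (g, t), sub in ph.groupby(["group", "treatment"]):
            assert np.allclose(sub["weight_g"], 10 ** p.mu_logw[(g, t)])

    def test_condition_factor_relation(self, study_dataset):
        ph = study_dataset["phenotypes"]
        k = 100 * ph["weight_g"] / ph["length_cm"] ** 3
        assert np.allclose(k, ph["condition_factor"])
        assert 1.1 < ph["condition_factor"].mean() < 1.45

    def test_fullsib_intraclass_correlation(self):
        # ICC of full sibs = (V_A/2) / (V_A + V_E) = 0.25 when V_A = V_E
        d = dg.BreedingDesign(50, 0, 0, offspring_per_family_per_tank=40,
                              tanks=(("T1", "control"),))
        p = dg.SimulationParams(v_a={"farm": 0.04, "hybrid": 0, "wild": 0},
                                v_e={"control": 0.04, "stress": 0.04}, v_tank=0.0)
        iccs = []
        for seed in range(5):
            ph = dg.simulate_phenotypes(dg.simulate_pedigree(d, seed), d, p, seed)
            y = np.log10(ph["weight_g"])
            grand = y.groupby(ph["family"])
            nj = 40
            msb = nj * grand.mean().var(ddof=1)
            msw = (grand.var(ddof=1)).mean()
            s2b = (msb - msw) / nj
            iccs.append(s2b / (s2b + msw))
        assert abs(np.mean(iccs) - 0.25) < 0.04

    def test_variance_additivity_within_cell(self):
        # many families, no tank effect: cell variance -> V_A + V_E
        d = dg.BreedingDesign(100, 0, 0, offspring_per_family_per_tank=20,
                              tanks=(("T1", "control"),))
        p = dg.SimulationParams(v_a={"farm": 0.01, "hybrid": 0, "wild": 0},
                                v_e={"control": 0.012, "stress": 0.012}, v_tank=0.0)
        ph = dg.simulate_phenotypes(dg.simulate_pedigree(d, 1), d, p, 1)
        v = np.log10(ph["weight_g"]).var(ddof=1)
        assert abs(v - 0.022) / 0.022 < 0.12

    def test_group_means_calibrated_to_reference(self):
        # expectation matches the reference means; average over seeds to damp
        # the family-sampling noise of a single 29-family draw
        d, p = dg.BreedingDesign(), dg.SimulationParams()
        sums = {cell: [] for cell in REFERENCE_MEAN_WEIGHT_G}
        for seed in range(10):
            ph = dg.simulate_phenotypes(dg.simulate_pedigree(d, seed), d, p, seed)
            m = ph.groupby(["group", "treatment"])["weight_g"].mean()
            for cell in sums:
                sums[cell].append(m[cell])
        for cell, target in REFERENCE_MEAN_WEIGHT_G.items():
            se = REFERENCE_SD_WEIGHT_G[cell] / np.sqrt(REFERENCE_N[cell])
            assert abs(np.mean(sums[cell]) - target) < 2 * se, cell

    def test_halfsib_relationship_in_a_matrix(self):
        d = dg.BreedingDesign(1, 1, 1, offspring_per_family_per_tank=1,
                              tanks=(("T1", "control"),))
        ped = dg.simulate_pedigree(d, 0)
        a = dg.build_relationship_matrix(ped)
        off = ped.offspring.set_index("family")["id"]
        assert a.loc[off["F01"], off["H01"]] == pytest.approx(0.25)  # shared dam
        assert a.loc[off["W01"], off["H01"]] == pytest.approx(0.25)  # shared sire
        assert a.loc[off["F01"], off["W01"]] == pytest.approx(0.0)

    def test_params_validation(self):
        with pytest.raises(dg.DesignError):
            dg.SimulationParams(v_a={"farm": -1.0, "hybrid": 0, "wild": 0})
        with pytest.raises(dg.DesignError):
            dg.SimulationParams(trisomy_rate=1.5)
        with pytest.raises(dg.DesignError):
            dg.SimulationParams(n_loci=2, allele_freqs=(np.array([0.5, 0.5]),))
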