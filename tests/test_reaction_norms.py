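"""Mixed-model engine: REML correctness, AIC selection, F-tests, reaction norms."""

import numpy as np
import pandas as pd
import pytest

import domestigrow as dg
from domestigrow.design import REFERENCE_MEAN_WEIGHT_G, SimulationParams
from domestigrow.reaction_norms import MixedModelSpec

from conftest import make_phenotypes


def _balanced_oneway(seed, n_fam=20, n_per=10, sd_fam=0.1, sd_e=0.2):
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(n_fam), n_per)
    y = rng.normal(0, sd_fam, n_fam)[fam] + rng.normal(0, sd_e, n_fam * n_per)
    df = pd.DataFrame({
        "weight_g": 10.0 ** (1.0 + y),
        "family": [f"f{i}" for i in fam],
        "group": "farm",
        "treatment": np.tile(["control", "stress"], n_fam * n_per // 2),
        "tank": "T1",
    })
    return df, y, fam


class TestREML:
    def test_matches_closed_form_anova_on_balanced_design(self):
        df, y, fam = _balanced_oneway(0)
        fit = dg.fit_growth_model(df, MixedModelSpec(fixed=(), random="intercept"))
        ybar = pd.Series(y).groupby(fam).mean()
        msw = float(np.sum((y - ybar[fam].to_numpy()) ** 2) / (200 - 20))
        msb = 10 * float(ybar.var(ddof=1))
        s2_fam = (msb - msw) / 10
        assert fit.sigma2 == pytest.approx(msw, rel=1e-6)
        assert fit.family_covariance["shared"][0, 0] == pytest.approx(s2_fam, rel=1e-6)

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        df, y, fam = _balanced_oneway(3)
        df = df.copy()
        df["treat01"] = (df["treatment"] == "stress").astype(float)
        fit = dg.fit_growth_model(
            df, MixedModelSpec(fixed=("treatment",), random="intercept")
        )
        X = np.column_stack([np.ones(len(df)), df["treat01"]])
        res = sm.MixedLM(np.log10(df["weight_g"]), X, groups=df["family"]).fit(reml=True)
        assert fit.sigma2 == pytest.approx(res.scale, rel=1e-4)
        assert fit.family_covariance["shared"][0, 0] == pytest.approx(
            float(res.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-8
        )
        assert np.allclose(fit.fixed_effects.to_numpy(), res.fe_params, rtol=1e-5)

    def test_zero_family_variance_hits_boundary_and_matches_ols(self):
        d = dg.BreedingDesign(offspring_per_family_per_tank=5)
        p = SimulationParams(v_a={g: 0.0 for g in dg.GROUPS}, v_tank=0.0)
        ped = dg.simulate_pedigree(d, 2)
        ph = dg.simulate_phenotypes(ped, d, p, 2)
        fit = dg.fit_growth_model(ph)
        cov = fit.family_covariance["shared"]
        # estimated family variances collapse to a sliver of the residual 0.012
        assert cov[0, 0] < 2e-3 and cov[1, 1] < 2e-3
        # fixed effects collapse to ordinary least squares
        y = np.log10(ph["weight_g"])
        treat = (ph["treatment"] == "stress").astype(float)
        X = np.column_stack([
            np.ones(len(ph)), treat,
            (ph["group"] == "hybrid").astype(float), (ph["group"] == "wild").astype(float),
            treat * (ph["group"] == "hybrid"), treat * (ph["group"] == "wild"),
        ])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.fixed_effects.to_numpy(), beta_ols, atol=2e-3)

    def test_selected_model_dominates_nested_candidate(self, study_dataset):
        ph = study_dataset["phenotypes"]
        full = dg.fit_growth_model(ph, MixedModelSpec(random="treatment_2x2"))
        nested = dg.fit_growth_model(ph, MixedModelSpec(random="intercept"))
        assert full.reml_loglik >= nested.reml_loglik - 1e-6

    def test_requires_both_treatments(self):
        df, _, _ = _balanced_oneway(0)
        with pytest.raises(ValueError):
            dg.fit_growth_model(df[df["treatment"] == "control"],
                                MixedModelSpec(fixed=("treatment",), random="intercept"))


class TestDfRule:
    @pytest.mark.parametrize("n_min, k, expect", [(329, 2, 327), (329, 3, 326), (10, 2, 8)])
    def test_denominator_df(self, n_min, k, expect):
        assert dg.ftest_denominator_df(n_min, k) == expect

    def test_invalid(self):
        with pytest.raises(ValueError):
            dg.ftest_denominator_df(3, 3)
        with pytest.raises(ValueError):
            dg.ftest_denominator_df(10, 1)

    def test_anova_uses_smallest_cell(self, study_dataset):
        ph = study_dataset["phenotypes"]
        fit = dg.fit_growth_model(ph)
        n_min = ph.groupby(["group", "treatment"]).size().min()
        row = fit.anova.set_index("term")
        assert row.loc["treatment", "df2"] == n_min - 2
        assert row.loc["type", "df2"] == n_min - 3
        assert row.loc["treatment:type", "df2"] == n_min - 3


class TestModelSelection:
    def test_interaction_recovered_when_strong(self):
        # pronounced group-specific slopes: AIC must keep the interaction term
        mu = dict(SimulationParams().mu_logw)
        mu[("wild", "stress")] = mu[("wild", "control")] - 0.25
        mu[("farm", "stress")] = mu[("farm", "control")] - 0.10
        mu[("hybrid", "stress")] = mu[("hybrid", "control")] - 0.17
        p = SimulationParams(mu_logw=mu)
        d = dg.BreedingDesign(offspring_per_family_per_tank=8)
        specs = [
            MixedModelSpec(("treatment", "type", "treatment:type"), "treatment_2x2"),
            MixedModelSpec(("treatment", "type"), "treatment_2x2"),
        ]
        for seed in range(3):
            ped = dg.simulate_pedigree(d, seed)
            ph = dg.simulate_phenotypes(ped, d, p, seed)
            fits = dg.select_model_aic(ph, specs)
            assert "treatment:type" in fits[0].spec.fixed

    def test_tank_term_not_selected_without_tank_variance(self):
        d = dg.BreedingDesign(offspring_per_family_per_tank=8)
        p = SimulationParams(v_tank=0.0)
        specs = [
            MixedModelSpec(random="treatment_2x2", tank=True),
            MixedModelSpec(random="treatment_2x2", tank=False),
        ]
        wins = 0
        for seed in range(3):
            ped = dg.simulate_pedigree(d, seed)
            ph = dg.simulate_phenotypes(ped, d, p, seed)
            fits = dg.select_model_aic(ph, specs)
            wins += not fits[0].spec.tank
        assert wins >= 2

    def test_needs_two_candidates(self, study_dataset):
        with pytest.raises(ValueError):
            dg.select_model_aic(study_dataset["phenotypes"], [MixedModelSpec()])

    def test_interaction_power_at_strong_slope_difference(self):
        # wild slope steeper than farm by ~0.1 log-units in the calibration
        mu = dict(SimulationParams().mu_logw)
        mu[("wild", "stress")] = mu[("wild", "control")] - 0.20
        mu[("farm", "stress")] = mu[("farm", "control")] - 0.10
        mu[("hybrid", "stress")] = mu[("hybrid", "control")] - 0.15
        p = SimulationParams(mu_logw=mu)
        d = dg.BreedingDesign(offspring_per_family_per_tank=5)
        ped = dg.simulate_pedigree(d, 0)
        hits = 0
        for seed in range(10):
            ph = dg.simulate_phenotypes(ped, d, p, seed)
            fit = dg.fit_growth_model(ph)
            pv = fit.anova.set_index("term").loc["treatment:type", "p"]
            hits += pv < 0.05
        assert hits >= 8


class TestPairwise:
    def test_adjusted_alpha_below_printed_threshold(self, study_dataset):
        res = dg.pairwise_group_tests(study_dataset["phenotypes"])
        assert res.adjusted_alpha == pytest.approx(0.05 / 3)
        assert res.adjusted_alpha < 0.02
        assert set(res.fits) == {("farm", "hybrid"), ("farm", "wild"), ("hybrid", "wild")}
        # every pair reuses the global smallest cell for its denominator df
        n_min = dg.smallest_cell_size(study_dataset["phenotypes"])
        for fit in res.fits.values():
            assert fit.n_min == n_min

    def test_unadjusted_when_single_comparison(self, study_dataset):
        res = dg.pairwise_group_tests(study_dataset["phenotypes"], m=1)
        assert res.adjusted_alpha == 0.05

    def test_requires_three_groups(self, study_dataset):
        ph = study_dataset["phenotypes"]
        with pytest.raises(ValueError):
            dg.pairwise_group_tests(ph[ph["group"] != "wild"])


class TestReactionNorms:
    def test_flat_and_analytic_slopes(self):
        ph = make_phenotypes({
            ("f1", "farm", "control", "T1"): [20, 20],
            ("f1", "farm", "stress", "T3"): [20, 20],
            ("f2", "farm", "control", "T1"): [20, 20],
            ("f2", "farm", "stress", "T3"): [10, 10],
        })
        norms = dg.family_reaction_norms(ph)
        norms = norms.set_index("family")
        assert norms.loc["f1", "slope"] == pytest.approx(0.0)
        assert norms.loc["f2", "slope"] == pytest.approx(np.log10(10) - np.log10(20))
        assert round(norms.loc["f2", "slope"], 3) == -0.301

    def test_reference_group_slopes_order_wild_steepest(self):
        ph = make_phenotypes({
            (g[0], g, t, "T1" if t == "control" else "T3"):
                [REFERENCE_MEAN_WEIGHT_G[(g, t)]] * 2
            for g in dg.GROUPS for t in dg.TREATMENTS
        })
        norms = dg.group_reaction_norms(ph).set_index("group")
        assert round(norms.loc["wild", "slope"], 3) == -0.170
        assert round(norms.loc["hybrid", "slope"], 3) == -0.124
        assert round(norms.loc["farm", "slope"], 3) == -0.101
        assert norms.loc["wild", "slope"] < norms.loc["hybrid", "slope"] < norms.loc["farm", "slope"]

    def test_family_missing_a_treatment_excluded(self):
        ph = make_phenotypes({
            ("f1", "farm", "control", "T1"): [20, 21],
            ("f1", "farm", "stress", "T3"): [15, 16],
            ("f2", "farm", "control", "T1"): [22, 23],
        })
        with pytest.warns(UserWarning):
            norms = dg.family_reaction_norms(ph)
        assert list(norms["family"]) == ["f1"]

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MixedModelSpec(fixed=("treatment", "treatment:type"))
        with pytest.raises(ValueError):
            MixedModelSpec(random="banana")
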