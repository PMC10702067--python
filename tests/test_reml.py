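"""AI-REML engine and the animal-model classes."""

import warnings

import numpy as np
import pandas as pd
import pytest

from crosslay.animal_model import (
    AnimalModel,
    BivariateAnimalModel,
    ConvergenceWarning,
    GroupMultivariateAnimalModel,
)
from crosslay.reml import DiagonalResidual, RandomTerm, REMLProblem

from conftest import random_pedigree


def _univariate_problem(seed=1, n_groups=2):
    """Small animal-model REML problem with known simulated structure."""
    rng = np.random.default_rng(seed)
    ped = random_pedigree(10, 90, seed)
    idx = ped.position([a for a in ped.ids if a.startswith("x")])
    A = ped.relationship_matrix()
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ped)))
    bv = (L @ rng.normal(size=len(ped))) * np.sqrt(2.0)
    y = 10 + bv[idx] + rng.normal(0, np.sqrt(3.0), idx.size)
    grp = np.arange(idx.size) % n_groups
    term = RandomTerm(
        "a", level_idx=idx, q=len(ped), kinv=ped.a_inverse(),
        logdet_k=ped.log_det_a(),
    )
    res = DiagonalResidual(group_idx=grp, n_groups=n_groups)
    return REMLProblem(y, np.ones((idx.size, 1)), [term], res)


class TestEngineCore:
    def test_score_matches_finite_differences(self):
        prob = _univariate_problem()
        theta = np.array([1.5, 2.5, 3.5])
        state = prob._assemble(theta)
        score, _ = prob.score_and_f(theta, state)
        fd = np.zeros_like(theta)
        for k in range(theta.size):
            e = np.zeros_like(theta)
            e[k] = 1e-5
            fd[k] = (
                prob._assemble(theta + e).ll - prob._assemble(theta - e).ll
            ) / 2e-5
        assert np.abs(score - fd).max() < 1e-5

    def test_em_loglik_monotone(self):
        prob = _univariate_problem(seed=2)
        fit = prob.fit(method="em", maxiter=40)
        diffs = np.diff(fit.history)
        assert (diffs > -1e-8).all()

    def test_converged_solution_is_stationary(self):
        prob = _univariate_problem(seed=3)
        fit = prob.fit()
        assert fit.converged
        state = prob._assemble(fit.theta)
        score, F = prob.score_and_f(fit.theta, state)
        AI = prob.ai_matrix(state, F)
        free = ~fit.pinned
        step = np.linalg.solve(AI[np.ix_(free, free)], score[free])
        rel = np.abs(step) / np.maximum(fit.theta[free], prob.var_floor)
        assert rel.max() < 1e-3

    def test_ai_matrix_symmetric_psd(self):
        prob = _univariate_problem(seed=4)
        theta = np.array([2.0, 3.0, 2.5])
        state = prob._assemble(theta)
        _, F = prob.score_and_f(theta, state)
        AI = prob.ai_matrix(state, F)
        assert np.abs(AI - AI.T).max() < 1e-10
        assert np.linalg.eigvalsh(AI).min() > 0


class TestUnivariate:
    def test_anova_equivalence_balanced_halfsib(self, halfsib_data):
        model = AnimalModel(
            halfsib_data["data"], halfsib_data["ped"], trait="y",
            residual_by_group=False,
        )
        res = model.fit()
        assert res.converged
        assert res.sigma_a2 == pytest.approx(
            halfsib_data["sa2_anova"], rel=1e-4
        )

    def test_zero_additive_variance_boundary(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(10, 200, 5)
        data = pd.DataFrame(
            {
                "animal": [a for a in ped.ids if a.startswith("x")],
                "group": "WW",
                "trait": "y",
                "value": rng.normal(0, 1, 200),  # no genetic signal
            }
        )
        res = AnimalModel(data, ped, trait="y", residual_by_group=False).fit()
        assert res.sigma_a2 <= 10 * res.model.problem.var_floor
        assert res.heritability < 0.02

    def test_h2_in_unit_interval_and_sigma_e_is_group_average(self, family_data):
        res = AnimalModel(family_data["phen"], family_data["ped"], trait="T").fit()
        assert 0.0 <= res.heritability <= 1.0
        assert res.repeatability >= res.heritability
        assert res.sigma_e2 == pytest.approx(res.sigma_e_groups.mean())
        assert res.sigma_p2 == pytest.approx(
            res.sigma_a2 + res.sigma_pe2 + res.sigma_e2
        )

    def test_pe_unidentifiable_without_repeats(self):
        ped = random_pedigree(4, 30, 6)
        data = pd.DataFrame(
            {
                "animal": [a for a in ped.ids if a.startswith("x")],
                "group": "WW",
                "trait": "y",
                "value": np.random.default_rng(0).normal(size=30),
            }
        )
        with pytest.warns(ConvergenceWarning, match="unidentifiable"):
            model = AnimalModel(data, ped, trait="y", permanent_env=True)
        assert not model.permanent_env
        assert model.fit().sigma_pe2 == 0.0


class TestRepeatability:
    def test_duplicated_records_drive_residual_to_zero(self):
        rng = np.random.default_rng(7)
        ped = random_pedigree(10, 80, 7)
        animals = [a for a in ped.ids if a.startswith("x")]
        vals = rng.normal(50, 3, len(animals))
        data = pd.DataFrame(
            {
                "animal": np.repeat(animals, 2),
                "group": "WW",
                "trait": "y",
                "value": np.repeat(vals, 2),  # exact duplicates
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = AnimalModel(data, ped, trait="y", residual_by_group=False).fit(
                maxiter=60
            )
        assert res.sigma_e2 < 1e-4 * res.sigma_p2
        assert res.repeatability > 0.999

    def test_parameter_recovery_moderate(self, family_data):
        """sigma components within rough range of the simulated truth."""
        res = AnimalModel(family_data["phen"], family_data["ped"], trait="T").fit()
        p = family_data["params"]
        truth_h2 = p.sigma_a2 / (p.sigma_a2 + p.sigma_pe2 + p.sigma_e2)
        se = res.heritability_se
        assert abs(res.heritability - truth_h2) < 3 * max(se, 0.05)

    def test_zero_pe_simulation_repeatability_near_h2(self):
        from crosslay.simulate import (
            TraitGeneticParams,
            simulate_breeding_values,
            simulate_phenotypes,
            simulate_pedigree,
            simulate_rack_assignment,
            MatingDesign,
        )

        design = MatingDesign(
            n_sires_per_line=8, n_dams_per_sire_cross=3,
            offspring_per_group={g: 60 for g in ("YY", "WW", "WY", "YW")},
            base_generations=1, n_base_females_per_line=24,
        )
        ped = simulate_pedigree(design, seed=20)
        racks = simulate_rack_assignment(ped, 6, seed=20)
        params = TraitGeneticParams(
            "T", {"W": 10.0, "Y": 12.0}, sigma_a2=5.0, sigma_pe2=0.0,
            sigma_e2=5.0, n_records=3,
        )
        bv = simulate_breeding_values(ped, params, seed=21)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=22)
        res = AnimalModel(phen, ped, trait="T").fit()
        assert res.repeatability - res.heritability < 0.08


class TestPredictionsAndContrasts:
    def test_noise_free_group_means_exact(self):
        from crosslay.simulate import (
            TraitGeneticParams,
            simulate_breeding_values,
            simulate_pedigree,
            simulate_phenotypes,
            simulate_rack_assignment,
            MatingDesign,
        )

        design = MatingDesign(
            n_sires_per_line=2, n_dams_per_sire_cross=2,
            offspring_per_group={g: 6 for g in ("YY", "WW", "WY", "YW")},
            base_generations=1, n_base_females_per_line=6,
        )
        ped = simulate_pedigree(design, seed=0)
        racks = simulate_rack_assignment(ped, 3, seed=0)
        params = TraitGeneticParams(
            "T", {"W": 60.0, "Y": 50.0}, heterosis_shift=1.5,
            reciprocal_shift=1.0,
        )
        bv = simulate_breeding_values(ped, params, seed=1)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=2)
        res = AnimalModel(phen, ped, trait="T").fit()
        gm = res.predicted_group_means()["mean"]
        assert gm["WW"] == pytest.approx(60.0, abs=1e-6)
        assert gm["YY"] == pytest.approx(50.0, abs=1e-6)
        assert gm["WY"] == pytest.approx(55.0 + 1.5 + 0.5, abs=1e-6)
        assert gm["YW"] == pytest.approx(55.0 + 1.5 - 0.5, abs=1e-6)

    def test_predictions_invariant_to_constraint(self, family_data):
        r1 = AnimalModel(
            family_data["phen"], family_data["ped"], trait="T", coding="reference"
        ).fit()
        r2 = AnimalModel(
            family_data["phen"], family_data["ped"], trait="T", coding="sum"
        ).fit()
        gm1 = r1.predicted_group_means()["mean"]
        gm2 = r2.predicted_group_means()["mean"]
        assert np.allclose(gm1, gm2, atol=1e-4)

    def test_balanced_no_rack_prediction_equals_raw_mean(self):
        ped = random_pedigree(4, 40, 9)
        rng = np.random.default_rng(9)
        animals = [a for a in ped.ids if a.startswith("x")]
        groups = np.array((["WW", "YY"] * 20)[:40])
        vals = rng.normal(np.where(groups == "WW", 30, 20), 1.0)
        data = pd.DataFrame(
            {"animal": animals, "group": groups, "trait": "y", "value": vals}
        )
        res = AnimalModel(data, ped, trait="y", residual_by_group=False).fit()
        gm = res.predicted_group_means()["mean"]
        # without rack effects, predicted means track raw means closely
        assert gm["WW"] == pytest.approx(vals[groups == "WW"].mean(), abs=0.3)

    def test_contrast_of_identical_means_is_null(self):
        ped = random_pedigree(4, 60, 10)
        rng = np.random.default_rng(10)
        animals = [a for a in ped.ids if a.startswith("x")]
        data = pd.DataFrame(
            {
                "animal": animals * 2,
                "group": ["WY"] * 60 + ["YW"] * 60,
                "trait": "y",
                "value": np.concatenate([rng.normal(5, 1, 60)] * 2),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = AnimalModel(
                data, ped, trait="y", residual_by_group=False, permanent_env=False
            ).fit(maxiter=50)
        out = res.wald_contrast({"WY": 1.0, "YW": -1.0})
        assert out["F"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_programmed_heterosis_power(self):
        """A 5% heterosis shift with tiny noise is overwhelmingly significant."""
        from crosslay.simulate import (
            MatingDesign,
            TraitGeneticParams,
            simulate_breeding_values,
            simulate_pedigree,
            simulate_phenotypes,
            simulate_rack_assignment,
        )

        design = MatingDesign(
            n_sires_per_line=4, n_dams_per_sire_cross=2,
            offspring_per_group={g: 30 for g in ("YY", "WW", "WY", "YW")},
            base_generations=1, n_base_females_per_line=16,
        )
        ped = simulate_pedigree(design, seed=40)
        racks = simulate_rack_assignment(ped, 3, seed=40)
        params = TraitGeneticParams(
            "T", {"W": 60.0, "Y": 50.0}, sigma_e2=1e-4,
            heterosis_shift=0.05 * 55.0,
        )
        bv = simulate_breeding_values(ped, params, seed=41)
        phen = simulate_phenotypes(ped, bv, params, racks, seed=42)
        res = AnimalModel(phen, ped, trait="T", permanent_env=False).fit()
        out = res.wald_contrast({"WY": 1.0, "WW": -0.5, "YY": -0.5})
        assert out["p_value"] < 1e-6

    def test_nonzero_sum_contrast_rejected(self, family_data):
        res = AnimalModel(family_data["phen"], family_data["ped"], trait="T").fit()
        with pytest.raises(ValueError, match="sum to 0"):
            res.wald_contrast({"WY": 1.0})

    def test_summary_mentions_key_quantities(self, family_data):
        res = AnimalModel(family_data["phen"], family_data["ped"], trait="T").fit()
        text = res.summary()
        assert "heritability" in text and "sigma_a2" in text
        assert "predicted group means" in text


class TestBivariate:
    def _bivariate_data(self, ra=0.8, n_fam=60, seed=11):
        from crosslay.pedigree import Pedigree

        rng = np.random.default_rng(seed)
        rows = [{"animal": f"s{i}", "sire": "", "dam": ""} for i in range(n_fam)]
        rows += [{"animal": f"d{i}", "sire": "", "dam": ""} for i in range(n_fam)]
        off = []
        for i in range(n_fam):
            for k in range(4):
                a = f"o{i}_{k}"
                off.append(a)
                rows.append({"animal": a, "sire": f"s{i}", "dam": f"d{i}"})
        ped = Pedigree(pd.DataFrame(rows))
        A = ped.relationship_matrix()
        L = np.linalg.cholesky(A + 1e-9 * np.eye(len(ped)))
        Ga = np.array([[4.0, ra * 4.0], [ra * 4.0, 4.0]])
        Bv = (L @ rng.normal(size=(len(ped), 2))) @ np.linalg.cholesky(Ga).T
        idx = ped.position(off)
        recs = []
        for j, a in enumerate(off):
            for t_ix, tr in enumerate(["A", "B"]):
                recs.append(
                    {
                        "animal": a,
                        "group": ["WW", "YY", "WY", "YW"][j % 4],
                        "trait": tr,
                        "value": 50 + Bv[idx[j], t_ix] + rng.normal(0, 2.0),
                    }
                )
        return pd.DataFrame(recs), ped

    def test_same_trait_twice_gives_unit_correlations(self, family_data):
        phen = family_data["phen"]
        single = phen.drop_duplicates(subset=["hen"])  # one record per hen
        both = pd.concat(
            [single.assign(trait="T1"), single.assign(trait="T2")],
            ignore_index=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BivariateAnimalModel(
                both, family_data["ped"], traits=("T1", "T2")
            ).fit(maxiter=40)
        assert res.r_a == pytest.approx(1.0, abs=1e-3)
        assert res.r_e == pytest.approx(1.0, abs=1e-3)

    def test_genetic_correlation_recovery(self):
        df, ped = self._bivariate_data(ra=0.8)
        res = BivariateAnimalModel(df, ped, traits=("A", "B")).fit()
        assert res.converged
        assert abs(res.r_a - 0.8) < 2.5 * max(res.r_a_se, 0.08)

    def test_independent_traits_near_zero(self):
        df, ped = self._bivariate_data(ra=0.0, seed=12)
        res = BivariateAnimalModel(df, ped, traits=("A", "B")).fit()
        assert abs(res.r_a) < 2.5 * max(res.r_a_se, 0.1)

    def test_bivariate_reproduces_univariate_components(self):
        df, ped = self._bivariate_data(ra=0.5, seed=13)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            uni = AnimalModel(
                df[df.trait == "A"], ped, trait="A", residual_by_group=False,
                permanent_env=False,
            ).fit()
            bi = BivariateAnimalModel(df, ped, traits=("A", "B")).fit()
        assert bi.G_a[0, 0] == pytest.approx(uni.sigma_a2, rel=0.05)
        assert bi.G_e[0, 0] == pytest.approx(
            uni.sigma_e_groups.iloc[0], rel=0.05
        )

    def test_phenotypic_correlation_from_summed_blocks(self):
        df, ped = self._bivariate_data(ra=0.6, seed=14)
        res = BivariateAnimalModel(df, ped, traits=("A", "B")).fit()
        Gp = res.G_a + res.G_pe + res.G_e
        assert res.r_p == pytest.approx(
            Gp[0, 1] / np.sqrt(Gp[0, 0] * Gp[1, 1])
        )


class TestGroupMultivariate:
    def test_weighted_average_arithmetic(self, family_data):
        res = GroupMultivariateAnimalModel(
            family_data["phen"], family_data["ped"], trait="T",
            weights={"WW": 0.22, "YY": 0.25, "cross": 0.53},
        ).fit()
        bg = res.by_group
        manual = (
            0.22 * bg.loc["WW", "sigma_a2"]
            + 0.25 * bg.loc["YY", "sigma_a2"]
            + 0.53 * bg.loc["cross", "sigma_a2"]
        )
        assert res.weighted_components()["sigma_a2"] == pytest.approx(manual)

    def test_identical_groups_give_common_h2(self, family_data):
        """Components simulated equal across groups: pooled h2 ~ per-group h2."""
        res = GroupMultivariateAnimalModel(
            family_data["phen"], family_data["ped"], trait="T"
        ).fit()
        h2s = res.by_group["h2"]
        assert abs(res.heritability - h2s.mean()) < 0.15
        uni = AnimalModel(family_data["phen"], family_data["ped"], trait="T").fit()
        assert abs(res.heritability - uni.heritability) < 0.2

    def test_group_variance_ordering_recovered(self):
        from crosslay.simulate import (
            MatingDesign,
            TraitGeneticParams,
            simulate_breeding_values,
            simulate_pedigree,
            simulate_phenotypes,
            simulate_rack_assignment,
        )
        from crosslay.pedigree import Pedigree

        # two populations with very different additive variance: simulate W
        # and Y lines separately and combine
        design = MatingDesign(
            n_sires_per_line=25, n_dams_per_sire_cross=4,
            offspring_per_group={"WW": 400, "YY": 400, "WY": 200, "YW": 200},
            base_generations=1, n_base_females_per_line=48,
        )
        ped = simulate_pedigree(design, seed=30)
        racks = simulate_rack_assignment(ped, 4, seed=30)
        lo = TraitGeneticParams("T", {"W": 50, "Y": 50}, sigma_a2=0.5, sigma_e2=6.0)
        hi = TraitGeneticParams("T", {"W": 50, "Y": 50}, sigma_a2=10.0, sigma_e2=6.0)
        bv_lo = simulate_breeding_values(ped, lo, seed=31)
        bv_hi = simulate_breeding_values(ped, hi, seed=32)
        ph_lo = simulate_phenotypes(ped, bv_lo, lo, racks, seed=33)
        ph_hi = simulate_phenotypes(ped, bv_hi, hi, racks, seed=34)
        phen = pd.concat(
            [
                ph_lo[ph_lo.group == "WW"],
                ph_hi[ph_hi.group.isin(["YY", "WY", "YW"])],
            ],
            ignore_index=True,
        )
        res = GroupMultivariateAnimalModel(phen, ped, trait="T").fit()
        assert res.by_group.loc["WW", "h2"] < res.by_group.loc["YY", "h2"]

    def test_small_group_warns(self, family_data):
        phen = family_data["phen"]
        few_ww = pd.concat(
            [
                phen[phen.group == "WW"].head(10),
                phen[phen.group != "WW"],
            ],
            ignore_index=True,
        )
        with pytest.warns(ConvergenceWarning, match="unstable"):
            GroupMultivariateAnimalModel(few_ww, family_data["ped"], trait="T")
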