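"""Mixed-model core: MME vs GLS oracle, REML vs grid search, phenotype
correction and GBLUP prediction."""

import numpy as np
import pandas as pd
import pytest

from panelgp import (
    GBLUP,
    MixedModel,
    build_a_matrix,
    build_grm,
    correct_phenotypes,
    make_fixed_design,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_qtl,
    solve_mme,
)
from panelgp.kinship import RelationshipMatrix
from panelgp.simulate import make_marker_map
from panelgp.types import TraitArchitecture

from oracles import mme_gls_oracle, reml_grid_oracle


def _random_instance(n, p, seed, k_kind="grm"):
    rng = np.random.default_rng(seed)
    if k_kind == "identity":
        k = np.eye(n)
    else:
        w = rng.normal(size=(n, n + 10))  # full rank so K is invertible
        k = w @ w.T / w.shape[1]
    x = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = rng.normal(size=n)
    z = np.eye(n)
    return y, x, z, k


class TestSolveMme:
    def test_infinite_lambda_gives_ols(self):
        y, x, z, k = _random_instance(40, 3, seed=0)
        b, u = solve_mme(y, x, z, k, np.inf)
        ols = np.linalg.lstsq(x, y, rcond=None)[0]
        np.testing.assert_allclose(b, ols, atol=1e-10)
        assert np.all(u == 0)

    def test_identity_k_is_ridge_regression(self):
        y, x, z, k = _random_instance(20, 2, seed=1, k_kind="identity")
        lam = 2.5
        b, u = solve_mme(y, x, z, k, lam)
        bo, uo = mme_gls_oracle(y, x, z, k, lam)
        np.testing.assert_allclose(b, bo, atol=1e-8)
        np.testing.assert_allclose(u, uo, atol=1e-8)

    @pytest.mark.parametrize("seed", [2, 3, 4])
    def test_matches_dense_gls_oracle(self, seed):
        y, x, z, k = _random_instance(50, 4, seed=seed)
        lam = 1.7
        b, u = solve_mme(y, x, z, k, lam)
        bo, uo = mme_gls_oracle(y, x, z, k, lam)
        assert np.abs(b - bo).max() < 1e-8
        assert np.abs(u - uo).max() < 1e-8

    def test_rank_deficient_design_rejected(self):
        y, x, z, k = _random_instance(30, 2, seed=5)
        x = np.column_stack([x, x[:, 0]])  # duplicate intercept
        with pytest.raises(ValueError):
            MixedModel(y, x, k)


class TestReml:
    @staticmethod
    def _simulated_model(n, m, h2, seed):
        ped = simulate_pedigree(n, 0, seed=seed)
        mm = make_marker_map(m, 5, 100, seed=seed + 1)
        geno = simulate_genotypes(ped, mm, founder_ld_rho=0.3, seed=seed + 2)
        arch = TraitArchitecture("t", min(100, m // 4), target_h2=h2)
        truth0 = simulate_qtl(geno, arch, seed=seed + 3)
        design = make_fixed_design(ped, seed=seed + 4)
        pheno, truth = simulate_phenotypes(
            truth0, arch, design, seed=seed + 5,
            sex_effect=0.0, cg_sd=0.0, age_slope=0.0,
        )
        grm = build_grm(geno)
        y = pheno["t"].to_numpy()
        return MixedModel(y, np.ones((n, 1)), grm.values), truth

    def test_pure_noise_gives_near_zero_h2(self):
        rng = np.random.default_rng(0)
        ped = simulate_pedigree(400, 0, seed=1)
        mm = make_marker_map(1500, 5, 100, seed=2)
        geno = simulate_genotypes(ped, mm, founder_ld_rho=0.3, seed=3)
        grm = build_grm(geno)
        y = rng.normal(size=400)
        fit = MixedModel(y, np.ones((400, 1)), grm.values).fit()
        assert fit.h2 < 0.05

    def test_recovers_simulated_heritability(self):
        fit, truth = TestReml._simulated_model(800, 1200, 0.4, seed=10)
        res = fit.fit()
        assert res.vc.converged
        assert abs(res.h2 - truth.realized_h2) < 0.1

    @pytest.mark.parametrize("seed", [20, 21])
    def test_optimum_matches_grid_search(self, seed):
        model, _ = TestReml._simulated_model(300, 800, 0.35, seed=seed)
        res = model.fit()
        grid_opt, step = reml_grid_oracle(model)
        assert abs(res.log_delta - grid_opt) <= step

    def test_location_invariance_and_scale_equivariance(self):
        model, _ = TestReml._simulated_model(300, 800, 0.35, seed=30)
        base = model.fit()
        shifted = MixedModel(model.y + 100.0, model.X, model.K).fit()
        scaled = MixedModel(model.y * 3.0, model.X, model.K).fit()
        assert shifted.vc.sigma2_g == pytest.approx(base.vc.sigma2_g, rel=1e-4)
        assert scaled.vc.sigma2_g == pytest.approx(9.0 * base.vc.sigma2_g, rel=1e-4)
        assert scaled.h2 == pytest.approx(base.h2, abs=1e-6)

    def test_reml_and_mme_mutually_consistent(self):
        base, _ = TestReml._simulated_model(200, 1500, 0.4, seed=40)
        # a centred GRM always has one zero eigenvalue; blend with I so the
        # Henderson route (which inverts K) is exactly comparable
        k = 0.95 * base.K + 0.05 * np.eye(200)
        model = MixedModel(base.y, base.X, k)
        res = model.fit()
        lam = res.vc.sigma2_e / res.vc.sigma2_g
        b, u = solve_mme(model.y, model.X, np.eye(200), k, lam)
        np.testing.assert_allclose(res.fixed_effects, b, atol=1e-6)
        np.testing.assert_allclose(res.blups(), u, atol=1e-6)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="variance|degenerate"):
            MixedModel(np.ones(50), np.ones((50, 1)), np.eye(50))


class TestCorrectPhenotypes:
    @staticmethod
    def _population(seed, n=600, sex_effect=0.3, cg_sd=0.5, age_slope=0.15):
        ped = simulate_pedigree(n // 3, 2, 2, seed=seed)
        mm = make_marker_map(800, 4, 100, seed=seed + 1)
        geno = simulate_genotypes(ped, mm, founder_ld_rho=0.3, seed=seed + 2)
        arch = TraitArchitecture("t", 80, target_h2=0.4)
        truth0 = simulate_qtl(geno, arch, seed=seed + 3)
        design = make_fixed_design(ped, seed=seed + 4)
        pheno, truth = simulate_phenotypes(
            truth0, arch, design, seed=seed + 5,
            sex_effect=sex_effect, cg_sd=cg_sd, age_slope=age_slope,
        )
        return ped, pheno, truth

    def test_near_identity_when_fixed_effects_absent(self):
        ped, pheno, _ = self._population(1, sex_effect=0.0, cg_sd=0.0, age_slope=0.0)
        res = correct_phenotypes(pheno, ped, "t")
        assert np.corrcoef(res.corrected, pheno["t"])[0, 1] > 0.99

    def test_sex_effect_removed(self):
        ped, pheno, _ = self._population(2, sex_effect=2.0, cg_sd=0.0, age_slope=0.0)
        raw_gap = (
            pheno.loc[pheno.sex == "M", "t"].mean()
            - pheno.loc[pheno.sex == "F", "t"].mean()
        )
        res = correct_phenotypes(pheno, ped, "t")
        yc = res.corrected
        gap = yc[pheno.sex.to_numpy() == "M"].mean() - yc[pheno.sex.to_numpy() == "F"].mean()
        assert abs(gap) < 0.1 * abs(raw_gap)

    def test_corrected_uncorrelated_with_true_fixed_effects(self):
        ped, pheno, truth = self._population(3)
        res = correct_phenotypes(pheno, ped, "t")
        r = np.corrcoef(res.corrected, truth.true_fixed_effects.loc[res.corrected.index])[0, 1]
        assert abs(r) < 0.08

    def test_unpedigreed_animal_rejected(self):
        ped, pheno, _ = self._population(4)
        bad = pheno.copy()
        bad.loc[0, "animal_id"] = "GHOST"
        with pytest.raises(ValueError, match="pedigree"):
            correct_phenotypes(bad, ped, "t")


class TestGblup:
    @staticmethod
    def _grm_and_yc(seed, n=150):
        ped = simulate_pedigree(n, 1, 2, seed=seed)
        mm = make_marker_map(600, 3, 100, seed=seed + 1)
        geno = simulate_genotypes(ped, mm, founder_ld_rho=0.3, seed=seed + 2)
        grm = build_grm(geno)
        arch = TraitArchitecture("t", 60, target_h2=0.4)
        truth0 = simulate_qtl(geno, arch, seed=seed + 3)
        design = make_fixed_design(ped, seed=seed + 4)
        pheno, _ = simulate_phenotypes(
            truth0, arch, design, seed=seed + 5,
            sex_effect=0.0, cg_sd=0.0, age_slope=0.0,
        )
        yc = pd.Series(pheno["t"].to_numpy(), index=list(geno.animal_ids))
        return grm, yc

    def test_zero_genetic_variance_gives_zero_gebv(self):
        grm, yc = self._grm_and_yc(1)
        from panelgp.models import VarianceComponents

        vc = VarianceComponents(0.0, 1.0, 0.0, True, 1)
        res = GBLUP(yc.iloc[:100], grm, vc=vc).fit()
        assert (res.gebv_table["gebv"] == 0).all()

    def test_duplicate_genomic_row_gets_equal_gebv(self):
        grm, yc = self._grm_and_yc(2)
        v = grm.values.copy()
        # make the last (validation) animal a genomic copy of animal 0
        v[-1, :] = v[0, :]
        v[:, -1] = v[:, 0]
        v[-1, -1] = v[0, 0]
        g2 = RelationshipMatrix(grm.ids, v, grm.kind)
        train = list(yc.index[:-1])
        res = GBLUP(yc.loc[train], g2).fit()
        gebv = res.gebv(list(grm.ids))
        assert gebv.iloc[-1] == pytest.approx(gebv.iloc[0], abs=1e-8)

    def test_training_gebvs_match_mme(self):
        grm, yc = self._grm_and_yc(3, n=100)
        train = list(yc.index[:100])
        fit = MixedModel(
            yc.loc[train].to_numpy(), np.ones((100, 1)), grm.subset(train).values
        ).fit()
        res = GBLUP(yc.loc[train], grm.subset(train), vc=fit.vc).fit()
        np.testing.assert_allclose(
            res.gebv(train).to_numpy(), fit.blups(), atol=1e-8
        )

    def test_validation_animal_missing_from_g_rejected(self):
        grm, yc = self._grm_and_yc(4)
        res = GBLUP(yc.iloc[:100], grm).fit()
        with pytest.raises(KeyError):
            res.gebv(["NOT_AN_ANIMAL"])
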