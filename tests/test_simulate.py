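"""Synthetic-population generator: pedigree, genotypes, annotation, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelgp import (
    TraitArchitecture,
    annotate_markers,
    make_fixed_design,
    make_marker_map,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_qtl,
)
from panelgp.simulate import DEFAULT_CLASS_WEIGHTS, TRAIT_SCALES
from panelgp.types import MISSING, UNKNOWN_PARENT

from conftest import genotypes_from_dosages


class TestPedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(10, 0, seed=1)
        assert len(ped) == 10
        assert (ped.table["sire_id"] == UNKNOWN_PARENT).all()
        assert (ped.table["dam_id"] == UNKNOWN_PARENT).all()
        assert set(ped.table["sex"]) == {"M", "F"}

    def test_forced_offspring_counts(self):
        ped = simulate_pedigree(2, 1, offspring_per_mating=3, seed=7)
        assert len(ped) == 5
        off = ped.table[ped.table["generation"] == 1]
        assert len(off) == 3
        assert (off["sire_id"] != UNKNOWN_PARENT).all()
        assert (off["dam_id"] != UNKNOWN_PARENT).all()

    def test_deterministic(self):
        a = simulate_pedigree(12, 2, 2, seed=42).table
        b = simulate_pedigree(12, 2, 2, seed=42).table
        pd.testing.assert_frame_equal(a, b)

    def test_single_sex_pool_errors(self):
        # 2 founders always get one of each sex by construction, so force
        # the failure through a generation whose offspring are all male
        with pytest.raises(ValueError, match="cannot mate|at least 2"):
            simulate_pedigree(1, 1, seed=0)

    def test_parents_precede_offspring(self):
        ped = simulate_pedigree(8, 3, 2, seed=5)
        seen = set()
        for r in ped.table.itertuples(index=False):
            for p in (r.sire_id, r.dam_id):
                assert p == UNKNOWN_PARENT or p in seen
            seen.add(r.animal_id)


class TestGenotypes:
    def test_no_ld_when_rho_zero(self):
        ped = simulate_pedigree(500, 0, seed=1)
        mm = make_marker_map(5000, 5, 100, seed=2)
        g = simulate_genotypes(ped, mm, founder_ld_rho=0.0, seed=3)
        d = g.dosages.astype(float)
        keep = d.std(axis=0) > 0
        d = d[:, keep]
        r = np.array(
            [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
        )
        assert abs(np.mean(r)) < 0.02

    def test_adjacent_correlation_tracks_rho_at_equal_frequency(self):
        ped = simulate_pedigree(600, 0, seed=1)
        mm = make_marker_map(2000, 2, 100, seed=2)
        # at MAF 0.5 every site shares the same allele frequency, where the
        # Markov copying process gives adjacent correlation exactly rho
        g = simulate_genotypes(
            ped, mm, founder_ld_rho=0.8, maf_spectrum=("uniform", 0.5, 0.5), seed=3
        )
        d = g.dosages.astype(float)
        r = np.array(
            [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] for j in range(d.shape[1] - 1)]
        )
        assert abs(np.mean(r) - 0.8) < 0.03

    def test_no_missing_by_default(self, small_genotypes):
        assert (small_genotypes.dosages != MISSING).all()

    def test_missing_rate_applied(self, small_pedigree):
        mm = make_marker_map(300, 2, 50, seed=9)
        g = simulate_genotypes(small_pedigree, mm, missing_rate=0.05, seed=10)
        frac = (g.dosages == MISSING).mean()
        assert 0.03 < frac < 0.07

    def test_deterministic(self, small_pedigree):
        mm = make_marker_map(200, 2, 50, seed=1)
        a = simulate_genotypes(small_pedigree, mm, seed=4)
        b = simulate_genotypes(small_pedigree, mm, seed=4)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_parent_offspring_ibs_exceeds_random_pairs(self):
        ped = simulate_pedigree(100, 1, 2, seed=8)
        mm = make_marker_map(1000, 2, 80, seed=9)
        g = simulate_genotypes(ped, mm, founder_ld_rho=0.3, seed=10)
        tab = ped.table
        idx = {a: i for i, a in enumerate(tab["animal_id"])}
        d = g.dosages.astype(float)

        def ibs(i, j):
            return np.mean(2 - np.abs(d[i] - d[j])) / 2

        rng = np.random.default_rng(0)
        po = [
            ibs(idx[r.animal_id], idx[r.sire_id])
            for r in tab.itertuples(index=False)
            if r.sire_id != UNKNOWN_PARENT
        ]
        rand = []
        founders = tab.loc[tab["generation"] == 0, "animal_id"].to_numpy()
        for _ in range(200):
            a, b = rng.choice(founders, 2, replace=False)
            rand.append(ibs(idx[a], idx[b]))
        assert np.mean(po) > np.mean(rand) + 0.01

    def test_mendelian_consistency_on_trios(self, small_pedigree, small_genotypes):
        tab = small_pedigree.table
        idx = {a: i for i, a in enumerate(tab["animal_id"])}
        d = small_genotypes.dosages
        trios = tab[(tab["sire_id"] != UNKNOWN_PARENT) & (tab["dam_id"] != UNKNOWN_PARENT)]
        for r in trios.itertuples(index=False):
            o, s, m = d[idx[r.animal_id]], d[idx[r.sire_id]], d[idx[r.dam_id]]
            # each parent transmits floor(g/2)..ceil(g/2) copies
            lo = s // 2 + m // 2
            hi = (s + 1) // 2 + (m + 1) // 2
            assert ((o >= lo) & (o <= hi)).all()

    def test_rho_bounds_validated(self, small_pedigree):
        mm = make_marker_map(10, 1, 10, seed=0)
        with pytest.raises(ValueError):
            simulate_genotypes(small_pedigree, mm, founder_ld_rho=1.0)
        with pytest.raises(ValueError):
            simulate_genotypes(small_pedigree, mm.iloc[:0])


class TestAnnotation:
    def test_single_class_weights(self):
        mm = make_marker_map(500, 2, 50, seed=1)
        out = annotate_markers(mm, {"IGR": 1.0}, seed=2)
        assert (out["anno_class"] == "IGR").all()

    def test_genome_survey_default_fractions(self):
        mm = make_marker_map(100_000, 10, 100, seed=3)
        out = annotate_markers(mm, seed=4)
        frac = (out["anno_class"] == "IGR").mean()
        expected = DEFAULT_CLASS_WEIGHTS["IGR"] / sum(DEFAULT_CLASS_WEIGHTS.values())
        assert abs(frac - expected) < 0.01

    def test_equal_weights_symmetry(self):
        mm = make_marker_map(50_000, 5, 100, seed=5)
        out = annotate_markers(mm, {c: 1 for c in DEFAULT_CLASS_WEIGHTS}, seed=6)
        fracs = out["anno_class"].value_counts(normalize=True)
        assert np.allclose(fracs, 0.2, atol=0.01)

    def test_chi2_goodness_of_fit(self):
        mm = make_marker_map(100_000, 10, 100, seed=7)
        out = annotate_markers(mm, seed=8)
        counts = out["anno_class"].value_counts()
        w = np.array([DEFAULT_CLASS_WEIGHTS[c] for c in counts.index], float)
        expected = w / w.sum() * len(out)
        chi2 = ((counts.to_numpy() - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=4) > 0.001

    def test_unknown_class_rejected(self):
        mm = make_marker_map(10, 1, 10, seed=0)
        with pytest.raises(ValueError, match="unknown"):
            annotate_markers(mm, {"EXON": 1.0})


class TestQtl:
    def test_zero_qtl_zero_tbv(self, small_genotypes):
        arch = TraitArchitecture("t", n_qtl=0)
        truth = simulate_qtl(small_genotypes, arch, seed=1)
        assert (truth.true_breeding_values == 0).all()

    def test_single_qtl_forced_arithmetic(self):
        g = genotypes_from_dosages([[0], [1], [2]])
        arch = TraitArchitecture("t", n_qtl=1, effect_dist=("normal", 1.0), target_h2=0.5)
        truth = simulate_qtl(g, arch, seed=3)
        eff = truth.qtl_effects[0]
        expected = np.array([0, 1, 2]) * eff
        np.testing.assert_allclose(
            truth.true_breeding_values.to_numpy(), expected - expected.mean()
        )

    def test_gamma_effects_heavier_tailed_than_normal(self, founder_population):
        _, g = founder_population
        norm = TraitArchitecture("t", 300, ("normal", 1.0), 0.5)
        gam = TraitArchitecture("t", 300, ("gamma", 0.4, 1.0), 0.5)
        e_n = np.abs(simulate_qtl(g, norm, seed=5).qtl_effects)
        e_g = np.abs(simulate_qtl(g, gam, seed=5).qtl_effects)
        e_n /= np.sqrt(np.mean(e_n**2))
        e_g /= np.sqrt(np.mean(e_g**2))
        # at equal total variance the gamma(0.4) architecture has more mass
        # in the extreme quantiles
        assert np.quantile(e_g, 0.99) > np.quantile(e_n, 0.99)

    def test_too_many_qtl_rejected(self):
        g = genotypes_from_dosages([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="polymorphic"):
            simulate_qtl(g, TraitArchitecture("t", 5), seed=0)

    def test_region_enrichment_biases_sampling(self, founder_population):
        _, g = founder_population
        g2 = g.subset_markers(g.marker_ids)
        cls = np.array(["IGR", "NSY"])[np.arange(g2.n_markers) % 2]
        g2.markers["anno_class"] = cls
        arch = TraitArchitecture("t", 200, target_h2=0.5)
        truth = simulate_qtl(g2, arch, {"NSY": 50.0, "IGR": 1.0}, seed=9)
        chosen = g2.markers.set_index("marker_id").loc[truth.qtl_ids, "anno_class"]
        assert (chosen == "NSY").mean() > 0.8


class TestPhenotypes:
    @pytest.fixture(scope="class")
    @staticmethod
    def big_founders():
        ped = simulate_pedigree(2000, 0, seed=21)
        mm = make_marker_map(1000, 5, 80, seed=22)
        return ped, simulate_genotypes(ped, mm, founder_ld_rho=0.2, seed=23)

    def test_realized_h2_near_target(self, big_founders):
        ped, g = big_founders
        arch = TraitArchitecture("t", 100, target_h2=0.5)
        truth0 = simulate_qtl(g, arch, seed=1)
        design = make_fixed_design(ped, seed=2)
        _, truth = simulate_phenotypes(truth0, arch, design, seed=3)
        assert 0.45 < truth.realized_h2 < 0.55

    def test_phenotype_variance_decomposition_without_fixed_effects(self, big_founders):
        ped, g = big_founders
        arch = TraitArchitecture("t", 100, target_h2=0.4)
        truth0 = simulate_qtl(g, arch, seed=4)
        design = make_fixed_design(ped, seed=5)
        pheno, truth = simulate_phenotypes(
            truth0, arch, design, seed=6, sex_effect=0.0, cg_sd=0.0, age_slope=0.0
        )
        r2 = np.corrcoef(pheno["t"], truth.true_breeding_values)[0, 1] ** 2
        assert abs(r2 - truth.realized_h2) < 0.03

    def test_marbling_score_scale(self, big_founders):
        ped, g = big_founders
        mean, sd = TRAIT_SCALES["MS"]
        arch = TraitArchitecture("MS", 100, target_h2=0.40, pheno_mean=mean, pheno_sd=sd)
        truth0 = simulate_qtl(g, arch, seed=7)
        design = make_fixed_design(ped, seed=8)
        pheno, _ = simulate_phenotypes(truth0, arch, design, seed=9)
        n = len(pheno)
        assert abs(pheno["MS"].mean() - mean) < 3 * sd / np.sqrt(n)
        # SD of the sample SD is approximately sd / sqrt(2 n)
        assert abs(pheno["MS"].std() - sd) < 3 * sd / np.sqrt(2 * n)

    def test_degenerate_h2_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture("t", 10, target_h2=1.0)
        with pytest.raises(ValueError):
            TraitArchitecture("t", 10, target_h2=0.0)
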