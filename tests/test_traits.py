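"""Trait architecture, residual structure and phenotype generation."""

import dataclasses

import numpy as np
import pytest

from layersim.genome import FEMALE, MALE, Haplotype, Individual, sample_founders
from layersim.traits import (TRAITS_AGE_51, TRAITS_AGE_72, TraitArchitecture,
                             TraitParams, assign_tbv, build_architecture,
                             genetic_covariance, nearest_psd_correlation,
                             record_phenotypes, record_phenotypes_batch,
                             residual_correlations, true_breeding_values)


def _params_with(**overrides) -> TraitParams:
    base = TraitParams()
    return dataclasses.replace(base, **overrides)


class TestResidualCorrelations:
    def test_reference_pair_value(self, params):
        # traits 1,2: h2=(0.35,0.10), rG=0.16, rP=0.06 plug into
        # (rP - rG sqrt(h2 h2')) / sqrt((1-h2)(1-h2')) = 0.0393
        rE = residual_correlations(params)
        assert rE[0, 1] == pytest.approx(0.0393, abs=2e-4)
        assert rE[1, 0] == rE[0, 1]
        np.testing.assert_allclose(np.diag(rE), 1.0)

    def test_low_heritability_limit_recovers_rP(self, params):
        p = _params_with(h2=np.full(9, 1e-6))
        rE = residual_correlations(p)
        off = ~np.eye(9, dtype=bool)
        np.testing.assert_allclose(rE[off], p.rP[off], atol=1e-4)

    def test_algebraic_zero(self, params):
        # rP exactly equal to the genetic co-heritability term -> rE = 0
        h2 = params.h2
        rp = params.rG * np.sqrt(np.outer(h2, h2))
        np.fill_diagonal(rp, 1.0)
        rE = residual_correlations(_params_with(rP=rp))
        off = ~np.eye(9, dtype=bool)
        np.testing.assert_allclose(rE[off], 0.0, atol=1e-10)

    def test_result_is_psd(self, params):
        rE = residual_correlations(params)
        assert np.linalg.eigvalsh(rE).min() > -1e-10

    def test_nearest_psd_projection(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        fixed = nearest_psd_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)


class TestArchitecture:
    def test_effect_correlations_recover_rG(self, params):
        # 10^4 QTL draws: empirical correlation of the Cholesky-mixed
        # effect columns within +-0.05 of the target matrix
        rng = np.random.default_rng(3)
        z = rng.standard_normal((10_000, 9))
        L = np.linalg.cholesky(params.rG)
        emp = np.corrcoef((z @ L.T).T)
        assert np.max(np.abs(emp - params.rG)) < 0.05

    def test_identity_rG_gives_independent_effects(self, small_map):
        rng = np.random.default_rng(4)
        p = _params_with(rG=np.eye(9))
        pool = sample_founders(small_map, 10, 10, rng)
        arch = build_architecture(small_map, p, pool.all, 30, rng)
        emp = np.corrcoef(arch.effects.T)
        off = ~np.eye(9, dtype=bool)
        assert np.max(np.abs(emp[off])) < 0.5  # 30 draws, loose bound

    def test_tbv_correlations_recover_rG(self, params):
        # base of unrelated founders (zero LD), 10^4 QTL so that the
        # finite-QTL draw contributes negligible correlation noise;
        # remaining deviation is animal sampling (SE ~ 1/sqrt(n))
        from layersim.genome import build_genetic_map

        rng = np.random.default_rng(5)
        gmap = build_genetic_map(5, 2000, 1.0, rng)
        pool = sample_founders(gmap, 1000, 1000, rng)
        arch = build_architecture(gmap, params, pool.all, 10_000, rng)
        assign_tbv(pool.all, arch)
        emp = np.corrcoef(np.stack([i.tbv for i in pool.all]).T)
        assert np.max(np.abs(emp - params.rG)) < 0.08

    def test_variance_calibration_and_centering(self, small_map, params, rng):
        pool = sample_founders(small_map, 20, 20, rng)
        arch = build_architecture(small_map, params, pool.all, 40, rng)
        assign_tbv(pool.all, arch)
        tbv = np.stack([i.tbv for i in pool.all])
        np.testing.assert_allclose(tbv.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tbv.var(axis=0, ddof=0),
                                   params.h2 * params.sdP**2, rtol=1e-6)

    def test_too_many_qtl_rejected(self, small_map, params, rng):
        pool = sample_founders(small_map, 2, 2, rng)
        with pytest.raises(ValueError):
            build_architecture(small_map, params, pool.all,
                               small_map.n_loci + 1, rng)

    def test_hand_built_two_qtl_score(self):
        # dosages (1, 2), effects (0.5, -0.25): raw score 0.5 - 0.5 = 0
        arch = TraitArchitecture(
            qtl_indices=np.array([0, 1]),
            effects=np.array([[0.5], [-0.25]]),
            scale=np.ones(1), intercept=np.zeros(1),
        )
        hp = Haplotype(np.array([1, 1], np.uint8), np.array([0.0]),
                       np.array([0], np.int64))
        hm = Haplotype(np.array([0, 1], np.uint8), np.array([0.0]),
                       np.array([1], np.int64))
        ind = Individual(1, MALE, 0.0, None, None, hp, hm)
        assert true_breeding_values(ind, arch)[0] == pytest.approx(0.0)

    def test_zero_effects_give_zero_tbv(self):
        arch = TraitArchitecture(
            qtl_indices=np.array([0, 1]),
            effects=np.zeros((2, 1)), scale=np.ones(1), intercept=np.zeros(1),
        )
        hp = Haplotype(np.array([1, 0], np.uint8), np.array([0.0]),
                       np.array([0], np.int64))
        ind = Individual(1, FEMALE, 0.0, None, None, hp, hp)
        assert true_breeding_values(ind, arch)[0] == 0.0

    def test_mendelian_sampling_mean_zero(self, small_map, params):
        from layersim.genome import make_offspring

        rng = np.random.default_rng(6)
        pool = sample_founders(small_map, 10, 10, rng)
        arch = build_architecture(small_map, params, pool.all, 40, rng)
        assign_tbv(pool.all, arch)
        sire, dam = pool.males[0], pool.females[0]
        kids = [make_offspring(1000 + k, sire, dam, MALE, 0.0, small_map, rng)
                for k in range(600)]
        assign_tbv(kids, arch)
        mendelian = (np.stack([k.tbv for k in kids])
                     - 0.5 * (sire.tbv + dam.tbv))
        # per-trait mean deviation small relative to the genetic SD
        sd_a = np.sqrt(params.h2) * params.sdP
        assert np.all(np.abs(mendelian.mean(axis=0)) < 0.2 * sd_a)


def _hen(hid, tbv, birth_week=0.0):
    hp = Haplotype(np.zeros(1, np.uint8), np.array([0.0]), np.array([0]))
    ind = Individual(hid, FEMALE, birth_week, None, None, hp, hp)
    ind.tbv = tbv
    return ind


class TestPhenotypes:
    def test_record_structure(self, params):
        rng = np.random.default_rng(0)
        rE = residual_correlations(params)
        hen = _hen(1, np.zeros(9), birth_week=10.0)
        early = record_phenotypes(hen, params, rE, 51.0, rng)
        late = record_phenotypes(hen, params, rE, 72.0, rng)
        assert [r.trait for r in early] == list(TRAITS_AGE_51)
        assert [r.trait for r in late] == list(TRAITS_AGE_72)
        assert all(r.recorded_week == 61.0 for r in early)
        assert all(r.recorded_week == 82.0 for r in late)
        both = set(TRAITS_AGE_51) & set(TRAITS_AGE_72)
        assert both == {4, 5, 6, 7, 8}  # five traits measured twice

    def test_males_have_no_phenotypes(self, params):
        rng = np.random.default_rng(0)
        hp = Haplotype(np.zeros(1, np.uint8), np.array([0.0]), np.array([0]))
        male = Individual(1, MALE, 0.0, None, None, hp, hp, tbv=np.zeros(9))
        with pytest.raises(ValueError, match="females only"):
            record_phenotypes(male, params, residual_correlations(params),
                              51.0, rng)

    def test_zero_residual_variance_returns_tbv(self):
        # h2 = 1 for every trait removes the residual entirely
        p = _params_with(h2=np.ones(9), rG=np.eye(9), rP=np.eye(9))
        rng = np.random.default_rng(0)
        tbv = np.arange(9, dtype=float)
        recs = record_phenotypes(_hen(1, tbv), p, residual_correlations(p),
                                 51.0, rng)
        for r in recs:
            assert r.value == pytest.approx(tbv[r.trait], abs=1e-4)

    def test_repeated_records_have_independent_residuals(self, params):
        rng = np.random.default_rng(1)
        rE = residual_correlations(params)
        hens = [_hen(i, np.zeros(9)) for i in range(3000)]
        early = record_phenotypes_batch(hens, params, rE, 51.0, rng)
        late = record_phenotypes_batch(hens, params, rE, 72.0, rng)
        e51 = {r.owner: r.value for r in early if r.trait == 4}  # egg weight
        e72 = {r.owner: r.value for r in late if r.trait == 4}
        pairs = np.array([[e51[h.id], e72[h.id]] for h in hens])
        r = np.corrcoef(pairs.T)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(hens))

    def test_same_age_phenotypic_correlations_recover_rP(self, params):
        # tbv ~ MVN(0, C): phenotypic correlations of same-age records
        # converge to the target rP by construction of rE
        rng = np.random.default_rng(2)
        C = genetic_covariance(params)
        tbvs = rng.multivariate_normal(np.zeros(9), C, size=4000)
        hens = [_hen(i, tbvs[i]) for i in range(4000)]
        recs = record_phenotypes_batch(hens, params,
                                       residual_correlations(params), 51.0, rng)
        mat = np.zeros((4000, 9))
        for r in recs:
            mat[r.owner, r.trait] = r.value
        idx = np.array(TRAITS_AGE_51)
        emp = np.corrcoef(mat[:, idx].T)
        target = params.rP[np.ix_(idx, idx)]
        off = ~np.eye(len(idx), dtype=bool)
        assert np.max(np.abs(emp[off] - target[off])) < 0.06

    def test_realized_heritability(self, params):
        # var(tbv) / var(phenotype) per trait matches the h2 diagonal
        rng = np.random.default_rng(3)
        C = genetic_covariance(params)
        tbvs = rng.multivariate_normal(np.zeros(9), C, size=4000)
        hens = [_hen(i, tbvs[i]) for i in range(4000)]
        recs = record_phenotypes_batch(hens, params,
                                       residual_correlations(params), 51.0, rng)
        for t in TRAITS_AGE_51:
            y = np.array([r.value for r in recs if r.trait == t])
            g = tbvs[:, t]
            h2_hat = g.var() / y.var()
            assert h2_hat == pytest.approx(params.h2[t], abs=0.05)


class TestParameterIO:
    def test_trait_params_yaml_roundtrip(self, params, tmp_path):
        from layersim.traits import load_trait_params, save_trait_params

        path = tmp_path / "traits.yaml"
        save_trait_params(params, path)
        loaded = load_trait_params(path)
        np.testing.assert_allclose(loaded.h2, params.h2)
        np.testing.assert_allclose(loaded.sdP, params.sdP)
        np.testing.assert_allclose(loaded.ew, params.ew)
        np.testing.assert_allclose(loaded.rG, params.rG)
        np.testing.assert_allclose(loaded.rP, params.rP)
        assert loaded.names == params.names

    def test_phenotype_csv_export(self, params, tmp_path):
        from layersim.traits import write_phenotypes_csv

        rng = np.random.default_rng(0)
        hen = _hen(7, np.zeros(9))
        hen.phenotypes = record_phenotypes(hen, params,
                                           residual_correlations(params),
                                           51.0, rng)
        path = tmp_path / "phen.csv"
        write_phenotypes_csv(path, [hen])
        lines = path.read_text().strip().split("\n")
        assert lines[0] == "id,trait,week,value"
        assert len(lines) == 1 + len(TRAITS_AGE_51)
        assert lines[1].startswith("7,laying_performance_1,51,")
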