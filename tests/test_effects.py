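"""Genotypic means, pattern classification, dominance geometry, crossing tests."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ailqtl
from ailqtl.effects import (classify_pattern, crossing_test,
                            differential_dominance, dominance_ratio,
                            effects_from_means, genotypic_means,
                            standardize_cohorts)
from ailqtl.simulate import QtlLocus, TraitModel, assign_cohorts, simulate_phenotypes


class TestGenotypicMeans:
    def test_balanced_no_covariates_equal_raw_averages(self):
        rng = np.random.default_rng(0)
        classes = np.repeat(["LL", "LS", "SL", "SS"], 25)
        y = rng.standard_normal(100) + (classes == "LL") * 2.0
        sex = np.array(["F"] * 100)
        diet = np.array(["HF"] * 100)
        gm = genotypic_means(y, classes, sex, diet, ("F", "HF"))
        for c in ("LL", "LS", "SL", "SS"):
            assert gm.means[c] == pytest.approx(y[classes == c].mean())

    def test_constant_trait_gives_zero_effects(self):
        classes = np.repeat(["LL", "LS", "SL", "SS"], 10)
        y = np.full(40, 3.3)
        sex = np.array(["F", "M"] * 20)
        diet = np.array(["HF"] * 40)
        gm = genotypic_means(y, classes, sex, diet, ("all",))
        a, d, i = effects_from_means(gm.means)
        assert (a, d, i) == pytest.approx((0.0, 0.0, 0.0), abs=1e-10)

    def test_adjusted_means_recover_simulated_genotypic_values(self, qtl_study):
        locus = QtlLocus(1, 20.0, {(s, d): (0.8, 0.3, 0.0)
                                   for s in "FM" for d in ("HF", "LF")})
        tm = TraitModel(mean=1.0, sex_effect=1.5, diet_effect=-0.8,
                        loci=[locus], var_residual=0.15)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        ph = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=3)
        mi = qtl_study.map.nearest_marker(1, 20.0)
        classes = qtl_study.genotypes.genotype_strings(mi)
        gm = genotypic_means(ph["y"].to_numpy(), classes,
                             ph["sex"].to_numpy(), ph["diet"].to_numpy())
        eff = gm.effect_table().set_index("effect")
        assert abs(eff.loc["a", "estimate"] - 0.8) < 2 * eff.loc["a", "se"]
        assert abs(eff.loc["d", "estimate"] - 0.3) < 2 * eff.loc["d", "se"]
        assert abs(eff.loc["i", "estimate"]) < 3 * eff.loc["i", "se"]

    def test_empty_cell_flagged(self):
        classes = np.repeat(["LL", "LS", "SS"], 10)  # no SL
        y = np.arange(30.0)
        sex = np.array(["F"] * 30)
        diet = np.array(["HF"] * 30)
        gm = genotypic_means(y, classes, sex, diet, ("F", "HF"))
        assert gm.missing == ["SL"]


# noise-free genotypic-mean fixtures for every pattern label:
# (G_LL, G_LS, G_SL, G_SS) -> expected label
PATTERN_FIXTURES = [
    ((1, 0, 0, -1), "additive"),
    ((1, 1, 1, -1), "L-dominant"),
    ((1, -1, -1, -1), "S-dominant"),
    ((0, 1, 1, 0), "overdominant"),
    ((0, -1, -1, 0), "underdominant"),
    ((1, -1, 1, -1), "maternal-expression"),   # phenotype tracks maternal allele
    ((1, 1, -1, -1), "paternal-expression"),   # phenotype tracks paternal allele
    ((0, 1, 0, 0), "polar-dominance"),         # one heterozygote deviates
    ((0, 1, -1, 0), "bipolar-dominance"),      # reciprocal hets deviate oppositely
    ((0, 0, 0, 0), "none"),
]


@pytest.mark.parametrize("means,expected", PATTERN_FIXTURES)
def test_pattern_classification_noise_free(means, expected):
    g = dict(zip(("LL", "LS", "SL", "SS"), map(float, means)))
    a, d, i = effects_from_means(g)
    pa, pd_, pi = (0.0 if abs(v) > 1e-9 else 1.0 for v in (a, d, i))
    label, flags = classify_pattern(a, d, i, pa, pd_, pi)
    assert label == expected
    assert not flags


def test_multi_pattern_conflict_is_flagged():
    # a, d, i all significant with |d/a| >> 1: dominance label + flag
    label, flags = classify_pattern(0.2, 1.5, 0.4, 0.01, 0.001, 0.02)
    assert label in ("overdominant", "underdominant")
    assert "multi-pattern" in flags


class TestDominanceRatio:
    def test_plain_ratios(self):
        assert dominance_ratio(1.0, 0.0) == 0.0
        assert dominance_ratio(-1.0, 0.9) == pytest.approx(-0.9)
        assert dominance_ratio(0.5, 0.6) == pytest.approx(1.2)

    def test_withheld_without_significant_additivity(self):
        assert np.isnan(dominance_ratio(0.5, 0.6, p_a=0.4))


class TestDifferentialDominance:
    def test_parallel_vectors_no_differential_dominance(self):
        geom = differential_dominance([1.0, 2.0], [0.5, 1.0])
        assert not geom.differential
        assert geom.weights is None

    def test_orthogonal_projection_example(self):
        geom = differential_dominance([1.0, 1.0], [1.0, -1.0])
        assert geom.differential
        assert np.allclose(np.abs(geom.weights), 1 / np.sqrt(2))
        assert geom.synthetic_a == pytest.approx(0.0, abs=1e-12)
        assert abs(geom.synthetic_d) == pytest.approx(np.sqrt(2))

    def test_antagonistic_pleiotropy_flagged(self):
        geom = differential_dominance([0.6, -0.5], [-0.54, 0.6],
                                      sd=[1.2, 0.8])
        assert geom.antagonistic

    def test_weights_orthogonal_to_additive_axis(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.standard_normal(4)
            d = rng.standard_normal(4)
            geom = differential_dominance(a, d)
            if geom.weights is not None:
                assert geom.weights @ geom.additive == pytest.approx(0, abs=1e-9)


class TestStandardizeCohorts:
    def test_single_cohort_reduces_to_centering_and_rescale(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50) * 3 + 7
        out = standardize_cohorts(x, np.zeros(50, int))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(x.std(ddof=1))

    def test_equal_sds_pure_centering(self):
        x = np.r_[np.arange(10.0), np.arange(10.0) + 100]
        coh = np.r_[np.zeros(10, int), np.ones(10, int)]
        out = standardize_cohorts(x, coh)
        assert np.allclose(out[:10], out[10:])
        assert np.allclose(out[:10], np.arange(10.0) - 4.5)

    @given(st.integers(0, 2**31 - 1))
    def test_all_cohorts_get_pooled_sd(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 20, size=4)
        coh = np.repeat(np.arange(4), sizes)
        x = rng.standard_normal(len(coh)) * rng.uniform(0.5, 5, 4)[coh] \
            + rng.uniform(-3, 3, 4)[coh]
        out = standardize_cohorts(x, coh)
        sds = [out[coh == k].std(ddof=1) for k in range(4)]
        assert np.allclose(sds, sds[0])
        for k in range(4):
            assert out[coh == k].mean() == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_cohort_named(self):
        x = np.r_[np.ones(5), np.arange(5.0)]
        coh = np.r_[np.zeros(5, int), np.ones(5, int)]
        with pytest.raises(ValueError, match="0"):
            standardize_cohorts(x, coh)


@pytest.fixture(scope="module")
def base(qtl_study):
    ph = qtl_study.phenotypes
    model = ailqtl.FamilyVarianceModel(ph["family"], ph["sex"], ph["diet"])
    mi = qtl_study.map.nearest_marker(1, 20.0)
    p = qtl_study.genotypes.paternal[:, mi].astype(float)
    m = qtl_study.genotypes.maternal[:, mi].astype(float)
    triplet = (p + m - 1.0, (p != m).astype(float), p - m)
    return qtl_study, model, triplet


class TestCrossing:
    def _simulate(self, study, effects_by_cohort, seed):
        locus = QtlLocus(1, 20.0, {c: (a, 0.0, 0.0)
                                   for c, a in effects_by_cohort.items()})
        tm = TraitModel(loci=[locus], var_family=0.05, var_residual=0.4)
        coh = study.phenotypes[["animal", "family", "sex", "diet"]]
        return simulate_phenotypes(study.genotypes, coh, {"y": tm},
                                   seed=seed)["y"].to_numpy()

    def test_sign_flip_interaction_is_crossing(self, base):
        study, model, triplet = base
        eff = {("F", "HF"): 0.8, ("F", "LF"): 0.8,
               ("M", "HF"): -0.8, ("M", "LF"): -0.8}
        y = self._simulate(study, eff, seed=41)
        res = crossing_test(y, triplet, study.phenotypes, model)
        assert res.verdict == "crossing"
        assert res.opposite_ranks_std

    def test_scale_only_interaction_is_spreading(self, base):
        study, model, triplet = base
        eff = {("F", "HF"): 1.4, ("F", "LF"): 1.4,
               ("M", "HF"): 0.25, ("M", "LF"): 0.25}
        y = self._simulate(study, eff, seed=43)
        res = crossing_test(y, triplet, study.phenotypes, model)
        assert res.verdict == "spreading"

    def test_identical_cohorts_no_interaction(self, base):
        study, model, triplet = base
        eff = {c: 0.5 for c in ailqtl.COHORTS}
        y = self._simulate(study, eff, seed=47)
        res = crossing_test(y, triplet, study.phenotypes, model)
        assert res.verdict == "none"

    def test_verdict_invariant_to_per_cohort_affine_rescale(self, base):
        """Cohort-wise affine transforms must not change the verdict —
        exactly what the standardization is for."""
        study, model, triplet = base
        eff = {("F", "HF"): 0.8, ("F", "LF"): 0.8,
               ("M", "HF"): -0.8, ("M", "LF"): -0.8}
        y = self._simulate(study, eff, seed=53)
        ph = study.phenotypes
        scale = np.where(ph["sex"] == "F", 3.0, 0.7)
        shift = np.where(ph["diet"] == "HF", 10.0, -5.0)
        res1 = crossing_test(y, triplet, ph, model)
        res2 = crossing_test(y * scale + shift, triplet, ph, model)
        assert res1.verdict == res2.verdict == "crossing"
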