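"""Breeding-design, gene-dropping and phenotype-generation behavior."""

import numpy as np
import pandas as pd
import pytest

import ailqtl
from ailqtl.simulate import (DesignError, QtlLocus, TraitModel, build_pedigree,
                             drop_genotypes, assign_cohorts, haldane,
                             simulate_phenotypes, validate_pedigree)


class TestPedigree:
    def test_ail_rule_one_breeder_per_sex_per_family(self):
        ped = build_pedigree(10, 30, 6, 5, seed=2)
        validate_pedigree(ped)
        by_id = ped.set_index("id")
        # once at full size, each family contributes exactly one sire and one dam
        for gen in range(3, 7):
            kids = ped[ped["generation"] == gen]
            pairs = kids[["sire", "dam"]].drop_duplicates()
            for col in ("sire", "dam"):
                fams = by_id.loc[pairs[col], "family"]
                assert not fams.duplicated().any()

    def test_final_generation_census(self):
        ped = build_pedigree(10, 30, 6, 5, seed=2)
        final = ped[ped["generation"] == 6]
        assert len(final) == 30 * 5
        assert final["family"].nunique() == 30

    def test_same_seed_identical_pedigree(self):
        a = build_pedigree(10, 30, 6, 5, seed=3)
        b = build_pedigree(10, 30, 6, 5, seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = build_pedigree(10, 30, 6, 5, seed=4)
        assert not a.equals(c)

    def test_minimal_design_needs_sib_mating_flag(self):
        with pytest.raises(DesignError):
            build_pedigree(1, 1, 2, 4)
        ped = build_pedigree(1, 1, 2, 4, allow_sib_mating=True)
        assert (ped["generation"] == 0).sum() == 2
        assert (ped["generation"] == 2).sum() == 4

    def test_bad_counts_rejected(self):
        with pytest.raises(DesignError):
            build_pedigree(0, 10, 5, 5)
        with pytest.raises(DesignError):
            build_pedigree(5, 10, 1, 5)


class TestGeneDropping:
    def test_mendelian_consistency(self, qtl_study):
        """Every transmitted allele is carried by the designated parent."""
        ped = qtl_study.pedigree
        geno = drop_genotypes(ped, qtl_study.map, seed=7)
        row = {int(a): i for i, a in enumerate(geno.animals)}
        kids = ped[ped["generation"] > 0].sample(200, random_state=0)
        for _, kid in kids.iterrows():
            k = row[int(kid["id"])]
            s, d = row[int(kid["sire"])], row[int(kid["dam"])]
            pat_ok = (geno.paternal[k] == geno.paternal[s]) | \
                     (geno.paternal[k] == geno.maternal[s])
            mat_ok = (geno.maternal[k] == geno.paternal[d]) | \
                     (geno.maternal[k] == geno.maternal[d])
            assert pat_ok.all() and mat_ok.all()

    def test_zero_distance_markers_never_recombine(self):
        frame = pd.DataFrame({"chrom": [1, 1], "marker": ["m1", "m2"],
                              "cm": [0.0, 1e-9], "bp": [1, 2]})
        gmap = ailqtl.GeneticMap(frame)
        ped = build_pedigree(1, 1, 3, 300, seed=5, allow_sib_mating=True)
        geno = drop_genotypes(ped, gmap, seed=5, keep="final")
        assert np.array_equal(geno.paternal[:, 0], geno.paternal[:, 1])
        assert np.array_equal(geno.maternal[:, 0], geno.maternal[:, 1])

    def test_recombinant_fraction_matches_haldane(self):
        """50 cM apart: recombinant gametes at (1-e^-1)/2 ~ 0.316."""
        frame = pd.DataFrame({"chrom": [1, 1], "marker": ["m1", "m2"],
                              "cm": [0.0, 50.0], "bp": [1, 2]})
        gmap = ailqtl.GeneticMap(frame)
        # F2 gametes come from fully heterozygous F1 parents
        ped = build_pedigree(1, 1, 2, 4000, seed=5, allow_sib_mating=True)
        geno = drop_genotypes(ped, gmap, seed=5, keep="final")
        rec = np.concatenate([geno.paternal[:, 0] != geno.paternal[:, 1],
                              geno.maternal[:, 0] != geno.maternal[:, 1]])
        expected = float(haldane(50.0))
        assert rec.mean() == pytest.approx(expected, abs=0.02)
        assert expected == pytest.approx((1 - np.exp(-1)) / 2, abs=1e-12)

    def test_f1_fully_heterozygous_paternal_from_sire_strain(self, small_map):
        ped = build_pedigree(5, 5, 2, 3, seed=1, allow_sib_mating=True)
        geno = drop_genotypes(ped, small_map, seed=1)
        f1_ids = ped.loc[ped["generation"] == 1, "id"]
        row = {int(a): i for i, a in enumerate(geno.animals)}
        for fid in f1_ids:
            k = row[int(fid)]
            assert (geno.paternal[k] == 0).all()  # sires are S strain
            assert (geno.maternal[k] == 1).all()  # dams are L strain

    def test_same_seed_identical_genotypes(self, qtl_study):
        a = drop_genotypes(qtl_study.pedigree, qtl_study.map, seed=9)
        b = drop_genotypes(qtl_study.pedigree, qtl_study.map, seed=9)
        assert np.array_equal(a.paternal, b.paternal)
        assert np.array_equal(a.maternal, b.maternal)


class TestCohortsAndPhenotypes:
    def test_cohort_balance_within_family(self, qtl_study):
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        for (fam, sex), sub in coh.groupby(["family", "sex"]):
            counts = sub["diet"].value_counts()
            assert abs(counts.get("HF", 0) - counts.get("LF", 0)) <= 1
        # family size >= 4 with both sexes: all four cohorts present
        sizes = coh.groupby("family").size()
        for fam in sizes[sizes >= 6].index:
            sub = coh[coh["family"] == fam]
            assert len(sub.groupby(["sex", "diet"])) == 4

    def test_zero_architecture_gives_constant_trait(self, qtl_study):
        tm = TraitModel(mean=2.5, var_residual=0.0)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        ph = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=1)
        assert np.allclose(ph["y"], 2.5)

    def test_additive_effect_separates_homozygotes_by_2a(self, qtl_study):
        locus = QtlLocus(1, 20.0, {(s, d): (1.0, 0.0, 0.0)
                                   for s in "FM" for d in ("HF", "LF")})
        tm = TraitModel(loci=[locus], var_residual=0.0)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        ph = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=1)
        mi = qtl_study.map.nearest_marker(1, 20.0)
        cls = qtl_study.genotypes.genotype_strings(mi)
        y = ph["y"].to_numpy()
        assert y[cls == "LL"].mean() - y[cls == "SS"].mean() == pytest.approx(2.0)
        assert y[cls == "LS"].mean() == pytest.approx(y[cls == "SL"].mean())

    def test_cohort_specific_imprinting_effect(self, qtl_study):
        locus = QtlLocus(1, 20.0, {("F", "HF"): (0.0, 0.0, 1.0)})
        tm = TraitModel(loci=[locus], var_residual=0.0)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        ph = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=1)
        mi = qtl_study.map.nearest_marker(1, 20.0)
        cls = qtl_study.genotypes.genotype_strings(mi)
        y = ph["y"].to_numpy()
        inside = (ph["sex"] == "F") & (ph["diet"] == "HF")
        m = inside.to_numpy()
        assert (y[m & (cls == "LS")].mean()
                - y[m & (cls == "SL")].mean()) == pytest.approx(2.0)
        assert np.allclose(y[~m], 0.0)  # untouched cohorts

    def test_negative_variance_rejected(self, qtl_study):
        tm = TraitModel(var_family=-0.1)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        with pytest.raises(ValueError, match="variance"):
            simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=1)

    def test_same_seed_identical_phenotypes(self, qtl_study):
        tm = TraitModel(var_family=0.2, var_residual=1.0)
        coh = assign_cohorts(qtl_study.pedigree, seed=7)
        a = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=5)
        b = simulate_phenotypes(qtl_study.genotypes, coh, {"y": tm}, seed=5)
        pd.testing.assert_frame_equal(a, b)


def test_heterozygosity_decay_matches_effective_size():
    """Mean heterozygosity at unlinked loci declines at ~1/(2Ne) per
    generation, with Ne ~ 2x census under the equalized-contribution rule."""
    n_loci, n_fams = 300, 10  # census 20 -> Ne ~ 40
    frame = pd.DataFrame({"chrom": np.arange(n_loci),
                          "marker": [f"m{i}" for i in range(n_loci)],
                          "cm": 0.0, "bp": 1})
    gmap = ailqtl.GeneticMap(frame)
    ped = build_pedigree(n_fams, n_fams, 12, 4, seed=5)
    geno = drop_genotypes(ped, gmap, seed=5)
    gens = ped.sort_values(["generation", "id"], kind="stable")["generation"]
    gens = gens.to_numpy()
    # decay regime starts at F2 (F1 is fully heterozygous by construction)
    het = np.array([(geno.paternal[gens == g] != geno.maternal[gens == g]).mean()
                    for g in range(2, 13)])
    slope = np.polyfit(np.arange(2, 13), np.log(het), 1)[0]
    expected = np.log(1 - 1 / (2 * 2 * 2 * n_fams))  # log(1 - 1/(2*Ne))
    assert expected * 2.0 < slope < expected * 0.5


class TestEffectiveSize:
    def test_wright_fisher_baseline_near_census(self):
        est = ailqtl.estimate_effective_size(75, 10, 10, 10,
                                             design="wright_fisher", seed=2)
        assert est.ne == pytest.approx(150, rel=0.20)

    def test_equalized_contributions_double_ne(self):
        small = ailqtl.estimate_effective_size(20, 10, 10, 10, seed=2)
        assert small.ne == pytest.approx(80, rel=0.30)
        assert small.se > 0 and small.n_transitions > 0

    def test_single_pair_estimate_is_finite(self):
        est = ailqtl.estimate_effective_size(1, 4, 30, 10, seed=2)
        assert np.isfinite(est.ne) and est.ne > 0

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            ailqtl.estimate_effective_size(10, 5, 5, 1)
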