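import pytest
from hypothesis import HealthCheck, settings

import ailqtl
from ailqtl.simulate import QtlLocus, TraitModel

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 6 markers at 10 cM spacing."""
    return ailqtl.uniform_map(2, 6, 10.0)


@pytest.fixture(scope="session")
def qtl_study(small_map):
    """A moderate AIL study with one uniform additive QTL on chromosome 1."""
    locus = QtlLocus(1, 20.0, {(s, d): (0.5, 0.0, 0.0)
                               for s in "FM" for d in ("HF", "LF")})
    tm = TraitModel(mean=3.0, sex_effect=0.4, diet_effect=0.6, loci=[locus],
                    var_family=0.15, var_family_sex=0.05,
                    var_family_diet=0.05, var_residual=1.0)
    return ailqtl.simulate_study({"t1": tm}, small_map, n_families=40,
                                 n_generations=8, final_family_size=6, seed=7)


@pytest.fixture(scope="session")
def family_model(qtl_study):
    ph = qtl_study.phenotypes
    return ailqtl.FamilyVarianceModel(ph["family"], ph["sex"], ph["diet"])


def null_study(seed, n_families=40, final_family_size=6, n_generations=8,
               gmap=None, n_traits=1, var_family=0.15):
    """A study whose traits carry family structure but no QTL."""
    if gmap is None:
        gmap = ailqtl.uniform_map(1, 6, 10.0)
    traits = {
        f"null{i}": TraitModel(var_family=var_family, var_family_sex=0.05,
                               var_family_diet=0.05, var_residual=1.0)
        for i in range(n_traits)
    }
    return ailqtl.simulate_study(traits, gmap, n_families=n_families,
                                 n_generations=n_generations,
                                 final_family_size=final_family_size,
                                 seed=seed)
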