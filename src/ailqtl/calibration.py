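"""Design-level calibration experiments run entirely on simulated data.

Two standing questions about the breeding design and the scan machinery are
answerable by simulation alone:

* what is the variance effective size of the equalized-contribution AIL
  breeding rule (75 pairs, census 150)?  Theory says ~2x census;
* how many chromosomes per pure-noise trait reach the per-chromosome Li-Ji
  threshold at alpha = 0.05 in a 19-autosome scan?  With a calibrated test
  the expectation is 19 x 0.05 ~ 0.95.

These experiments double as end-to-end exercises of the simulator, the
scoring, the mixed-model scan and the threshold machinery.
"""

from __future__ import annotations

import numpy as np

from .mixedlm import FamilyVarianceModel
from .scan import scan as run_scan
from .scan import thresholds
from .scores import score_genotypes
from .simulate import TraitModel, estimate_effective_size, simulate_study, uniform_map


def breeding_design_ne(n_pairs: int = 75, n_generations: int = 10,
                       n_loci: int = 10, n_replicates: int = 10,
                       seed: int = 0):
    """Variance Ne of the AIL rule at the study's census (default 75 pairs)."""
    return estimate_effective_size(n_pairs, n_generations, n_loci,
                                   n_replicates, design="ail", seed=seed)


def false_positives_per_trait(n_traits: int = 20, n_chromosomes: int = 19,
                              markers_per_chromosome: int = 10,
                              spacing_cm: float = 8.0, n_families: int = 75,
                              final_family_size: int = 4,
                              n_generations: int = 16, alpha: float = 0.05,
                              seed: int = 0) -> dict:
    """Chromosome-wise false-positive calibration of the full scan.

    Simulates one F-``n_generations`` AIL population (family structure
    intact), generates ``n_traits`` traits that carry family random effects
    but no QTL, scans each trait at every marker with the full 12-df mixed
    model, and counts chromosomes whose scan maximum clears the
    per-chromosome Li-Ji threshold.  Returns the per-trait counts and their
    mean (the expected value for a calibrated test is
    ``n_chromosomes * alpha``).
    """
    gmap = uniform_map(n_chromosomes, markers_per_chromosome, spacing_cm)
    traits = {
        f"null{i}": TraitModel(var_family=0.15, var_family_sex=0.05,
                               var_family_diet=0.05, var_residual=1.0)
        for i in range(n_traits)
    }
    study = simulate_study(traits, gmap, n_families=n_families,
                           n_generations=n_generations,
                           final_family_size=final_family_size, seed=seed)
    ph = study.phenotypes
    st = score_genotypes(study.genotypes)  # markers only
    model = FamilyVarianceModel(ph["family"], ph["sex"], ph["diet"])
    result = run_scan(st, ph, list(traits), model=model)
    thr = thresholds(st, alpha)
    cut = {row["scope"]: row["lod_threshold"] for _, row in thr.iterrows()}
    counts = []
    for name in traits:
        n_hits = 0
        for chrom in gmap.chromosomes:
            prof = result.profile(name, chrom)
            if prof["lod"].max() >= cut[chrom]:
                n_hits += 1
        counts.append(n_hits)
    counts = np.asarray(counts)
    return {
        "per_trait": counts,
        "mean": float(counts.mean()),
        "expected": n_chromosomes * alpha,
        "n_traits": n_traits,
        "thresholds": thr,
    }
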