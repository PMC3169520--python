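"""End-to-end pipeline: simulate/read -> score -> scan -> pleiotropy ->
effects -> crossing -> summary.

The pipeline is configured by a :class:`PipelineConfig` (loadable from a
YAML file); every stage writes its tab-delimited output under the output
directory, a run log echoes the configuration and seed, and re-running with
the same config and seed reproduces every file byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import effects as fx
from . import io as aio
from . import pleiotropy as pl
from . import scan as _scan
from .mixedlm import FamilyVarianceModel
from .scores import impute_scores
from .simulate import simulate_study, uniform_map

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; paths are ignored when ``simulate`` is true."""

    out_dir: str = "ailqtl_out"
    map_path: str | None = None
    genotypes_path: str | None = None
    phenotypes_path: str | None = None
    simulate: bool = True
    architecture_path: str | None = None
    n_founder_pairs: int = 10
    n_families: int = 75
    n_generations: int = 16
    final_family_size: int = 7
    n_chromosomes: int = 19
    markers_per_chromosome: int = 10
    marker_spacing_cm: float = 8.0
    step_cm: float | None = 1.0
    alpha: float = 0.05
    traits: list = field(default_factory=list)
    seed: int = 0
    threshold_scope: str = "chromosome"  # or "genome"

    def __post_init__(self):
        if self.step_cm is not None and self.step_cm <= 0:
            raise ValueError("step_cm must be > 0 (or null for markers only)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def default_architecture(gmap=None) -> dict:
    """A small demonstration architecture with context-dependent loci.

    Loci are placed on markers of ``gmap`` (first and last chromosome, about
    a third and two thirds along); without a map the positions assume the
    default 19 x 10-marker genome.
    """
    from .simulate import QtlLocus, TraitModel

    if gmap is None:
        c_a, p_a, c_b, p_b = 1, 24.0, 3, 40.0
    else:
        chroms = gmap.chromosomes
        c_a, c_b = chroms[0], chroms[-1]
        cm_a = gmap.markers_on(c_a)["cm"].to_numpy(float)
        cm_b = gmap.markers_on(c_b)["cm"].to_numpy(float)
        p_a = float(cm_a[len(cm_a) // 3])
        p_b = float(cm_b[2 * len(cm_b) // 3])

    shared = {(s, d): (0.45, 0.0, 0.0) for s in "FM" for d in ("HF", "LF")}
    locus1 = QtlLocus(c_a, p_a, dict(shared))
    locus2 = QtlLocus(c_a, p_a, {("F", "HF"): (0.0, 0.0, 0.6),   # bipolar imprinting
                                 ("M", "HF"): (0.6, 0.0, 0.0)})  # additive, HF males
    locus3 = QtlLocus(c_b, p_b, {("F", "LF"): (0.5, -0.45, 0.0),
                                 ("M", "HF"): (-0.5, 0.6, 0.0)})  # crossing GxE
    vc = dict(var_family=0.15, var_family_sex=0.05, var_family_diet=0.05,
              var_family_sex_diet=0.05, var_residual=1.0)
    return {
        "trait1": TraitModel(mean=10.0, sex_effect=0.5, diet_effect=0.8,
                             loci=[locus1], **vc),
        "trait2": TraitModel(mean=5.0, diet_effect=0.4,
                             loci=[locus2], **vc),
        "trait3": TraitModel(mean=0.0, sex_effect=0.3,
                             loci=[locus3], **vc),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns a dict of the in-memory stage results.

    Output files: map/genotypes/phenotypes (when simulating), truth.yaml,
    scan.tsv, thresholds.tsv, pleiotropy.tsv, effects.tsv, crossing.tsv,
    differential_dominance.tsv, summary.tsv and run.log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("ailqtl")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stage = "configure"
    try:
        log.info("run started %s", datetime.now(timezone.utc).isoformat())
        log.info("config: %s", config)

        stage = "inputs"
        if config.simulate:
            gmap = uniform_map(config.n_chromosomes,
                               config.markers_per_chromosome,
                               config.marker_spacing_cm)
            if config.architecture_path:
                traits = aio.read_architecture(config.architecture_path)
            else:
                traits = default_architecture(gmap)
            study = simulate_study(traits, gmap,
                                   n_founder_pairs=config.n_founder_pairs,
                                   n_families=config.n_families,
                                   n_generations=config.n_generations,
                                   final_family_size=config.final_family_size,
                                   seed=config.seed)
            geno, pheno = study.genotypes, study.phenotypes
            aio.write_map(gmap, out / "map.tsv")
            aio.write_genotypes(geno, out / "genotypes.tsv")
            aio.write_phenotypes(pheno, out / "phenotypes.tsv")
            aio.write_architecture(traits, out / "truth.yaml")
        else:
            gmap, geno, pheno = aio.read_inputs(
                config.map_path, config.genotypes_path, config.phenotypes_path)

        trait_names = config.traits or [
            c for c in pheno.columns
            if c not in ("animal", "family", "sex", "diet")]

        stage = "score"
        scores = impute_scores(geno, step_cm=config.step_cm)

        stage = "scan"
        model = FamilyVarianceModel(pheno["family"], pheno["sex"], pheno["diet"])
        result = _scan.scan(scores, pheno, trait_names, model=model)
        aio.write_table(result.table, out / "scan.tsv", "scan")
        thr = _scan.thresholds(scores, config.alpha)
        aio.write_table(thr, out / "thresholds.tsv", "thresholds")

        stage = "pleiotropy"
        regions = pl.overlapping_regions(result, thr, scope=config.threshold_scope)
        prows = []
        ptests = []
        for chrom, region, rtraits in regions:
            if len(rtraits) < 2:
                continue
            res = pl.test_pleiotropy(result, chrom, region, rtraits,
                                     alpha=config.alpha)
            ptests.append(res)
            prows.append(res.to_row())
        ptable = pd.DataFrame(prows)
        aio.write_table(ptable, out / "pleiotropy.tsv", "pleiotropy")

        stage = "effects"
        sexv = pheno["sex"].to_numpy()
        dietv = pheno["diet"].to_numpy()
        erows, crows = [], []
        for chrom, region, rtraits in regions:
            for trait in rtraits:
                peak = result.peak(trait, chrom, region)
                mi = gmap.nearest_marker(chrom, float(peak["pos_cm"]))
                classes = geno.genotype_strings(mi)
                locus_name = f"{chrom}@{peak['pos_cm']:.1f}cM"
                rep = fx.effect_report(pheno[trait].to_numpy(float), classes,
                                       sexv, dietv, trait=trait,
                                       locus=locus_name, alpha=config.alpha)
                erows.append(rep)
                stage = "crossing"
                marker_cm = float(gmap.frame["cm"].iloc[mi])
                j = int(np.flatnonzero(
                    (scores.grid["chrom"] == chrom).to_numpy()
                    & np.isclose(scores.grid["pos_cm"], marker_cm))[0])
                cres = fx.crossing_test(pheno[trait].to_numpy(float),
                                        scores.triplet(j), pheno, model,
                                        alpha=config.alpha, trait=trait,
                                        chrom=chrom, pos_cm=marker_cm)
                crows.append({"locus": locus_name, "trait": trait,
                              "verdict": cres.verdict,
                              "min_interaction_p": min(cres.interaction_terms.values()),
                              "min_interaction_p_std":
                                  min(cres.interaction_terms_std.values())
                                  if cres.interaction_terms_std else np.nan,
                              "opposite_ranks": cres.opposite_ranks})
                stage = "effects"
        etable = pd.concat(erows, ignore_index=True) if erows else pd.DataFrame()
        ctable = pd.DataFrame(crows)
        aio.write_table(etable, out / "effects.tsv", "effects")
        aio.write_table(ctable, out / "crossing.tsv", "crossing")

        stage = "differential-dominance"
        drows = []
        for res in ptests:
            a_vec, d_vec, sds = [], [], []
            for trait in res.traits:
                mi = gmap.nearest_marker(res.chrom, res.combined_cm)
                classes = geno.genotype_strings(mi)
                gm = fx.genotypic_means(pheno[trait].to_numpy(float), classes,
                                        sexv, dietv)
                a, d, _ = fx.effects_from_means(gm.means)
                a_vec.append(a)
                d_vec.append(d)
                sds.append(float(pheno[trait].std(ddof=1)))
            geom = fx.differential_dominance(a_vec, d_vec, sd=sds,
                                             traits=res.traits)
            drows.append({"chrom": res.chrom, "combined_cm": res.combined_cm,
                          "traits": ",".join(map(str, res.traits)),
                          "differential": geom.differential,
                          "antagonistic": geom.antagonistic,
                          "angle_deg": geom.angle_deg,
                          "synthetic_d": geom.synthetic_d})
        aio.write_table(pd.DataFrame(drows), out / "differential_dominance.tsv",
                        "effects")

        stage = "summary"
        srows = []
        for (chrom, region, rtraits), res in zip(
                [r for r in regions if len(r[2]) >= 2] or [], ptests):
            srows.append({
                "chrom": chrom, "traits": ",".join(map(str, rtraits)),
                "combined_cm": res.combined_cm,
                "support_left_cm": res.support["left_cm"],
                "support_right_cm": res.support["right_cm"],
                "pleiotropy_p": res.p, "verdict": res.verdict,
            })
        for chrom, region, rtraits in regions:
            if len(rtraits) == 1:
                peak = result.peak(rtraits[0], chrom, region)
                srows.append({"chrom": chrom, "traits": rtraits[0],
                              "combined_cm": float(peak["pos_cm"]),
                              "support_left_cm": region[0],
                              "support_right_cm": region[1],
                              "pleiotropy_p": np.nan,
                              "verdict": "single trait"})
        summary = pd.DataFrame(srows)
        aio.write_table(summary, out / "summary.tsv", "summary")
        log.info("run finished; %d region(s)", len(regions))
        return {"map": gmap, "genotypes": geno, "phenotypes": pheno,
                "scores": scores, "scan": result, "thresholds": thr,
                "regions": regions, "pleiotropy": ptable,
                "effects": etable, "crossing": ctable, "summary": summary}
    except Exception:
        log.exception("pipeline failed during stage %r", stage)
        manifest = sorted(p.name for p in out.iterdir())
        log.error("partial outputs: %s", manifest)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
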