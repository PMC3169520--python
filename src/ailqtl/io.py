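"""Tab-delimited file formats and input validation.

All tables are UTF-8, tab-delimited, with '#' comment lines; the first
comment line names units and conventions (cM positions, 1-based bp,
paternal-first allele order).  The formats:

* map:        chrom  marker  cm  bp
* genotypes:  animal  marker  paternal  maternal     (alleles L/S)
* phenotypes: animal  family  sex  diet  <trait columns>
* truth:      YAML dump of the generating trait models
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import (GeneticMap, OrderedGenotypes, QtlLocus, TraitModel)

_HEADERS = {
    "map": "# genetic map: positions in cM (float) and bp (1-based int)",
    "genotypes": "# ordered genotypes: paternal allele first; alleles L/S",
    "phenotypes": "# phenotypes: sex F/M, diet HF/LF, one column per trait",
    "scores": "# genotypic scores on the scan grid; positions in cM",
    "scan": "# scan results: chi-square vs 12-df null, LOD = -log10(p)",
    "thresholds": "# Li-Ji adjusted thresholds, alpha' = 1-(1-alpha)^(1/M_eff)",
    "pleiotropy": "# pleiotropy tests: summed chi-square differences, df = traits-1",
    "effects": "# genotypic means (paternal-first classes) and a/d/i per scope",
    "crossing": "# crossing-vs-spreading verdicts after cohort standardization",
    "summary": "# per-region summary of the full pipeline",
}


def write_table(frame: pd.DataFrame, path, kind: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf8") as fh:
        if kind in _HEADERS:
            fh.write(_HEADERS[kind] + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#")
    except Exception as e:
        raise ValueError(f"{path}: malformed table ({e})") from e


def write_map(gmap: GeneticMap, path) -> None:
    write_table(gmap.frame, path, "map")


def read_map(path) -> GeneticMap:
    frame = read_table(path)
    try:
        return GeneticMap(frame)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_genotypes(geno: OrderedGenotypes, path) -> None:
    write_table(geno.to_frame(), path, "genotypes")


def read_genotypes(path, gmap: GeneticMap) -> OrderedGenotypes:
    frame = read_table(path)
    try:
        return OrderedGenotypes.from_frame(frame, gmap)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from e


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    write_table(pheno, path, "phenotypes")


def read_phenotypes(path) -> pd.DataFrame:
    frame = read_table(path)
    for col in ("animal", "family", "sex", "diet"):
        if col not in frame.columns:
            raise ValueError(f"{path}: phenotype table lacks column {col!r}")
    return frame


def read_inputs(map_path, geno_path, pheno_path):
    """Read and cross-validate the three pipeline inputs.

    Checks that the genotyped and phenotyped animal sets agree (mismatches
    are listed) and that the genotype table covers exactly the map's
    markers.  Returns (GeneticMap, OrderedGenotypes, phenotype frame) with
    both tables aligned to the same animal order.
    """
    gmap = read_map(map_path)
    geno = read_genotypes(geno_path, gmap)
    pheno = read_phenotypes(pheno_path)
    ganimals = set(int(a) for a in geno.animals)
    panimals = set(int(a) for a in pheno["animal"])
    if ganimals != panimals:
        only_g = sorted(ganimals - panimals)[:10]
        only_p = sorted(panimals - ganimals)[:10]
        raise ValueError(
            f"animal sets disagree: {len(ganimals - panimals)} genotyped-only "
            f"(e.g. {only_g}), {len(panimals - ganimals)} phenotyped-only "
            f"(e.g. {only_p})"
        )
    pheno = pheno.set_index("animal").loc[geno.animals].reset_index()
    return gmap, geno, pheno


# ---------------------------------------------------------------------------
# architecture (truth) files


def architecture_to_dict(traits: dict) -> dict:
    out = {}
    for name, tm in traits.items():
        out[name] = {
            "mean": tm.mean,
            "sex_effect": tm.sex_effect,
            "diet_effect": tm.diet_effect,
            "sex_diet_effect": tm.sex_diet_effect,
            "variance_components": tm.variance_components(),
            "loci": [
                {
                    "chrom": locus.chrom,
                    "pos_cm": locus.pos_cm,
                    "effects": {f"{s}-{d}": list(map(float, adi))
                                for (s, d), adi in locus.effects.items()},
                }
                for locus in tm.loci
            ],
        }
    return out


def architecture_from_dict(data: dict) -> dict:
    traits = {}
    for name, spec in data.items():
        vc = spec.get("variance_components", {})
        loci = []
        for ld in spec.get("loci", []):
            effects = {}
            for key, adi in ld.get("effects", {}).items():
                sex, diet = key.split("-")
                effects[(sex, diet)] = tuple(float(x) for x in adi)
            loci.append(QtlLocus(ld["chrom"], float(ld["pos_cm"]), effects))
        traits[name] = TraitModel(
            mean=float(spec.get("mean", 0.0)),
            sex_effect=float(spec.get("sex_effect", 0.0)),
            diet_effect=float(spec.get("diet_effect", 0.0)),
            sex_diet_effect=float(spec.get("sex_diet_effect", 0.0)),
            loci=loci,
            var_family=float(vc.get("family", 0.0)),
            var_family_sex=float(vc.get("family_sex", 0.0)),
            var_family_diet=float(vc.get("family_diet", 0.0)),
            var_family_sex_diet=float(vc.get("family_sex_diet", 0.0)),
            var_residual=float(vc.get("residual", 1.0)),
        )
    return traits


def write_architecture(traits: dict, path) -> None:
    with open(path, "w", encoding="utf8") as fh:
        yaml.safe_dump(architecture_to_dict(traits), fh, sort_keys=False)


def read_architecture(path) -> dict:
    with open(path, encoding="utf8") as fh:
        return architecture_from_dict(yaml.safe_load(fh))
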