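"""Synthetic advanced intercross line (AIL) populations.

An AIL is bred from two fully inbred founder strains (here labelled L and S,
after the LG/J and SM/J mouse strains) by crossing to an F2 and then
pseudo-randomly mating for many further generations.  Two rules define the
breeding design emulated here:

* brother-sister mating is never allowed;
* in the steady-state generations each family contributes exactly one male
  and one female breeder to the next generation, which equalizes family
  contributions and approximately doubles the effective population size
  relative to the census of breeders.

This module provides pedigree construction under that design, gene dropping
of fully phased genotypes (so the parent of origin of every allele is known
exactly), cohort assignment (each family split by sex between a high-fat and
a low-fat diet), phenotype simulation from a context-dependent additive /
dominance / imprinting QTL architecture with family-structured random
effects, and a variance-based estimator of the effective population size of
the breeding design.

All randomness flows from a single master seed through named substreams, so
each stage is independently reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEXES = ("F", "M")
DIETS = ("HF", "LF")
#: the four sex-by-diet cohorts, in canonical order
COHORTS = tuple((s, d) for s in SEXES for d in DIETS)


class DesignError(ValueError):
    """Raised when a requested breeding design is infeasible."""


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG of the master seed.

    The substream key is a CRC32 of the stage name, so e.g. the meiosis
    stream is identical whether or not the pedigree stream was consumed
    first.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# genetic map


class GeneticMap:
    """Marker positions (cM and bp) along autosomes.

    Parameters
    ----------
    frame : DataFrame with columns ``chrom``, ``marker``, ``cm``, ``bp``.
        Positions must be strictly increasing within each chromosome and
        marker names unique.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["chrom", "marker", "cm", "bp"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"genetic map is missing columns {missing}")
        frame = frame[required].reset_index(drop=True)
        if frame["marker"].duplicated().any():
            dup = frame.loc[frame["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker name {dup!r} in map")
        for chrom, sub in frame.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(float)
            if len(cm) < 1:
                raise ValueError(f"chromosome {chrom} has no markers")
            if np.any(np.diff(cm) <= 0):
                bad = sub["marker"].iloc[int(np.argmax(np.diff(cm) <= 0)) + 1]
                raise ValueError(
                    f"map positions not strictly increasing on chromosome "
                    f"{chrom} at marker {bad!r}"
                )
        self.frame = frame

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.frame["chrom"]))

    def markers_on(self, chrom) -> pd.DataFrame:
        return self.frame[self.frame["chrom"] == chrom]

    def marker_index(self, name: str) -> int:
        idx = self.frame.index[self.frame["marker"] == name]
        if len(idx) == 0:
            raise KeyError(f"marker {name!r} not in map")
        return int(idx[0])

    def nearest_marker(self, chrom, pos_cm: float) -> int:
        """Global index of the marker on ``chrom`` closest to ``pos_cm``."""
        sub = self.markers_on(chrom)
        if len(sub) == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        cm = sub["cm"].to_numpy(float)
        return int(sub.index[np.argmin(np.abs(cm - pos_cm))])

    def adjacent_recomb(self) -> np.ndarray:
        """Haldane recombination fraction between marker i and i+1.

        Entries spanning a chromosome boundary are 0.5 (independent
        assortment), which lets gametes be simulated in one pass over the
        genome-wide marker vector.
        """
        cm = self.frame["cm"].to_numpy(float)
        chrom = self.frame["chrom"].to_numpy()
        r = haldane(np.diff(cm))
        r[chrom[1:] != chrom[:-1]] = 0.5
        return r


def haldane(d_cm):
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, float) / 100.0))


def uniform_map(n_chrom: int = 19, n_markers: int = 10, spacing_cm: float = 8.0,
                bp_per_cm: float = 2_000_000.0) -> GeneticMap:
    """An evenly spaced synthetic map, ``n_markers`` per chromosome."""
    rows = []
    for c in range(1, n_chrom + 1):
        for j in range(n_markers):
            cm = j * spacing_cm
            rows.append((c, f"c{c}m{j + 1}", cm, int(cm * bp_per_cm) + 3_000_000))
    return GeneticMap(pd.DataFrame(rows, columns=["chrom", "marker", "cm", "bp"]))


# ---------------------------------------------------------------------------
# pedigree


def build_pedigree(n_founder_pairs: int, n_families: int, n_generations: int,
                   final_family_size: int, seed: int = 0, *,
                   allow_sib_mating: bool = False) -> pd.DataFrame:
    """Breed an AIL pedigree.

    Generation 0 holds ``n_founder_pairs`` S-strain males paired with
    L-strain females.  Intermediate generations are expanded (if needed) to
    ``n_families`` breeding pairs; once that size is reached each family
    contributes exactly one male and one female breeder per generation (the
    AIL rule).  The final generation (index ``n_generations``) has
    ``final_family_size`` offspring per pair and is the experimental
    population.

    Returns a DataFrame with columns ``id, sire, dam, sex, generation,
    family, strain`` (strain is set for founders only).
    """
    if min(n_founder_pairs, n_families, final_family_size) < 1:
        raise DesignError("all design counts must be >= 1")
    if n_generations < 2:
        raise DesignError("need n_generations >= 2 (founders -> F1 -> F2)")
    if n_families == 1 and not allow_sib_mating:
        raise DesignError(
            "a single family cannot be bred without sib mating; "
            "pass allow_sib_mating=True for minimal designs"
        )
    rng = substream(seed, "pedigree")
    rows: list[tuple] = []  # id, sire, dam, sex, gen, family, strain
    next_id = 0

    pairs = []  # (sire_id, dam_id) producing the next generation
    # founders are unrelated strain animals: each gets its own family id
    for f in range(n_founder_pairs):
        sire, dam = next_id, next_id + 1
        next_id += 2
        rows.append((sire, -1, -1, "M", 0, 2 * f, "S"))
        rows.append((dam, -1, -1, "F", 0, 2 * f + 1, "L"))
        pairs.append((sire, dam))

    for gen in range(1, n_generations + 1):
        final = gen == n_generations
        if final:
            litter = final_family_size
        else:
            # enough offspring of each sex to satisfy breeder quotas
            litter = max(4, 2 * math.ceil(n_families / len(pairs)) + 2)
        fam_members: list[dict] = []
        for fam, (sire, dam) in enumerate(pairs):
            members = {"M": [], "F": []}
            start = int(rng.integers(0, 2))
            for k in range(litter):
                sex = SEXES[(k + start) % 2]
                rows.append((next_id, sire, dam, sex, gen, fam, None))
                members[sex].append(next_id)
                next_id += 1
            fam_members.append(members)
        if final:
            break
        pairs = _select_and_pair(fam_members, n_families, rng, allow_sib_mating)
    return pd.DataFrame(
        rows, columns=["id", "sire", "dam", "sex", "generation", "family", "strain"]
    )


def _select_and_pair(fam_members, n_families, rng, allow_sib_mating):
    """Choose breeders (AIL quota rule) and pair them avoiding sib matings."""
    n_fams = len(fam_members)
    quotas = np.full(n_fams, n_families // n_fams)
    extra = rng.permutation(n_fams)[: n_families % n_fams]
    quotas[extra] += 1
    males, male_fam, females, female_fam = [], [], [], []
    for fam, members in enumerate(fam_members):
        q = int(quotas[fam])
        if q == 0:
            continue
        males.extend(rng.choice(members["M"], size=q, replace=False))
        females.extend(rng.choice(members["F"], size=q, replace=False))
        male_fam.extend([fam] * q)
        female_fam.extend([fam] * q)
    males = np.asarray(males)
    females = np.asarray(females)
    male_fam = np.asarray(male_fam)
    female_fam = np.asarray(female_fam)

    order = rng.permutation(len(females))
    females, female_fam = females[order], female_fam[order]
    if not allow_sib_mating:
        for _ in range(200):
            conflicts = np.flatnonzero(male_fam == female_fam)
            if len(conflicts) == 0:
                break
            # swap each conflicting female with a random partner slot
            for i in conflicts:
                j = int(rng.integers(0, len(females)))
                females[[i, j]] = females[[j, i]]
                female_fam[[i, j]] = female_fam[[j, i]]
        else:
            raise DesignError("could not pair breeders without sib mating")
        if np.any(male_fam == female_fam):
            raise DesignError("could not pair breeders without sib mating")
    return list(zip(males.tolist(), females.tolist()))


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check structural invariants; raise ``ValueError`` on violation."""
    by_id = ped.set_index("id")
    founders = ped[ped["generation"] == 0]
    if ((founders["sire"] != -1) | (founders["dam"] != -1)).any():
        raise ValueError("founders must have no parents")
    kids = ped[ped["generation"] > 0]
    for col, sex in (("sire", "M"), ("dam", "F")):
        parents = by_id.loc[kids[col]]
        if (parents["sex"] != sex).any():
            raise ValueError(f"{col} of wrong sex")
        if not (parents["generation"].to_numpy()
                == kids["generation"].to_numpy() - 1).all():
            raise ValueError("parents must come from the previous generation")
    # no sib mating: sires and dams of one family must not be sibs
    for gen, sub in kids.groupby("generation"):
        pairs = sub[["sire", "dam"]].drop_duplicates()
        sire_fam = by_id.loc[pairs["sire"], "family"].to_numpy()
        dam_fam = by_id.loc[pairs["dam"], "family"].to_numpy()
        if np.any(sire_fam == dam_fam):
            raise ValueError(f"sib mating at generation {gen}")


# ---------------------------------------------------------------------------
# gene dropping (fully phased)


class OrderedGenotypes:
    """Phased two-allele genotypes, paternal allele first.

    Alleles are stored as uint8 (1 = L, 0 = S) in two (n_animals, n_markers)
    arrays.  The string form of a genotype is e.g. ``"LS"`` meaning paternal
    L, maternal S — reciprocal heterozygotes LS and SL are distinct.
    """

    ALLELES = np.array(["S", "L"])

    def __init__(self, animals: np.ndarray, gmap: GeneticMap,
                 paternal: np.ndarray, maternal: np.ndarray):
        self.animals = np.asarray(animals)
        self.map = gmap
        self.paternal = np.asarray(paternal, dtype=np.uint8)
        self.maternal = np.asarray(maternal, dtype=np.uint8)
        if self.paternal.shape != (len(self.animals), gmap.n_markers):
            raise ValueError("genotype array shape does not match animals x markers")
        if self.maternal.shape != self.paternal.shape:
            raise ValueError("paternal/maternal shapes differ")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    def genotype_strings(self, marker_index: int) -> np.ndarray:
        """Ordered genotype strings (LL/LS/SL/SS) at one marker."""
        p = self.ALLELES[self.paternal[:, marker_index]]
        m = self.ALLELES[self.maternal[:, marker_index]]
        return np.char.add(p, m)

    def to_frame(self) -> pd.DataFrame:
        """Long table: animal, marker, paternal, maternal."""
        n, m = self.paternal.shape
        return pd.DataFrame({
            "animal": np.repeat(self.animals, m),
            "marker": np.tile(self.map.frame["marker"].to_numpy(), n),
            "paternal": self.ALLELES[self.paternal.ravel()],
            "maternal": self.ALLELES[self.maternal.ravel()],
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gmap: GeneticMap) -> "OrderedGenotypes":
        markers = gmap.frame["marker"].to_numpy()
        bad = set(frame["marker"]) - set(markers)
        if bad:
            raise ValueError(f"genotype markers absent from map: {sorted(bad)[:5]}")
        animals = frame["animal"].drop_duplicates().to_numpy()
        wide_p = frame.pivot(index="animal", columns="marker", values="paternal")
        wide_m = frame.pivot(index="animal", columns="marker", values="maternal")
        if wide_p.isna().any().any() or wide_m.isna().any().any():
            raise ValueError("every animal needs a call at every marker")
        wide_p = wide_p.loc[animals, markers]
        wide_m = wide_m.loc[animals, markers]
        for wide in (wide_p, wide_m):
            vals = set(np.unique(wide.to_numpy()))
            if not vals <= {"L", "S"}:
                raise ValueError(f"allele labels must be L/S, got {vals - {'L', 'S'}}")
        return cls(animals, gmap,
                   (wide_p.to_numpy() == "L").astype(np.uint8),
                   (wide_m.to_numpy() == "L").astype(np.uint8))


def drop_genotypes(ped: pd.DataFrame, gmap: GeneticMap, seed: int = 0,
                   keep: str = "all") -> OrderedGenotypes:
    """Gene-drop phased genotypes through a pedigree.

    Founders are homozygous for their strain allele (L or S).  Each
    non-founder receives one recombined gamete per parent; crossovers follow
    the Haldane (no interference) model on the map's cM distances, with free
    recombination across chromosome boundaries.

    ``keep`` is ``"all"`` or ``"final"`` (final generation only).
    """
    rng = substream(seed, "meiosis")
    r = gmap.adjacent_recomb()
    m = gmap.n_markers
    ped = ped.sort_values(["generation", "id"], kind="stable")
    ids = ped["id"].to_numpy()
    row_of = {int(a): i for i, a in enumerate(ids)}
    pat = np.zeros((len(ids), m), dtype=np.uint8)
    mat = np.zeros_like(pat)

    gens = ped["generation"].to_numpy()
    sires = ped["sire"].to_numpy()
    dams = ped["dam"].to_numpy()
    strains = ped["strain"].to_numpy(object)
    for i in range(len(ids)):
        if gens[i] == 0:
            allele = 1 if strains[i] == "L" else 0
            pat[i, :] = allele
            mat[i, :] = allele
        else:
            si, di = row_of[int(sires[i])], row_of[int(dams[i])]
            pat[i] = _gamete(pat[si], mat[si], r, rng)
            mat[i] = _gamete(pat[di], mat[di], r, rng)

    if keep == "final":
        mask = gens == gens.max()
        return OrderedGenotypes(ids[mask], gmap, pat[mask], mat[mask])
    return OrderedGenotypes(ids, gmap, pat, mat)


def _gamete(h0: np.ndarray, h1: np.ndarray, r: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One recombined gamete from a diplotype (Markov walk over markers)."""
    m = len(h0)
    strand = np.empty(m, dtype=np.int64)
    strand[0] = rng.integers(0, 2)
    if m > 1:
        switches = rng.random(m - 1) < r
        strand[1:] = (strand[0] + np.cumsum(switches)) % 2
    return np.where(strand == 0, h0, h1)


# ---------------------------------------------------------------------------
# cohorts


def assign_cohorts(ped: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Assign final-generation animals to high-fat / low-fat diet cohorts.

    Within each family, animals of each sex are alternated between HF and LF
    (random starting diet per family x sex), so each sex is split as evenly
    as possible between diets — emulating partitioning litters at weaning.

    Returns a DataFrame ``animal, family, sex, diet``.
    """
    rng = substream(seed, "cohorts")
    final = ped[ped["generation"] == ped["generation"].max()]
    rows = []
    for (fam, sex), sub in final.groupby(["family", "sex"]):
        start = int(rng.integers(0, 2))
        for k, animal in enumerate(sub["id"].to_numpy()):
            rows.append((animal, fam, sex, DIETS[(k + start) % 2]))
    out = pd.DataFrame(rows, columns=["animal", "family", "sex", "diet"])
    return out.sort_values("animal", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# QTL architecture and phenotypes


@dataclass
class QtlLocus:
    """One QTL with per-cohort additive/dominance/imprinting effects.

    ``effects`` maps cohort ``(sex, diet)`` to an ``(a, d, i)`` triplet in
    trait units; cohorts omitted from the dict have zero effects.
    """

    chrom: object
    pos_cm: float
    effects: dict = field(default_factory=dict)

    def triplet(self, sex: str, diet: str) -> tuple:
        return tuple(self.effects.get((sex, diet), (0.0, 0.0, 0.0)))


@dataclass
class TraitModel:
    """Generating model for one trait.

    Fixed part: ``mean`` plus half-coded sex/diet/sex-by-diet offsets
    (sex M = +1/2, F = -1/2; diet HF = +1/2, LF = -1/2), plus the summed
    QTL contributions a*X_a + d*X_d + i*X_i with cohort-specific effects.
    Random part: independent family, family x sex, family x diet and
    family x sex x diet effects plus residual noise.
    """

    mean: float = 0.0
    sex_effect: float = 0.0
    diet_effect: float = 0.0
    sex_diet_effect: float = 0.0
    loci: list = field(default_factory=list)
    var_family: float = 0.0
    var_family_sex: float = 0.0
    var_family_diet: float = 0.0
    var_family_sex_diet: float = 0.0
    var_residual: float = 1.0

    def variance_components(self) -> dict:
        return {
            "family": self.var_family,
            "family_sex": self.var_family_sex,
            "family_diet": self.var_family_diet,
            "family_sex_diet": self.var_family_sex_diet,
            "residual": self.var_residual,
        }

    def validate(self, gmap: GeneticMap | None = None) -> None:
        for name, v in self.variance_components().items():
            if v < 0:
                raise ValueError(f"variance component {name} is negative ({v})")
        if gmap is not None:
            for locus in self.loci:
                sub = gmap.markers_on(locus.chrom)
                if len(sub) == 0:
                    raise ValueError(f"locus chromosome {locus.chrom!r} not in map")
                lo, hi = sub["cm"].min(), sub["cm"].max()
                if not (lo <= locus.pos_cm <= hi):
                    raise ValueError(
                        f"locus at {locus.pos_cm} cM outside chromosome "
                        f"{locus.chrom} span [{lo}, {hi}]"
                    )


def half_coding(sex, diet):
    """Effect coding: M/HF -> +1/2, F/LF -> -1/2 (vectorized)."""
    s = np.where(np.asarray(sex) == "M", 0.5, -0.5)
    t = np.where(np.asarray(diet) == "HF", 0.5, -0.5)
    return s, t


def simulate_phenotypes(geno: OrderedGenotypes, cohorts: pd.DataFrame,
                        traits: dict, ped: pd.DataFrame | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Generate phenotypes Y = mu + context offsets + QTL + family RE + noise.

    ``traits`` maps trait name -> :class:`TraitModel`.  QTL positions are
    resolved to the nearest marker of their chromosome; with the default
    simulator workflow loci sit exactly on markers.

    Returns ``animal, family, sex, diet`` plus one column per trait, rows
    aligned to ``cohorts``.
    """
    rng = substream(seed, "phenotypes")
    cohorts = cohorts.reset_index(drop=True)
    row_of = {int(a): i for i, a in enumerate(geno.animals)}
    try:
        gidx = np.array([row_of[int(a)] for a in cohorts["animal"]])
    except KeyError as e:
        raise ValueError(f"animal {e} has no genotypes") from None
    sex = cohorts["sex"].to_numpy()
    diet = cohorts["diet"].to_numpy()
    fam = cohorts["family"].to_numpy()
    s, t = half_coding(sex, diet)
    trait_cols = {}

    for name, model in traits.items():
        model.validate(geno.map)
        y = model.mean + model.sex_effect * s + model.diet_effect * t \
            + model.sex_diet_effect * s * t
        for locus in model.loci:
            mi = geno.map.nearest_marker(locus.chrom, locus.pos_cm)
            p = geno.paternal[gidx, mi].astype(float)
            m_ = geno.maternal[gidx, mi].astype(float)
            xa, xd, xi = p + m_ - 1.0, (p != m_).astype(float), p - m_
            for (cs, cd) in COHORTS:
                a, d, i = locus.triplet(cs, cd)
                if a == d == i == 0.0:
                    continue
                mask = (sex == cs) & (diet == cd)
                y[mask] += a * xa[mask] + d * xd[mask] + i * xi[mask]
        # family-structured random effects
        for var, keys in (
            (model.var_family, [fam]),
            (model.var_family_sex, [fam, sex]),
            (model.var_family_diet, [fam, diet]),
            (model.var_family_sex_diet, [fam, sex, diet]),
        ):
            if var <= 0:
                continue
            labels = pd.MultiIndex.from_arrays(keys)
            codes, uniq = pd.factorize(labels)
            y += math.sqrt(var) * rng.standard_normal(len(uniq))[codes]
        y += math.sqrt(model.var_residual) * rng.standard_normal(len(y))
        trait_cols[name] = y
    return pd.concat([cohorts, pd.DataFrame(trait_cols, index=cohorts.index)],
                     axis=1)


# ---------------------------------------------------------------------------
# effective population size


@dataclass
class NeEstimate:
    ne: float
    se: float
    n_transitions: int
    per_replicate: np.ndarray

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"NeEstimate(ne={self.ne:.1f}, se={self.se:.1f})"


def estimate_effective_size(n_pairs: int = 75, n_generations: int = 10,
                            n_loci: int = 10, n_replicates: int = 10,
                            design: str = "ail", p0: float = 0.5,
                            seed: int = 0) -> NeEstimate:
    """Variance effective size of a breeding design, by gene dropping.

    Unlinked neutral biallelic loci (starting frequency ``p0``) are dropped
    through the design; the standardized per-generation variance of allele
    frequency change gives ``Ne = p(1-p) / (2 Var(dp))``, estimated by the
    pooled ratio ``1 / (2 * mean[(dp)^2 / (p(1-p))])`` over loci,
    generations and replicates.  Transitions starting from a fixed locus are
    excluded.

    ``design="ail"``: monogamous pairs, one male and one female breeding
    offspring per family, random non-sib re-pairing (census ``2 * n_pairs``);
    equalized family contributions give Ne ~ 2x census.
    ``design="wright_fisher"``: idealized random mating at the same census
    (each offspring draws two random parents), the Ne ~ census baseline.
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2 for a standard error")
    if design not in ("ail", "wright_fisher"):
        raise ValueError(f"unknown design {design!r}")
    rng = substream(seed, "ne")
    census = 2 * n_pairs
    per_rep_x: list[np.ndarray] = []
    for _ in range(n_replicates):
        geno = (rng.random((census, 2, n_loci)) < p0).astype(np.int8)
        fam = np.repeat(np.arange(n_pairs), 2) if design == "ail" else None
        xs = []
        for _ in range(n_generations):
            p = geno.mean(axis=(0, 1))
            if design == "ail":
                geno, fam = _ail_generation(geno, fam, n_pairs, rng)
            else:
                geno = _wf_generation(geno, rng)
            p2 = geno.mean(axis=(0, 1))
            ok = (p > 0) & (p < 1)
            xs.append((p2[ok] - p[ok]) ** 2 / (p[ok] * (1 - p[ok])))
        per_rep_x.append(np.concatenate(xs))
    if all(len(x) == 0 for x in per_rep_x):
        raise ValueError("all loci fixed in all replicates; cannot estimate Ne")
    pooled = np.concatenate(per_rep_x)
    ne = 1.0 / (2.0 * pooled.mean())
    per_rep = np.array([1.0 / (2.0 * x.mean()) for x in per_rep_x if len(x)])
    se = per_rep.std(ddof=1) / math.sqrt(len(per_rep))
    return NeEstimate(ne, se, len(pooled), per_rep)


def _ail_generation(geno, fam, n_pairs, rng):
    """One AIL generation: 2 breeding offspring per pair, non-sib re-pairing."""
    n_loci = geno.shape[2]
    sires, dams = geno[0::2], geno[1::2]  # (P, 2, L)
    # two offspring per pair, each drawing one random allele per parent per locus
    pick = rng.integers(0, 2, size=(n_pairs, 2, 2, n_loci))
    pair_idx = np.arange(n_pairs)[:, None, None]
    locus_idx = np.arange(n_loci)[None, None, :]
    pat = sires[pair_idx, pick[:, :, 0, :], locus_idx]  # (P, 2, L)
    mat = dams[pair_idx, pick[:, :, 1, :], locus_idx]
    kids = np.stack([pat, mat], axis=2)  # (P, 2 offspring, 2 copies, L)
    males, females = kids[:, 0], kids[:, 1]
    # random pairing of the new males and females avoiding sibs
    order = rng.permutation(n_pairs)
    if n_pairs > 1:
        for _ in range(20):
            conflicts = np.flatnonzero(order == np.arange(n_pairs))
            if len(conflicts) == 0:
                break
            for i in conflicts:
                j = int(rng.integers(0, n_pairs))
                order[[i, j]] = order[[j, i]]
    new = np.empty((2 * n_pairs, 2, n_loci), dtype=geno.dtype)
    new[0::2] = males
    new[1::2] = females[order]
    new_fam = np.empty(2 * n_pairs, dtype=np.int64)
    new_fam[0::2] = np.arange(n_pairs)
    new_fam[1::2] = order
    return new, new_fam


def _wf_generation(geno, rng):
    """Idealized Wright-Fisher generation at the same census."""
    n, _, n_loci = geno.shape
    parents = rng.integers(0, n, size=(n, 2))
    pick = rng.integers(0, 2, size=(n, 2, n_loci))
    locus_idx = np.arange(n_loci)[None, :]
    pat = geno[parents[:, 0][:, None], pick[:, 0, :], locus_idx]
    mat = geno[parents[:, 1][:, None], pick[:, 1, :], locus_idx]
    return np.stack([pat, mat], axis=1)


# ---------------------------------------------------------------------------
# one-call study simulation


@dataclass
class StudyData:
    """Everything downstream stages consume, from one simulated study."""

    pedigree: pd.DataFrame
    map: GeneticMap
    genotypes: OrderedGenotypes  # final generation only
    phenotypes: pd.DataFrame
    traits: dict


def simulate_study(traits: dict, gmap: GeneticMap | None = None,
                   n_founder_pairs: int = 10, n_families: int = 75,
                   n_generations: int = 16, final_family_size: int = 7,
                   seed: int = 0) -> StudyData:
    """Simulate a full AIL study: pedigree, genotypes, cohorts, phenotypes.

    Defaults emulate the mouse AIL design this package targets: 10 founder
    pairs crossed and expanded to 75 breeding families, pseudo-random mating
    to F16, and a final experimental generation split between high- and
    low-fat diets at weaning.
    """
    if gmap is None:
        gmap = uniform_map()
    ped = build_pedigree(n_founder_pairs, n_families, n_generations,
                         final_family_size, seed=seed)
    geno = drop_genotypes(ped, gmap, seed=seed, keep="final")
    cohorts = assign_cohorts(ped, seed=seed)
    pheno = simulate_phenotypes(geno, cohorts, traits, ped, seed=seed)
    return StudyData(ped, gmap, geno, pheno, traits)
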