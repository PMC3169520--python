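"""Cohort-specific genotypic values, effect-pattern classification, and
genotype-by-environment geometry at detected loci.

From covariate-adjusted ordered-genotype means G_LL, G_LS, G_SL, G_SS the
genetic effects are

    a = (G_LL - G_SS) / 2          additive
    d = (G_LS + G_SL)/2 - (G_LL + G_SS)/2    dominance (mid-heterozygote
                                             minus mid-homozygote)
    i = (G_LS - G_SL) / 2          parent-of-origin (paternal allele first)

Patterns are classified per cohort from which effects are significant:
plain additivity and L/S dominance, over/underdominance, and the four
imprinting patterns — paternal expression (i tracks a), maternal expression
(i opposes a), polar dominance (i and d, no a) and bipolar dominance (i
alone).  Differential dominance across traits at one locus is summarized by
the geometry of the multi-trait additive and dominance vectors: when they
are not colinear, the dominance component orthogonal to the additive axis
defines a synthetic trait combination that is purely over- or
underdominant.  Crossing-vs-spreading genotype-by-environment interactions
are distinguished by re-testing the interaction after a per-cohort
standardization that equalizes dispersion, so only rank changes of the
genotypic means can carry the interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .mixedlm import FamilyVarianceModel
from .scan import fit_position
from .simulate import COHORTS, half_coding

log = logging.getLogger(__name__)

GENO_CLASSES = ("LL", "LS", "SL", "SS")

PATTERNS = ("additive", "L-dominant", "S-dominant", "overdominant",
            "underdominant", "maternal-expression", "paternal-expression",
            "polar-dominance", "bipolar-dominance", "none")


# ---------------------------------------------------------------------------
# genotypic means and a/d/i


@dataclass
class GenotypicMeans:
    """Adjusted means per ordered genotype within one scope."""

    scope: str
    means: dict        # class -> mean
    se: dict           # class -> standard error
    n: dict            # class -> cell count
    missing: list = field(default_factory=list)

    def effect_table(self) -> pd.DataFrame:
        """a/d/i estimates with SEs (error propagation) and normal p-values."""
        g = self.means
        v = {k: self.se[k] ** 2 for k in g}
        need = [c for c in GENO_CLASSES if c not in g]
        if need:
            raise ValueError(f"scope {self.scope!r} lacks genotype cells {need}")
        a = (g["LL"] - g["SS"]) / 2
        d = (g["LS"] + g["SL"]) / 2 - (g["LL"] + g["SS"]) / 2
        i = (g["LS"] - g["SL"]) / 2
        se_a = np.sqrt((v["LL"] + v["SS"]) / 4)
        se_d = np.sqrt(sum(v.values()) / 4)
        se_i = np.sqrt((v["LS"] + v["SL"]) / 4)
        rows = []
        for name, est, se in (("a", a, se_a), ("d", d, se_d), ("i", i, se_i)):
            p = 2 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
            rows.append((self.scope, name, est, se, p))
        return pd.DataFrame(rows, columns=["scope", "effect", "estimate",
                                           "se", "p"])


SCOPES = (("all",), ("F",), ("M",), ("HF",), ("LF",)) + tuple(
    (s, d) for s, d in COHORTS)


def scope_mask(scope: tuple, sex: np.ndarray, diet: np.ndarray) -> np.ndarray:
    mask = np.ones(len(sex), dtype=bool)
    for key in scope:
        if key == "all":
            continue
        elif key in ("F", "M"):
            mask &= sex == key
        elif key in ("HF", "LF"):
            mask &= diet == key
        else:
            raise ValueError(f"unknown scope key {key!r}")
    return mask


def scope_label(scope: tuple) -> str:
    return "-".join(scope)


def genotypic_means(y: np.ndarray, classes: np.ndarray, sex: np.ndarray,
                    diet: np.ndarray, scope: tuple = ("all",)) -> GenotypicMeans:
    """Least-squares adjusted genotype means within a scope.

    The design regresses the trait on the four ordered-genotype indicators
    (no intercept) plus mean-centered sex/diet covariates for whichever
    factors still vary inside the scope, so each genotype coefficient is the
    adjusted mean at the scope-average covariate value.  Empty genotype
    cells are omitted and flagged.
    """
    y = np.asarray(y, float)
    classes = np.asarray(classes)
    sex = np.asarray(sex)
    diet = np.asarray(diet)
    mask = scope_mask(scope, sex, diet)
    ys, cls = y[mask], classes[mask]
    present = [c for c in GENO_CLASSES if np.any(cls == c)]
    missing = [c for c in GENO_CLASSES if c not in present]
    if missing:
        log.warning("scope %s: empty genotype cells %s omitted",
                    scope_label(scope), missing)
    dummies = np.column_stack([(cls == c).astype(float) for c in present])
    covs = []
    s, t = half_coding(sex[mask], diet[mask])
    if len(np.unique(s)) > 1:
        covs.append(s - s.mean())
    if len(np.unique(t)) > 1:
        covs.append(t - t.mean())
    if len(covs) == 2:
        st = s * t
        covs.append(st - st.mean())
    x = np.column_stack([dummies] + [c[:, None] for c in covs]) if covs else dummies
    fit = sm.OLS(ys, x).fit()
    means = {c: float(fit.params[k]) for k, c in enumerate(present)}
    ses = {c: float(fit.bse[k]) for k, c in enumerate(present)}
    ns = {c: int((cls == c).sum()) for c in present}
    return GenotypicMeans(scope_label(scope), means, ses, ns, missing)


def effects_from_means(g: dict) -> tuple:
    """(a, d, i) from a dict of the four genotypic means (point values)."""
    a = (g["LL"] - g["SS"]) / 2
    d = (g["LS"] + g["SL"]) / 2 - (g["LL"] + g["SS"]) / 2
    i = (g["LS"] - g["SL"]) / 2
    return a, d, i


# ---------------------------------------------------------------------------
# pattern classification


def classify_pattern(a: float, d: float, i: float, p_a: float, p_d: float,
                     p_i: float, alpha: float = 0.05, ratio_tol: float = 0.1,
                     imprint_band: tuple = (0.5, 2.0)) -> tuple:
    """Label the effect pattern of one cohort.

    Decision rules (significance at ``alpha`` per term):

    * imprinting + additivity, |i/a| within ``imprint_band``: paternal
      expression if i and a share sign, maternal expression otherwise
      (paternal-first convention — under paternal expression the phenotype
      tracks the paternally inherited allele);
    * imprinting + dominance without additivity: polar dominance;
    * imprinting alone: bipolar dominance;
    * additivity + dominance with |d/a| <= 1 + ``ratio_tol``: L- or
      S-dominance by the sign concordance of d with a;
    * dominance beyond the additive effect (or without one): over- or
      underdominance by the sign of d;
    * additivity alone: additive; nothing significant: none.

    Returns ``(label, flags)``; flags record multi-pattern conflicts and
    band violations rather than hiding them.
    """
    sa, sd, si = p_a <= alpha, p_d <= alpha, p_i <= alpha
    flags: list[str] = []
    if si:
        if sa and not sd:
            ratio = abs(i) / abs(a) if a != 0 else np.inf
            if imprint_band[0] <= ratio <= imprint_band[1]:
                label = ("paternal-expression" if np.sign(i) == np.sign(a)
                         else "maternal-expression")
            else:
                flags.append("imprinting-outside-band")
                label = "additive" if abs(a) >= abs(i) else "bipolar-dominance"
        elif sa and sd:
            flags.append("multi-pattern")
            if a != 0 and abs(d / a) <= 1.0 + ratio_tol:
                label = "L-dominant" if np.sign(d) == np.sign(a) else "S-dominant"
            else:
                label = "overdominant" if d > 0 else "underdominant"
        elif sd:
            label = "polar-dominance"
        else:
            label = "bipolar-dominance"
    elif sa and sd:
        if a != 0 and abs(d / a) <= 1.0 + ratio_tol:
            label = "L-dominant" if np.sign(d) == np.sign(a) else "S-dominant"
        else:
            flags.append("additive-also-significant")
            label = "overdominant" if d > 0 else "underdominant"
    elif sa:
        label = "additive"
    elif sd:
        label = "overdominant" if d > 0 else "underdominant"
    else:
        label = "none"
    return label, flags


def dominance_ratio(a: float, d: float, p_a: float = 0.0,
                    alpha: float = 0.05) -> float:
    """d/a, reported only when the additive effect is significant.

    Returns NaN (undefined) when a is not significantly non-zero.
    """
    if p_a > alpha or a == 0:
        return float("nan")
    return d / a


# ---------------------------------------------------------------------------
# differential dominance geometry


@dataclass
class DominanceGeometry:
    """Multi-trait additive/dominance vector geometry at one locus."""

    traits: list
    additive: np.ndarray      # standardized a per trait
    dominance: np.ndarray     # standardized d per trait
    angle_deg: float          # angle between the two vectors
    d_orthogonal: np.ndarray  # dominance component orthogonal to the additive axis
    weights: np.ndarray | None  # synthetic-trait weights (unit, w . a = 0)
    synthetic_a: float
    synthetic_d: float
    differential: bool
    antagonistic: bool        # additive signs differ across traits


def differential_dominance(a: np.ndarray, d: np.ndarray, sd: np.ndarray | None = None,
                           traits: list | None = None,
                           tol: float = 1e-8) -> DominanceGeometry:
    """Over/underdominance of the synthetic trait orthogonal to additivity.

    ``a`` and ``d`` hold per-trait additive and dominance effects at one
    locus; ``sd`` (phenotypic SD per trait) standardizes traits measured in
    different units before the geometry is computed.  The orthogonal
    component d_perp = d - (d . a_hat) a_hat defines weights w = d_perp /
    |d_perp|; the synthetic trait w'y then has additive effect w.a = 0 and
    dominance effect |d_perp| — pure over/underdominance whenever the two
    vectors are not colinear.
    """
    a = np.asarray(a, float)
    d = np.asarray(d, float)
    if a.shape != d.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need matched additive/dominance vectors for >= 2 traits")
    if sd is not None:
        sd = np.asarray(sd, float)
        if np.any(sd <= 0):
            raise ValueError("trait SDs must be positive")
        a, d = a / sd, d / sd
    traits = list(traits) if traits is not None else list(range(len(a)))
    na, nd = np.linalg.norm(a), np.linalg.norm(d)
    if na < tol:
        # no additive axis: all dominance is orthogonal
        d_perp = d.copy()
        angle = 90.0 if nd > tol else 0.0
    else:
        ahat = a / na
        d_perp = d - (d @ ahat) * ahat
        angle = float(np.degrees(np.arccos(np.clip(
            (d @ a) / (na * nd), -1.0, 1.0)))) if nd > tol else 0.0
    norm_perp = float(np.linalg.norm(d_perp))
    if norm_perp < tol:
        return DominanceGeometry(traits, a, d, angle, d_perp, None, 0.0, 0.0,
                                 False, bool(np.nanmin(a) < 0 < np.nanmax(a)))
    w = d_perp / norm_perp
    return DominanceGeometry(traits, a, d, angle, d_perp, w,
                             float(w @ a), float(w @ d), True,
                             bool(np.nanmin(a) < 0 < np.nanmax(a)))


# ---------------------------------------------------------------------------
# crossing vs spreading


def standardize_cohorts(values: np.ndarray, cohort: np.ndarray) -> np.ndarray:
    """Equalize per-cohort dispersion: X' = (X - mean_k) / SD_k * SD_pooled.

    SD_pooled is the plain average of the cohort SDs, so every cohort ends
    centered with SD exactly SD_pooled; differences in scale between
    cohorts are removed while rank orders of genotypic means within cohorts
    are untouched.
    """
    values = np.asarray(values, float)
    cohort = np.asarray(cohort)
    out = np.empty_like(values)
    sds = {}
    for k in np.unique(cohort):
        mask = cohort == k
        if mask.sum() < 2:
            raise ValueError(f"cohort {k!r} has fewer than 2 animals")
        sd = values[mask].std(ddof=1)
        if sd == 0:
            raise ValueError(f"cohort {k!r} has zero standard deviation")
        sds[k] = sd
    pooled = float(np.mean(list(sds.values())))
    for k, sd in sds.items():
        mask = cohort == k
        out[mask] = (values[mask] - values[mask].mean()) / sd * pooled
    return out


@dataclass
class CrossingResult:
    trait: str
    chrom: object
    pos_cm: float
    interaction_terms: dict       # term -> p before standardization
    interaction_terms_std: dict   # term -> p after standardization
    cohort_additive: pd.DataFrame
    cohort_additive_std: pd.DataFrame
    opposite_ranks: bool
    opposite_ranks_std: bool
    verdict: str                  # "crossing" | "spreading" | "none"


ADDITIVE_INTERACTIONS = ("Xa:sex", "Xa:diet", "Xa:sex:diet")


def crossing_test(y: np.ndarray, triplet: tuple, pheno: pd.DataFrame,
                  model: FamilyVarianceModel | None = None,
                  alpha: float = 0.05, trait: str = "y", chrom=None,
                  pos_cm: float = np.nan) -> CrossingResult:
    """Crossing-vs-spreading classification of an additive GxE interaction.

    The full mixed model is fitted at the locus; if no additive-by-context
    interaction (Xa:sex, Xa:diet, Xa:sex:diet) is significant the verdict is
    "none".  Otherwise the trait is re-analyzed after per-cohort
    standardization: "crossing" requires the interaction to remain
    significant on the standardized scale *and* the LL/SS genotypic ranks
    (the sign of the cohort additive effect) to be opposite between two
    cohorts with significant additive effects; anything else is "spreading".
    """
    if model is None:
        model = FamilyVarianceModel(pheno["family"], pheno["sex"], pheno["diet"])
    fit = fit_position(y, triplet, pheno, model, trait=trait,
                       chrom=chrom, pos_cm=pos_cm)
    pvals = fit.wald_p()
    inter = {t: float(pvals[fit.term_index(t)]) for t in ADDITIVE_INTERACTIONS}
    coh = fit.cohort_effects()
    coh_a = coh[coh["effect"] == "a"].reset_index(drop=True)
    opp = _opposite_ranks(coh_a, alpha)
    if min(inter.values()) > alpha:
        return CrossingResult(trait, chrom, pos_cm, inter, {}, coh_a,
                              pd.DataFrame(), opp, False, "none")

    cohort_labels = pheno["sex"].astype(str) + ":" + pheno["diet"].astype(str)
    y_std = standardize_cohorts(np.asarray(y, float), cohort_labels.to_numpy())
    fit_std = fit_position(y_std, triplet, pheno, model, trait=trait,
                           chrom=chrom, pos_cm=pos_cm)
    pvals_std = fit_std.wald_p()
    inter_std = {t: float(pvals_std[fit_std.term_index(t)])
                 for t in ADDITIVE_INTERACTIONS}
    coh_std = fit_std.cohort_effects()
    coh_a_std = coh_std[coh_std["effect"] == "a"].reset_index(drop=True)
    opp_std = _opposite_ranks(coh_a_std, alpha)
    crossing = min(inter_std.values()) <= alpha and opp_std
    verdict = "crossing" if crossing else "spreading"
    return CrossingResult(trait, chrom, pos_cm, inter, inter_std, coh_a,
                          coh_a_std, opp, opp_std, verdict)


def _opposite_ranks(coh_a: pd.DataFrame, alpha: float) -> bool:
    """Do two cohorts with significant additive effects disagree on the
    LL-vs-SS rank order (opposite signs of a)?"""
    sig = coh_a[coh_a["p"] <= alpha]
    if len(sig) < 2:
        return False
    signs = np.sign(sig["estimate"].to_numpy())
    return bool(signs.min() < 0 < signs.max())


# ---------------------------------------------------------------------------
# locus-level report


def effect_report(y: np.ndarray, classes: np.ndarray, sex: np.ndarray,
                  diet: np.ndarray, trait: str = "y", locus: str = "",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-scope genotypic means, a/d/i, d/a ratio and pattern label.

    Scopes are the full population, each sex, each diet, and the four
    sex-by-diet cohorts.  One row per scope.
    """
    rows = []
    for scope in SCOPES:
        if not scope_mask(scope, np.asarray(sex), np.asarray(diet)).any():
            continue
        gm = genotypic_means(y, classes, sex, diet, scope)
        if gm.missing:
            continue
        eff = gm.effect_table().set_index("effect")
        a, d, i = (eff.loc[k, "estimate"] for k in "adi")
        pa, pd_, pi = (eff.loc[k, "p"] for k in "adi")
        label, flags = classify_pattern(a, d, i, pa, pd_, pi, alpha=alpha)
        rows.append({
            "locus": locus, "trait": trait, "scope": gm.scope,
            **{f"G_{c}": gm.means[c] for c in GENO_CLASSES},
            "a": a, "se_a": eff.loc["a", "se"], "p_a": pa,
            "d": d, "se_d": eff.loc["d", "se"], "p_d": pd_,
            "i": i, "se_i": eff.loc["i", "se"], "p_i": pi,
            "d_over_a": dominance_ratio(a, d, pa, alpha),
            "pattern": label, "flags": ";".join(flags),
        })
    return pd.DataFrame(rows)
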