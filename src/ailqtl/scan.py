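"""Genome scan: per-position mixed-model LRTs, LOD profiles, thresholds.

At every grid position the full model

    Y = mu + s + t + s:t
        + a*X_a + d*X_d + i*X_i
        + (each score) x s, x t, x s:t          (12 genetic terms)
        + family random effects + e

is compared by maximum likelihood against the null model with the same
random structure but only mu, s, t, s:t fixed effects, giving a 12-df
chi-square; probabilities become LOD = -log10(Pr).  Sex and diet are coded
+-1/2 (M/HF positive), so the genetic main effects are averages over the
four cohorts and the interaction coefficients are cohort contrasts — any
cohort's (a, d, i) is a simple linear combination of four coefficients.

Significance thresholds use the Li & Ji (2005) effective number of
independent tests from the eigenvalues of the marker additive-score
correlation matrix, Bonferroni-adjusted as alpha' = 1 - (1-alpha)^(1/M_eff),
genome-wide and per chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedlm import FamilyVarianceModel, VCFit, lr_chisq
from .scores import ScoreTable
from .simulate import COHORTS, half_coding

log = logging.getLogger(__name__)

GENETIC_DF = 12

NULL_TERMS = ["mu", "sex", "diet", "sex:diet"]
SCORE_NAMES = ("Xa", "Xd", "Xi")
GENETIC_TERMS = [f"{s}{suffix}" for s in SCORE_NAMES
                 for suffix in ("", ":sex", ":diet", ":sex:diet")]
FULL_TERMS = NULL_TERMS + GENETIC_TERMS


def null_design(pheno: pd.DataFrame) -> np.ndarray:
    """(n, 4) design: intercept, sex, diet, sex:diet (half coding)."""
    s, t = half_coding(pheno["sex"].to_numpy(), pheno["diet"].to_numpy())
    return np.column_stack([np.ones(len(pheno)), s, t, s * t])


def full_design(pheno: pd.DataFrame, xa, xd, xi) -> np.ndarray:
    """(n, 16) design: null terms plus the 12 genetic terms."""
    x0 = null_design(pheno)
    s, st = x0[:, 1], x0[:, 3]
    t = x0[:, 2]
    cols = [x0]
    for score in (xa, xd, xi):
        cols.append(np.column_stack([score, score * s, score * t, score * st]))
    return np.column_stack(cols)


def lod_from_chisq(chisq: float, df: int = GENETIC_DF) -> float:
    """LOD = -log10 of the chi-square upper-tail probability.

    Computed on the log scale so extreme statistics keep a finite LOD; when
    even the log survival function underflows, the standard asymptotic tail
    expansion sf(x) ~ e^{-x/2} (x/2)^{k/2-1} / Gamma(k/2) * (1 + (k/2-1)/(x/2))
    takes over.
    """
    logsf = stats.chi2.logsf(chisq, df)
    if not np.isfinite(logsf) and chisq > df:
        from scipy.special import gammaln

        h, a = chisq / 2.0, df / 2.0
        logsf = -h + (a - 1.0) * np.log(h) - gammaln(a) + np.log1p((a - 1.0) / h)
    return float(-logsf / np.log(10.0))


@dataclass
class PositionFit:
    """Full-vs-null mixed-model comparison at one position for one trait."""

    trait: str
    chrom: object
    pos_cm: float
    loglik_full: float
    loglik_null: float
    chisq: float
    df: int
    p: float
    lod: float
    terms: list
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    gamma: np.ndarray
    sigma2: float

    def wald_p(self) -> np.ndarray:
        """Two-sided normal p-value per fixed-effect coefficient."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, 0.0)
        return 2.0 * stats.norm.sf(np.abs(z))

    def term_index(self, term: str) -> int:
        return self.terms.index(term)

    def cohort_effects(self) -> pd.DataFrame:
        """Per-cohort a/d/i estimates as contrasts of the interaction model.

        For cohort (sex, diet) with half codes (s, t) the additive effect is
        a_c = b[Xa] + s*b[Xa:sex] + t*b[Xa:diet] + s*t*b[Xa:sex:diet], and
        likewise for d and i; standard errors come from the coefficient
        covariance, p-values from the normal approximation.
        """
        rows = []
        for sex, diet in COHORTS:
            s = 0.5 if sex == "M" else -0.5
            t = 0.5 if diet == "HF" else -0.5
            for score, label in zip(SCORE_NAMES, "adi"):
                c = np.zeros(len(self.terms))
                c[self.term_index(score)] = 1.0
                c[self.term_index(f"{score}:sex")] = s
                c[self.term_index(f"{score}:diet")] = t
                c[self.term_index(f"{score}:sex:diet")] = s * t
                est = float(c @ self.beta)
                se = float(np.sqrt(max(c @ self.cov_beta @ c, 0.0)))
                p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else 1.0
                rows.append((sex, diet, label, est, se, p))
        return pd.DataFrame(rows, columns=["sex", "diet", "effect",
                                           "estimate", "se", "p"])


def fit_position(y: np.ndarray, triplet: tuple, pheno: pd.DataFrame,
                 model: FamilyVarianceModel | None = None,
                 null_fit: VCFit | None = None, trait: str = "y",
                 chrom=None, pos_cm: float = np.nan,
                 gamma: np.ndarray | None = None,
                 small_sample_correction: bool = True) -> PositionFit:
    """Fit the full and null mixed models at one position.

    ``null_fit`` (one per trait; position-independent) is reused across a
    scan; the full fit warm-starts at the null's variance ratios, which also
    guarantees a non-negative likelihood-ratio statistic.  ``gamma`` pins
    the variance ratios for both models (used by oracle tests).

    ``small_sample_correction`` rescales the likelihood-ratio statistic by
    the Bartlett-type factor (n - p_full)/n.  Profiled-ML likelihood ratios
    over p fixed effects are known to run hot by a multiplicative O(p/n)
    factor, which compounds badly in the extreme tail a genome scan
    thresholds on; the rescaling restores the 12-df reference calibration
    and is a <2% change at the ~1,000-animal scale the design targets.
    """
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError(f"trait {trait!r} is constant")
    if model is None:
        model = FamilyVarianceModel(pheno["family"], pheno["sex"], pheno["diet"])
    if null_fit is None:
        null_fit = model.fit(null_design(pheno), y, gamma=gamma)
    xa, xd, xi = triplet
    x_full = full_design(pheno, xa, xd, xi)
    full = model.fit(x_full, y, start=null_fit.gamma, gamma=gamma)
    chisq = lr_chisq(full, null_fit)
    if small_sample_correction:
        n = len(y)
        chisq *= (n - x_full.shape[1]) / n
    p = float(stats.chi2.sf(chisq, GENETIC_DF))
    return PositionFit(
        trait=trait, chrom=chrom, pos_cm=float(pos_cm),
        loglik_full=full.loglik, loglik_null=null_fit.loglik,
        chisq=chisq, df=GENETIC_DF, p=p, lod=lod_from_chisq(chisq),
        terms=list(FULL_TERMS), beta=full.beta, se=full.se,
        cov_beta=full.cov_beta, gamma=full.gamma, sigma2=full.sigma2,
    )


@dataclass
class ScanResult:
    """LOD/chi-square profiles for every trait over the scan grid."""

    table: pd.DataFrame  # trait, chrom, pos_cm, is_marker, chisq, df, p, lod + est_*/se_*
    traits: list
    fits: dict = field(default_factory=dict)  # (trait, position index) -> PositionFit

    def profile(self, trait: str, chrom=None) -> pd.DataFrame:
        sub = self.table[self.table["trait"] == trait]
        if chrom is not None:
            sub = sub[sub["chrom"] == chrom]
        return sub.reset_index(drop=True)

    def peak(self, trait: str, chrom=None, region: tuple | None = None) -> pd.Series:
        sub = self.profile(trait, chrom)
        if region is not None:
            sub = sub[(sub["pos_cm"] >= region[0]) & (sub["pos_cm"] <= region[1])]
        if len(sub) == 0:
            raise ValueError(f"no scan positions for {trait!r} in the requested scope")
        return sub.loc[sub["lod"].idxmax()]

    def at(self, trait: str, chrom, pos_cm: float) -> pd.Series:
        sub = self.profile(trait, chrom)
        hit = sub[np.isclose(sub["pos_cm"], pos_cm)]
        if len(hit) == 0:
            raise ValueError(f"position {pos_cm} cM not on the scan grid")
        return hit.iloc[0]


def scan(score_table: ScoreTable, pheno: pd.DataFrame, traits: list | None = None,
         model: FamilyVarianceModel | None = None, keep_fits: bool = False,
         gamma: np.ndarray | None = None) -> ScanResult:
    """Scan every grid position for every trait.

    ``pheno`` rows must align with ``score_table.animals``.  Hard failures
    at single positions are logged and recorded as NaN rows rather than
    aborting the scan.
    """
    if not np.array_equal(np.asarray(pheno["animal"]), score_table.animals):
        raise ValueError("phenotype rows must align with score-table animals")
    if traits is None:
        reserved = {"animal", "family", "sex", "diet"}
        traits = [c for c in pheno.columns if c not in reserved]
    if model is None:
        model = FamilyVarianceModel(pheno["family"], pheno["sex"], pheno["diet"])
    x0 = null_design(pheno)
    grid = score_table.grid
    rows = []
    fits = {}
    est_cols = [f"est_{t}" for t in FULL_TERMS] + [f"se_{t}" for t in FULL_TERMS]
    for trait in traits:
        y = pheno[trait].to_numpy(float)
        null_fit = model.fit(x0, y, gamma=gamma)
        for j in range(score_table.n_positions):
            chrom = grid["chrom"].iloc[j]
            pos = float(grid["pos_cm"].iloc[j])
            try:
                pf = fit_position(y, score_table.triplet(j), pheno, model,
                                  null_fit, trait=trait, chrom=chrom,
                                  pos_cm=pos, gamma=gamma)
            except Exception:  # pragma: no cover - defensive
                log.exception("fit failed for %s at %s:%.2f", trait, chrom, pos)
                rows.append([trait, chrom, pos, bool(grid["is_marker"].iloc[j]),
                             np.nan, GENETIC_DF, np.nan, np.nan]
                            + [np.nan] * len(est_cols))
                continue
            rows.append([trait, chrom, pos, bool(grid["is_marker"].iloc[j]),
                         pf.chisq, pf.df, pf.p, pf.lod]
                        + list(pf.beta) + list(pf.se))
            if keep_fits:
                fits[(trait, j)] = pf
    table = pd.DataFrame(rows, columns=["trait", "chrom", "pos_cm", "is_marker",
                                        "chisq", "df", "p", "lod"] + est_cols)
    return ScanResult(table, list(traits), fits)


# ---------------------------------------------------------------------------
# multiple testing


def effective_tests(score_matrix: np.ndarray) -> float:
    """Li & Ji (2005) effective number of independent tests.

    ``score_matrix`` is (n_animals, n_markers) of additive scores.  From the
    eigenvalues of the marker correlation matrix,
    M_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ].
    Constant marker columns carry no test and are dropped with a warning.
    """
    x = np.asarray(score_matrix, float)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("need an (n_animals, n_markers) score matrix")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        log.warning("dropping %d constant marker column(s) from M_eff",
                    int((sd == 0).sum()))
        x = x[:, sd > 0]
        if x.shape[1] == 0:
            raise ValueError("all marker columns constant")
    corr = np.corrcoef(x, rowvar=False)
    if corr.ndim == 0:  # single marker
        return 1.0
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    return float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))


def adjusted_alpha(m_eff: float, alpha: float = 0.05) -> float:
    """Bonferroni-type adjustment 1 - (1-alpha)^(1/M_eff)."""
    if m_eff < 1:
        raise ValueError("M_eff must be >= 1")
    if alpha == 0:
        return 0.0
    return 1.0 - (1.0 - alpha) ** (1.0 / m_eff)


def thresholds(marker_scores: ScoreTable, alpha: float = 0.05) -> pd.DataFrame:
    """Genome-wide and per-chromosome Li–Ji LOD thresholds.

    Returns rows (scope, m_eff, alpha_adjusted, lod_threshold) where scope
    is ``"genome"`` or a chromosome id; the LOD threshold is
    -log10(adjusted alpha).
    """
    mk = marker_scores.marker_scores()
    rows = []
    scopes = [("genome", slice(None))]
    scopes += [(c, mk.positions_on(c)) for c in dict.fromkeys(mk.grid["chrom"])]
    for scope, idx in scopes:
        m_eff = effective_tests(mk.xa[:, idx])
        a_adj = adjusted_alpha(m_eff, alpha)
        lod_thr = np.inf if a_adj == 0 else -np.log10(a_adj)
        rows.append((scope, m_eff, a_adj, lod_thr))
    return pd.DataFrame(rows, columns=["scope", "m_eff", "alpha_adjusted",
                                       "lod_threshold"])


def support_interval(positions: np.ndarray, lod: np.ndarray,
                     drop: float = 1.0) -> dict:
    """One-LOD-drop support interval around the profile peak.

    Returns the contiguous region containing the peak where
    LOD >= peak - drop, with truncation flags at the chromosome ends and a
    flat-profile flag (flat profiles span the whole chromosome).
    """
    positions = np.asarray(positions, float)
    lod = np.asarray(lod, float)
    if len(positions) == 0 or not np.isfinite(lod).any():
        raise ValueError("profile has no finite maximum")
    peak_idx = int(np.nanargmax(lod))
    peak = lod[peak_idx]
    flat = bool(np.nanmax(lod) - np.nanmin(lod) < 1e-12)
    lo = peak_idx
    while lo > 0 and lod[lo - 1] >= peak - drop:
        lo -= 1
    hi = peak_idx
    while hi < len(lod) - 1 and lod[hi + 1] >= peak - drop:
        hi += 1
    return {
        "peak_cm": float(positions[peak_idx]),
        "peak_lod": float(peak),
        "left_cm": float(positions[lo]),
        "right_cm": float(positions[hi]),
        "left_truncated": bool(lo == 0 and lod[0] >= peak - drop),
        "right_truncated": bool(hi == len(lod) - 1 and lod[-1] >= peak - drop),
        "flat": flat,
    }
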