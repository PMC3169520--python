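"""Additive / dominance / imprinting genotypic scores and imputation.

At an observed marker the ordered genotype (paternal allele first) codes to

====  ====  ====  ====
geno  X_a   X_d   X_i
====  ====  ====  ====
LL     +1    0     0
LS      0    1    +1
SL      0    1    -1
SS     -1    0     0
====  ====  ====  ====

so the regression coefficients on X_a, X_d, X_i are the additive effect a,
the dominance deviation d, and the parent-of-origin (imprinting) effect i.

Between markers, expected scores are imputed on a pseudomarker grid by
flanking-marker regression in the Haley–Knott style, extended to the
imprinting score: because the paternal and maternal transmissions are
independent, with p = P(paternal allele is L | paternal flanks) and
q = P(maternal allele is L | maternal flanks),

    X_a = p + q - 1,   X_i = p - q,   X_d = p(1-q) + (1-p)q,

which obey the identity X_d = (1 + X_i^2 - X_a^2) / 2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneticMap, OrderedGenotypes, haldane

#: exact coding at observed markers, ordered genotype -> (X_a, X_d, X_i)
SCORE_CODING = {
    "LL": (1.0, 0.0, 0.0),
    "LS": (0.0, 1.0, 1.0),
    "SL": (0.0, 1.0, -1.0),
    "SS": (-1.0, 0.0, 0.0),
}


@dataclass
class ScoreTable:
    """Genotypic scores for all animals over a position grid.

    ``grid`` has one row per position (``chrom``, ``pos_cm``, ``is_marker``);
    ``xa``/``xd``/``xi`` are (n_animals, n_positions) arrays.
    """

    animals: np.ndarray
    grid: pd.DataFrame
    xa: np.ndarray
    xd: np.ndarray
    xi: np.ndarray

    @property
    def n_positions(self) -> int:
        return len(self.grid)

    def triplet(self, j: int) -> tuple:
        """Score columns at grid position ``j``."""
        return self.xa[:, j], self.xd[:, j], self.xi[:, j]

    def marker_scores(self) -> "ScoreTable":
        """Restrict to observed-marker positions."""
        mask = self.grid["is_marker"].to_numpy()
        return ScoreTable(self.animals, self.grid[mask].reset_index(drop=True),
                          self.xa[:, mask], self.xd[:, mask], self.xi[:, mask])

    def positions_on(self, chrom) -> np.ndarray:
        return np.flatnonzero((self.grid["chrom"] == chrom).to_numpy())

    def to_frame(self) -> pd.DataFrame:
        """Long table: animal, chrom, pos_cm, is_marker, X_a, X_d, X_i."""
        n, m = self.xa.shape
        return pd.DataFrame({
            "animal": np.repeat(self.animals, m),
            "chrom": np.tile(self.grid["chrom"].to_numpy(), n),
            "pos_cm": np.tile(self.grid["pos_cm"].to_numpy(), n),
            "is_marker": np.tile(self.grid["is_marker"].to_numpy(), n),
            "X_a": self.xa.ravel(),
            "X_d": self.xd.ravel(),
            "X_i": self.xi.ravel(),
        })


def score_genotypes(geno: OrderedGenotypes) -> ScoreTable:
    """Exact a/d/i scores at every observed marker."""
    p = geno.paternal.astype(float)
    m = geno.maternal.astype(float)
    xa = p + m - 1.0
    xi = p - m
    xd = (geno.paternal != geno.maternal).astype(float)
    grid = pd.DataFrame({
        "chrom": geno.map.frame["chrom"].to_numpy(),
        "pos_cm": geno.map.frame["cm"].to_numpy(float),
        "is_marker": True,
    })
    return ScoreTable(geno.animals.copy(), grid, xa, xd, xi)


def transmission_probability(left_allele, right_allele, d_left_cm: float,
                             d_right_cm: float):
    """P(transmitted allele at the target position is L | flanking alleles).

    ``left_allele`` / ``right_allele`` are the alleles observed on the *same
    transmitted haplotype* at the flanking markers ("L"/"S", or None for a
    missing flank at a chromosome end); distances are target-to-flank in cM,
    converted to recombination fractions by the Haldane map function.
    Vectorized over allele arrays.
    """
    if d_left_cm < 0 or d_right_cm < 0:
        raise ValueError("flank distances must be >= 0")
    r1, r2 = float(haldane(d_left_cm)), float(haldane(d_right_cm))
    if left_allele is None and right_allele is None:
        raise ValueError("need at least one flanking allele")
    if left_allele is None:
        return _single_flank(right_allele, r2)
    if right_allele is None:
        return _single_flank(left_allele, r1)
    f = _single_flank(left_allele, r1)
    g = _single_flank(right_allele, r2)
    return f * g / (f * g + (1.0 - f) * (1.0 - g))


def _single_flank(allele, r: float):
    is_l = np.asarray(allele) == "L"
    out = np.where(is_l, 1.0 - r, r)
    return float(out) if out.ndim == 0 else out


def build_grid(gmap: GeneticMap, step_cm: float | None = 1.0) -> pd.DataFrame:
    """Pseudomarker grid: all markers plus points every ``step_cm``.

    ``step_cm=None`` yields markers only.  Interpolated points are inserted
    at multiples of the step within each inter-marker interval (open on both
    ends, so marker positions are never duplicated).
    """
    if step_cm is not None and step_cm <= 0:
        raise ValueError("grid step must be > 0")
    rows = []
    for chrom in gmap.chromosomes:
        cm = gmap.markers_on(chrom)["cm"].to_numpy(float)
        pos = list(cm)
        if step_cm is not None:
            for lo, hi in zip(cm[:-1], cm[1:]):
                k = np.floor(lo / step_cm) * step_cm + step_cm
                extra = np.arange(k, hi - 1e-9, step_cm)
                pos.extend(p for p in extra if p > lo + 1e-9)
        pos = np.array(sorted(pos))
        for p in pos:
            rows.append((chrom, float(p), bool(np.any(np.isclose(cm, p)))))
    return pd.DataFrame(rows, columns=["chrom", "pos_cm", "is_marker"])


def impute_scores(geno: OrderedGenotypes, grid: pd.DataFrame | None = None,
                  step_cm: float | None = 1.0) -> ScoreTable:
    """Expected a/d/i scores at every grid position.

    Marker positions carry the exact coding; interpolated positions carry
    expectations from the flanking markers of the same chromosome, with
    paternal and maternal transmissions conditioned independently.  Grid
    points beyond the terminal markers (not produced by :func:`build_grid`)
    condition on the single nearest flank.
    """
    gmap = geno.map
    if grid is None:
        grid = build_grid(gmap, step_cm)
    n = geno.n_animals
    xa = np.empty((n, len(grid)))
    xd = np.empty_like(xa)
    xi = np.empty_like(xa)
    al = OrderedGenotypes.ALLELES
    for chrom in dict.fromkeys(grid["chrom"]):
        sub = gmap.markers_on(chrom)
        mk_cm = sub["cm"].to_numpy(float)
        mk_idx = sub.index.to_numpy()
        gmask = np.flatnonzero((grid["chrom"] == chrom).to_numpy())
        for j in gmask:
            pos = float(grid["pos_cm"].iloc[j])
            exact = np.flatnonzero(np.isclose(mk_cm, pos))
            if len(exact):
                mi = int(mk_idx[exact[0]])
                p_ = geno.paternal[:, mi].astype(float)
                m_ = geno.maternal[:, mi].astype(float)
                xa[:, j] = p_ + m_ - 1.0
                xi[:, j] = p_ - m_
                xd[:, j] = (p_ != m_).astype(float)
                continue
            li = int(np.searchsorted(mk_cm, pos)) - 1
            ri = li + 1
            left = int(mk_idx[li]) if li >= 0 else None
            right = int(mk_idx[ri]) if ri < len(mk_cm) else None
            dl = pos - mk_cm[li] if left is not None else 0.0
            dr = mk_cm[ri] - pos if right is not None else 0.0
            p = _flank_prob(al[geno.paternal], left, right, dl, dr)
            q = _flank_prob(al[geno.maternal], left, right, dl, dr)
            xa[:, j] = p + q - 1.0
            xi[:, j] = p - q
            xd[:, j] = p * (1.0 - q) + (1.0 - p) * q
    return ScoreTable(geno.animals.copy(), grid.reset_index(drop=True), xa, xd, xi)


def _flank_prob(hap_alleles: np.ndarray, left: int | None, right: int | None,
                d_left: float, d_right: float) -> np.ndarray:
    la = hap_alleles[:, left] if left is not None else None
    ra = hap_alleles[:, right] if right is not None else None
    return transmission_probability(la, ra, d_left, d_right)
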