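"""Formal test of pleiotropy for traits mapping to overlapping regions.

When several traits' QTL support intervals overlap but their peaks do not
coincide, the question is whether one shared locus (pleiotropy) explains
them or the region holds multiple QTL.  The test compares each trait fitted
at its own peak against all traits fitted at a single combined position:

* the combined position is the grid point maximizing the summed LOD over
  traits (the LOD-weighted most likely shared position);
* the statistic is sum_t [ chi2_t(peak_t) - chi2_t(combined) ] with
  df = n_traits - 1 (separate model has one position per trait, the
  combined model a single one);
* a small p (<= 0.05) rejects the simpler single-QTL model, i.e. indicates
  more than one QTL; failing to reject retains pleiotropy.

Traits whose peaks fall at the identical cM position are declared
pleiotropic without the formal test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scan import ScanResult, support_interval

log = logging.getLogger(__name__)


@dataclass
class PleiotropyResult:
    chrom: object
    region: tuple  # (left cM, right cM)
    traits: list
    peaks: dict          # trait -> (pos_cm, chisq, lod)
    combined_cm: float
    chisq_at_combined: dict  # trait -> chisq
    statistic: float
    df: int
    p: float
    verdict: str         # "pleiotropy retained" | "pleiotropy rejected"
    coincident: bool
    tie_broken: bool
    support: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "chrom": self.chrom,
            "region_left_cm": self.region[0],
            "region_right_cm": self.region[1],
            "traits": ",".join(map(str, self.traits)),
            "combined_cm": self.combined_cm,
            "chisq": self.statistic,
            "df": self.df,
            "p": self.p,
            "verdict": self.verdict,
            "support_left_cm": self.support.get("left_cm", np.nan),
            "support_right_cm": self.support.get("right_cm", np.nan),
        }


def combined_position(profiles: dict) -> tuple:
    """Grid position maximizing the summed LOD over traits.

    ``profiles`` maps trait -> DataFrame with ``pos_cm`` and ``lod`` on a
    shared grid.  Ties are broken toward the position closest to the
    unweighted mean of the per-trait peak positions (and logged).

    Returns ``(pos_cm, tie_broken)``.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 traits to combine")
    items = list(profiles.items())
    pos = items[0][1]["pos_cm"].to_numpy(float)
    total = np.zeros(len(pos))
    peaks = []
    for trait, prof in items:
        p = prof["pos_cm"].to_numpy(float)
        if len(p) != len(pos) or not np.allclose(p, pos):
            raise ValueError("trait profiles are on different grids")
        lod = prof["lod"].to_numpy(float)
        total += lod
        peaks.append(pos[int(np.nanargmax(lod))])
    best = np.flatnonzero(np.isclose(total, np.nanmax(total), atol=1e-10))
    if len(best) == 1:
        return float(pos[best[0]]), False
    center = float(np.mean(peaks))
    winner = best[int(np.argmin(np.abs(pos[best] - center)))]
    log.info("combined-position tie among %d grid points; broke toward %.2f cM",
             len(best), pos[winner])
    return float(pos[winner]), True


def test_pleiotropy(scan: ScanResult, chrom, region: tuple, traits: list,
                    alpha: float = 0.05) -> PleiotropyResult:
    """Summed chi-square-difference pleiotropy test over one region."""
    if len(traits) < 2:
        raise ValueError("pleiotropy test needs >= 2 traits")
    lo, hi = float(region[0]), float(region[1])
    profiles = {}
    peaks = {}
    for trait in traits:
        prof = scan.profile(trait, chrom)
        prof = prof[(prof["pos_cm"] >= lo) & (prof["pos_cm"] <= hi)]
        if len(prof) == 0:
            raise ValueError(f"trait {trait!r} has no scan positions in region")
        prof = prof.reset_index(drop=True)
        profiles[trait] = prof
        pk = prof.loc[prof["lod"].idxmax()]
        peaks[trait] = (float(pk["pos_cm"]), float(pk["chisq"]), float(pk["lod"]))
    peak_positions = [p[0] for p in peaks.values()]
    coincident = len(set(peak_positions)) == 1

    if coincident:
        comb, tie = peak_positions[0], False
    else:
        comb, tie = combined_position(profiles)

    chisq_comb = {}
    statistic = 0.0
    for trait, prof in profiles.items():
        row = prof[np.isclose(prof["pos_cm"], comb)]
        c = float(row["chisq"].iloc[0])
        chisq_comb[trait] = c
        statistic += max(peaks[trait][1] - c, 0.0)
    df = len(traits) - 1
    p = 1.0 if coincident else float(stats.chi2.sf(statistic, df))
    if coincident:
        statistic = 0.0
    verdict = "pleiotropy rejected" if p <= alpha else "pleiotropy retained"

    total_prof = profiles[traits[0]][["pos_cm"]].copy()
    total_lod = np.sum([profiles[t]["lod"].to_numpy(float) for t in traits], axis=0)
    support = support_interval(total_prof["pos_cm"].to_numpy(), total_lod)
    return PleiotropyResult(chrom, (lo, hi), list(traits), peaks, comb,
                            chisq_comb, statistic, df, p, verdict,
                            coincident, tie, support)


def overlapping_regions(scan: ScanResult, thresholds: pd.DataFrame,
                        scope: str = "chromosome") -> list:
    """Group significant trait peaks into candidate pleiotropic regions.

    For each chromosome, traits whose peak LOD passes the scope threshold
    contribute their one-LOD support interval; intervals sharing any
    overlap are merged (union), and each merged region with its member
    traits is returned as ``(chrom, (left, right), [traits])``.
    """
    thr = {row["scope"]: row["lod_threshold"] for _, row in thresholds.iterrows()}
    out = []
    for chrom in dict.fromkeys(scan.table["chrom"]):
        cut = thr.get(chrom if scope == "chromosome" else "genome",
                      thr.get("genome"))
        hits = []
        for trait in scan.traits:
            prof = scan.profile(trait, chrom)
            if prof["lod"].max() < cut:
                continue
            si = support_interval(prof["pos_cm"].to_numpy(),
                                  prof["lod"].to_numpy())
            hits.append((si["left_cm"], si["right_cm"], trait))
        hits.sort()
        merged: list[list] = []
        for left, right, trait in hits:
            if merged and left <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], right)
                merged[-1][2].append(trait)
            else:
                merged.append([left, right, [trait]])
        out.extend((chrom, (m[0], m[1]), m[2]) for m in merged)
    return out
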