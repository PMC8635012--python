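"""Extended haplotype homozygosity, iHH integration, XP-EHH, and LD decay.

EHH here is the *site* form: at a span from the core marker to a flanking
marker, all haplotypes are partitioned by their allele string over the span
and EHH is the probability that two haplotypes drawn without replacement fall
in the same class, ``sum_g C(c_g, 2) / C(n, 2)``.  At the core itself this is
the core-site homozygosity.

iHH integrates EHH against physical distance (bp) with the trapezoid rule,
separately left and right of the core, walking marker by marker until EHH
drops below a cutoff (default 0.05) and interpolating linearly to the exact
crossing.  If the chromosome edge arrives first the side is integrated to the
edge and flagged.

XP-EHH is ``ln(iHH_low / iHH_high)`` between the low- and high-phenotype
subpopulations; negative scores therefore point at extended haplotypes (a
sweep) in the *high* subpopulation.  Scores are used unstandardized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeMatrix, HaplotypeMatrix, MarkerMap
from .cohortpairs import GradientPairs

__all__ = [
    "EhhProfile",
    "ehh_at",
    "ehh_profile",
    "ihh",
    "xpehh",
    "xpehh_scan",
    "ld_r2",
    "ld_decay",
]

EDGE = "chromosome_edge"
CUTOFF = "cutoff_reached"
DEGENERATE = "core_below_cutoff"


def _homozygosity(counts: np.ndarray, n: int) -> float:
    """All-pairs identity probability from class counts."""
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _values(H) -> np.ndarray:
    return H.values if isinstance(H, HaplotypeMatrix) else np.asarray(H)


def ehh_at(H, core: int, j: int) -> float:
    """EHH over the inclusive marker span [min(core, j), max(core, j)].

    Haplotypes are grouped by their allele string over the span; EHH is the
    fraction of haplotype pairs that are identical over it.
    """
    vals = _values(H)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("EHH requires at least 2 haplotypes")
    lo, hi = min(core, j), max(core, j)
    span = vals[:, lo : hi + 1]
    _, counts = np.unique(span, axis=0, return_counts=True)
    return _homozygosity(counts, n)


@dataclass
class EhhProfile:
    """EHH as a function of distance from a core marker, both directions.

    Distances are in bp; index 0 of each side is the core itself (distance 0,
    EHH = core-site homozygosity).  ``left_flag``/``right_flag`` say why the
    walk stopped: the EHH cutoff was crossed or the chromosome edge reached.
    """

    core: int
    left_dist: np.ndarray
    left_ehh: np.ndarray
    right_dist: np.ndarray
    right_ehh: np.ndarray
    left_flag: str = EDGE
    right_flag: str = EDGE


def _side_walk(vals, positions, core, stop, step, cutoff):
    """Walk from the core toward ``stop`` (inclusive index bound), refining the
    haplotype partition one marker at a time; returns (dists, ehhs, flag)."""
    n = vals.shape[0]
    labels = vals[:, core].astype(np.int64)
    counts = np.bincount(labels, minlength=1)
    e = _homozygosity(counts[counts > 0], n)
    dists = [0.0]
    ehhs = [e]
    flag = EDGE
    if e < cutoff:
        return np.array(dists), np.array(ehhs), CUTOFF
    p0 = positions[core]
    j = core
    while j != stop:
        j += step
        labels = labels * 2 + vals[:, j]
        labels = np.unique(labels, return_inverse=True)[1]
        counts = np.bincount(labels)
        e = _homozygosity(counts, n)
        dists.append(abs(int(positions[j]) - int(p0)))
        ehhs.append(e)
        if e < cutoff:
            flag = CUTOFF
            break
    return np.asarray(dists, dtype=float), np.asarray(ehhs, dtype=float), flag


def ehh_profile(H, core: int, M: MarkerMap, cutoff: float = 0.05) -> EhhProfile:
    """EHH decay profile around a core marker, truncated at ``cutoff``.

    The walk never leaves the core's chromosome.
    """
    vals = _values(H)
    if vals.shape[0] < 2:
        raise ValueError("EHH requires at least 2 haplotypes")
    blocks = M.chrom_blocks()
    i0, i1 = blocks[M.chrom[core]]
    ld, le, lf = _side_walk(vals, M.pos, core, i0, -1, cutoff)
    rd, re, rf = _side_walk(vals, M.pos, core, i1 - 1, +1, cutoff)
    return EhhProfile(core, ld, le, rd, re, lf, rf)


def _side_area(dists: np.ndarray, ehhs: np.ndarray, flag: str, cutoff: float) -> float:
    """Trapezoid area under an EHH-vs-distance side profile.

    Integrates up to the interpolated cutoff crossing when the walk ended by
    cutoff; to the last marker when it ended at the chromosome edge.
    """
    area = 0.0
    for k in range(1, len(dists)):
        d0, d1 = dists[k - 1], dists[k]
        e0, e1 = ehhs[k - 1], ehhs[k]
        if e1 < cutoff:
            # linear interpolation to the exact crossing
            if e0 > e1:
                dstar = d0 + (e0 - cutoff) / (e0 - e1) * (d1 - d0)
            else:  # e0 == e1 < cutoff cannot happen (walk would have stopped)
                dstar = d1
            area += 0.5 * (e0 + cutoff) * (dstar - d0)
            break
        area += 0.5 * (e0 + e1) * (d1 - d0)
    return area


def ihh(H, core: int, M: MarkerMap, cutoff: float = 0.05) -> tuple[float, dict]:
    """Integrated EHH (bp units) around the core, with per-side stop flags.

    Returns 0 with flag ``core_below_cutoff`` when even the core-site
    homozygosity is below the cutoff.
    """
    prof = ehh_profile(H, core, M, cutoff)
    flags = {"left": prof.left_flag, "right": prof.right_flag}
    if prof.left_ehh[0] < cutoff:
        flags["left"] = flags["right"] = DEGENERATE
        return 0.0, flags
    left = _side_area(prof.left_dist, prof.left_ehh, prof.left_flag, cutoff)
    right = _side_area(prof.right_dist, prof.right_ehh, prof.right_flag, cutoff)
    return left + right, flags


def xpehh(
    H_low, H_high, core: int, M: MarkerMap, cutoff: float = 0.05,
    drop_edge: bool = False,
) -> float:
    """Unstandardized XP-EHH: ln(iHH_low / iHH_high).

    Negative values indicate extended haplotype homozygosity (selection) in
    the high-phenotype subpopulation.  Returns NaN when either iHH is zero or
    (with ``drop_edge``) when either walk was truncated by a chromosome edge.
    """
    ihh_low, fl = ihh(H_low, core, M, cutoff)
    ihh_high, fh = ihh(H_high, core, M, cutoff)
    if ihh_low <= 0.0 or ihh_high <= 0.0:
        return float("nan")
    if drop_edge and (EDGE in fl.values() or EDGE in fh.values()):
        return float("nan")
    return math.log(ihh_low / ihh_high)


def xpehh_scan(
    H: HaplotypeMatrix,
    gp: GradientPairs,
    M: MarkerMap,
    cutoff: float = 0.05,
    drop_edge: bool = False,
) -> np.ndarray:
    """XP-EHH at every marker for each pair level, shape (m, 3); NaN = missing."""
    m = H.n_markers
    out = np.full((m, 3), np.nan)
    for k, (high, low) in enumerate(gp.levels):
        v_low = H.subset_samples(low).values
        v_high = H.subset_samples(high).values
        for core in range(m):
            out[core, k] = xpehh(v_low, v_high, core, M, cutoff, drop_edge)
    return out


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns over samples complete
    in both; NaN if either column is constant among the complete samples."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValueError("ld_r2 requires at least 2 complete observations")
    x, y = g1[ok], g2[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


def ld_decay(
    G: GenotypeMatrix, M: MarkerMap, bin_bp: int = 1000, max_dist: int = 1_000_000
) -> pd.DataFrame:
    """Mean r^2 per distance bin over all within-chromosome marker pairs.

    Bins are half-open [k*bin, (k+1)*bin); pairs at distance > ``max_dist``
    are skipped.  Pairs with undefined r^2 (a constant column) are dropped.
    """
    nbins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    for _chrom, (i0, i1) in M.chrom_blocks().items():
        pos = M.pos[i0:i1]
        for a in range(i0, i1):
            for b in range(a + 1, i1):
                d = int(M.pos[b] - M.pos[a])
                if d > max_dist:
                    break
                r2 = ld_r2(G.values[:, a], G.values[:, b])
                if np.isnan(r2):
                    continue
                k = min(d // bin_bp, nbins - 1)
                sums[k] += r2
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(nbins) * bin_bp,
            "bin_end": (np.arange(nbins) + 1) * bin_bp,
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
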