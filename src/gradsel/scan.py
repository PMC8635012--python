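"""Empirical outlier p-values, the gradient filter, and signature calling.

A marker is called a *trait-specific selection signature* when

1. its score is an empirical genome-wide outlier (p < 0.01, with p = rank/N
   from ranking all scored markers; ties share the worst rank), and
2. its score triple across the three nested pair levels shows a strict
   gradient: F_ST strictly increasing; XP-EHH sharing one sign with strictly
   increasing magnitude (negative -> sweep in the high subpopulation,
   positive -> low).

By default significance is anchored in the level-3 (most contrasted) pair;
an ``all`` mode instead requires significance at every level.  F_ST uses the
upper tail, XP-EHH ranks by absolute value since both signs are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genodata import GenotypeMatrix, HaplotypeMatrix, MarkerMap
from .cohortpairs import GradientPairs, build_pairs, rank_by_trait, DEFAULT_SIZES
from . import diffstats, haplostats

__all__ = [
    "empirical_p",
    "significant",
    "gradient_pass",
    "build_score_table",
    "detect_signatures",
    "scan_trait",
]


def empirical_p(scores, tail: str = "upper") -> np.ndarray:
    """Empirical p = rank / N by genome-wide ranking of the scores.

    Rank 1 is the most extreme marker: the largest score for ``tail='upper'``,
    the largest absolute score for ``tail='two_sided_abs'``.  Tied scores all
    receive the worst (largest) rank of the tie group, making p conservative.
    Missing (NaN) scores are excluded from N and get NaN.
    """
    scores = np.asarray(scores, dtype=float)
    if tail == "upper":
        key = scores
    elif tail == "two_sided_abs":
        key = np.abs(scores)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    ok = np.isfinite(key)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all scores are missing")
    p = np.full(scores.shape, np.nan)
    ranks = rankdata(-key[ok], method="max")
    p[ok] = ranks / n
    return p


def significant(p_values, alpha: float = 0.01) -> np.ndarray:
    """Boolean mask of markers with p strictly below alpha (NaN -> False)."""
    p = np.asarray(p_values, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(p, nan=np.inf) < alpha


def gradient_pass(triple, method: str) -> tuple[bool, str]:
    """Does a (level1, level2, level3) score triple show a strict gradient?

    F_ST: pass iff s1 < s2 < s3 (direction ``none`` — F_ST is directionless).
    XP-EHH: pass iff all three scores share one sign and |s1| < |s2| < |s3|;
    direction ``high`` for negative triples, ``low`` for positive.  A missing
    score fails.
    """
    s1, s2, s3 = (float(x) for x in triple)
    if not (np.isfinite(s1) and np.isfinite(s2) and np.isfinite(s3)):
        return False, "none"
    if method == "fst":
        return (s1 < s2 < s3), "none"
    if method == "xpehh":
        if s1 > 0 and s2 > 0 and s3 > 0 and s1 < s2 < s3:
            return True, "low"
        if s1 < 0 and s2 < 0 and s3 < 0 and abs(s1) < abs(s2) < abs(s3):
            return True, "high"
        return False, "none"
    raise ValueError(f"unknown method {method!r}")


def build_score_table(
    M: MarkerMap,
    fst_levels: np.ndarray,
    xpehh_levels: np.ndarray | None = None,
    anchor_level: int = 3,
) -> pd.DataFrame:
    """Assemble the per-marker score table with anchor-level empirical p.

    ``fst_levels``/``xpehh_levels`` are (m, 3) arrays; ``p_fst`` ranks the
    anchor level's F_ST upper tail, ``p_xpehh`` the anchor level's |XP-EHH|.
    """
    k = anchor_level - 1
    df = pd.DataFrame(
        {
            "chrom": M.chrom,
            "pos": M.pos,
            "marker_id": M.marker_id,
            "fst_level1": fst_levels[:, 0],
            "fst_level2": fst_levels[:, 1],
            "fst_level3": fst_levels[:, 2],
        }
    )
    df["p_fst"] = empirical_p(fst_levels[:, k], tail="upper")
    if xpehh_levels is not None:
        df["xpehh_level1"] = xpehh_levels[:, 0]
        df["xpehh_level2"] = xpehh_levels[:, 1]
        df["xpehh_level3"] = xpehh_levels[:, 2]
        df["p_xpehh"] = empirical_p(xpehh_levels[:, k], tail="two_sided_abs")
    return df


_METHOD_COLS = {
    "fst": (("fst_level1", "fst_level2", "fst_level3"), "p_fst", "upper"),
    "xpehh": (("xpehh_level1", "xpehh_level2", "xpehh_level3"), "p_xpehh", "two_sided_abs"),
}


def detect_signatures(
    table: pd.DataFrame,
    trait: str,
    alpha: float = 0.01,
    mode: str = "level3",
) -> pd.DataFrame:
    """Call trait-specific signatures from a score table.

    ``mode='level3'`` (default): the anchor-level empirical p must be < alpha
    and the score triple must pass the gradient filter.  ``mode='all'``:
    per-level empirical p must be < alpha at all three levels (gradient filter
    still applies).  F_ST and XP-EHH lists are kept separate.
    """
    if mode not in ("level3", "all"):
        raise ValueError(f"unknown significance mode {mode!r}")
    rows = []
    for method, (cols, pcol, tail) in _METHOD_COLS.items():
        if cols[0] not in table.columns:
            continue
        scores = table[list(cols)].to_numpy(dtype=float)
        if mode == "level3":
            sig = significant(table[pcol].to_numpy(), alpha)
        else:
            sig = np.ones(len(table), dtype=bool)
            for k in range(3):
                sig &= significant(empirical_p(scores[:, k], tail=tail), alpha)
        for i in np.nonzero(sig)[0]:
            ok, direction = gradient_pass(scores[i], method)
            if not ok:
                continue
            rows.append(
                {
                    "trait": trait,
                    "method": method,
                    "chrom": table["chrom"].iat[i],
                    "pos": int(table["pos"].iat[i]),
                    "marker_id": table["marker_id"].iat[i],
                    "direction": direction,
                    "s1": scores[i, 0],
                    "s2": scores[i, 1],
                    "s3": scores[i, 2],
                    "p": float(table[pcol].iat[i]),
                }
            )
    cols = ["trait", "method", "chrom", "pos", "marker_id", "direction",
            "s1", "s2", "s3", "p"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["method", "chrom", "pos"], kind="stable").reset_index(drop=True)


def scan_trait(
    H: HaplotypeMatrix,
    M: MarkerMap,
    P: pd.DataFrame,
    trait: str,
    sizes=DEFAULT_SIZES,
    cutoff: float = 0.05,
    alpha: float = 0.01,
    mode: str = "level3",
    estimator: str = "wright",
    run_xpehh: bool = True,
    G: GenotypeMatrix | None = None,
) -> tuple[GradientPairs, pd.DataFrame, pd.DataFrame]:
    """End-to-end scan of one trait: pairs -> F_ST/XP-EHH -> signatures.

    ``G`` defaults to the genotype collapse of ``H``.  Returns the gradient
    pairs, the score table and the called signatures.
    """
    if G is None:
        G = H.to_genotypes()
    order = rank_by_trait(P, trait)
    gp = build_pairs(order, trait=trait, sizes=sizes)
    fst = diffstats.fst_scan(G, gp, estimator=estimator)
    xp = haplostats.xpehh_scan(H, gp, M, cutoff=cutoff) if run_xpehh else None
    table = build_score_table(M, fst, xp)
    sigs = detect_signatures(table, trait, alpha=alpha, mode=mode)
    return gp, table, sigs
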