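"""Nested high/low phenotype population pairs.

The scan design splits one cohort three times per trait, by phenotype rank:

* level 1 — top half vs bottom half of the cohort,
* level 2 — top 75 vs bottom 75 of the full ranking,
* level 3 — top 45 vs bottom 45.

Levels are nested by construction (each level's high set contains the next
level's), giving a gradient of phenotypic contrast.  Ties in the ranking are
broken by ascending sample id so the split is a pure, repeatable function of
the phenotype table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GradientPairs",
    "rank_by_trait",
    "build_pairs",
    "validate_pairs",
    "trait_correlations",
    "pairs_to_frame",
]

DEFAULT_SIZES = ("half", 75, 45)


@dataclass(frozen=True)
class GradientPairs:
    """Three nested (high, low) sample-id splits for one trait."""

    trait: str
    levels: tuple  # three (high_ids: tuple, low_ids: tuple)

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError("GradientPairs requires exactly 3 levels")
        prev_high: set | None = None
        prev_low: set | None = None
        for k, (high, low) in enumerate(self.levels, 1):
            hs, ls = set(high), set(low)
            if hs & ls:
                raise ValueError(f"level {k}: high and low sets overlap")
            if prev_high is not None and not (hs <= prev_high and ls <= prev_low):
                raise ValueError(f"level {k} is not nested within level {k - 1}")
            prev_high, prev_low = hs, ls

    def sizes(self) -> list:
        return [(len(h), len(l)) for h, l in self.levels]


def rank_by_trait(P: pd.DataFrame, trait: str) -> list:
    """Sample ids in descending trait order; ties broken by ascending id.

    Samples with a missing value for the trait are excluded.
    """
    if trait not in P.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    s = P[trait].dropna()
    if len(s) < 2:
        raise ValueError(f"trait {trait!r}: fewer than 2 usable samples")
    order = sorted(s.index, key=lambda sid: (-s[sid], str(sid)))
    return list(order)


def build_pairs(
    ordered_ids, trait: str = "", sizes=DEFAULT_SIZES
) -> GradientPairs:
    """Cut the ranking into three nested high/low pairs.

    ``sizes`` is (s1, s2, s3) where s1 may be the string ``"half"`` (top
    ceil(N/2) vs bottom floor(N/2); for odd N the extra individual goes to the
    high side).  s2 and s3 are per-side counts taken from the top and bottom
    of the full ranking, so nesting holds by construction.
    """
    ids = list(ordered_ids)
    n = len(ids)
    s1, s2, s3 = sizes
    if s1 == "half":
        hi1 = math.ceil(n / 2)
        lo1 = n - hi1
    else:
        hi1 = lo1 = int(s1)
    s2, s3 = int(s2), int(s3)
    if not (s3 <= s2 <= n // 2):
        raise ValueError(
            f"pair sizes must satisfy s3 <= s2 <= floor(N/2); got "
            f"({s2}, {s3}) with N={n}"
        )
    if hi1 + lo1 > n:
        raise ValueError("level-1 sizes exceed cohort size")
    levels = (
        (tuple(ids[:hi1]), tuple(ids[n - lo1:])),
        (tuple(ids[:s2]), tuple(ids[n - s2:])),
        (tuple(ids[:s3]), tuple(ids[n - s3:])),
    )
    return GradientPairs(trait=trait, levels=levels)


def validate_pairs(gp: GradientPairs, min_size: int = 40) -> list:
    """Warn (do not fail) when any subpopulation falls below ``min_size``.

    Selection scans on fewer than ~40 unrelated individuals are considered
    underpowered; returns the warning strings it logged.
    """
    warnings: list = []
    for k, (high, low) in enumerate(gp.levels, 1):
        for side, ids in (("high", high), ("low", low)):
            if len(ids) < min_size:
                msg = (
                    f"trait {gp.trait!r} level {k} {side} subpopulation has "
                    f"{len(ids)} samples (< {min_size})"
                )
                warnings.append(msg)
                logger.warning(msg)
    return warnings


def trait_correlations(P: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p-values over complete pairs of observations."""
    traits = list(P.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = P[[traits[i], traits[j]]].dropna()
            if len(sub) < 3:
                raise ValueError(
                    f"traits {traits[i]!r}/{traits[j]!r}: fewer than 3 complete pairs"
                )
            res = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=traits, columns=traits),
        pd.DataFrame(p, index=traits, columns=traits),
    )


def pairs_to_frame(gp: GradientPairs) -> pd.DataFrame:
    """Serialize pairs as long-format rows (sample_id, trait, level, side)."""
    rows = []
    for k, (high, low) in enumerate(gp.levels, 1):
        rows += [(sid, gp.trait, k, "high") for sid in high]
        rows += [(sid, gp.trait, k, "low") for sid in low]
    return pd.DataFrame(rows, columns=["sample_id", "trait", "level", "side"])
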