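"""Signature windows (+/- 200 kb), region merging, and interval intersection.

Each called signature defines a candidate selection region of ``window`` bp
on each side of the SNP (clamped at position 1).  Overlapping or bookended
regions of the same trait are merged irrespective of detection method; the
source markers, methods and directions are carried along so per-method
regions remain recoverable.  Regions are then intersected with gene/QTL
intervals (any overlap >= 1 bp is reported with its length).

Coordinates are 1-based inclusive internally; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genodata import IntervalRecord

logger = logging.getLogger(__name__)

__all__ = ["Region", "make_regions", "intersect", "regions_to_frame", "write_regions_bed"]


@dataclass(frozen=True)
class Region:
    """A merged signature window (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    trait: str
    markers: tuple
    methods: tuple
    directions: tuple

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError("invalid region coordinates")


def make_regions(sigs: pd.DataFrame, window: int = 200_000) -> list[Region]:
    """Build +/- ``window`` bp regions around signatures and merge per trait.

    ``sigs`` needs columns trait, method, chrom, pos, marker_id, direction.
    Same-trait regions that overlap or are bookended (adjacent bp) are merged.
    Output is sorted by (trait, chrom, start) and pairwise non-overlapping
    within a (trait, chrom).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    regions: list[Region] = []
    if len(sigs) == 0:
        return regions
    for (trait, chrom), grp in sigs.groupby(["trait", "chrom"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        cur = None
        for row in grp.itertuples(index=False):
            start = max(1, int(row.pos) - window)
            end = int(row.pos) + window
            item = (start, end, [row.marker_id], [row.method], [row.direction])
            if cur is None:
                cur = item
            elif start <= cur[1] + 1:  # overlap or bookended
                cur = (cur[0], max(cur[1], end), cur[2] + item[2],
                       cur[3] + item[3], cur[4] + item[4])
            else:
                regions.append(Region(chrom, cur[0], cur[1], trait,
                                      tuple(cur[2]), tuple(cur[3]), tuple(cur[4])))
                cur = item
        if cur is not None:
            regions.append(Region(chrom, cur[0], cur[1], trait,
                                  tuple(cur[2]), tuple(cur[3]), tuple(cur[4])))
    return regions


def intersect(
    regions: Sequence[Region], annot: Sequence[IntervalRecord]
) -> pd.DataFrame:
    """All (region, interval) pairs with >= 1 bp overlap (sweep-line).

    Annotation intervals on chromosomes absent from the regions are skipped
    with a warning.  Overlap length is inclusive-coordinate bp.
    """
    by_chrom: dict = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    iv_by_chrom: dict = {}
    for iv in annot:
        iv_by_chrom.setdefault(iv.chrom, []).append(iv)
    unknown = set(iv_by_chrom) - set(by_chrom)
    if unknown:
        logger.warning(
            "annotation chromosomes absent from regions skipped: %s",
            ", ".join(sorted(map(str, unknown))),
        )

    rows = []
    for chrom, regs in sorted(by_chrom.items(), key=lambda kv: str(kv[0])):
        ivs = sorted(iv_by_chrom.get(chrom, []), key=lambda v: (v.start, v.end))
        regs = sorted(regs, key=lambda r: (r.start, r.end))
        active: list = []
        j = 0
        for r in regs:
            while j < len(ivs) and ivs[j].start <= r.end:
                active.append(ivs[j])
                j += 1
            active = [v for v in active if v.end >= r.start]
            for v in active:
                ov = min(r.end, v.end) - max(r.start, v.start) + 1
                if ov >= 1:
                    rows.append(
                        {
                            "chrom": chrom,
                            "region_start": r.start,
                            "region_end": r.end,
                            "trait": r.trait,
                            "feature": v.name,
                            "kind": v.kind,
                            "feature_start": v.start,
                            "feature_end": v.end,
                            "overlap_bp": ov,
                        }
                    )
    cols = ["chrom", "region_start", "region_end", "trait", "feature", "kind",
            "feature_start", "feature_end", "overlap_bp"]
    return pd.DataFrame(rows, columns=cols)


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "trait": r.trait,
                "markers": ",".join(map(str, r.markers)),
                "methods": ",".join(r.methods),
                "directions": ",".join(r.directions),
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "trait", "markers", "methods", "directions"],
    )


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED (0-based half-open), name = trait."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.trait}\n")
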