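"""Domain containers and file I/O for genotypes, haplotypes, phenotypes and intervals.

Conventions
-----------
* Genomic coordinates are 1-based inclusive internally (PLINK/VCF convention);
  BED import/export converts to/from 0-based half-open.
* ``GenotypeMatrix`` stores dosages of ``allele_b`` in ``{0, 1, 2}`` with ``-1``
  for missing calls.  ``HaplotypeMatrix`` stores phased binary alleles and never
  contains missing data (phase/impute upstream, e.g. with BEAGLE).
* ``allele_b`` — the counted allele — is chosen deterministically at load time
  as the minor allele (ties broken by first observation order).  Downstream
  statistics (MAF, FST, EHH) are invariant to this orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "MarkerMap",
    "GenotypeMatrix",
    "HaplotypeMatrix",
    "IntervalRecord",
    "read_plink_text",
    "write_plink_text",
    "read_vcf_phased",
    "write_vcf_phased",
    "read_phenotypes",
    "write_phenotypes",
    "read_intervals_bed",
    "read_intervals_gff3",
    "write_intervals_bed",
]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker metadata: id, chromosome, 1-based position, alleles.

    Markers must be grouped by chromosome and strictly sorted by position
    within each chromosome; marker ids must be unique.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "allele_a", np.asarray(self.allele_a, dtype=object))
        object.__setattr__(self, "allele_b", np.asarray(self.allele_b, dtype=object))
        n = len(self.marker_id)
        for name in ("chrom", "pos", "allele_a", "allele_b"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} has mismatched length")
        if n and self.pos.min() < 1:
            raise ValueError("marker positions must be >= 1")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker ids must be unique")
        # chromosomes must form contiguous blocks, sorted by pos within each
        seen: set = set()
        prev_chrom = None
        prev_pos = 0
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
                seen.add(c)
                prev_chrom = c
                prev_pos = p
            else:
                if p <= prev_pos:
                    raise ValueError(f"positions on chromosome {c!r} not strictly increasing")
                prev_pos = p

    def __len__(self) -> int:
        return len(self.marker_id)

    def chrom_blocks(self) -> dict:
        """Map chromosome -> (start, stop) column index range (half-open)."""
        blocks: dict = {}
        if len(self) == 0:
            return blocks
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or self.chrom[i] != self.chrom[start]:
                blocks[self.chrom[start]] = (start, i)
                start = i
        return blocks

    def take(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(
            self.marker_id[idx], self.chrom[idx], self.pos[idx],
            self.allele_a[idx], self.allele_b[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos": self.pos,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
            }
        )


@dataclass
class GenotypeMatrix:
    """Per-sample dosages of ``allele_b``: values in {0,1,2}, -1 = missing."""

    samples: list
    values: np.ndarray  # (n_samples, n_markers) int8

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.samples):
            raise ValueError("values must be (n_samples, n_markers)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2,-1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def sample_index(self, ids: Iterable) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def subset_samples(self, ids: Sequence) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix([self.samples[i] for i in idx], self.values[idx])

    def take_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.values[:, np.asarray(idx)])


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes; rows 2i and 2i+1 belong to sample i."""

    samples: list
    values: np.ndarray  # (2*n_samples, n_markers) uint8, no missing

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[0] != 2 * len(self.samples):
            raise ValueError("values must be (2*n_samples, n_markers)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1 (no missing allowed)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        g = self.values[0::2].astype(np.int8) + self.values[1::2].astype(np.int8)
        return GenotypeMatrix(self.samples, g)

    def subset_samples(self, ids: Sequence) -> "HaplotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([lookup[s] for s in ids], dtype=np.intp)
        rows = np.empty(2 * len(idx), dtype=np.intp)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypeMatrix([self.samples[i] for i in idx], self.values[rows])

    def take_markers(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(self.samples, self.values[:, np.asarray(idx)])


@dataclass(frozen=True)
class IntervalRecord:
    """A named genomic interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str
    kind: str = "other"  # {gene, qtl, other}

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval {self.name!r}: start > end")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------


def read_plink_text(ped_path, map_path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK text ``.ped``/``.map``.

    Missing alleles are coded ``0`` in .ped; a genotype is missing if either
    allele is missing.  ``allele_b`` is the minor allele per marker (ties broken
    by order of first observation), so dosages count minor-allele copies.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(f"{map_path}: line {lineno}: expected 4 columns, got {len(fields)}")
            chrom, mid, _cm, pos = fields
            map_rows.append((mid, chrom, int(pos)))
    m = len(map_rows)

    samples: list = []
    allele_rows: list = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2x{m} alleles), got {len(fields)}"
                )
            sid = fields[1]
            if sid in samples:
                raise ParseError(f"{ped_path}: line {lineno}: duplicate sample id {sid!r}")
            samples.append(sid)
            allele_rows.append(fields[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), m, 2) if samples else np.empty((0, m, 2), dtype=object)

    values = np.full((len(samples), m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :].ravel()
        obs = col[col != "0"]
        # order of first observation, then counts
        order: list = []
        counts: dict = {}
        for a in obs:
            if a not in counts:
                counts[a] = 0
                order.append(a)
            counts[a] += 1
        if len(order) > 2:
            raise ParseError(f"marker {map_rows[j][0]!r} has more than two alleles")
        if len(order) == 0:
            allele_a[j], allele_b[j] = "A", "B"  # placeholder labels, all missing
        elif len(order) == 1:
            allele_a[j], allele_b[j] = order[0], order[0]
        else:
            a1, a2 = order
            minor = a2 if counts[a2] <= counts[a1] else a1
            major = a1 if minor is a2 else a2
            allele_a[j], allele_b[j] = major, minor
        if len(order) >= 1:
            pair = alleles[:, j, :]
            miss = (pair == "0").any(axis=1)
            dose = (pair == allele_b[j]).sum(axis=1).astype(np.int8)
            if len(order) == 1:
                # monomorphic: every call is 2 copies of the single allele,
                # which equals allele_b; recode dosage 2 -> 2 (kept as is)
                dose = np.where(miss, MISSING, 2).astype(np.int8)
            values[:, j] = np.where(miss, MISSING, dose)

    mids = [r[0] for r in map_rows]
    chroms = [r[1] for r in map_rows]
    poss = [r[2] for r in map_rows]
    mmap = MarkerMap(np.array(mids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss), allele_a, allele_b)
    return GenotypeMatrix(samples, values), mmap


def write_plink_text(G: GenotypeMatrix, M: MarkerMap, ped_path, map_path) -> None:
    """Write PLINK text .ped/.map (dosage 0 -> a/a, 1 -> a/b, 2 -> b/b)."""
    with open(map_path, "w") as fh:
        for mid, chrom, pos in zip(M.marker_id, M.chrom, M.pos):
            fh.write(f"{chrom}\t{mid}\t0\t{pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.samples):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            row = G.values[i]
            for j in range(G.n_markers):
                d = row[j]
                a, b = M.allele_a[j], M.allele_b[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a, a]
                elif d == 1:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF (phased)
# ---------------------------------------------------------------------------


def read_vcf_phased(path) -> tuple[HaplotypeMatrix, MarkerMap]:
    """Read a phased VCF into a HaplotypeMatrix.

    Only biallelic records with fully phased, non-missing GT fields are
    accepted (this tool expects post-imputation input).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    mids, chroms, poss, ra, aa = [], [], [], [], []
    cols = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ParseError(
                f"{path}: record {var.CHROM}:{var.POS} is not biallelic (ALT={var.ALT})"
            )
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased or a0 < 0 or a1 < 0:
                raise ParseError(
                    f"{path}: record {var.CHROM}:{var.POS} sample {samples[i]!r}: "
                    "GT must be phased ('|') and non-missing"
                )
            col[2 * i] = a0
            col[2 * i + 1] = a1
        cols.append(col)
        mids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ra.append(var.REF)
        aa.append(var.ALT[0])
    values = np.column_stack(cols) if cols else np.empty((2 * len(samples), 0), dtype=np.uint8)
    mmap = MarkerMap(np.array(mids, dtype=object), np.array(chroms, dtype=object),
                     np.array(poss, dtype=np.int64), np.array(ra, dtype=object),
                     np.array(aa, dtype=object))
    return HaplotypeMatrix(samples, values), mmap


def write_vcf_phased(H: HaplotypeMatrix, M: MarkerMap, path) -> None:
    """Write a minimal phased VCF (REF = allele_a, ALT = allele_b)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(M.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in H.samples) + "\n")
        v = H.values
        for j in range(len(M)):
            gts = "\t".join(f"{v[2 * i, j]}|{v[2 * i + 1, j]}" for i in range(H.n_samples))
            fh.write(
                f"{M.chrom[j]}\t{M.pos[j]}\t{M.marker_id[j]}\t{M.allele_a[j]}\t"
                f"{M.allele_b[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def read_phenotypes(path, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a tab-separated phenotype table (header row, first column = sample id).

    Returns a DataFrame indexed by sample id with float trait columns; blank
    and ``NA`` entries become NaN.  If ``traits`` is given, only those columns
    are returned and each must be present.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicated sample id {dup!r}")
    df = df.set_index(id_col)
    df.index.name = "sample_id"
    if traits is not None:
        missing = [t for t in traits if t not in df.columns]
        if missing:
            raise KeyError(f"trait column(s) not found: {missing}")
        df = df[list(traits)]
    return df.astype(float)


def write_phenotypes(P: pd.DataFrame, path) -> None:
    P.to_csv(path, sep="\t", index=True, index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# annotation intervals
# ---------------------------------------------------------------------------


def read_intervals_bed(path, kind: str = "other") -> list[IntervalRecord]:
    """Read BED (0-based half-open) into 1-based inclusive IntervalRecords."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: BED needs >=3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            records.append(IntervalRecord(chrom, start + 1, end, name, kind))
    return records


def read_intervals_gff3(path) -> list[IntervalRecord]:
    """Read GFF3 (1-based inclusive) features into IntervalRecords.

    Feature name comes from the ``Name`` attribute, falling back to ``ID``.
    ``gene`` features map to kind ``gene``, ``QTL`` to ``qtl``, others to
    ``other``.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: line {lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, _strand, _phase, attrs = fields
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
            )
            name = attr.get("Name", attr.get("ID", f"{chrom}:{start}-{end}"))
            kind = {"gene": "gene", "QTL": "qtl", "qtl": "qtl"}.get(ftype, "other")
            records.append(IntervalRecord(chrom, int(start), int(end), name, kind))
    return records


def write_intervals_bed(records: Sequence[IntervalRecord], path) -> None:
    """Write IntervalRecords as BED (converting to 0-based half-open)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")
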