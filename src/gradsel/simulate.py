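"""Synthetic chip cohort: founder-mosaic haplotypes plus a QTL-driven trait.

The generator emulates a single farm cohort genotyped on a medium-density SNP
chip.  Each gamete is a first-order mosaic over ``n_founders`` founder
haplotypes: it starts on a uniformly drawn founder and, between adjacent
markers at distance ``d`` bp, switches to a uniformly drawn founder with
probability ``1 - exp(-switch_rate * d)``.  This yields block-wise shared
haplotypes and LD that decays with physical distance — the substrate EHH
integrates over.

Each QTL is pinned to a marker and to a subset of *carrier* founders: the
QTL allele is forced to 1 on carriers and 0 on the others, so the allele tags
the carriers' local haplotype background.  The trait is
``y = sum_q beta_q * dosage_q + Normal(0, noise_sd^2)``; individuals in the
high-phenotype tail are then enriched for carrier haplotypes, producing
exactly the differentiation + haplotype-homozygosity signal the scan targets.

All randomness flows from one seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    MarkerMap,
    write_phenotypes,
    write_vcf_phased,
)
from . import scan as scan_mod
from . import annotate as annotate_mod
from .cohortpairs import DEFAULT_SIZES

__all__ = [
    "SimConfig",
    "simulate_founders",
    "simulate_cohort",
    "add_missingness",
    "write_truth",
    "run_recovery_experiment",
]


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings.

    Defaults model a 233-animal chip cohort on one 120 Mb chromosome with
    2,000 markers (mean spacing 60 kb, matching a ~60K chip genome-wide), 8
    founder haplotypes, mosaic switch rate 1e-6 per bp (haplotype blocks of
    ~1 Mb, so r^2 decays over a few hundred kb), and one additive QTL of
    effect 1.5 trait SD carried by a single founder (carrier allele frequency
    ~1/8, comfortably above the MAF filter).
    """

    n_individuals: int = 233
    n_snps: int = 2000
    chrom_length: int = 120_000_000
    n_founders: int = 8
    switch_rate: float = 1e-6
    # (marker index, beta, carrier founders); None -> one QTL of effect 1.5
    # carried by founder 0 at the middle marker
    qtls: tuple | None = None
    noise_sd: float = 1.0
    founder_freq_range: tuple = (0.1, 0.9)
    missing_rate: float = 0.0
    chrom: str = "1"
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.qtls is None:
            object.__setattr__(self, "qtls", ((self.n_snps // 2, 1.5, (0,)),))
        lo, hi = self.founder_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("founder_freq_range must satisfy 0 < low <= high < 1")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        for idx, _beta, carriers in self.qtls:
            if not 0 <= idx < self.n_snps:
                raise ValueError(f"QTL marker index {idx} out of range")
            if not all(0 <= c < self.n_founders for c in carriers):
                raise ValueError("QTL carrier founders out of range")


def _rng(cfg: SimConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def marker_positions(cfg: SimConfig) -> np.ndarray:
    """Evenly spaced 1-based positions: spacing = chrom_length / n_snps."""
    spacing = cfg.chrom_length / cfg.n_snps
    return np.round(spacing * np.arange(1, cfg.n_snps + 1)).astype(np.int64)


def marker_map(cfg: SimConfig) -> MarkerMap:
    pos = marker_positions(cfg)
    ids = np.array([f"snp{j:06d}" for j in range(cfg.n_snps)], dtype=object)
    chrom = np.full(cfg.n_snps, cfg.chrom, dtype=object)
    a = np.full(cfg.n_snps, "A", dtype=object)
    b = np.full(cfg.n_snps, "B", dtype=object)
    return MarkerMap(ids, chrom, pos, a, b)


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """K x m founder haplotypes; QTL columns are forced to tag the carriers."""
    rng = rng or _rng(cfg)
    lo, hi = cfg.founder_freq_range
    p = rng.uniform(lo, hi, size=cfg.n_snps)
    founders = (rng.random((cfg.n_founders, cfg.n_snps)) < p).astype(np.uint8)
    for idx, _beta, carriers in cfg.qtls:
        founders[:, idx] = 0
        founders[list(carriers), idx] = 1
    return founders


def simulate_cohort(
    cfg: SimConfig,
) -> tuple[HaplotypeMatrix, MarkerMap, pd.DataFrame]:
    """Simulate phased haplotypes, the marker map and the phenotype table."""
    rng = _rng(cfg)
    founders = simulate_founders(cfg, rng)
    M = marker_map(cfg)
    n_gam = 2 * cfg.n_individuals
    m = cfg.n_snps
    gaps = np.diff(M.pos).astype(float)
    p_switch = 1.0 - np.exp(-cfg.switch_rate * gaps)

    path = np.empty((n_gam, m), dtype=np.int16)
    cur = rng.integers(0, cfg.n_founders, size=n_gam)
    path[:, 0] = cur
    for j in range(1, m):
        sw = rng.random(n_gam) < p_switch[j - 1]
        if sw.any():
            cur = cur.copy()
            cur[sw] = rng.integers(0, cfg.n_founders, size=int(sw.sum()))
        path[:, j] = cur
    values = founders[path, np.arange(m)[None, :]]

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_individuals)]
    H = HaplotypeMatrix(samples, values)

    y = rng.normal(0.0, cfg.noise_sd, size=cfg.n_individuals)
    for idx, beta, _carriers in cfg.qtls:
        dose = values[0::2, idx].astype(float) + values[1::2, idx].astype(float)
        y = y + beta * dose
    P = pd.DataFrame({cfg.trait: y}, index=pd.Index(samples, name="sample_id"))
    return H, M, P


def add_missingness(
    G: GenotypeMatrix, rate: float, rng: np.random.Generator
) -> GenotypeMatrix:
    """Return a copy of ``G`` with calls knocked out uniformly at ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    vals = G.values.copy()
    mask = rng.random(vals.shape) < rate
    vals[mask] = MISSING
    return GenotypeMatrix(G.samples, vals)


def write_truth(cfg: SimConfig, M: MarkerMap, path) -> None:
    """Write the simulated QTL truth table (position, effect, carriers)."""
    rows = [
        {
            "marker_id": M.marker_id[idx],
            "chrom": M.chrom[idx],
            "pos": int(M.pos[idx]),
            "beta": beta,
            "carrier_founders": ",".join(map(str, carriers)),
        }
        for idx, beta, carriers in cfg.qtls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_cohort(cfg: SimConfig, out_dir) -> None:
    """Simulate and write VCF + phenotype TSV + truth TSV into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    H, M, P = simulate_cohort(cfg)
    write_vcf_phased(H, M, out / "cohort.vcf")
    write_phenotypes(P, out / "phenotypes.tsv")
    write_truth(cfg, M, out / "truth.tsv")


def run_recovery_experiment(
    cfg: SimConfig,
    n_seeds: int = 20,
    base_seed: int = 0,
    radius: int = 500_000,
    sizes=DEFAULT_SIZES,
    cutoff: float = 0.05,
    alpha: float = 0.01,
    mode: str = "level3",
) -> pd.DataFrame:
    """Run the full pipeline over replicate cohorts and score QTL recovery.

    For each seed the cohort is simulated, pairs are built, both scans run,
    signatures called and merged into regions.  A seed *recovers* the QTL when
    any signature of either method lies within ``radius`` bp of a QTL marker;
    direction is correct when an XP-EHH signature within the radius of a
    trait-increasing QTL points at the high subpopulation.

    Returns one row per seed with columns seed, n_signatures, recovered,
    n_xpehh_near, direction_high_ok.
    """
    rows = []
    for s in range(n_seeds):
        c = replace(cfg, seed=base_seed + s)
        H, M, P = simulate_cohort(c)
        qtl_pos = {int(marker_positions(c)[idx]): beta for idx, beta, _ in c.qtls}
        _gp, _table, sigs = scan_mod.scan_trait(
            H, M, P, c.trait, sizes=sizes, cutoff=cutoff, alpha=alpha, mode=mode
        )
        regions = annotate_mod.make_regions(sigs, window=200_000)
        near = sigs[
            sigs["pos"].apply(lambda p: any(abs(p - q) <= radius for q in qtl_pos))
        ]
        xp_near = near[near["method"] == "xpehh"]
        direction_ok = bool(len(xp_near)) and (xp_near["direction"] == "high").mean() > 0.5
        rows.append(
            {
                "seed": c.seed,
                "n_signatures": len(sigs),
                "n_regions": len(regions),
                "recovered": bool(len(near)),
                "n_xpehh_near": len(xp_near),
                "direction_high_ok": direction_ok,
            }
        )
    return pd.DataFrame(rows)
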