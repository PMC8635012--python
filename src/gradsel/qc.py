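"""SNP-chip quality control and marker-spectrum diagnostics.

Filters are applied in a fixed order (SNP missingness, sample call rate,
Hardy-Weinberg, MAF, autosomal/known-position) and each stage is counted in
the :class:`QcReport`.  Order matters: MAF and HWE are recomputed on the
samples that survive the call-rate filter.

Inequalities are strict on the side the thresholds name: a SNP is kept when
its missing rate is *below* ``max_snp_missing``, a sample when its call rate
is *above* ``min_sample_callrate``, a SNP when its HWE p-value is *above*
``hwe_min_p`` and its MAF *above* ``min_maf``.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import MISSING, GenotypeMatrix, MarkerMap

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_snp_missing",
    "filter_sample_callrate",
    "hwe_exact_p",
    "hwe_chi2_p",
    "filter_hwe",
    "filter_maf",
    "filter_autosomal",
    "apply_qc",
    "maf_spectrum",
    "minor_allele_freq",
]


@dataclass
class QcConfig:
    max_snp_missing: float = 0.05
    min_sample_callrate: float = 0.90
    hwe_min_p: float = 1e-6
    min_maf: float = 0.05
    hwe_method: str = "exact"  # or "chi2"
    autosomes: frozenset | None = None  # None: any purely numeric chrom label >= 1


@dataclass
class QcReport:
    n_input_snps: int = 0
    n_removed_missing: int = 0
    n_removed_hwe: int = 0
    n_removed_maf: int = 0
    n_removed_nonauto_or_unmapped: int = 0
    n_samples_removed: int = 0
    n_output_snps: int = 0
    mean_spacing_kb: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# per-marker summaries
# ---------------------------------------------------------------------------


def _freq_b(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """allele_b frequency and non-missing call count per marker."""
    called = values != MISSING
    n_calls = called.sum(axis=0)
    dose = np.where(called, values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_calls > 0, dose / (2.0 * n_calls), np.nan)
    return freq, n_calls


def minor_allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """MAF per marker over non-missing calls (NaN where no calls)."""
    freq, _ = _freq_b(G.values)
    return np.minimum(freq, 1.0 - freq)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def filter_snp_missing(
    G: GenotypeMatrix, max_rate: float = 0.05, M: MarkerMap | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Keep markers whose missing-call fraction is strictly below ``max_rate``.

    Returns the filtered matrix and the *column indices* removed (marker ids
    if ``M`` is given).
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    miss = (G.values == MISSING).mean(axis=0)
    keep = miss < max_rate
    removed = np.nonzero(~keep)[0]
    out = G.take_markers(np.nonzero(keep)[0])
    return out, (M.marker_id[removed] if M is not None else removed)


def filter_sample_callrate(
    G: GenotypeMatrix, min_rate: float = 0.90
) -> tuple[GenotypeMatrix, list]:
    """Keep samples whose call rate is strictly above ``min_rate``."""
    call = (G.values != MISSING).mean(axis=1)
    keep = call > min_rate
    if not keep.any():
        raise ValueError("sample call-rate filter removed every sample")
    removed = [s for s, k in zip(G.samples, keep) if not k]
    kept_ids = [s for s, k in zip(G.samples, keep) if k]
    return G.subset_samples(kept_ids), removed


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one biallelic marker.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts no more probable than the observed one (the mid-free,
    PLINK-style exact test).  Monomorphic markers return 1 by convention.
    """
    n_aa, n_ab, n_bb = int(n_aa), int(n_ab), int(n_bb)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(homr + 1)
        - gammaln(hets + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs_het = n_ab
    p_obs = probs[hets == obs_het]
    if p_obs.size == 0:  # impossible configuration for these allele counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-degree-of-freedom chi-square HWE test (optional alternative)."""
    from scipy.stats import chi2

    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def _genotype_counts(values: np.ndarray) -> np.ndarray:
    """Counts of (hom-a, het, hom-b) per marker, shape (m, 3)."""
    return np.stack(
        [(values == 0).sum(axis=0), (values == 1).sum(axis=0), (values == 2).sum(axis=0)],
        axis=1,
    )


def filter_hwe(
    G: GenotypeMatrix, min_p: float = 1e-6, method: str = "exact",
    M: MarkerMap | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Keep markers with HWE p strictly above ``min_p``."""
    test = hwe_exact_p if method == "exact" else hwe_chi2_p
    counts = _genotype_counts(G.values)
    keep = np.array(
        [c.sum() == 0 or test(c[0], c[1], c[2]) > min_p for c in counts], dtype=bool
    )
    removed = np.nonzero(~keep)[0]
    out = G.take_markers(np.nonzero(keep)[0])
    return out, (M.marker_id[removed] if M is not None else removed)


def filter_maf(
    G: GenotypeMatrix, min_maf: float = 0.05, M: MarkerMap | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Keep markers with minor allele frequency strictly above ``min_maf``.

    Markers with zero non-missing calls have undefined MAF and are removed.
    """
    maf = minor_allele_freq(G)
    keep = np.nan_to_num(maf, nan=-1.0) > min_maf
    removed = np.nonzero(~keep)[0]
    out = G.take_markers(np.nonzero(keep)[0])
    return out, (M.marker_id[removed] if M is not None else removed)


def _is_autosome(chrom: str, autosomes: frozenset | None) -> bool:
    if autosomes is not None:
        return chrom in autosomes
    try:
        return int(chrom) >= 1
    except (TypeError, ValueError):
        return False


def filter_autosomal(
    G: GenotypeMatrix, M: MarkerMap, autosomes: frozenset | None = None
) -> tuple[GenotypeMatrix, MarkerMap, np.ndarray]:
    """Keep autosomal markers with known (>=1) positions."""
    keep = np.array(
        [_is_autosome(c, autosomes) and p >= 1 for c, p in zip(M.chrom, M.pos)],
        dtype=bool,
    )
    idx = np.nonzero(keep)[0]
    removed = M.marker_id[np.nonzero(~keep)[0]]
    return G.take_markers(idx), M.take(idx), removed


def mean_spacing_kb(M: MarkerMap) -> float:
    """Mean adjacent-marker distance within chromosomes, in kb."""
    gaps = []
    for _chrom, (i0, i1) in M.chrom_blocks().items():
        if i1 - i0 > 1:
            gaps.append(np.diff(M.pos[i0:i1]))
    if not gaps:
        return float("nan")
    return float(np.concatenate(gaps).mean() / 1000.0)


def apply_qc(
    G: GenotypeMatrix, M: MarkerMap, config: QcConfig | None = None
) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Run the full QC cascade and report per-stage removal counts."""
    cfg = config or QcConfig()
    report = QcReport(n_input_snps=G.n_markers)

    keep_mask = np.ones(G.n_markers, dtype=bool)

    # 1. SNP missingness
    miss = (G.values == MISSING).mean(axis=0)
    stage = miss < cfg.max_snp_missing
    report.n_removed_missing = int((~stage).sum())
    keep_mask &= stage
    idx = np.nonzero(keep_mask)[0]
    G1, M1 = G.take_markers(idx), M.take(idx)

    # 2. sample call rate
    G2, removed_samples = filter_sample_callrate(G1, cfg.min_sample_callrate)
    report.n_samples_removed = len(removed_samples)

    # 3. HWE (on surviving samples)
    G3, rem_hwe = filter_hwe(G2, cfg.hwe_min_p, cfg.hwe_method, M1)
    report.n_removed_hwe = len(rem_hwe)
    M3 = M1.take(np.nonzero(~np.isin(M1.marker_id, rem_hwe))[0])

    # 4. MAF
    G4, rem_maf = filter_maf(G3, cfg.min_maf, M3)
    report.n_removed_maf = len(rem_maf)
    M4 = M3.take(np.nonzero(~np.isin(M3.marker_id, rem_maf))[0])

    # 5. autosomal with known positions
    G5, M5, rem_auto = filter_autosomal(G4, M4, cfg.autosomes)
    report.n_removed_nonauto_or_unmapped = len(rem_auto)

    report.n_output_snps = G5.n_markers
    if G5.n_markers == 0:
        raise ValueError("QC removed every marker")
    report.mean_spacing_kb = mean_spacing_kb(M5)
    return G5, M5, report


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def maf_spectrum(G: GenotypeMatrix, bin_width: float = 0.1) -> pd.DataFrame:
    """Proportion of markers per MAF bin over (0, 0.5].

    Bins are right-closed: (0, w], (w, 2w], ... (0.5-w, 0.5].  Monomorphic
    markers (MAF 0) and no-call markers fall outside (0, 0.5] and are excluded
    from the denominator.
    """
    nbins = round(0.5 / bin_width)
    if abs(nbins * bin_width - 0.5) > 1e-9:
        raise ValueError("bin_width must divide 0.5")
    maf = minor_allele_freq(G)
    maf = maf[np.isfinite(maf) & (maf > 0)]
    edges = np.linspace(0.0, 0.5, nbins + 1)
    # right-closed bins
    which = np.clip(np.searchsorted(edges, maf, side="left") - 1, 0, nbins - 1)
    counts = np.bincount(which, minlength=nbins)
    total = counts.sum()
    prop = counts / total if total else np.zeros(nbins)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "proportion": prop, "n": counts}
    )
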