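"""Per-SNP allele frequencies and two-population F_ST.

Two estimators are provided:

* ``fst_wright`` — Wright/Nei fixation index (H_T - H_S) / H_T with unweighted
  pooling of the two subpopulation frequencies.  This is the default; it is
  bounded in [0, 1] and returns 0 for markers monomorphic in both groups so
  the genome-wide ranking stays total.
* ``fst_weir_cockerham`` — the Weir-Cockerham variance-components estimator
  theta-hat for two populations at one locus; unbiased under the null but may
  be negative (it is deliberately not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genodata import MISSING, GenotypeMatrix
from .cohortpairs import GradientPairs

__all__ = [
    "FreqVector",
    "allele_frequency",
    "fst_wright",
    "fst_weir_cockerham",
    "fst_scan",
]


@dataclass(frozen=True)
class FreqVector:
    """allele_b frequency and non-missing call count per marker, one subset."""

    freq: np.ndarray  # NaN where a marker has zero calls in the subset
    n_calls: np.ndarray

    @property
    def undefined(self) -> np.ndarray:
        return self.n_calls == 0


def allele_frequency(G: GenotypeMatrix, ids: Sequence) -> FreqVector:
    """allele_b frequency over the given samples: dosage sum / (2 * calls)."""
    sub = G.values[G.sample_index(ids)]
    called = sub != MISSING
    n_calls = called.sum(axis=0)
    dose = np.where(called, sub, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_calls > 0, dose / (2.0 * n_calls), np.nan)
    return FreqVector(freq=freq, n_calls=n_calls)


def fst_wright(p1, p2):
    """Wright/Nei F_ST from the two subpopulation allele frequencies.

    H_S = mean(2*p1*q1, 2*p2*q2); H_T = 2*p_bar*q_bar with p_bar the
    unweighted mean frequency; F_ST = (H_T - H_S) / H_T, defined as 0 when
    H_T = 0 (both groups fixed for the same allele).  Vectorized; NaN inputs
    propagate.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = (p1 + p2) / 2.0
    ht = 2 * pbar * (1 - pbar)
    # algebraically H_T - H_S = (p1 - p2)^2 / 2; this form avoids the
    # catastrophic cancellation of subtracting two near-equal heterozygosities
    diff = (p1 - p2) ** 2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, diff / np.where(ht > 0, ht, 1.0), 0.0)
    fst = np.where(np.isnan(p1) | np.isnan(p2), np.nan, fst)
    fst = np.clip(fst, 0.0, 1.0)
    return float(fst) if fst.ndim == 0 else fst


def fst_weir_cockerham(counts1, counts2):
    """Weir-Cockerham theta-hat for two populations at one or more loci.

    ``counts1``/``counts2`` are (hom-a, het, hom-b) genotype counts, shape
    (3,) or (m, 3).  Returns NaN where a population has zero calls or the
    denominator vanishes; values may be negative.
    """
    c1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    c2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * c1[:, 2] + c1[:, 1]) / (2 * n1)
        p2 = (2 * c2[:, 2] + c2[:, 1]) / (2 * n2)
        h1 = c1[:, 1] / n1
        h2 = c2[:, 1] / n2
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)
    theta = np.where((n1 == 0) | (n2 == 0), np.nan, theta)
    return float(theta[0]) if np.asarray(counts1).ndim == 1 else theta


def _genotype_counts(sub: np.ndarray) -> np.ndarray:
    return np.stack(
        [(sub == 0).sum(axis=0), (sub == 1).sum(axis=0), (sub == 2).sum(axis=0)],
        axis=1,
    )


def fst_scan(
    G: GenotypeMatrix, gp: GradientPairs, estimator: str = "wright"
) -> np.ndarray:
    """Per-marker F_ST at each of the three pair levels, shape (m, 3).

    Markers with zero calls in either subpopulation of a level get NaN for
    that level.
    """
    if estimator not in ("wright", "weir_cockerham"):
        raise ValueError(f"unknown F_ST estimator {estimator!r}")
    out = np.full((G.n_markers, 3), np.nan)
    for k, (high, low) in enumerate(gp.levels):
        if estimator == "wright":
            fh = allele_frequency(G, high)
            fl = allele_frequency(G, low)
            out[:, k] = fst_wright(fh.freq, fl.freq)
        else:
            sub_h = G.values[G.sample_index(high)]
            sub_l = G.values[G.sample_index(low)]
            out[:, k] = fst_weir_cockerham(
                _genotype_counts(sub_h), _genotype_counts(sub_l)
            )
    return out
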