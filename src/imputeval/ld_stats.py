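"""Linkage disequilibrium r², the VanRaden genomic relationship matrix and
validation-to-reference relatedness summaries (Maxr / Mean10).

r² is the squared Pearson correlation of genotype dosages (composite LD)
over pairwise-complete individuals; no phasing is assumed.  Undefined values
(monomorphic columns on the complete subset) are returned as NaN and
excluded from averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix


def allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Frequency of allele B per SNP over non-missing calls (NaN if none)."""
    d = matrix.dosage
    called = d != MISSING
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, d, 0).sum(axis=0) / (2.0 * n), np.nan)
    return p


def r2(col_i: np.ndarray, col_j: np.ndarray) -> float:
    """Squared dosage correlation over pairwise-complete individuals.

    NaN when fewer than two complete pairs remain or either column is
    monomorphic on the complete subset.
    """
    x = np.asarray(col_i, dtype=np.float64)
    y = np.asarray(col_j, dtype=np.float64)
    ok = (np.asarray(col_i) != MISSING) & (np.asarray(col_j) != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2(columns: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise r² for a block of SNP columns.

    ``columns`` is individuals x k.  With no missing data this is a single
    correlation-matrix call; with missing data it falls back to pairwise
    computation.  Diagonal is NaN (self-LD is not a pair).
    """
    cols = np.asarray(columns)
    k = cols.shape[1]
    out = np.full((k, k), np.nan)
    if (cols != MISSING).all():
        sd = cols.std(axis=0)
        poly = sd > 0
        if poly.any():
            c = np.corrcoef(cols[:, poly].astype(np.float64), rowvar=False)
            c = np.atleast_2d(c)
            idx = np.flatnonzero(poly)
            out[np.ix_(idx, idx)] = c * c
    else:
        for a in range(k):
            for b in range(a + 1, k):
                out[a, b] = out[b, a] = r2(cols[:, a], cols[:, b])
    np.fill_diagonal(out, np.nan)
    return out


def window_avg_r2(columns: np.ndarray) -> np.ndarray:
    """Per-SNP mean of the defined r² values with the other SNPs of a window.

    A single-SNP window, or a SNP whose every pair is undefined, yields NaN.
    """
    cols = np.asarray(columns)
    if cols.shape[1] == 1:
        return np.array([np.nan])
    rr = pairwise_r2(cols)
    with np.errstate(invalid="ignore"):
        return np.nanmean(rr, axis=1)


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """VanRaden genomic relationship matrix G = MM' / Σ 2 p_i (1 - p_i)."""

    ids: list
    values: np.ndarray
    allele_freqs: np.ndarray

    def submatrix(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.ids)}
        ri = [lookup[str(i)] for i in row_ids]
        ci = [lookup[str(i)] for i in col_ids]
        return self.values[np.ix_(ri, ci)]


def vanraden_grm(matrix: GenotypeMatrix, freqs: np.ndarray | None = None) -> GRM:
    """Compute G from B-allele dosages.

    M has elements dosage - 2 p_i; residual missing dosages are mean-imputed
    to 2 p_i (a zero in M) before centering.  ``freqs`` defaults to the
    frequencies observed in ``matrix`` itself.
    """
    p = allele_frequencies(matrix) if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (matrix.n_snps,):
        raise ValueError("freqs must give one frequency per SNP")
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all SNPs monomorphic: zero VanRaden denominator")
    d = matrix.dosage.astype(np.float64)
    d[matrix.dosage == MISSING] = np.nan
    centered = d - 2.0 * p
    centered = np.nan_to_num(centered, nan=0.0)  # mean imputation
    g = centered @ centered.T / denom
    return GRM(list(matrix.individual_ids), g, p)


# ---------------------------------------------------------------------------
# Relatedness summaries
# ---------------------------------------------------------------------------


def relatedness_summary(
    grm: GRM,
    reference_ids: Sequence[str],
    validation_ids: Sequence[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Per validation individual: Maxr and Mean10 against the reference set.

    Maxr is the largest genomic relationship with any reference individual;
    Mean10 averages the ``top_n`` (default 10) largest, or all of them when
    the reference holds fewer than ``top_n`` animals.
    """
    ref = [str(i) for i in reference_ids]
    val = [str(i) for i in validation_ids]
    if not ref or not val:
        raise ValueError("reference and validation sets must be non-empty")
    overlap = set(ref) & set(val)
    if overlap:
        raise ValueError(f"reference and validation sets overlap: {sorted(overlap)[:3]}")
    block = grm.submatrix(val, ref)
    k = min(top_n, len(ref))
    top = -np.sort(-block, axis=1)[:, :k]
    return pd.DataFrame(
        {"individual_id": val, "maxr": block.max(axis=1), "mean10": top.mean(axis=1)}
    )
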