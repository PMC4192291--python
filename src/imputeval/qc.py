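"""SNP and individual quality control with per-filter exclusion accounting.

Five SNP filters are applied in a fixed order — non-autosomal placement,
duplicate genomic position, Hardy–Weinberg disequilibrium, low minor allele
frequency and low call rate — followed by an individual call-rate filter.
Each excluded SNP is attributed to the FIRST filter in that order that
removes it, so the report's counts always sum to the input SNP count.  All
per-SNP statistics are computed on a designated reference subset of
individuals; the resulting SNP exclusion list is then applied to every
individual (reference and validation alike).

Every filter is a predicate of the input data alone (the duplicate rule
keeps the first record at each (chromosome, position) of the *input* map),
so the surviving set does not depend on the order in which filters are
evaluated — only the attribution of exclusions does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import MISSING, GenotypeMatrix, MarkerMap

FILTER_ORDER = ("non_autosomal", "duplicate_position", "hwe", "maf", "snp_call_rate")


@dataclass
class QcThresholds:
    """Exclusion thresholds.

    A SNP is removed when its Hardy–Weinberg p-value is <= ``hwe_p_max``,
    its MAF is < ``maf_min`` or its call rate is < ``snp_call_rate_min``
    (calls with quality < ``gencall_min`` count as missing for the call-rate
    statistic).  Individuals with call rate < ``ind_call_rate_min`` over the
    surviving SNPs are removed.  Chromosome labels outside 1..``n_autosomes``
    are non-autosomal.
    """

    hwe_p_max: float = 1e-5
    maf_min: float = 0.02
    snp_call_rate_min: float = 0.98
    gencall_min: float = 0.70
    ind_call_rate_min: float = 0.90
    n_autosomes: int = 29

    def __post_init__(self) -> None:
        for name in ("hwe_p_max", "maf_min", "snp_call_rate_min", "gencall_min",
                     "ind_call_rate_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_autosomes < 1:
            raise ValueError("n_autosomes must be >= 1")


@dataclass
class QcReport:
    n_input_snps: int
    exclusions: dict = field(default_factory=dict)  # filter name -> count
    surviving_snp_ids: tuple = ()
    excluded_individual_ids: tuple = ()
    n_surviving_individuals: int = 0

    def __post_init__(self) -> None:
        total = sum(self.exclusions.values()) + len(self.surviving_snp_ids)
        if total != self.n_input_snps:
            raise ValueError(
                f"QC accounting broken: {sum(self.exclusions.values())} excluded "
                f"+ {len(self.surviving_snp_ids)} surviving != {self.n_input_snps} input"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input_snps)]
        rows += [(name, self.exclusions[name]) for name in FILTER_ORDER]
        rows.append(("surviving", len(self.surviving_snp_ids)))
        return pd.DataFrame(rows, columns=["stage", "n_snps"])


# ---------------------------------------------------------------------------
# Per-SNP statistics
# ---------------------------------------------------------------------------


def hwe_z_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided z-test of Hardy–Weinberg equilibrium on the heterozygote
    proportion.

    z = (h_obs - h_exp) / sqrt(h_exp (1 - h_exp) / n) with h_obs = n_AB/n and
    h_exp = 2 p (1 - p) from the sample allele frequency.  A monomorphic
    sample (h_exp = 0, h_obs = 0) is in perfect equilibrium: p = 1.
    """
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("HWE test needs at least one genotyped individual")
    p_hat = (2 * n_bb + n_ab) / (2 * n)
    h_exp = 2.0 * p_hat * (1.0 - p_hat)
    h_obs = n_ab / n
    if h_exp == 0.0:
        return 1.0  # h_obs is necessarily 0 too
    z = (h_obs - h_exp) / np.sqrt(h_exp * (1.0 - h_exp) / n)
    return float(2.0 * sps.norm.sf(abs(z)))


def snp_maf(column: np.ndarray) -> float:
    """Minor allele frequency over non-missing calls."""
    column = np.asarray(column)
    called = column[column != MISSING]
    if called.size == 0:
        raise ValueError("MAF undefined: all calls missing")
    p = called.sum() / (2.0 * called.size)
    return float(min(p, 1.0 - p))


def snp_call_rate(
    column: np.ndarray, quality: np.ndarray | None = None, gencall_min: float = 0.70
) -> float:
    """Proportion of individuals with a non-missing call of adequate quality."""
    column = np.asarray(column)
    if column.size == 0:
        raise ValueError("call rate undefined for an empty column")
    ok = column != MISSING
    if quality is not None:
        ok &= np.asarray(quality) >= gencall_min
    return float(ok.mean())


def _vectorized_snp_stats(
    dosage: np.ndarray, quality: np.ndarray, gencall_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(hwe_p, maf, call_rate) per SNP, matching the scalar functions."""
    called = dosage != MISSING
    n_called = called.sum(axis=0)
    n_ab = ((dosage == 1) & called).sum(axis=0)
    n_bb = (dosage == 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p_hat = np.where(n_called > 0, (2 * n_bb + n_ab) / (2.0 * n_called), np.nan)
        h_exp = 2.0 * p_hat * (1.0 - p_hat)
        h_obs = np.where(n_called > 0, n_ab / n_called, np.nan)
        se = np.sqrt(h_exp * (1.0 - h_exp) / n_called)
        z = (h_obs - h_exp) / se
    hwe_p = 2.0 * sps.norm.sf(np.abs(z))
    hwe_p = np.where(h_exp == 0.0, 1.0, hwe_p)  # monomorphic -> equilibrium
    hwe_p = np.where(n_called == 0, np.nan, hwe_p)

    maf = np.minimum(p_hat, 1.0 - p_hat)
    call_rate = (called & (quality >= gencall_min)).mean(axis=0)
    return hwe_p, maf, call_rate


# ---------------------------------------------------------------------------
# Full QC pipeline
# ---------------------------------------------------------------------------


def run_qc(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    thresholds: QcThresholds | None = None,
    reference_ids: Sequence[str] | None = None,
) -> tuple[QcReport, GenotypeMatrix, MarkerMap]:
    """Apply SNP filters (statistics from the reference individuals) and the
    individual call-rate filter; return the report and filtered data.

    ``reference_ids`` defaults to all individuals.  SNPs excluded on the
    reference statistics are removed for every individual, which is how a
    validation matrix sharing this map is kept in sync (see
    :func:`harmonize`).
    """
    thresholds = thresholds or QcThresholds()
    if matrix.n_snps != marker_map.n_snps:
        raise ValueError("matrix and map disagree on SNP count")
    if reference_ids is None:
        reference_ids = matrix.individual_ids
    ref = matrix.subset_individuals(reference_ids)

    t = marker_map.table
    m = marker_map.n_snps

    autosomes = set(range(1, thresholds.n_autosomes + 1))
    non_autosomal = ~t["chromosome"].isin(autosomes).to_numpy()
    duplicate = t.duplicated(subset=["chromosome", "position_bp"], keep="first").to_numpy()

    hwe_p, maf, call_rate = _vectorized_snp_stats(
        ref.dosage, ref.quality_or_ones(), thresholds.gencall_min
    )
    fails = {
        "non_autosomal": non_autosomal,
        "duplicate_position": duplicate,
        "hwe": np.nan_to_num(hwe_p, nan=1.0) <= thresholds.hwe_p_max,
        "maf": np.nan_to_num(maf, nan=0.0) < thresholds.maf_min,
        "snp_call_rate": call_rate < thresholds.snp_call_rate_min,
    }

    attributed = np.zeros(m, dtype=bool)
    exclusions: dict = {}
    for name in FILTER_ORDER:
        newly = fails[name] & ~attributed
        exclusions[name] = int(newly.sum())
        attributed |= newly
    keep = ~attributed
    if not keep.any():
        worst = max(FILTER_ORDER, key=lambda f: exclusions[f])
        raise ValueError(f"no SNPs survive QC (largest exclusion: {worst})")

    keep_idx = np.flatnonzero(keep)
    filtered_map = marker_map.subset(keep_idx)
    filtered = matrix.subset_snps(keep_idx)

    # individual call rate over surviving SNPs, GenCall-masked for consistency
    called = (filtered.dosage != MISSING) & (
        filtered.quality_or_ones() >= thresholds.gencall_min
    )
    ind_rate = called.mean(axis=1)
    ind_keep = ind_rate >= thresholds.ind_call_rate_min
    if not ind_keep.any():
        raise ValueError("no individuals survive the call-rate filter")
    excluded_inds = tuple(
        ind for ind, ok in zip(filtered.individual_ids, ind_keep) if not ok
    )
    if excluded_inds:
        kept_inds = [i for i in filtered.individual_ids if i not in set(excluded_inds)]
        filtered = filtered.subset_individuals(kept_inds)

    report = QcReport(
        n_input_snps=m,
        exclusions=exclusions,
        surviving_snp_ids=tuple(filtered_map.snp_ids),
        excluded_individual_ids=excluded_inds,
        n_surviving_individuals=filtered.n_individuals,
    )
    return report, filtered, filtered_map


def harmonize(
    matrix: GenotypeMatrix, marker_map: MarkerMap, report: QcReport
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Subset any matrix sharing the pre-QC map to the surviving SNPs."""
    idx = marker_map.index_of(report.surviving_snp_ids)
    return matrix.subset_snps(idx), marker_map.subset(idx)
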