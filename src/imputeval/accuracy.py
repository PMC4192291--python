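"""Imputation accuracy: PERC and CORR by individual and by SNP, accuracy-on-
relatedness regression, and genome-window accuracy scans.

PERC is the percentage of imputed genotypes identical to the (masked) true
genotypes.  CORR is the Pearson correlation between imputed and true B-allele
dosages; unlike PERC it penalizes a one-allele error less than a two-allele
error.  Both are computed over imputed (masked) cells only.  CORR is
undefined when either vector is constant; undefined values are recorded as
NaN, counted, and excluded from summary means/SDs (sample SD, n-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix, MarkerMap
from .chip_design import partition_windows
from .ld_stats import pairwise_r2
from .qc import snp_maf
from .scenario import ImputationScenario


def perc(imputed: np.ndarray, observed: np.ndarray) -> float:
    """Percentage of identically imputed genotypes."""
    imputed = np.asarray(imputed)
    observed = np.asarray(observed)
    if imputed.shape != observed.shape:
        raise ValueError("vectors must have equal length")
    if imputed.size == 0:
        raise ValueError("no scored positions")
    return float(100.0 * np.mean(imputed == observed))


def corr(imputed: np.ndarray, observed: np.ndarray) -> float:
    """Pearson correlation of imputed vs observed dosages (NaN if constant)."""
    x = np.asarray(imputed, dtype=np.float64)
    y = np.asarray(observed, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    v = values[~np.isnan(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(np.mean(v)), sd


@dataclass
class AccuracyResult:
    """Per-individual and per-SNP PERC/CORR with summary statistics.

    ``summary`` holds mean/SD pairs (keys ``corr_mean``, ``corr_sd``,
    ``perc_mean``, ``perc_sd`` for both groupings) plus the count of
    undefined CORR values excluded from the summaries.
    """

    per_individual: pd.DataFrame  # individual_id, perc, corr
    per_snp: pd.DataFrame  # snp_id, perc, corr
    summary: dict
    n_imputed_snps: int
    pct_imputed_snps: float


def imputation_load(n_total_snps: int, n_chip_snps: int) -> tuple[int, float]:
    """SNPs to be imputed and their percentage of the full panel.

    For an animal genotyped on a chip sharing ``n_chip_snps`` markers with a
    post-QC panel of ``n_total_snps``, the remaining markers are imputed.
    """
    if not 0 <= n_chip_snps <= n_total_snps:
        raise ValueError("chip size must lie in [0, panel size]")
    n_imputed = n_total_snps - n_chip_snps
    return n_imputed, 100.0 * n_imputed / n_total_snps


def score_scenario(
    scenario: ImputationScenario, imputed: GenotypeMatrix
) -> AccuracyResult:
    """Score an imputed matrix against the scenario's truth.

    Scored cells are the masked ones (validation rows, off-chip SNPs) whose
    true genotype is itself called; truth no-calls cannot be scored and are
    skipped.  Per-individual metrics concatenate each animal's masked SNPs
    genome-wide; per-SNP metrics run across validation animals.
    """
    val_rows_truth = scenario.truth.row_index(scenario.validation_ids)
    val_rows_imp = imputed.row_index(scenario.validation_ids)
    off_chip = np.flatnonzero(~scenario.chip_mask)
    if off_chip.size == 0 or len(val_rows_truth) == 0:
        raise ValueError("scenario has no masked cells to score")

    truth_block = scenario.truth.dosage[np.ix_(val_rows_truth, off_chip)]
    imp_block = imputed.dosage[np.ix_(val_rows_imp, off_chip)]
    if (imp_block == MISSING).any():
        raise ValueError("imputed matrix still contains missing validation calls")
    scoreable = truth_block != MISSING

    per_ind = []
    for i, ind in enumerate(scenario.validation_ids):
        sel = scoreable[i]
        if not sel.any():
            per_ind.append((ind, np.nan, np.nan))
            continue
        per_ind.append(
            (ind, perc(imp_block[i, sel], truth_block[i, sel]),
             corr(imp_block[i, sel], truth_block[i, sel]))
        )
    per_individual = pd.DataFrame(per_ind, columns=["individual_id", "perc", "corr"])

    snp_ids = scenario.marker_map.snp_ids[off_chip]
    per_snp_rows = []
    for j, snp in enumerate(snp_ids):
        sel = scoreable[:, j]
        if not sel.any():
            per_snp_rows.append((snp, np.nan, np.nan))
            continue
        per_snp_rows.append(
            (snp, perc(imp_block[sel, j], truth_block[sel, j]),
             corr(imp_block[sel, j], truth_block[sel, j]))
        )
    per_snp = pd.DataFrame(per_snp_rows, columns=["snp_id", "perc", "corr"])

    summary: dict = {}
    for label, frame in (("individual", per_individual), ("snp", per_snp)):
        for metric in ("perc", "corr"):
            mean, sd = _mean_sd(frame[metric].to_numpy())
            summary[f"{metric}_mean_by_{label}"] = mean
            summary[f"{metric}_sd_by_{label}"] = sd
        summary[f"n_undefined_corr_by_{label}"] = int(frame["corr"].isna().sum())

    n_imp, pct = imputation_load(scenario.marker_map.n_snps, len(scenario.chip))
    return AccuracyResult(
        per_individual=per_individual,
        per_snp=per_snp,
        summary=summary,
        n_imputed_snps=n_imp,
        pct_imputed_snps=pct,
    )


# ---------------------------------------------------------------------------
# Accuracy vs relatedness
# ---------------------------------------------------------------------------


@dataclass
class RegressionFit:
    """Polynomial OLS fit of per-individual CORR on Mean10."""

    degree: int
    coefficients: np.ndarray  # ascending powers: intercept first
    r_squared: float
    fitted: pd.DataFrame  # individual_id, mean10, corr, fitted

    @property
    def slope(self) -> float:
        """Linear coefficient (the slope for degree-1 fits)."""
        return float(self.coefficients[1])


def regress_accuracy_on_relatedness(
    result: AccuracyResult, relatedness: pd.DataFrame, degree: int = 1
) -> RegressionFit:
    """OLS regression of per-individual CORR on Mean10 (degree 1 or 2)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    merged = result.per_individual.merge(
        relatedness[["individual_id", "mean10"]], on="individual_id"
    ).dropna(subset=["corr", "mean10"])
    if len(merged) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} individuals with defined CORR and Mean10"
        )
    x = merged["mean10"].to_numpy()
    y = merged["corr"].to_numpy()
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_sq = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    frame = merged[["individual_id", "mean10", "corr"]].copy()
    frame["fitted"] = fitted
    return RegressionFit(degree=degree, coefficients=coeffs, r_squared=r_sq,
                         fitted=frame)


# ---------------------------------------------------------------------------
# Genome-window accuracy scan
# ---------------------------------------------------------------------------


def window_accuracy_scan(
    per_snp: pd.DataFrame,
    marker_map: MarkerMap,
    matrix: GenotypeMatrix,
    window_snps: int = 50,
    flag_threshold: float = 0.60,
) -> pd.DataFrame:
    """Scan SNP-wise CORR in consecutive windows of ``window_snps`` markers.

    Returns one row per window: chromosome, start/end bp, SNP count, mean
    CORR (defined values only), mean MAF, mean pairwise r² within the window,
    and a flag for windows whose mean CORR falls below ``flag_threshold``
    (candidate assembly/mapping problem regions).  SNPs without a CORR value
    (e.g. chip SNPs that were never imputed) contribute to MAF/r² but not to
    mean CORR.
    """
    if marker_map.n_snps == 0:
        raise ValueError("empty map")
    corr_by_snp = dict(zip(per_snp["snp_id"], per_snp["corr"]))
    corr_vec = np.array(
        [corr_by_snp.get(s, np.nan) for s in marker_map.snp_ids], dtype=float
    )
    positions = marker_map.table["position_bp"].to_numpy()
    plan = partition_windows(marker_map, window_snps)
    rows = []
    for chrom, idx in plan.windows:
        block = matrix.dosage[:, idx]
        with np.errstate(invalid="ignore"):
            mean_corr = float(np.nanmean(corr_vec[idx])) if np.isfinite(
                corr_vec[idx]).any() else float("nan")
            rr = pairwise_r2(block)
            mean_r2 = float(np.nanmean(rr)) if np.isfinite(rr).any() else float("nan")
        mafs = []
        for j in range(block.shape[1]):
            try:
                mafs.append(snp_maf(block[:, j]))
            except ValueError:
                pass
        mean_maf = float(np.mean(mafs)) if mafs else float("nan")
        rows.append(
            (chrom, int(positions[idx[0]]), int(positions[idx[-1]]), len(idx),
             mean_corr, mean_maf, mean_r2,
             bool(np.isfinite(mean_corr) and mean_corr < flag_threshold))
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start_bp", "end_bp", "n_snps",
                 "mean_corr", "mean_maf", "mean_r2", "flagged"],
    )
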