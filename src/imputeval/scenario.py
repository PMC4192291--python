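"""Masking-based imputation scenarios.

A scenario freezes a reference/validation split and a chip: validation
animals keep their true genotypes only at chip markers (everything else is
set to MISSING), while reference animals stay complete.  The untouched truth
matrix is carried alongside for scoring only — imputers see the masked
matrix and nothing else.

Two built-in baseline imputers are provided so the evaluation stack can be
exercised without external software: a per-SNP reference-mode filler and a
windowed nearest-neighbour haplotype copier whose accuracy responds to chip
density and to relatedness between validation and reference animals.  They
are deliberately simple baselines, not reimplementations of population
phasing/imputation algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    MISSING,
    ChipDefinition,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    intersect_chip,
    read_genotypes,
    write_genotypes,
)
from .chip_design import partition_windows

SPLIT_RULES = ("sires_before_year", "dams")


def split_by_rule(
    pedigree: Pedigree,
    rule: str,
    year_cutoff: int = 2005,
    genotyped_ids: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Reference/validation split from pedigree sex and birth year.

    Reference = males born before ``year_cutoff``.  Validation = the younger
    males (rule ``sires_before_year``) or all females (rule ``dams``).
    ``genotyped_ids`` optionally restricts both sets to genotyped animals.
    """
    if rule not in SPLIT_RULES:
        raise ValueError(f"unknown split rule {rule!r}; expected one of {SPLIT_RULES}")
    t = pedigree.table
    if genotyped_ids is not None:
        t = t[t["individual_id"].isin({str(i) for i in genotyped_ids})]
    male = t["sex"].str.upper().isin({"M", "MALE", "1"})
    year = t["birth_year"]
    reference = list(t.loc[male & (year < year_cutoff), "individual_id"])
    if rule == "sires_before_year":
        validation = list(t.loc[male & ~(year < year_cutoff), "individual_id"])
    else:
        validation = list(t.loc[~male, "individual_id"])
    if not reference:
        raise ValueError(f"empty reference set (no males born before {year_cutoff})")
    if not validation:
        raise ValueError(f"empty validation set for rule {rule!r}")
    return reference, validation


@dataclass
class ImputationScenario:
    """A masked evaluation scenario.  ``truth`` is for scoring only."""

    reference_ids: list
    validation_ids: list
    chip: ChipDefinition
    marker_map: MarkerMap
    masked: GenotypeMatrix
    truth: GenotypeMatrix

    def __post_init__(self) -> None:
        overlap = set(self.reference_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"reference/validation overlap: {sorted(overlap)[:3]}")

    @property
    def chip_mask(self) -> np.ndarray:
        """Boolean per map SNP: True where the chip retains the genotype."""
        return np.isin(self.marker_map.snp_ids, list(self.chip.snp_ids))

    @property
    def n_snps_to_impute(self) -> int:
        return self.marker_map.n_snps - len(self.chip)


def mask_to_chip(
    truth: GenotypeMatrix,
    marker_map: MarkerMap,
    chip: ChipDefinition,
    reference_ids: Sequence[str],
    validation_ids: Sequence[str],
) -> ImputationScenario:
    """Mask validation rows down to the chip markers."""
    if len(chip) == 0:
        raise ValueError("cannot mask to an empty chip")
    chip, _ = intersect_chip(chip, marker_map)
    masked = truth.copy()
    val_rows = masked.row_index(validation_ids)
    off_chip = ~np.isin(marker_map.snp_ids, list(chip.snp_ids))
    masked.dosage[np.ix_(val_rows, np.flatnonzero(off_chip))] = MISSING
    return ImputationScenario(
        reference_ids=[str(i) for i in reference_ids],
        validation_ids=[str(i) for i in validation_ids],
        chip=chip,
        marker_map=marker_map,
        masked=masked,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Baseline imputers (operate on scenario.masked only)
# ---------------------------------------------------------------------------


def _reference_modes(scenario: ImputationScenario) -> np.ndarray:
    """Most frequent non-missing reference genotype per SNP (tie -> lower)."""
    ref = scenario.masked.subset_individuals(scenario.reference_ids)
    counts = np.stack([(ref.dosage == g).sum(axis=0) for g in (0, 1, 2)])
    # argmax returns the first (lowest dosage) on ties
    modes = counts.argmax(axis=0).astype(np.int8)
    return modes


def impute_mode(scenario: ImputationScenario) -> GenotypeMatrix:
    """Fill every masked cell with the per-SNP reference mode genotype."""
    modes = _reference_modes(scenario)
    out = scenario.masked.copy()
    miss_rows, miss_cols = np.nonzero(out.dosage == MISSING)
    out.dosage[miss_rows, miss_cols] = modes[miss_cols]
    return out


def impute_nn_window(
    scenario: ImputationScenario,
    window_snps: int = 50,
    pedigree: Pedigree | None = None,
) -> GenotypeMatrix:
    """Windowed nearest-neighbour imputation.

    For each validation animal and each genomic window (``window_snps``
    markers, same partition rule as chip design), the reference animal with
    the smallest Hamming distance on the window's chip SNPs donates its
    genotypes for the masked cells (ties break to the first reference animal
    in id order).  Windows without chip SNPs fall back to the per-SNP mode.

    ``pedigree`` is accepted so that any imputer can be run with and without
    family information through a single interface; this baseline ignores it.
    """
    del pedigree  # baseline is population-only
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    masked = scenario.masked
    out = masked.copy()
    ref_rows = masked.row_index(scenario.reference_ids)
    val_rows = masked.row_index(scenario.validation_ids)
    chip_mask = scenario.chip_mask
    modes = _reference_modes(scenario)

    plan = partition_windows(scenario.marker_map, window_snps)
    for _chrom, idx in plan.windows:
        chip_idx = idx[chip_mask[idx]]
        fill = ~chip_mask[idx]
        fill_idx = idx[fill]
        if chip_idx.size == 0:
            for r in val_rows:
                cells = fill_idx[out.dosage[r, fill_idx] == MISSING]
                out.dosage[r, cells] = modes[cells]
            continue
        ref_block = masked.dosage[np.ix_(ref_rows, chip_idx)]
        val_block = masked.dosage[np.ix_(val_rows, chip_idx)]
        # Hamming distance on observed chip genotypes (missing cells ignored)
        diff = val_block[:, None, :] != ref_block[None, :, :]
        observed = (val_block != MISSING)[:, None, :] & (ref_block != MISSING)[None, :, :]
        dist = (diff & observed).sum(axis=2)
        nearest = dist.argmin(axis=1)  # first minimal -> first reference id
        for vi, r in enumerate(val_rows):
            donor = ref_rows[nearest[vi]]
            cells = fill_idx[out.dosage[r, fill_idx] == MISSING]
            out.dosage[r, cells] = masked.dosage[donor, cells]
    # donor cells can themselves be missing (reference no-calls): mode-fill
    residual_rows, residual_cols = np.nonzero(out.dosage == MISSING)
    out.dosage[residual_rows, residual_cols] = modes[residual_cols]
    return out


# ---------------------------------------------------------------------------
# Data exchange with external imputation tools
# ---------------------------------------------------------------------------


def export_for_tool(
    scenario: ImputationScenario, path: str | Path, format: str = "vcf"
) -> None:
    """Write the masked matrix for an external imputation tool."""
    write_genotypes(scenario.masked, scenario.marker_map, path, format)


def import_imputed(
    path: str | Path, format: str, scenario: ImputationScenario
) -> GenotypeMatrix:
    """Read a tool's output and validate it against the scenario.

    Individuals and markers must match the scenario exactly; mismatches are
    reported by id.
    """
    matrix, marker_map = read_genotypes(path, format)
    expected_inds = set(scenario.masked.individual_ids)
    got_inds = set(matrix.individual_ids)
    if expected_inds - got_inds:
        missing = sorted(expected_inds - got_inds)[0]
        raise ValueError(f"imported file is missing individual {missing!r}")
    if got_inds - expected_inds:
        extra = sorted(got_inds - expected_inds)[0]
        raise ValueError(f"imported file has unexpected individual {extra!r}")
    expected_snps = set(scenario.marker_map.snp_ids)
    got_snps = set(marker_map.snp_ids)
    if expected_snps - got_snps:
        missing = sorted(expected_snps - got_snps)[0]
        raise ValueError(f"imported file is missing SNP {missing!r}")
    if got_snps - expected_snps:
        extra = sorted(got_snps - expected_snps)[0]
        raise ValueError(f"imported file has unexpected SNP {extra!r}")
    # align row/column order with the scenario
    matrix = matrix.subset_individuals(scenario.masked.individual_ids)
    matrix = matrix.subset_snps(marker_map.index_of(scenario.marker_map.snp_ids))
    return matrix
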