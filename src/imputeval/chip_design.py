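"""Design of customized lower-density SNP panels by windowed selection.

The genome (the post-QC map, in marker order) is partitioned per chromosome
into consecutive windows of k markers (a trailing remainder forms a short
final window; windows never span chromosomes) and exactly one SNP is picked
per window by one of four criteria:

- ``even_last``          : the last marker of the window (even spacing),
- ``max_maf``            : highest minor allele frequency,
- ``max_avg_r2``         : highest mean r² with the other window members,
- ``max_maf_times_r2``   : highest MAF x mean-r² product.

Add-on panels augment an existing base chip: windows are partitioned over
the post-QC map *excluding* the base-chip markers, one marker is added per
window, so the add-on size is the base size plus the window count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .io_formats import ChipDefinition, GenotypeMatrix, MarkerMap, intersect_chip
from .ld_stats import window_avg_r2
from .qc import snp_maf


class SelectionCriterion(str, Enum):
    EVEN_LAST = "even_last"
    MAX_MAF = "max_maf"
    MAX_AVG_R2 = "max_avg_r2"
    MAX_MAF_TIMES_R2 = "max_maf_times_r2"

    @classmethod
    def parse(cls, value: "str | SelectionCriterion") -> "SelectionCriterion":
        """Accept long names or the customary short codes e/em/el/eml."""
        if isinstance(value, cls):
            return value
        aliases = {"e": cls.EVEN_LAST, "em": cls.MAX_MAF,
                   "el": cls.MAX_AVG_R2, "eml": cls.MAX_MAF_TIMES_R2}
        if value in aliases:
            return aliases[value]
        return cls(value)


@dataclass
class WindowingPlan:
    """Disjoint consecutive index windows covering every SNP of a map."""

    window_size: int
    windows: list  # of (chromosome, np.ndarray of map row indices)

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def partition_windows(marker_map: MarkerMap, k: int) -> WindowingPlan:
    """Partition the map into per-chromosome windows of k consecutive markers."""
    if k < 1:
        raise ValueError("window size must be >= 1")
    if marker_map.n_snps == 0:
        raise ValueError("cannot window an empty map")
    windows = []
    for chrom, idx in marker_map.chrom_indices().items():
        for start in range(0, len(idx), k):
            windows.append((chrom, idx[start:start + k]))
    return WindowingPlan(k, windows)


def _criterion_scores(
    criterion: SelectionCriterion,
    dosage_block: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Per-SNP selection score inside one window (NaN = undefined)."""
    w = dosage_block.shape[1]
    if criterion is SelectionCriterion.EVEN_LAST:
        return np.arange(w, dtype=float)  # monotone in position: last wins
    def _maf_or_nan(col: np.ndarray) -> float:
        try:
            return snp_maf(col)
        except ValueError:  # all calls missing
            return float("nan")

    maf = np.array([_maf_or_nan(dosage_block[:, j]) for j in range(w)])
    if criterion is SelectionCriterion.MAX_MAF:
        return maf
    avg_r2 = window_avg_r2(dosage_block)
    if criterion is SelectionCriterion.MAX_AVG_R2:
        return avg_r2
    return maf * avg_r2


def _select_in_window(scores: np.ndarray) -> int:
    """Argmax with NaN treated as undefined; ties break to the lowest bp
    position (windows are in position order, so the first max wins).  All
    undefined falls back to the even-spacing choice (last marker)."""
    if np.all(np.isnan(scores)):
        return len(scores) - 1
    return int(np.nanargmax(scores))


def design_chip(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    k: int,
    criterion: "str | SelectionCriterion",
    stat_individual_ids: Sequence[str] | None = None,
    name: str | None = None,
) -> ChipDefinition:
    """Select one SNP per window of k markers.

    ``stat_individual_ids`` restricts the MAF/r² statistics to a subset
    (typically the reference animals); the window layout is unaffected.
    """
    criterion = SelectionCriterion.parse(criterion)
    if matrix.n_snps != marker_map.n_snps:
        raise ValueError("matrix and map disagree on SNP count")
    stat = (
        matrix if stat_individual_ids is None
        else matrix.subset_individuals(stat_individual_ids)
    )
    plan = partition_windows(marker_map, k)
    positions = marker_map.table["position_bp"].to_numpy()
    chosen = []
    for _chrom, idx in plan.windows:
        scores = _criterion_scores(criterion, stat.dosage[:, idx], positions[idx])
        chosen.append(idx[_select_in_window(scores)])
    snp_ids = marker_map.snp_ids[np.sort(np.array(chosen))]
    return ChipDefinition(name or f"{criterion.value}_k{k}", tuple(snp_ids))


def design_addon_chip(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    base: ChipDefinition,
    k: int,
    criterion: "str | SelectionCriterion",
    stat_individual_ids: Sequence[str] | None = None,
    name: str | None = None,
) -> ChipDefinition:
    """Augment ``base`` with one SNP per window of the non-base markers.

    The base chip is first intersected with the map.  The resulting panel is
    base ∪ selected and has exactly |base| + (number of windows) markers.
    An empty base degenerates to :func:`design_chip`.
    """
    criterion = SelectionCriterion.parse(criterion)
    base_on_map = [s for s in marker_map.snp_ids if s in base]
    if not base_on_map:
        return design_chip(matrix, marker_map, k, criterion,
                           stat_individual_ids, name=name or f"addon_{k}")
    base_set = set(base_on_map)
    remaining = np.array(
        [i for i, s in enumerate(marker_map.snp_ids) if s not in base_set],
        dtype=np.int64,
    )
    if remaining.size == 0:
        return ChipDefinition(name or f"{base.name}_addon_k{k}", tuple(base_on_map))

    sub_map = marker_map.subset(remaining)
    sub_matrix = matrix.subset_snps(remaining)
    added = design_chip(sub_matrix, sub_map, k, criterion, stat_individual_ids)
    union = set(base_on_map) | set(added.snp_ids)
    snp_ids = tuple(s for s in marker_map.snp_ids if s in union)
    return ChipDefinition(name or f"{base.name}_addon_k{k}", snp_ids)


def mimic_commercial_chip(
    marker_map: MarkerMap, manifest: ChipDefinition
) -> ChipDefinition:
    """Restrict a commercial-chip manifest to the (post-QC) map.

    The difference between the map size and the intersected chip size is the
    number of SNPs an animal genotyped on that chip would need imputed.
    """
    chip, _dropped = intersect_chip(manifest, marker_map)
    return chip


def expected_chip_size(marker_map: MarkerMap, k: int) -> int:
    """Σ_c ceil(m_c / k): one selected SNP per window per chromosome."""
    return sum(-(-len(idx) // k) for idx in marker_map.chrom_indices().values())
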