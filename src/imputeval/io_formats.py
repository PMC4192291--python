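"""Shared data model and readers/writers for genotype data.

Genotypes are held as an individuals x SNPs dosage matrix counting copies of
the B allele (0/1/2), with ``MISSING`` (-1) as a distinguished sentinel for
no-calls.  Marker coordinates are 1-based base pairs.  Supported on-disk
dialects are PLINK PED/MAP, PLINK 1.9 binary BED/BIM/FAM (SNP-major) and
VCF v4.2 (GT field only).  Per-call quality scores (GenCall-like, in [0, 1])
travel in a plain-text sidecar because none of these formats can hold them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

#: Sentinel for a missing genotype call.  Never conflate with dosage 0.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1.9, SNP-major


class ParseError(ValueError):
    """A file could not be interpreted in the named dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def _normalize_chrom(value) -> object:
    """Autosome labels become ints; anything else stays a string label."""
    s = str(value)
    try:
        return int(s)
    except ValueError:
        return s


@dataclass
class MarkerMap:
    """Ordered SNP records defining the genome coordinate system.

    ``table`` columns: snp_id, chromosome, position_bp, allele_a, allele_b.
    Within each chromosome records are sorted by ascending 1-based position.
    Dosages elsewhere in the package count copies of ``allele_b``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"marker map missing columns: {missing_cols}")
        t = self.table.reset_index(drop=True)
        t["chromosome"] = [_normalize_chrom(c) for c in t["chromosome"]]
        t["position_bp"] = t["position_bp"].astype(np.int64)
        if (t["position_bp"] < 1).any():
            raise ValueError("position_bp must be >= 1 (1-based coordinates)")
        if t["snp_id"].duplicated().any():
            dup = t.loc[t["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id in map: {dup!r}")
        # sort within chromosome, keeping chromosome first-appearance order
        order = {c: i for i, c in enumerate(dict.fromkeys(t["chromosome"]))}
        t = t.sort_values(
            by=["chromosome", "position_bp"],
            key=lambda col: col.map(order) if col.name == "chromosome" else col,
            kind="stable",
        ).reset_index(drop=True)
        self.table = t

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chromosome"]))

    def chrom_indices(self) -> dict:
        """Map chromosome label -> array of row indices, in map order."""
        groups: dict = {}
        chroms = self.table["chromosome"].to_numpy()
        for c in self.chromosomes:
            groups[c] = np.flatnonzero(chroms == c)
        return groups

    def index_of(self, snp_ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"snp_id not in map: {exc.args[0]!r}") from None

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.sort(np.asarray(indices))].reset_index(drop=True))

    def __len__(self) -> int:
        return self.n_snps


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with optional per-call quality.

    Entries count copies of the B allele: 0, 1, 2 or :data:`MISSING`.
    Column order matches an associated :class:`MarkerMap`.
    """

    individual_ids: list
    dosage: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual ids must be unique")
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x SNPs)")
        if self.dosage.shape[0] != len(self.individual_ids):
            raise ValueError("dosage rows must match individual_ids")
        valid = np.isin(self.dosage, [MISSING, 0, 1, 2])
        if not valid.all():
            bad = self.dosage[~valid].flat[0]
            raise ValueError(f"invalid dosage value {bad}")
        if self.quality is not None:
            self.quality = np.asarray(self.quality, dtype=np.float64)
            if self.quality.shape != self.dosage.shape:
                raise ValueError("quality must have same shape as dosage")
            if ((self.quality < 0) | (self.quality > 1)).any():
                raise ValueError("quality scores must lie in [0, 1]")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def quality_or_ones(self) -> np.ndarray:
        if self.quality is None:
            return np.ones_like(self.dosage, dtype=np.float64)
        return self.quality

    def row_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[str(s)] for s in ids], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"individual not in matrix: {exc.args[0]!r}") from None

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        rows = self.row_index(ids)
        q = self.quality[rows] if self.quality is not None else None
        return GenotypeMatrix([self.individual_ids[r] for r in rows], self.dosage[rows], q)

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        q = self.quality[:, indices] if self.quality is not None else None
        return GenotypeMatrix(list(self.individual_ids), self.dosage[:, indices], q)

    def copy(self) -> "GenotypeMatrix":
        q = self.quality.copy() if self.quality is not None else None
        return GenotypeMatrix(list(self.individual_ids), self.dosage.copy(), q)


#: Recorded-unknown parent / missing-field sentinel in pedigree files.
UNKNOWN = "0"


@dataclass
class Pedigree:
    """Pedigree entries: individual, sire, dam, birth year, sex.

    Unknown parents are recorded as :data:`UNKNOWN`.  Construction rejects
    cyclic ancestries.  Parents referenced but absent from the entry list are
    treated as (unlisted) founders.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["individual_id", "sire_id", "dam_id", "birth_year", "sex"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"pedigree missing columns: {missing_cols}")
        t = self.table.reset_index(drop=True).copy()
        for col in ("individual_id", "sire_id", "dam_id", "sex"):
            t[col] = t[col].astype(str)
        if t["individual_id"].duplicated().any():
            raise ValueError("duplicate individual_id in pedigree")
        self.table = t
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        parents = {
            row.individual_id: [p for p in (row.sire_id, row.dam_id) if p != UNKNOWN]
            for row in self.table.itertuples()
        }
        state: dict = {}  # 0 = in progress, 1 = done

        for start in parents:
            if start in state:
                continue
            stack = [(start, iter(parents.get(start, ())))]
            state[start] = 0
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent in it:
                    if parent not in parents:
                        continue  # unlisted founder
                    if state.get(parent) == 0:
                        raise ValueError(f"pedigree cycle involving {parent!r}")
                    if parent not in state:
                        state[parent] = 0
                        stack.append((parent, iter(parents[parent])))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

    @property
    def individual_ids(self) -> list:
        return list(self.table["individual_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ChipDefinition:
    """A named subset of marker ids (a commercial or customized panel)."""

    name: str
    snp_ids: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [str(s) for s in self.snp_ids]
        if len(set(ids)) != len(ids):
            raise ValueError("chip contains duplicate snp ids")
        self.snp_ids = tuple(ids)
        self._id_set = frozenset(ids)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._id_set

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def id_set(self) -> frozenset:
        return self._id_set


# ---------------------------------------------------------------------------
# Chip manifests
# ---------------------------------------------------------------------------


def read_chip_manifest(path: str | os.PathLike, name: str | None = None) -> ChipDefinition:
    """Read a chip manifest: one snp_id per line, ``#`` comments allowed."""
    path = Path(path)
    ids = []
    seen = set()
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line not in seen:
            seen.add(line)
            ids.append(line)
    if not ids:
        raise ParseError(f"empty chip manifest: {path}")
    return ChipDefinition(name or path.stem, tuple(ids))


def write_chip_manifest(chip: ChipDefinition, path: str | os.PathLike) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in chip.snp_ids))


def intersect_chip(chip: ChipDefinition, marker_map: MarkerMap) -> tuple[ChipDefinition, int]:
    """Restrict a chip to ids present in the map, in map order.

    Returns the intersected chip and the count of dropped ids.  An empty
    intersection is an error — a chip with no markers on the platform cannot
    be evaluated.
    """
    kept = [s for s in marker_map.snp_ids if s in chip]
    dropped = len(chip) - len(kept)
    if not kept:
        raise ValueError(f"empty chip after intersection: {chip.name!r}")
    return ChipDefinition(chip.name, tuple(kept)), dropped


# ---------------------------------------------------------------------------
# Pedigree I/O (5-column whitespace-separated text)
# ---------------------------------------------------------------------------


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        ind, sire, dam, year, sex = fields
        try:
            year_val = int(year) if year != UNKNOWN else None
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad birth year {year!r}") from None
        rows.append((ind, sire, dam, year_val, sex))
    if not rows:
        raise ParseError(f"empty pedigree file: {path}")
    return Pedigree(
        pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id", "birth_year", "sex"])
    )


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for row in pedigree.table.itertuples():
            year = UNKNOWN if pd.isna(row.birth_year) else int(row.birth_year)
            fh.write(f"{row.individual_id} {row.sire_id} {row.dam_id} {year} {row.sex}\n")


# ---------------------------------------------------------------------------
# Quality sidecar (individual, snp, score) — only scores < 1 are materialized
# ---------------------------------------------------------------------------


def write_quality_sidecar(
    matrix: GenotypeMatrix, marker_map: MarkerMap, path: str | os.PathLike
) -> None:
    if matrix.quality is None:
        Path(path).write_text("")
        return
    snps = marker_map.snp_ids
    with open(path, "w") as fh:
        rows, cols = np.nonzero(matrix.quality < 1.0)
        for r, c in zip(rows, cols):
            fh.write(f"{matrix.individual_ids[r]}\t{snps[c]}\t{matrix.quality[r, c]:.6f}\n")


def read_quality_sidecar(
    path: str | os.PathLike, matrix: GenotypeMatrix, marker_map: MarkerMap
) -> np.ndarray:
    """Return a full quality matrix; entries absent from the sidecar are 1.0."""
    quality = np.ones_like(matrix.dosage, dtype=np.float64)
    row_lookup = {s: i for i, s in enumerate(matrix.individual_ids)}
    col_lookup = {s: i for i, s in enumerate(marker_map.snp_ids)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            ind, snp, score = line.split("\t")
            quality[row_lookup[ind], col_lookup[snp]] = float(score)
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return quality


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------


def _read_map_file(path: Path) -> list:
    """Read a .map file.

    Standard 4-column PLINK maps (chrom id cM pos) carry no alleles, which
    leaves the B allele ambiguous for monomorphic columns; this package also
    writes and reads a 6-column extended map (chrom id cM pos alleleA alleleB)
    so that the second listed allele fixes B and round-trips are exact.
    """
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) == 4:
            chrom, snp_id, _cm, pos = fields
            rows.append((snp_id, chrom, int(pos), None, None))
        elif len(fields) == 6:
            chrom, snp_id, _cm, pos, a, b = fields
            rows.append((snp_id, chrom, int(pos), a, b))
        else:
            raise ParseError(
                f"{path}:{lineno}: expected 4 or 6 fields (chrom id cM pos [A B])"
            )
    return rows


def _read_ped_map(prefix: Path) -> tuple[GenotypeMatrix, MarkerMap]:
    map_rows = _read_map_file(prefix.with_suffix(".map"))
    m = len(map_rows)
    individual_ids: list = []
    allele_pairs: list = []
    ped_path = prefix.with_suffix(".ped")
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * m:
            raise ParseError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
            )
        individual_ids.append(fields[1])
        allele_pairs.append(fields[6:])
    if not individual_ids:
        raise ParseError(f"empty PED file: {ped_path}")

    # Establish A/B alleles per SNP.  A 6-column map fixes them; otherwise the
    # observed alleles are sorted and the second is B (deterministic fallback
    # for allele-less 4-column maps).
    n = len(individual_ids)
    dosage = np.full((n, m), MISSING, dtype=np.int8)
    alleles_ab: list = []
    for j in range(m):
        snp_id, _chrom, _pos, a_allele, b_allele = map_rows[j]
        col = [(allele_pairs[i][2 * j], allele_pairs[i][2 * j + 1]) for i in range(n)]
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if a_allele is None:
            if len(observed) > 2:
                raise ParseError(f"{ped_path}: SNP {snp_id!r} has >2 alleles")
            a_allele = observed[0] if observed else "A"
            b_allele = observed[1] if len(observed) > 1 else "B"
        else:
            extra = [a for a in observed if a not in (a_allele, b_allele)]
            if extra:
                raise ParseError(
                    f"{ped_path}: SNP {snp_id!r} carries allele {extra[0]!r} "
                    f"not in map alleles ({a_allele}/{b_allele})"
                )
        alleles_ab.append((a_allele, b_allele))
        for i, (a1, a2) in enumerate(col):
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == b_allele) + (a2 == b_allele)

    table = pd.DataFrame(
        [
            (snp_id, chrom, pos, ab[0], ab[1])
            for (snp_id, chrom, pos, _a, _b), ab in zip(map_rows, alleles_ab)
        ],
        columns=["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"],
    )
    marker_map = MarkerMap(table)
    # MarkerMap construction may reorder; realign dosage columns
    original_ids = [r[0] for r in map_rows]
    order = [original_ids.index(s) for s in marker_map.snp_ids]
    return GenotypeMatrix(individual_ids, dosage[:, order]), marker_map


def _write_ped_map(
    matrix: GenotypeMatrix, marker_map: MarkerMap, prefix: Path
) -> None:
    t = marker_map.table
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in t.itertuples():
            fh.write(
                f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}"
                f"\t{row.allele_a}\t{row.allele_b}\n"
            )
    a_alleles = t["allele_a"].to_numpy()
    b_alleles = t["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(matrix.individual_ids):
            fields = [ind, ind, "0", "0", "0", "-9"]
            row = matrix.dosage[i]
            for j in range(matrix.n_snps):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a_alleles[j], a_alleles[j]]
                elif d == 1:
                    fields += [a_alleles[j], b_alleles[j]]
                else:
                    fields += [b_alleles[j], b_alleles[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED/BIM/FAM (PLINK 1.9 binary, SNP-major)
# ---------------------------------------------------------------------------

# 2-bit codes, SNP-major: 00 = hom allele1 (A), 01 = missing, 10 = het,
# 11 = hom allele2 (B).  allele1/allele2 are BIM columns 5/6.
_BED_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


def _read_bed(prefix: Path) -> tuple[GenotypeMatrix, MarkerMap]:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele_a", "allele_b"],
        dtype={"snp_id": str, "allele_a": str, "allele_b": str},
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    individual_ids = list(fam[1])
    n, m = len(individual_ids), len(bim)

    data = prefix.with_suffix(".bed").read_bytes()
    if data[:3] != _BED_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes (not PLINK 1.9 SNP-major)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(data) != expected:
        raise ParseError(f"{prefix}.bed: expected {expected} bytes, got {len(data)}")
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit fields, individual index advances within each byte (LSB first)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosage = _BED_CODE_TO_DOSAGE[codes].T  # -> individuals x SNPs

    table = bim[["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]]
    marker_map = MarkerMap(table.copy())
    original_ids = list(bim["snp_id"])
    order = [original_ids.index(s) for s in marker_map.snp_ids]
    return GenotypeMatrix(individual_ids, dosage[:, order]), marker_map


def _write_bed(matrix: GenotypeMatrix, marker_map: MarkerMap, prefix: Path) -> None:
    t = marker_map.table
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for row in t.itertuples():
            fh.write(
                f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}"
                f"\t{row.allele_a}\t{row.allele_b}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for ind in matrix.individual_ids:
            fh.write(f"{ind} {ind} 0 0 0 -9\n")

    n, m = matrix.n_individuals, matrix.n_snps
    bytes_per_snp = (n + 3) // 4
    code = np.empty((n,), dtype=np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
        for j in range(m):
            col = matrix.dosage[:, j]
            code[col == 0] = 0b00
            code[col == MISSING] = 0b01
            code[col == 1] = 0b10
            code[col == 2] = 0b11
            padded[j, :n] = code
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        packed = (padded.reshape(m, bytes_per_snp, 4) << shifts[None, None, :]).sum(
            axis=2, dtype=np.uint8
        )
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF v4.2 (GT only)
# ---------------------------------------------------------------------------


def _read_vcf(path: Path) -> tuple[GenotypeMatrix, MarkerMap]:
    with pysam.VariantFile(str(path)) as vcf:
        individual_ids = list(vcf.header.samples)
        rows = []
        dosage_cols = []
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: {rec.id or rec.pos}: only biallelic records supported"
                )
            rows.append((rec.id, rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            col = np.full(len(individual_ids), MISSING, dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                col[i] = sum(gt)
            dosage_cols.append(col)
    if not rows:
        raise ParseError(f"no records in VCF: {path}")
    table = pd.DataFrame(
        rows, columns=["snp_id", "chromosome", "position_bp", "allele_a", "allele_b"]
    )
    marker_map = MarkerMap(table)
    dosage = np.column_stack(dosage_cols)
    original_ids = list(table["snp_id"])
    order = [original_ids.index(s) for s in marker_map.snp_ids]
    return GenotypeMatrix(individual_ids, dosage[:, order]), marker_map


def _write_vcf(matrix: GenotypeMatrix, marker_map: MarkerMap, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
                                     ("Description", "Genotype")])
    for chrom in marker_map.chromosomes:
        max_pos = int(
            marker_map.table.loc[marker_map.table["chromosome"] == chrom, "position_bp"].max()
        )
        header.contigs.add(str(chrom), length=max_pos + 1)
    for ind in matrix.individual_ids:
        header.add_sample(ind)

    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(marker_map.table.itertuples()):
            rec = vcf.new_record(
                contig=str(row.chromosome),
                start=int(row.position_bp) - 1,
                stop=int(row.position_bp),
                id=row.snp_id,
                alleles=(str(row.allele_a), str(row.allele_b)),
            )
            for i, ind in enumerate(matrix.individual_ids):
                rec.samples[ind]["GT"] = gt_of[int(matrix.dosage[i, j])]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

FORMATS = ("ped", "bed", "vcf")


def read_genotypes(
    path: str | os.PathLike, format: str
) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read genotypes in the named dialect.

    ``path`` is a PLINK prefix for ``ped``/``bed`` and a file path for ``vcf``.
    """
    path = Path(path)
    if format == "ped":
        return _read_ped_map(path)
    if format == "bed":
        return _read_bed(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def write_genotypes(
    matrix: GenotypeMatrix,
    marker_map: MarkerMap,
    path: str | os.PathLike,
    format: str,
) -> None:
    if matrix.n_individuals == 0:
        raise ValueError("refusing to write a genotype file with zero individuals")
    if matrix.n_snps != marker_map.n_snps:
        raise ValueError("matrix and map disagree on SNP count")
    path = Path(path)
    if format == "ped":
        _write_ped_map(matrix, marker_map, path)
    elif format == "bed":
        _write_bed(matrix, marker_map, path)
    elif format == "vcf":
        _write_vcf(matrix, marker_map, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
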