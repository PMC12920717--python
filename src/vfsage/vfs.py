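"""Somatic variant frequency spectra (VFS): derivation, filtering, and I/O.

A VFS is the collection of one individual's somatic variants together with
their variant allele frequencies (VAFs).  Two sources are supported:

* ``bulk_reads`` — VAF is the raw alt-read fraction in [0, 1].
* ``colony_cells`` — VAF is half the mutant-cell fraction, because a
  heterozygous somatic variant carried by a fraction ``f`` of cells appears
  on a fraction ``f/2`` of sequenced alleles; hence VAF <= 0.5.

Variants private to a single sampled HSC lineage ("tip variants") sit at
frequencies around ``1/(2 * n_lineages)`` and are removed by the 1% VAF
threshold before any diversity-decay metric is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantSource",
    "VariantRecord",
    "VFS",
    "CohortFilterResult",
    "vaf_from_cell_counts",
    "vaf_from_read_counts",
    "rescale_counts_to_depth",
    "filter_tip_variants",
    "cohort_germline_filter",
    "read_vfs",
    "write_vfs",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "genotype_matrix_to_vfs",
]

DEFAULT_VAF_THRESHOLD = 0.01

_TSV_COLUMNS = ["sample_id", "variant_id", "ref_count", "alt_count", "vaf", "source"]


class VariantSource(str, Enum):
    """Provenance of the counts behind a VAF."""

    BULK = "bulk_reads"
    COLONY = "colony_cells"


class VariantRecord(NamedTuple):
    """One somatic variant with its supporting counts.

    ``mutant_count``/``nonmutant_count`` are alt/ref read counts for
    ``bulk_reads`` and mutant/non-mutant cell counts for ``colony_cells``.
    Counts may be non-integer after deterministic depth rescaling.
    """

    variant_id: str
    mutant_count: float
    nonmutant_count: float
    vaf: float
    source: str = VariantSource.BULK.value
    chrom: str | None = None
    pos: int | None = None
    gene: str | None = None


@dataclass
class VFS:
    """One individual's somatic variant frequency spectrum.

    Columns are stored as parallel numpy arrays so that filtering and metric
    computation stay vectorised even for genome-scale spectra (hundreds of
    thousands of variants).  ``records`` materialises :class:`VariantRecord`
    views on demand.
    """

    sample_id: str
    variant_ids: np.ndarray
    mutant: np.ndarray
    nonmutant: np.ndarray
    vaf: np.ndarray
    source: np.ndarray
    age: float | None = None
    vaf_threshold_applied: float | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    gene: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.mutant = np.asarray(self.mutant, dtype=float)
        self.nonmutant = np.asarray(self.nonmutant, dtype=float)
        self.vaf = np.asarray(self.vaf, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        n = len(self.variant_ids)
        for name in ("mutant", "nonmutant", "vaf", "source"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VFS column {name!r} has length "
                                 f"{len(getattr(self, name))}, expected {n}")
        if len(set(self.variant_ids)) != n:
            raise ValueError(f"duplicate variant_id in VFS {self.sample_id!r}")
        if n and (self.vaf.min() < 0 or self.vaf.max() > 1):
            raise ValueError("VAF outside [0, 1]")

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def records(self) -> tuple[VariantRecord, ...]:
        chrom = self.chrom if self.chrom is not None else [None] * len(self)
        pos = self.pos if self.pos is not None else [None] * len(self)
        gene = self.gene if self.gene is not None else [None] * len(self)
        return tuple(
            VariantRecord(v, m, u, f, s, c, None if p is None else int(p), g)
            for v, m, u, f, s, c, p, g in zip(
                self.variant_ids, self.mutant, self.nonmutant, self.vaf,
                self.source, chrom, pos, gene
            )
        )

    @classmethod
    def from_records(
        cls,
        sample_id: str,
        records: Sequence[VariantRecord],
        age: float | None = None,
        vaf_threshold_applied: float | None = None,
    ) -> "VFS":
        recs = list(records)
        has_locus = any(r.chrom is not None for r in recs)
        has_gene = any(r.gene is not None for r in recs)
        return cls(
            sample_id=sample_id,
            variant_ids=np.array([r.variant_id for r in recs], dtype=object),
            mutant=np.array([r.mutant_count for r in recs], dtype=float),
            nonmutant=np.array([r.nonmutant_count for r in recs], dtype=float),
            vaf=np.array([r.vaf for r in recs], dtype=float),
            source=np.array([r.source for r in recs], dtype=object),
            age=age,
            vaf_threshold_applied=vaf_threshold_applied,
            chrom=np.array([r.chrom for r in recs], dtype=object) if has_locus else None,
            pos=np.array([-1 if r.pos is None else r.pos for r in recs], dtype=int)
            if has_locus else None,
            gene=np.array([r.gene for r in recs], dtype=object) if has_gene else None,
        )

    def subset(self, mask: np.ndarray, **overrides) -> "VFS":
        """Row-subset preserving all annotation columns."""
        kwargs = dict(
            sample_id=self.sample_id,
            variant_ids=self.variant_ids[mask],
            mutant=self.mutant[mask],
            nonmutant=self.nonmutant[mask],
            vaf=self.vaf[mask],
            source=self.source[mask],
            age=self.age,
            vaf_threshold_applied=self.vaf_threshold_applied,
            chrom=None if self.chrom is None else self.chrom[mask],
            pos=None if self.pos is None else self.pos[mask],
            gene=None if self.gene is None else self.gene[mask],
        )
        kwargs.update(overrides)
        return VFS(**kwargs)


def vaf_from_cell_counts(mutant_cells: float, nonmutant_cells: float) -> float:
    """Cell counts -> allele frequency: VAF = ½·mutant/(mutant + nonmutant).

    The ½ factor converts the fraction of cells carrying a heterozygous
    somatic variant into the fraction of alleles; the result lies in [0, 0.5].
    """
    if mutant_cells < 0 or nonmutant_cells < 0:
        raise ValueError("cell counts must be non-negative")
    total = mutant_cells + nonmutant_cells
    if total <= 0:
        raise ZeroDivisionError("frequency undefined: zero total cell count")
    return 0.5 * mutant_cells / total


def vaf_from_read_counts(alt_reads: float, ref_reads: float) -> float:
    """Read counts -> allele frequency: the raw alt-read fraction in [0, 1]."""
    if alt_reads < 0 or ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = alt_reads + ref_reads
    if total <= 0:
        raise ZeroDivisionError("frequency undefined: zero total read count")
    return alt_reads / total


def rescale_counts_to_depth(
    mutant_count: float,
    total_count: float,
    target_total: int = 30,
    integer: bool = False,
) -> tuple[float, float]:
    """Deterministically rescale counts to a target total depth.

    Divides the mutant count by ``total_count / target_total`` and sets the
    non-mutant count to the remainder of ``target_total``, so the VAF is
    preserved exactly in real arithmetic (e.g. 100/300 at target 30 gives
    divisor 10 and counts (10, 20)).  ``integer=True`` rounds the scaled
    mutant count half-away-from-zero for integer-count consumers.
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    if total_count < target_total:
        raise ValueError(
            f"cannot rescale total {total_count} below target {target_total}: "
            "upscaling is undefined"
        )
    if mutant_count > total_count:
        raise ValueError("mutant_count exceeds total_count")
    divisor = total_count / target_total
    scaled_mutant = mutant_count / divisor
    if integer:
        scaled_mutant = float(np.floor(scaled_mutant + 0.5))
    return scaled_mutant, target_total - scaled_mutant


def filter_tip_variants(vfs: VFS, threshold: float = DEFAULT_VAF_THRESHOLD) -> VFS:
    """Remove variants with VAF below ``threshold`` (boundary kept).

    A variant private to one of ``n`` sampled lineages has VAF ~ 1/(2n); the
    default 1% cutoff removes such single-tip variants whenever n >= 50.
    Idempotent; records the threshold on the returned VFS.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mask = vfs.vaf >= threshold
    return vfs.subset(mask, vaf_threshold_applied=threshold)


@dataclass
class CohortFilterResult:
    """Filtered VFS plus a log of removed variants (id -> reason)."""

    vfs: VFS
    removed: dict[str, str] = field(default_factory=dict)


def cohort_germline_filter(
    target: VFS,
    cohort: Iterable[VFS],
    known_germline_sites: Iterable[str] = (),
    min_other_samples: int = 2,
) -> CohortFilterResult:
    """Remove probable germline variants from ``target``.

    A variant is removed if it is a known germline site (e.g. from a
    population reference panel) or if it recurs in at least
    ``min_other_samples`` *other* members of the cohort — recurrent "somatic"
    calls across unrelated individuals are overwhelmingly germline leakage.
    """
    germline = set(known_germline_sites)
    counts: dict[str, int] = {}
    for other in cohort:
        if other is target or other.sample_id == target.sample_id:
            continue
        for vid in set(other.variant_ids):
            counts[vid] = counts.get(vid, 0) + 1
    removed: dict[str, str] = {}
    keep = np.ones(len(target), dtype=bool)
    for i, vid in enumerate(target.variant_ids):
        if vid in germline:
            keep[i] = False
            removed[vid] = "known_germline_site"
        elif counts.get(vid, 0) >= min_other_samples:
            keep[i] = False
            removed[vid] = f"recurrent_in_{counts[vid]}_other_samples"
    return CohortFilterResult(vfs=target.subset(keep), removed=removed)


# ---------------------------------------------------------------------------
# Tabular (TSV) and VCF I/O
# ---------------------------------------------------------------------------

def write_vfs(vfs: VFS, path: str | Path) -> None:
    """Write a VFS as UTF-8 TSV (columns: sample_id, variant_id, ref_count,
    alt_count, vaf, source, plus chrom/pos/gene when annotated)."""
    cols = {
        "sample_id": [vfs.sample_id] * len(vfs),
        "variant_id": vfs.variant_ids,
        "ref_count": vfs.nonmutant,
        "alt_count": vfs.mutant,
        "vaf": vfs.vaf,
        "source": vfs.source,
    }
    if vfs.chrom is not None:
        cols["chrom"] = vfs.chrom
        cols["pos"] = vfs.pos
    if vfs.gene is not None:
        cols["gene"] = vfs.gene
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.12g")


def _read_vfs_tsv(path: Path, sample_id: str | None, age: float | None) -> VFS:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _TSV_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {c: header.index(c) for c in header}
        ids, mut, non, vaf, src = [], [], [], [], []
        chrom: list[str | None] = []
        pos: list[int] = []
        gene: list[str | None] = []
        sid = sample_id
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            try:
                ref_c = float(parts[idx["ref_count"]])
                alt_c = float(parts[idx["alt_count"]])
                stored_vaf = float(parts[idx["vaf"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field ({exc})")
            source = parts[idx["source"]]
            if source == VariantSource.COLONY.value:
                recomputed = vaf_from_cell_counts(alt_c, ref_c)
            else:
                recomputed = vaf_from_read_counts(alt_c, ref_c)
            if abs(recomputed - stored_vaf) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: stored vaf {stored_vaf} disagrees with "
                    f"counts-derived vaf {recomputed}"
                )
            row_sid = parts[idx["sample_id"]]
            if sid is None:
                sid = row_sid
            ids.append(parts[idx["variant_id"]])
            mut.append(alt_c)
            non.append(ref_c)
            vaf.append(stored_vaf)
            src.append(source)
            chrom.append(parts[idx["chrom"]] if "chrom" in idx else None)
            pos.append(int(parts[idx["pos"]]) if "pos" in idx else -1)
            gene.append(parts[idx["gene"]] if "gene" in idx else None)
    has_locus = "chrom" in idx
    has_gene = "gene" in idx
    return VFS(
        sample_id=sid if sid is not None else path.stem,
        variant_ids=np.array(ids, dtype=object),
        mutant=np.array(mut),
        nonmutant=np.array(non),
        vaf=np.array(vaf),
        source=np.array(src, dtype=object),
        age=age,
        chrom=np.array(chrom, dtype=object) if has_locus else None,
        pos=np.array(pos, dtype=int) if has_locus else None,
        gene=np.array(gene, dtype=object) if has_gene else None,
    )


def _read_vfs_vcf(path: Path, sample_id: str | None, age: float | None) -> VFS:
    from cyvcf2 import VCF

    reader = VCF(str(path))
    samples = list(reader.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns with allele depths")
    if sample_id is not None and sample_id in samples:
        sample_idx = samples.index(sample_id)
    else:
        sample_idx = 0
    ids, mut, non, vaf = [], [], [], []
    chrom: list[str] = []
    pos: list[int] = []
    for rec in reader:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS}; "
                "split multi-allelic sites upstream"
            )
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(
                f"{path}: non-SNV record at {rec.CHROM}:{rec.POS} "
                f"({rec.REF}>{rec.ALT[0]}); only biallelic SNVs are supported"
            )
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks the FORMAT/AD "
                "allele-depth field"
            )
        ref_d, alt_d = float(ad[sample_idx][0]), float(ad[sample_idx][1])
        if ref_d < 0 or alt_d < 0:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} has missing allele depths"
            )
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}"
        ids.append(vid)
        mut.append(alt_d)
        non.append(ref_d)
        vaf.append(vaf_from_read_counts(alt_d, ref_d))
        chrom.append(rec.CHROM)
        pos.append(rec.POS)  # 1-based per the VCF standard
    return VFS(
        sample_id=sample_id if sample_id is not None else (samples[sample_idx]),
        variant_ids=np.array(ids, dtype=object),
        mutant=np.array(mut),
        nonmutant=np.array(non),
        vaf=np.array(vaf),
        source=np.array([VariantSource.BULK.value] * len(ids), dtype=object),
        age=age,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=int),
    )


def read_vfs(
    path: str | Path,
    format: str = "tsv",
    sample_id: str | None = None,
    age: float | None = None,
) -> VFS:
    """Read a VFS from ``tsv`` (the package's tabular format) or ``vcf``.

    TSV rows are validated (VAF recomputed from counts at 1e-9 tolerance) and
    malformed rows are reported with their line number.  VCF reading consumes
    biallelic SNVs with a FORMAT/AD allele-depth field; positions are 1-based.
    """
    path = Path(path)
    if format == "tsv":
        return _read_vfs_tsv(path, sample_id, age)
    if format == "vcf":
        return _read_vfs_vcf(path, sample_id, age)
    raise ValueError(f"unknown VFS format {format!r}")


# ---------------------------------------------------------------------------
# Genotype matrices (colony-seq lineages x variants)
# ---------------------------------------------------------------------------

def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="lineage", na_rep="NA")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    """Read a lineages-by-variants binary matrix (entries 0/1/NA) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col="lineage", na_values=["NA"])
    values = df.to_numpy(dtype=float)
    valid = np.isnan(values) | (values == 0) | (values == 1)
    if not valid.all():
        bad = np.argwhere(~valid)[0]
        raise ValueError(
            f"{path}: non-binary entry at lineage {df.index[bad[0]]!r}, "
            f"variant {df.columns[bad[1]]!r}"
        )
    return df.astype(float)


def genotype_matrix_to_vfs(
    matrix: pd.DataFrame,
    sample_id: str = "sample",
    age: float | None = None,
) -> VFS:
    """Derive a colony-seq VFS from a binary genotype matrix.

    Column-wise application of the ½ cell-fraction rule: mutant cells are
    entries equal to 1, non-mutant cells entries equal to 0; missing entries
    are excluded from both counts.
    """
    values = matrix.to_numpy(dtype=float)
    mutant = np.nansum(values == 1, axis=0).astype(float)
    nonmutant = np.nansum(values == 0, axis=0).astype(float)
    total = mutant + nonmutant
    if (total == 0).any():
        bad = matrix.columns[np.argmax(total == 0)]
        raise ZeroDivisionError(f"variant {bad!r} has no genotyped lineages")
    return VFS(
        sample_id=sample_id,
        variant_ids=np.array(matrix.columns, dtype=object),
        mutant=mutant,
        nonmutant=nonmutant,
        vaf=0.5 * mutant / total,
        source=np.array([VariantSource.COLONY.value] * matrix.shape[1], dtype=object),
        age=age,
    )
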