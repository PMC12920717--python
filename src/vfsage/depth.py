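"""Sequencing-design emulation: read-depth resampling and panel restriction.

A decay–age model must be trained at the coverage and genomic footprint of
the data it will be applied to, because the VAF-sum metric is additive: more
sites and deeper reads both raise it.  ``simulate_depth`` draws a per-variant
depth from Poisson(mean_depth) and a mutant-read count from
Binomial(depth, VAF), mimicking finite-coverage bulk sequencing of a known
spectrum; ``restrict_panel`` cuts a spectrum down to a BED region set or a
gene list.

Detection model: a variant is observed only if at least ``min_alt_reads``
reads support it (default 2, the floor below which somatic callers cannot
distinguish signal from error).  The tip-variant VAF threshold is re-applied
to the observed VAFs afterwards.  With this floor, deeper sequencing
recovers more low-frequency variants past the threshold, so the expected
decay metric rises with depth; setting ``min_alt_reads=0`` disables the
floor (a bare ratio rule, under which that relationship disappears).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .vfs import DEFAULT_VAF_THRESHOLD, VFS, VariantSource

__all__ = [
    "DepthProfile",
    "simulate_depth",
    "restrict_panel",
    "read_bed",
    "read_gene_list",
]


@dataclass(frozen=True)
class DepthProfile:
    """Target sequencing design for stochastic depth resampling."""

    mean_depth: float
    seed: int = 0
    reapply_threshold: float | None = DEFAULT_VAF_THRESHOLD
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


def _variant_rng(seed: int, variant_id: str) -> np.random.Generator:
    """Deterministic per-variant substream keyed on (seed, variant_id).

    Subsetting a VFS therefore never shifts the draws of the remaining
    variants.
    """
    digest = hashlib.blake2b(f"{seed}|{variant_id}".encode(), digest_size=16).digest()
    return np.random.Generator(np.random.Philox(key=int.from_bytes(digest, "little")))


def simulate_depth(vfs: VFS, profile: DepthProfile) -> VFS:
    """Resample a VFS at finite read depth.

    Per variant k: depth r_k ~ Poisson(mean_depth); mutant reads
    m_k ~ Binomial(r_k, VAF_k); observed VAF = m_k / r_k.  Variants with
    r_k = 0 are unobserved and dropped; variants with m_k below the
    detection floor are undetected and dropped; the tip-variant threshold is
    then re-applied to the observed VAFs.  Deterministic given the profile
    seed; no new variant identities are ever created.
    """
    n = len(vfs)
    depths = np.empty(n, dtype=float)
    mutants = np.empty(n, dtype=float)
    for i, vid in enumerate(vfs.variant_ids):
        rng = _variant_rng(profile.seed, str(vid))
        r = rng.poisson(profile.mean_depth)
        depths[i] = r
        mutants[i] = rng.binomial(r, vfs.vaf[i]) if r > 0 else 0
    observed = depths > 0
    detected = observed & (mutants >= profile.min_alt_reads)
    with np.errstate(invalid="ignore", divide="ignore"):
        new_vaf = np.where(detected, mutants / np.maximum(depths, 1), 0.0)
    out = vfs.subset(
        detected,
        mutant=mutants[detected],
        nonmutant=(depths - mutants)[detected],
        vaf=new_vaf[detected],
        source=np.array([VariantSource.BULK.value] * int(detected.sum()),
                        dtype=object),
        vaf_threshold_applied=None,
    )
    threshold = profile.reapply_threshold
    if threshold is None:
        threshold = vfs.vaf_threshold_applied
    if threshold is not None:
        keep = out.vaf >= threshold
        out = out.subset(keep, vaf_threshold_applied=threshold)
    return out


# ---------------------------------------------------------------------------
# Panel restriction
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED regions (0-based half-open intervals)."""
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
        regions.append((parts[0], int(parts[1]), int(parts[2])))
    return regions


def read_gene_list(path: str | Path) -> list[str]:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def _is_region_panel(panel: Iterable) -> bool:
    panel = list(panel)
    return bool(panel) and isinstance(panel[0], (tuple, list))


def restrict_panel(
    vfs: VFS,
    panel: "Sequence[tuple[str, int, int]] | Iterable[str]",
) -> VFS:
    """Keep exactly the variants inside a panel.

    ``panel`` is either BED-style regions (chrom, start, end), 0-based
    half-open, matched against the 1-based variant positions, or a gene
    list matched against gene annotations.  Records lacking the needed
    annotation raise an error naming the offending variant ids.
    """
    panel = list(panel)
    if not panel:
        return vfs.subset(np.zeros(len(vfs), dtype=bool))
    if _is_region_panel(panel):
        if vfs.chrom is None or vfs.pos is None:
            raise ValueError(
                "panel restriction by regions requires chrom/pos annotations; "
                f"missing for all records of {vfs.sample_id!r}"
            )
        missing = [str(v) for v, c, p in zip(vfs.variant_ids, vfs.chrom, vfs.pos)
                   if c is None or p is None or p < 0]
        if missing:
            raise ValueError(
                f"records lack locus annotations: {missing[:10]}"
            )
        keep = np.zeros(len(vfs), dtype=bool)
        for i, (c, p) in enumerate(zip(vfs.chrom, vfs.pos)):
            # 1-based position p overlaps [start, end) iff start <= p-1 < end
            keep[i] = any(c == rc and rs <= p - 1 < re
                          for rc, rs, re in panel)
        return vfs.subset(keep)
    genes = set(panel)
    if vfs.gene is None:
        raise ValueError(
            "panel restriction by gene list requires gene annotations; "
            f"missing for all records of {vfs.sample_id!r}"
        )
    missing = [str(v) for v, g in zip(vfs.variant_ids, vfs.gene) if g is None]
    if missing:
        raise ValueError(f"records lack gene annotations: {missing[:10]}")
    keep = np.array([g in genes for g in vfs.gene], dtype=bool)
    return vfs.subset(keep)
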