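"""Per-sample fragment counting from single-end alignments.

Converts SAM/BAM alignment streams into per-contig primary-alignment
fragment counts, aligned-base totals and mean depths.  Reads are single-end
(fragments == reads) and only the primary record of each read is counted,
mirroring a best-hit aligner that reports a single alignment per read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam

from .reference_io import GenomeIndex

__all__ = [
    "SampleCounts",
    "DepthSummary",
    "count_sample",
    "counts_from_arrays",
    "mean_depth",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_design",
]

logger = logging.getLogger(__name__)

GROUPS = ("germline", "soma")


@dataclass
class SampleCounts:
    """One sample's per-contig fragment counts and library size."""

    sample_id: str
    group: str
    counts: dict[str, int]
    aligned_bases: dict[str, int]
    total_mapped: int
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.total_mapped != sum(self.counts.values()):
            raise ValueError("total_mapped does not equal the sum of per-contig counts")


@dataclass
class DepthSummary:
    """Mean per-base fold coverage per contig (aligned_bases / length)."""

    sample_id: str
    depth: dict[str, float] = field(default_factory=dict)


def _aligned_ref_length(read: pysam.AlignedSegment, include_deletions: bool) -> int:
    # reference-consuming ops: M(0), D(2), N(3), =(7), X(8); default M/=/X only
    ops = {0, 7, 8} | ({2} if include_deletions else set())
    return sum(length for op, length in (read.cigartuples or []) if op in ops)


def count_sample(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    genome: GenomeIndex,
    sample_id: str,
    group: str,
    min_mapq: int = 0,
    include_deletions: bool = False,
) -> SampleCounts:
    """Count one fragment per mapped primary single-end alignment.

    Parameters
    ----------
    alignments
        A SAM/BAM file path or an iterable of :class:`pysam.AlignedSegment`.
    min_mapq
        Minimum mapping quality for a read to be counted (default 0, i.e.
        no filter, matching a best-hit aligner run with default parameters).
    include_deletions
        If True, deletions (D) contribute to the aligned reference length.

    Secondary and supplementary records are ignored; paired-end flags are a
    hard error because the counting contract is single-end.
    """
    counts: dict[str, int] = {c: 0 for c in genome.ids}
    bases: dict[str, int] = {c: 0 for c in genome.ids}
    n_unmapped = 0

    opened = None
    if isinstance(alignments, (str, Path)):
        opened = pysam.AlignmentFile(str(alignments), check_sq=False)
        stream: Iterable[pysam.AlignedSegment] = opened
    else:
        stream = alignments
    try:
        for read in stream:
            if read.is_paired:
                raise ValueError(
                    f"read {read.query_name!r} carries paired-end flags; this pipeline "
                    "counts single-end fragments only (map forward reads unpaired)"
                )
            if read.is_unmapped:
                n_unmapped += 1
                continue
            if read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            ref = read.reference_name
            if ref not in counts:
                raise ValueError(f"alignment reference {ref!r} is not in the genome index")
            counts[ref] += 1
            bases[ref] += _aligned_ref_length(read, include_deletions)
    finally:
        if opened is not None:
            opened.close()

    total = sum(counts.values())
    logger.info(
        "sample %s (%s): %d mapped fragments counted, %d unmapped ignored",
        sample_id, group, total, n_unmapped,
    )
    return SampleCounts(sample_id, group, counts, bases, total, n_unmapped)


def counts_from_arrays(
    contig_index: np.ndarray,
    aligned_len: np.ndarray,
    genome: GenomeIndex,
    sample_id: str,
    group: str,
    n_unmapped: int = 0,
) -> SampleCounts:
    """Build :class:`SampleCounts` from mapper output arrays.

    ``contig_index`` holds, per mapped read, the index of its contig in the
    genome's contig order; ``aligned_len`` the reference-consuming aligned
    length.  This is the fast in-memory path used by the simulator's mapper;
    it is equivalent to writing a SAM file and running :func:`count_sample`.
    """
    n_contigs = len(genome)
    c = np.bincount(contig_index, minlength=n_contigs)
    b = np.bincount(contig_index, weights=aligned_len.astype(np.float64), minlength=n_contigs)
    ids = genome.ids
    counts = {ids[i]: int(c[i]) for i in range(n_contigs)}
    bases = {ids[i]: int(b[i]) for i in range(n_contigs)}
    return SampleCounts(sample_id, group, counts, bases, int(c.sum()), n_unmapped)


def mean_depth(sc: SampleCounts, genome: GenomeIndex) -> DepthSummary:
    """Mean per-base depth per contig: aligned_bases / contig length."""
    depth = {c.id: sc.aligned_bases.get(c.id, 0) / c.length for c in genome}
    return DepthSummary(sample_id=sc.sample_id, depth=depth)


def write_counts_tsv(sc: SampleCounts, genome: GenomeIndex, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "contig_id": genome.ids,
            "count": [sc.counts[c] for c in genome.ids],
            "aligned_bases": [sc.aligned_bases[c] for c in genome.ids],
            "mean_depth": [sc.aligned_bases[c] / genome[c].length for c in genome.ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path, sample_id: str, group: str) -> SampleCounts:
    df = pd.read_csv(path, sep="\t")
    counts = dict(zip(df["contig_id"], df["count"].astype(int)))
    bases = dict(zip(df["contig_id"], df["aligned_bases"].astype(int)))
    return SampleCounts(sample_id, group, counts, bases, int(df["count"].sum()))


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sample design table: sample_id, group[, path]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels in design table: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design table")
    return df
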