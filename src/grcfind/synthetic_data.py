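"""Germline/soma genome, read and alignment simulation.

Generates test universes with the coverage structure the comparative
coverage method assumes: a diploid A-chromosome complement present in both
tissues, plus germline-restricted (GRC) sequence in three classes —

* category 1, ``high_copy``: a diverged GRC sequence present in many
  near-identical germline copies but assembled as a single (collapsed)
  contig, so its germline read depth is elevated;
* category 2, ``low_copy_divergent``: a single-copy GRC sequence diverged
  from its A-chromosome paralog, so somatic reads barely touch it;
* category 3, ``low_copy_similar``: a single extra germline allele nearly
  identical to an A-chromosome paralog; it is *not* a separate assembly
  contig — its reads collapse onto the paralog, producing the 3:2
  germline:soma coverage ratio of two A alleles plus one GRC allele.

Reads are single-end, fixed-length, substitution-error-only, drawn
multinomially across genome copies in proportion to copy number × length
(so per-contig counts fluctuate like real library sampling).  A minimal
deterministic best-hit mapper (exact k-mer seeding + full-read Hamming
extension, ties broken by contig order, position, then forward strand)
closes the loop so the full pipeline runs with no external aligner.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .reference_io import ContigRecord, GenomeIndex

__all__ = [
    "SimulationConfig",
    "collapsed_allele_config",
    "power_config",
    "SyntheticTruth",
    "TruthEntry",
    "CopySpec",
    "ReadSet",
    "MapResult",
    "BestHitMapper",
    "simulate_genomes",
    "mutate",
    "simulate_reads",
    "map_reads",
    "random_sequence",
    "encode_seq",
    "decode_seq",
    "write_fastq",
    "read_fastq",
    "write_sam",
    "write_truth_tsv",
]

logger = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

SENTINEL = np.int8(4)


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string → int8 array (A=0, C=1, G=2, T=3; anything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_seq(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated germline/soma comparison.

    Defaults model a replicated design of four germline and four somatic
    libraries at 20× sequencing depth per haploid genome copy, on an
    assembly where GRC-derived contigs make up just under 10% of assembled
    length (large enough to measure, small enough that library-size
    normalisation barely distorts coverage ratios).
    """

    n_a_contigs: int = 130
    a_length_range: tuple[int, int] = (2500, 4000)
    n_cat1: int = 5
    n_cat2: int = 4
    n_cat3: int = 4
    cat1_copy_range: tuple[int, int] = (4, 8)
    divergence_cat1: float = 0.05
    divergence_cat2: float = 0.05
    divergence_cat3: float = 0.0
    read_length: int = 100
    depth_per_haploid_copy: float = 20.0
    error_rate: float = 0.002
    n_germline: int = 4
    n_soma: int = 4
    seed: int = 0
    max_grc_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("divergence_cat1", "divergence_cat2", "divergence_cat3", "error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        for name in ("n_a_contigs", "n_cat1", "n_cat2", "n_cat3", "n_germline", "n_soma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if self.a_length_range[0] > self.a_length_range[1] or self.a_length_range[0] < 1:
            raise ValueError("invalid a_length_range")
        if self.cat1_copy_range[0] > self.cat1_copy_range[1] or self.cat1_copy_range[0] < 1:
            raise ValueError("invalid cat1_copy_range")
        n_grc = self.n_cat1 + self.n_cat2 + self.n_cat3
        if n_grc > 0 and self.n_a_contigs == 0:
            raise ValueError("GRC contigs requested but no A contigs to derive them from")
        # GRC-derived length must stay a small fraction of the genome so that
        # library-size normalisation distorts expected coverage ratios by <~1%
        mean_len = 0.5 * (self.a_length_range[0] + self.a_length_range[1])
        frac = n_grc * mean_len / max((self.n_a_contigs + self.n_cat1 + self.n_cat2) * mean_len, 1)
        if frac > self.max_grc_fraction + 1e-9:
            raise ValueError(
                f"GRC-derived length fraction {frac:.3f} exceeds {self.max_grc_fraction:.3f}; "
                "increase n_a_contigs or reduce GRC contig counts"
            )


def collapsed_allele_config(seed: int = 0) -> SimulationConfig:
    """Design isolating the collapsed-allele (category-3) coverage ratio.

    A ~200-contig diploid assembly where the only germline-restricted
    sequence is a handful of extra haploid alleles sequence-identical to
    their A-chromosome paralogs.  Each affected contig then receives reads
    from three germline copies versus two somatic copies, so its linear
    FPKM fold change should converge on 3:2 = 1.5 (minus a ~1% library-
    size effect from the extra germline reads).
    """
    return SimulationConfig(
        n_a_contigs=200,
        a_length_range=(2500, 3500),
        n_cat1=0,
        n_cat2=0,
        n_cat3=5,
        divergence_cat3=0.0,
        seed=seed,
    )


def power_config(seed: int = 0) -> SimulationConfig:
    """Small, cheap design for replicate-number power experiments.

    Kept deliberately modest (40 A contigs at 10× per haploid copy) so a
    power curve over many seeds and replicate counts stays inexpensive;
    the effect structure (all three GRC categories) matches the default
    design.
    """
    return SimulationConfig(
        n_a_contigs=40,
        a_length_range=(1500, 2500),
        n_cat1=2,
        n_cat2=1,
        n_cat3=1,
        cat1_copy_range=(4, 6),
        depth_per_haploid_copy=10.0,
        seed=seed,
    )


@dataclass(frozen=True)
class TruthEntry:
    category: str  # a_chromosome | high_copy | low_copy_divergent | low_copy_similar
    germline_copies: int
    soma_copies: int
    source_a_paralog: str | None = None


@dataclass
class SyntheticTruth:
    """Ground-truth per-contig labels for a simulated assembly."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def grc_contigs(self) -> list[str]:
        """Assembly contigs whose germline copy plan differs from soma."""
        return [
            c for c, t in self.entries.items() if t.germline_copies != t.soma_copies
        ]

    def of_category(self, category: str) -> list[str]:
        return [c for c, t in self.entries.items() if t.category == category]


@dataclass(frozen=True)
class CopySpec:
    """One template sequence present in a genome at some copy number."""

    name: str           # template name (encodes read provenance)
    target_contig: str  # assembly contig these reads should collapse onto
    seq: np.ndarray     # int8-encoded sequence
    copies: int


@dataclass
class ReadSet:
    """Simulated single-end reads for one sample, kept in encoded form."""

    sample_id: str
    seqs: np.ndarray        # (n_reads, read_length) int8
    source: np.ndarray      # per-read index into `templates`
    pos: np.ndarray         # 0-based start on the source template
    strand: np.ndarray      # 0 = forward, 1 = reverse complement
    templates: list[str]    # template names, aligned with `source` indices
    target_contig: list[str]  # expected mapping target per template

    @property
    def n_reads(self) -> int:
        return self.seqs.shape[0]

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def names(self) -> list[str]:
        return [
            f"{self.templates[s]}|{p}|{'-' if st else '+'}|{i}"
            for i, (s, p, st) in enumerate(zip(self.source, self.pos, self.strand))
        ]


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def mutate(sequence: str | np.ndarray, rate: float, seed: int | np.random.Generator) -> str | np.ndarray:
    """Substitute each position independently with probability ``rate``.

    Substitutions always change the base (uniform over the three others);
    length is preserved.  Accepts and returns either a string or an encoded
    array.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    as_str = isinstance(sequence, str)
    arr = encode_seq(sequence).copy() if as_str else np.asarray(sequence, dtype=np.int8).copy()
    hit = rng.random(arr.shape[0]) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit, dtype=np.int8)
        arr[hit] = (arr[hit] + shift) % 4
    return decode_seq(arr) if as_str else arr


def simulate_genomes(
    cfg: SimulationConfig,
) -> tuple[GenomeIndex, list[CopySpec], list[CopySpec], SyntheticTruth]:
    """Draw an assembly plus germline and soma genome copy plans.

    Returns ``(assembly, germline_plan, soma_plan, truth)``.  The soma plan
    is two copies of each A contig; the germline plan adds category-1
    contigs at elevated copy number, category-2 contigs at one copy, and
    category-3 extra alleles that are *not* separate assembly contigs.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.a_length_range

    a_seqs = [
        random_sequence(int(rng.integers(lo, hi + 1)), rng) for _ in range(cfg.n_a_contigs)
    ]
    a_ids = [f"A{i:04d}" for i in range(cfg.n_a_contigs)]

    # each GRC sequence derives from a distinct A paralog
    n_grc = cfg.n_cat1 + cfg.n_cat2 + cfg.n_cat3
    if n_grc > cfg.n_a_contigs:
        raise ValueError("need at least one distinct A paralog per GRC contig")
    paralogs = rng.choice(cfg.n_a_contigs, size=n_grc, replace=False)
    i_cat1 = paralogs[: cfg.n_cat1]
    i_cat2 = paralogs[cfg.n_cat1 : cfg.n_cat1 + cfg.n_cat2]
    i_cat3 = paralogs[cfg.n_cat1 + cfg.n_cat2 :]

    contigs = [ContigRecord(i, decode_seq(s)) for i, s in zip(a_ids, a_seqs)]
    truth = SyntheticTruth()
    for cid in a_ids:
        truth.entries[cid] = TruthEntry("a_chromosome", 2, 2, None)

    germline: list[CopySpec] = [
        CopySpec(cid, cid, seq, 2) for cid, seq in zip(a_ids, a_seqs)
    ]
    soma: list[CopySpec] = list(germline)

    for j, ai in enumerate(i_cat1):
        cid = f"GRC1_{j:03d}"
        seq = mutate(a_seqs[ai], cfg.divergence_cat1, rng)
        copies = int(rng.integers(cfg.cat1_copy_range[0], cfg.cat1_copy_range[1] + 1))
        contigs.append(ContigRecord(cid, decode_seq(seq)))
        germline.append(CopySpec(cid, cid, seq, copies))
        truth.entries[cid] = TruthEntry("high_copy", copies, 0, a_ids[ai])

    for j, ai in enumerate(i_cat2):
        cid = f"GRC2_{j:03d}"
        seq = mutate(a_seqs[ai], cfg.divergence_cat2, rng)
        contigs.append(ContigRecord(cid, decode_seq(seq)))
        germline.append(CopySpec(cid, cid, seq, 1))
        truth.entries[cid] = TruthEntry("low_copy_divergent", 1, 0, a_ids[ai])

    for j, ai in enumerate(i_cat3):
        cid = a_ids[ai]  # collapsed: the allele has no contig of its own
        allele = mutate(a_seqs[ai], cfg.divergence_cat3, rng)
        germline.append(CopySpec(f"{cid}_grc_allele", cid, allele, 1))
        truth.entries[cid] = TruthEntry("low_copy_similar", 3, 2, cid)

    assembly = GenomeIndex(contigs)
    return assembly, germline, soma, truth


def simulate_reads(
    plan: Sequence[CopySpec],
    cfg: SimulationConfig,
    sample_seed: int,
    sample_id: str = "sample",
) -> ReadSet:
    """Draw single-end reads from a genome copy plan.

    The library size is the total genomic mass divided by the read length;
    reads are assigned to templates multinomially in proportion to
    copies × template length, then placed uniformly, flipped to the reverse
    strand with probability 1/2, and hit with independent per-base
    substitution errors at ``cfg.error_rate``.
    """
    rng = np.random.default_rng(sample_seed)
    L = cfg.read_length
    usable = [sp for sp in plan if len(sp.seq) >= L]
    for sp in plan:
        if len(sp.seq) < L:
            logger.warning("template %s shorter than read length; skipped", sp.name)
    if not usable:
        raise ValueError("no template is at least one read length long")

    mass = np.array([sp.copies * len(sp.seq) for sp in usable], dtype=np.float64)
    n_total = int(round(mass.sum() * cfg.depth_per_haploid_copy / L))
    counts = rng.multinomial(n_total, mass / mass.sum())

    seqs = np.empty((n_total, L), dtype=np.int8)
    source = np.repeat(np.arange(len(usable), dtype=np.int32), counts)
    pos = np.empty(n_total, dtype=np.int64)
    strand = rng.integers(0, 2, size=n_total, dtype=np.int8)

    at = 0
    col = np.arange(L)
    for sp, n_i in zip(usable, counts):
        if n_i == 0:
            continue
        p = rng.integers(0, len(sp.seq) - L + 1, size=n_i)
        pos[at : at + n_i] = p
        seqs[at : at + n_i] = sp.seq[p[:, None] + col]
        at += n_i

    rev = strand == 1
    seqs[rev] = 3 - seqs[rev][:, ::-1]

    if cfg.error_rate > 0:
        chunk = 20000
        for s in range(0, n_total, chunk):
            block = seqs[s : s + chunk]
            hit = rng.random(block.shape) < cfg.error_rate
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, size=n_hit, dtype=np.int8)
                block[hit] = (block[hit] + shift) % 4

    return ReadSet(
        sample_id=sample_id,
        seqs=seqs,
        source=source,
        pos=pos,
        strand=strand,
        templates=[sp.name for sp in usable],
        target_contig=[sp.target_contig for sp in usable],
    )


# ---------------------------------------------------------------------------
# deterministic best-hit mapper


@dataclass
class MapResult:
    """Single best alignment per read (primary records only)."""

    contig_idx: np.ndarray   # index into genome contig order; -1 = unmapped
    pos: np.ndarray          # 0-based leftmost position on the contig
    strand: np.ndarray       # 0 forward, 1 reverse
    n_mismatch: np.ndarray   # Hamming mismatches of the full-read alignment
    read_length: int

    @property
    def mapped(self) -> np.ndarray:
        return self.contig_idx >= 0

    @property
    def n_unmapped(self) -> int:
        return int((~self.mapped).sum())


def _pack_codes(mat: np.ndarray, offset: int, k: int) -> np.ndarray:
    """2-bit pack k-mers starting at a fixed column offset, one per row."""
    c = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(k):
        c = (c << np.uint64(2)) | mat[:, offset + j].astype(np.uint64)
    return c


def _ranges_flatten(lo: np.ndarray, cnt: np.ndarray) -> np.ndarray:
    """Concatenate [lo_i, lo_i + cnt_i) ranges into one index vector."""
    total = int(cnt.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    starts = np.repeat(lo.astype(np.int64), cnt)
    within = np.arange(total, dtype=np.int64) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    return starts + within


class BestHitMapper:
    """Exact-k-mer-seeded, Hamming-extended single-best-hit read mapper.

    For each read, candidate loci are found by exact k-mer lookups (default
    k = 31) at three offsets along the read, on both strands; every
    candidate is extended to a full-read ungapped Hamming comparison and
    the single best alignment (fewest mismatches) is reported.  Ties break
    deterministically: lowest contig index, then leftmost position, then
    forward strand.  Reads with no seed hit are unmapped.
    """

    def __init__(self, genome: GenomeIndex, k: int = 31, pad: int = 512):
        if not 1 <= k <= 32:
            raise ValueError("k must be in [1, 32] (2-bit packed in 64 bits)")
        self.genome = genome
        self.k = k
        parts, starts, ends = [], [], []
        at = pad
        for c in genome:
            arr = encode_seq(c.sequence)
            parts.append(np.full(pad, SENTINEL))
            parts.append(arr)
            starts.append(at)
            ends.append(at + len(arr))
            at += pad + len(arr)
        parts.append(np.full(pad, SENTINEL))
        self.gcat = np.concatenate(parts)
        self.starts = np.array(starts, dtype=np.int64)
        self.ends = np.array(ends, dtype=np.int64)

        g = self.gcat
        n = len(g)
        bad = (g >= 4).astype(np.int64)
        cb = np.concatenate([[0], np.cumsum(bad)])
        valid = (cb[k:] - cb[: n - k + 1]) == 0
        gs = np.where(g >= 4, 0, g).astype(np.uint64)
        codes = np.zeros(n - k + 1, dtype=np.uint64)
        for j in range(k):
            codes = (codes << np.uint64(2)) | gs[j : j + n - k + 1]
        vpos = np.nonzero(valid)[0]
        order = np.argsort(codes[vpos], kind="stable")
        self.sorted_codes = codes[vpos][order]
        self.sorted_pos = vpos[order]

    def _candidates(self, mat: np.ndarray, offsets: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
        ridx_all, astart_all = [], []
        n = mat.shape[0]
        for o in offsets:
            qc = _pack_codes(mat, o, self.k)
            lo = np.searchsorted(self.sorted_codes, qc, side="left")
            hi = np.searchsorted(self.sorted_codes, qc, side="right")
            cnt = hi - lo
            flat = _ranges_flatten(lo, cnt)
            ridx_all.append(np.repeat(np.arange(n, dtype=np.int64), cnt))
            astart_all.append(self.sorted_pos[flat] - o)
        return np.concatenate(ridx_all), np.concatenate(astart_all)

    def map(self, seqs: np.ndarray, chunk: int = 200_000) -> MapResult:
        seqs = np.ascontiguousarray(seqs, dtype=np.int8)
        n, L = seqs.shape
        if self.k > L:
            raise ValueError("seed length k exceeds read length")
        offsets = sorted({0, (L - self.k) // 2, L - self.k})
        rc = np.ascontiguousarray(3 - seqs[:, ::-1])

        best_key = None
        all_r = []
        all_mm = []
        all_cidx = []
        all_pos = []
        all_strand = []
        col = np.arange(L, dtype=np.int64)
        for strand, mat in ((0, seqs), (1, rc)):
            ridx, astart = self._candidates(mat, offsets)
            if ridx.size == 0:
                continue
            # dedupe identical (read, locus) pairs found by multiple seeds
            key = ridx * (2 * len(self.gcat)) + astart
            _, uniq = np.unique(key, return_index=True)
            ridx, astart = ridx[uniq], astart[uniq]
            # keep only alignments fully inside one contig
            cidx = np.searchsorted(self.starts, astart, side="right") - 1
            ok = (cidx >= 0) & (astart >= self.starts[np.clip(cidx, 0, None)])
            ok &= astart + L <= self.ends[np.clip(cidx, 0, None)]
            ridx, astart, cidx = ridx[ok], astart[ok], cidx[ok]
            mm = np.empty(len(ridx), dtype=np.int32)
            for s in range(0, len(ridx), chunk):
                sl = slice(s, min(s + chunk, len(ridx)))
                gm = self.gcat[astart[sl, None] + col]
                mm[sl] = (gm != mat[ridx[sl]]).sum(axis=1)
            all_r.append(ridx)
            all_mm.append(mm)
            all_cidx.append(cidx)
            all_pos.append(astart - self.starts[cidx])
            all_strand.append(np.full(len(ridx), strand, dtype=np.int8))

        contig_idx = np.full(n, -1, dtype=np.int64)
        pos = np.zeros(n, dtype=np.int64)
        strand_out = np.zeros(n, dtype=np.int8)
        n_mismatch = np.zeros(n, dtype=np.int32)
        if all_r:
            r = np.concatenate(all_r)
            mm = np.concatenate(all_mm)
            cidx = np.concatenate(all_cidx)
            p = np.concatenate(all_pos)
            st = np.concatenate(all_strand)
            order = np.lexsort((st, p, cidx, mm, r))
            r_sorted = r[order]
            first = np.ones(len(order), dtype=bool)
            first[1:] = r_sorted[1:] != r_sorted[:-1]
            pick = order[first]
            contig_idx[r[pick]] = cidx[pick]
            pos[r[pick]] = p[pick]
            strand_out[r[pick]] = st[pick]
            n_mismatch[r[pick]] = mm[pick]
        return MapResult(contig_idx, pos, strand_out, n_mismatch, L)


def map_reads(
    reads: ReadSet | np.ndarray, assembly: GenomeIndex, k: int = 31
) -> MapResult:
    """Map a read set against an assembly with :class:`BestHitMapper`."""
    seqs = reads.seqs if isinstance(reads, ReadSet) else reads
    return BestHitMapper(assembly, k=k).map(seqs)


# ---------------------------------------------------------------------------
# file output


def write_fastq(reads: ReadSet, path: str | Path) -> None:
    qual = "I" * reads.read_length
    names = reads.names()
    with open(path, "w") as fh:
        for i in range(reads.n_reads):
            fh.write(f"@{names[i]}\n{decode_seq(reads.seqs[i])}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> ReadSet:
    """Load single-end reads from FASTQ (all reads must share one length)."""
    names, rows = [], []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            names.append(h[1:].strip())
            rows.append(encode_seq(seq))
    if not rows:
        raise ValueError(f"no reads in {path}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("reads of mixed length are not supported")
    n = len(rows)
    return ReadSet(
        sample_id=str(path),
        seqs=np.vstack(rows),
        source=np.zeros(n, dtype=np.int32),
        pos=np.zeros(n, dtype=np.int64),
        strand=np.zeros(n, dtype=np.int8),
        templates=["unknown"],
        target_contig=["unknown"],
    )


def write_sam(
    result: MapResult, reads: ReadSet, genome: GenomeIndex, path: str | Path
) -> None:
    """Emit the mapper's primary alignments as a valid SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.id, "LN": c.length} for c in genome],
        "PG": [{"ID": "grcfind-sim", "PN": "grcfind-sim"}],
    }
    names = reads.names()
    L = result.read_length
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(reads.n_reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = names[i]
            fwd = decode_seq(reads.seqs[i])
            if result.contig_idx[i] < 0:
                a.is_unmapped = True
                a.query_sequence = fwd
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
            else:
                rev = bool(result.strand[i])
                a.is_reverse = rev
                a.reference_id = int(result.contig_idx[i])
                a.reference_start = int(result.pos[i])
                a.mapping_quality = 42
                a.cigarstring = f"{L}M"
                # SAM stores the read in reference orientation
                a.query_sequence = decode_seq(3 - reads.seqs[i][::-1]) if rev else fwd
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                a.set_tag("NM", int(result.n_mismatch[i]))
            out.write(a)


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    rows = [
        {
            "contig_id": cid,
            "category": t.category,
            "germline_copies": t.germline_copies,
            "soma_copies": t.soma_copies,
            "source_paralog": t.source_a_paralog or ".",
        }
        for cid, t in truth.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_manifest(cfg: SimulationConfig, paths: dict[str, str], out: str | Path) -> None:
    with open(out, "w") as fh:
        json.dump({"config": asdict(cfg), "outputs": paths}, fh, indent=2, default=list)
        fh.write("\n")
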