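"""Calling high-confidence germline-restricted contigs and sizing the GRC.

A contig is a high-confidence GRC (hcGRC) contig when its germline/soma
FPKM fold change, differential q-value and length all clear the thresholds
(defaults: fold ≥ 2, q < 0.05, length > 2,000 bp).  Called contigs are then
assigned one of three sequence categories:

1. ``high_copy`` — multicopy GRC sequence, detected through a large germline
   FPKM numerator (the assembly contig is collapsed, so its germline depth
   implies copy number ≥ 2 against the single-copy baseline);
2. ``low_copy_divergent`` — low/single-copy GRC sequence divergent from all
   A-chromosome paralogs, detected through a near-zero somatic denominator;
3. ``low_copy_similar`` — low-copy GRC nearly identical to an A paralog;
   a haploid GRC allele plus two A alleles predicts only a 3:2 (1.5-fold)
   germline:soma ratio, below the 2-fold cutoff, so these contigs are
   flagged from a sub-2-fold band of significant fold changes rather than
   called hcGRC.

Total GRC length is estimated by inflating each hcGRC contig's length by
its germline copy number (depth / single-copy baseline depth), compensating
for assembly collapse of multicopy sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_counting import DepthSummary
from .reference_io import GenomeIndex

__all__ = [
    "ThresholdSet",
    "GrcCall",
    "SizeEstimate",
    "classify_hcgrc",
    "baseline_depth",
    "estimate_copy_number",
    "estimate_total_grc_length",
    "categorize",
    "call_grc",
]

CATEGORIES = ("high_copy", "low_copy_divergent", "low_copy_similar", "not_grc", "ambiguous")


@dataclass(frozen=True)
class ThresholdSet:
    """hcGRC decision thresholds.

    ``min_fold`` is inclusive (≥), ``max_q`` strict (<), ``min_length_bp``
    strict (>).
    """

    min_fold: float = 2.0
    max_q: float = 0.05
    min_length_bp: int = 2000

    def __post_init__(self) -> None:
        if self.min_fold <= 0:
            raise ValueError("min_fold must be > 0")
        if not (0 < self.max_q <= 1):
            raise ValueError("max_q must be in (0, 1]")
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")


@dataclass(frozen=True)
class GrcCall:
    contig_id: str
    is_hcgrc: bool
    category: str
    est_copy_number: float


@dataclass
class SizeEstimate:
    """Copy-number-adjusted total GRC length."""

    baseline_depth: float
    total_adjusted_bp: float
    per_contig_adjusted_bp: dict[str, float]


def _is_tested(rec) -> bool:
    q = getattr(rec, "q_value", None)
    tested = getattr(rec, "tested", True)
    return bool(tested) and q is not None and not np.isnan(q)


def classify_hcgrc(rec, thresholds: ThresholdSet = ThresholdSet()) -> bool:
    """True iff fold ≥ min_fold AND q < max_q AND length > min_length_bp.

    ``rec`` is any object with ``fold_change``, ``q_value`` and ``length_bp``
    attributes (a differential-table row).  Untested records (no q-value)
    are a hard error: filter them out first.
    """
    if not _is_tested(rec):
        raise ValueError(
            f"contig {rec.contig_id!r} was not tested (no q-value); "
            "filter untested records before classification"
        )
    return (
        rec.fold_change >= thresholds.min_fold
        and rec.q_value < thresholds.max_q
        and rec.length_bp > thresholds.min_length_bp
    )


def baseline_depth(
    depths: Sequence[DepthSummary], genome: GenomeIndex, ploidy: int = 2
) -> float:
    """Per-haploid-copy (single-copy) germline sequencing depth.

    The length-weighted median of per-contig mean depth, averaged across
    germline replicates, estimates the depth of a typical contig.  The
    genome is dominated by diploid A-chromosome contigs, so the weighted
    median is robust to the minority of collapsed high-copy contigs and
    sits at the diploid-A coverage; dividing by ``ploidy`` (default 2)
    converts it to the depth contributed by a single genomic copy, the
    denominator of all copy-number estimates.
    """
    if not depths:
        raise ValueError("need at least one germline depth summary")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    lengths = np.array([c.length for c in genome], dtype=float)
    per_rep = []
    for ds in depths:
        d = np.array([ds.depth.get(c.id, 0.0) for c in genome])
        per_rep.append(_weighted_median(d, lengths))
    base = float(np.mean(per_rep)) / ploidy
    if base <= 0:
        raise ValueError("all-zero germline depths: cannot estimate baseline")
    return base


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def estimate_copy_number(depth: float, baseline: float) -> float:
    """Germline copies per haploid baseline: depth / baseline (unrounded)."""
    if baseline <= 0:
        raise ValueError("baseline depth must be > 0")
    return depth / baseline


def estimate_total_grc_length(
    hcgrc_ids: Sequence[str],
    copy_numbers: Mapping[str, float],
    lengths: Mapping[str, int],
) -> SizeEstimate:
    """Sum of length × max(1, copy number) over hcGRC contigs.

    The floor of 1 ensures a detected contig contributes at least its own
    assembled length even when its depth-based copy estimate dips below one.
    """
    if len(hcgrc_ids) == 0:
        raise ValueError("hcGRC set is empty")
    per_contig = {
        c: lengths[c] * max(1.0, float(copy_numbers[c])) for c in hcgrc_ids
    }
    return SizeEstimate(
        baseline_depth=float("nan"),
        total_adjusted_bp=float(sum(per_contig.values())),
        per_contig_adjusted_bp=per_contig,
    )


def categorize(
    rec,
    est_copy_number: float,
    thresholds: ThresholdSet = ThresholdSet(),
    similar_band: tuple[float, float] = (1.2, 2.0),
    soma_fpkm_floor: float = 1.0,
) -> str:
    """Assign a sequence category to a tested differential record.

    hcGRC contigs split into ``high_copy`` (copy number ≥ 2) and
    ``low_copy_divergent`` (copy < 2 with a near-zero somatic FPKM
    denominator); an hcGRC contig matching neither signature is
    ``ambiguous``.  Non-hcGRC contigs with a significant fold change inside
    ``similar_band`` (default [1.2, 2.0), bracketing the 3:2 = 1.5
    single-GRC-allele expectation) are ``low_copy_similar``; the rest are
    ``not_grc``.
    """
    if not _is_tested(rec):
        raise ValueError("cannot categorize an untested record")
    if classify_hcgrc(rec, thresholds):
        if est_copy_number >= 2.0:
            return "high_copy"
        if rec.mean_fpkm_soma < soma_fpkm_floor:
            return "low_copy_divergent"
        return "ambiguous"
    lo, hi = similar_band
    if lo <= rec.fold_change < hi and rec.q_value < thresholds.max_q:
        return "low_copy_similar"
    return "not_grc"


def call_grc(
    diff: pd.DataFrame,
    germline_depths: Sequence[DepthSummary],
    genome: GenomeIndex,
    thresholds: ThresholdSet = ThresholdSet(),
    similar_band: tuple[float, float] = (1.2, 2.0),
    soma_fpkm_floor: float = 1.0,
) -> tuple[pd.DataFrame, SizeEstimate]:
    """Full calling pass over a differential table.

    Returns the calls table (contig_id, is_hcgrc, category, est_copy_number,
    adjusted_bp) in assembly order and the copy-number-adjusted GRC size
    estimate over the hcGRC set.
    """
    base = baseline_depth(germline_depths, genome)
    mean_depth = {
        c.id: float(np.mean([ds.depth.get(c.id, 0.0) for ds in germline_depths]))
        for c in genome
    }
    rows = []
    for rec in diff.itertuples(index=False):
        cn = estimate_copy_number(mean_depth[rec.contig_id], base)
        if _is_tested(rec):
            is_hc = classify_hcgrc(rec, thresholds)
            cat = categorize(rec, cn, thresholds, similar_band, soma_fpkm_floor)
        else:
            is_hc, cat = False, "not_grc"
        rows.append(
            {
                "contig_id": rec.contig_id,
                "is_hcgrc": is_hc,
                "category": cat,
                "est_copy_number": cn,
                "adjusted_bp": rec.length_bp * max(1.0, cn) if is_hc else 0.0,
            }
        )
    calls = pd.DataFrame(rows)
    hc_ids = calls.loc[calls["is_hcgrc"], "contig_id"].tolist()
    if hc_ids:
        size = estimate_total_grc_length(
            hc_ids, dict(zip(calls["contig_id"], calls["est_copy_number"])), genome.lengths
        )
        size.baseline_depth = base
    else:
        size = SizeEstimate(baseline_depth=base, total_adjusted_bp=0.0, per_contig_adjusted_bp={})
    return calls, size
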