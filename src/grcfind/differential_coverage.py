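"""Per-contig FPKM and the germline-vs-soma differential test.

The method treats each assembly contig as a transcript and quantifies DNA
read coverage as FPKM (fragments per kilobase per million mapped fragments),
which normalises simultaneously for contig length and sequencing library
depth.  For every contig the germline/soma fold change of mean FPKM is the
effect size, and a two-group F-test on log2(FPKM + 1) with Benjamini–
Hochberg FDR correction supplies the q-value — the two axes of the volcano
plot used to call germline-restricted contigs.

The fold change is reported on the linear FPKM scale (with a small
pseudocount) so that copy-ratio expectations stay interpretable: a haploid
germline-restricted allele next to a diploid A-chromosome paralog predicts
a 3:2 coverage ratio, i.e. a fold change of exactly 1.5 in linear space.
The hypothesis test runs in log space, where replicate noise is closer to
homoscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .alignment_counting import SampleCounts
from .reference_io import GenomeIndex

__all__ = [
    "FPKMTable",
    "DifferentialRecord",
    "fpkm",
    "build_fpkm_table",
    "fold_change",
    "group_f_test",
    "group_f_test_matrix",
    "bh_fdr",
    "run_differential",
]

DEFAULT_EPSILON = 0.01  # FPKM pseudocount guarding zero-soma denominators


@dataclass
class FPKMTable:
    """Contig × sample FPKM matrix with its design.

    ``values``: DataFrame indexed by contig_id, one column per sample_id.
    ``lengths``: contig_id → bp.  ``design``: sample_id → group.
    """

    values: pd.DataFrame
    lengths: dict[str, int]
    design: dict[str, str]


@dataclass(frozen=True)
class DifferentialRecord:
    """One volcano-plot row."""

    contig_id: str
    length_bp: int
    mean_fpkm_germline: float
    mean_fpkm_soma: float
    fold_change: float
    log2_fc: float
    f_stat: float
    p_value: float
    q_value: float
    tested: bool = True


def fpkm(count: int, length_bp: int, total_mapped: int) -> float:
    """FPKM = count × 10⁹ / (length_bp × total_mapped)."""
    if total_mapped < 1:
        raise ValueError("empty library: total_mapped must be >= 1")
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    return count * 1e9 / (length_bp * total_mapped)


def build_fpkm_table(samples: Sequence[SampleCounts], genome: GenomeIndex) -> FPKMTable:
    """Assemble the contig × sample FPKM matrix from per-sample counts."""
    if not samples:
        raise ValueError("no samples provided")
    lengths = genome.lengths
    ids = genome.ids
    length_arr = np.array([lengths[c] for c in ids], dtype=np.float64)
    cols = {}
    design = {}
    for sc in samples:
        if sc.total_mapped < 1:
            raise ValueError(f"empty library: sample {sc.sample_id!r} has no mapped fragments")
        counts = np.array([sc.counts.get(c, 0) for c in ids], dtype=np.float64)
        cols[sc.sample_id] = counts * 1e9 / (length_arr * sc.total_mapped)
        design[sc.sample_id] = sc.group
    values = pd.DataFrame(cols, index=pd.Index(ids, name="contig_id"))
    return FPKMTable(values=values, lengths=lengths, design=design)


def fold_change(
    fpkm_germline: Iterable[float],
    fpkm_soma: Iterable[float],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[float, float]:
    """Linear germline/soma ratio of mean FPKM with pseudocount.

    Returns ``(fold_change, log2_fc)`` where
    ``fold_change = (mean_germline + eps) / (mean_soma + eps)``.
    """
    g = np.asarray(list(fpkm_germline), dtype=float)
    s = np.asarray(list(fpkm_soma), dtype=float)
    if g.size == 0 or s.size == 0:
        raise ValueError("need at least one value per group")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    fc = (g.mean() + epsilon) / (s.mean() + epsilon)
    return float(fc), float(np.log2(fc))


def group_f_test(
    values: Sequence[float], groups: Sequence[str], tol: float = 1e-12
) -> tuple[float, float]:
    """Two-group one-way F-test for a single contig.

    ``values`` are the per-sample transformed coverages (log2(FPKM+1));
    ``groups`` the matching group labels.  Equivalent to the square of the
    pooled-variance two-sample t statistic, with df1 = 1 and df2 = n − 2.
    Degenerate inputs (total sum of squares below ``tol``) return (0, 1).
    """
    v = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    mask = labels == uniq[0]
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("insufficient replicates: need >=2 per group")
    f, p = group_f_test_matrix(v[None, :], mask, tol=tol)
    return float(f[0]), float(p[0])


def group_f_test_matrix(
    values: np.ndarray, group1_mask: np.ndarray, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group F-test over rows of a contig × sample matrix."""
    v = np.asarray(values, dtype=float)
    mask = np.asarray(group1_mask, dtype=bool)
    n1 = int(mask.sum())
    n2 = int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("insufficient replicates: need >=2 per group")
    n = n1 + n2
    m1 = v[:, mask].mean(axis=1)
    m2 = v[:, ~mask].mean(axis=1)
    grand = v.mean(axis=1)
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = ((v[:, mask] - m1[:, None]) ** 2).sum(axis=1) + (
        (v[:, ~mask] - m2[:, None]) ** 2
    ).sum(axis=1)
    sst = ssb + ssw
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / (n - 2))
    p = stats.f.sf(f, 1, n - 2)
    # perfectly flat rows carry no evidence; perfectly separated rows (ssw=0) give F=inf, p=0
    degenerate = sst < tol
    f = np.where(degenerate, 0.0, f)
    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isinf(f), 0.0, p)
    return f, p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def run_differential(
    samples: Sequence[SampleCounts],
    genome: GenomeIndex,
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Full differential-coverage computation: FPKM → fold change → F-test → BH.

    Returns one row per contig (assembly order) with columns
    ``contig_id, length_bp, fpkm_<sample>…, mean_fpkm_germline,
    mean_fpkm_soma, fold_change, log2_fc, f_stat, p_value, q_value, tested,
    no_signal``.

    Contigs with zero counts in every sample are flagged ``no_signal``: their
    fold change is 1 (epsilon/epsilon) and they are excluded from the test
    family.  All tested contigs form a single BH family.
    """
    table = build_fpkm_table(samples, genome)
    groups = np.array([table.design[s] for s in table.values.columns])
    g_mask = groups == "germline"
    s_mask = groups == "soma"
    if g_mask.sum() < 1 or s_mask.sum() < 1:
        raise ValueError("need at least one germline and one soma sample")
    testable = g_mask.sum() >= 2 and s_mask.sum() >= 2

    v = table.values.to_numpy()
    mean_g = v[:, g_mask].mean(axis=1)
    mean_s = v[:, s_mask].mean(axis=1)
    fc = (mean_g + epsilon) / (mean_s + epsilon)
    no_signal = v.sum(axis=1) == 0

    n_contigs = v.shape[0]
    f_stat = np.full(n_contigs, np.nan)
    p_value = np.full(n_contigs, np.nan)
    q_value = np.full(n_contigs, np.nan)
    tested = np.zeros(n_contigs, dtype=bool)
    if testable:
        log_v = np.log2(v + 1.0)
        f_all, p_all = group_f_test_matrix(log_v, g_mask)
        tested = ~no_signal
        f_stat[tested] = f_all[tested]
        p_value[tested] = p_all[tested]
        if tested.any():
            q_value[tested] = bh_fdr(p_value[tested])

    df = pd.DataFrame(
        {
            "contig_id": table.values.index,
            "length_bp": [table.lengths[c] for c in table.values.index],
        }
    )
    for s in table.values.columns:
        df[f"fpkm_{s}"] = table.values[s].to_numpy()
    df["mean_fpkm_germline"] = mean_g
    df["mean_fpkm_soma"] = mean_s
    df["fold_change"] = fc
    df["log2_fc"] = np.log2(fc)
    df["f_stat"] = f_stat
    df["p_value"] = p_value
    df["q_value"] = q_value
    df["tested"] = tested
    df["no_signal"] = no_signal
    return df.reset_index(drop=True)
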