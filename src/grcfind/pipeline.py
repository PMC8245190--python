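"""End-to-end orchestration: counts → FPKM differential → GRC calls.

Two entry points: :func:`run_from_counts` drives the analysis half of the
pipeline from per-sample fragment counts (however they were obtained), and
:func:`simulate_and_run` closes the full loop on a synthetic universe —
genome simulation, read simulation, best-hit mapping, counting, the
differential test and GRC calling — entirely in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment_counting import DepthSummary, SampleCounts, counts_from_arrays, mean_depth
from .differential_coverage import DEFAULT_EPSILON, run_differential
from .grc_analysis import SizeEstimate, ThresholdSet, call_grc
from .reference_io import GenomeIndex
from .synthetic_data import (
    BestHitMapper,
    SimulationConfig,
    SyntheticTruth,
    simulate_genomes,
    simulate_reads,
)

__all__ = ["PipelineResult", "SimulationRun", "run_from_counts", "simulate_and_run"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    diff: pd.DataFrame
    calls: pd.DataFrame
    size: SizeEstimate
    samples: list[SampleCounts]
    germline_depths: list[DepthSummary]

    def summary(self, thresholds: ThresholdSet) -> dict:
        cat_counts = self.calls["category"].value_counts().to_dict()
        return {
            "n_contigs": int(len(self.diff)),
            "n_tested": int(self.diff["tested"].sum()),
            "n_hcgrc": int(self.calls["is_hcgrc"].sum()),
            "category_counts": {k: int(v) for k, v in sorted(cat_counts.items())},
            "baseline_depth": self.size.baseline_depth,
            "total_adjusted_bp": self.size.total_adjusted_bp,
            "thresholds": {
                "min_fold": thresholds.min_fold,
                "max_q": thresholds.max_q,
                "min_length_bp": thresholds.min_length_bp,
            },
            "samples": {
                sc.sample_id: {"group": sc.group, "total_mapped": sc.total_mapped}
                for sc in self.samples
            },
        }


@dataclass
class SimulationRun(PipelineResult):
    cfg: SimulationConfig = None
    assembly: GenomeIndex = None
    truth: SyntheticTruth = None
    n_unmapped: dict[str, int] = field(default_factory=dict)


def run_from_counts(
    samples: Sequence[SampleCounts],
    genome: GenomeIndex,
    epsilon: float = DEFAULT_EPSILON,
    thresholds: ThresholdSet = ThresholdSet(),
    similar_band: tuple[float, float] = (1.2, 2.0),
    soma_fpkm_floor: float = 1.0,
) -> PipelineResult:
    """Differential test plus GRC calling from per-sample counts."""
    n_g = sum(1 for s in samples if s.group == "germline")
    n_s = sum(1 for s in samples if s.group == "soma")
    if min(n_g, n_s) < 3:
        logger.warning(
            "only %d germline / %d soma replicates; at least 3 per group is "
            "recommended for a statistically robust comparison", n_g, n_s,
        )
    diff = run_differential(samples, genome, epsilon=epsilon)
    depths = [mean_depth(s, genome) for s in samples if s.group == "germline"]
    calls, size = call_grc(
        diff, depths, genome, thresholds,
        similar_band=similar_band, soma_fpkm_floor=soma_fpkm_floor,
    )
    return PipelineResult(diff, calls, size, list(samples), depths)


def sample_counts_from_simulation(
    cfg: SimulationConfig, k: int = 31
) -> tuple[GenomeIndex, SyntheticTruth, list[SampleCounts], dict[str, int]]:
    """Simulate genomes + reads and map/count every sample."""
    assembly, gplan, splan, truth = simulate_genomes(cfg)
    mapper = BestHitMapper(assembly, k=k)
    seed_rng = np.random.default_rng([cfg.seed, 0x5EED])
    samples: list[SampleCounts] = []
    n_unmapped: dict[str, int] = {}
    for group, plan, n_rep in (("germline", gplan, cfg.n_germline), ("soma", splan, cfg.n_soma)):
        for i in range(n_rep):
            sid = f"{group}_{i + 1}"
            s_seed = int(seed_rng.integers(0, 2**31 - 1))
            reads = simulate_reads(plan, cfg, s_seed, sample_id=sid)
            res = mapper.map(reads.seqs)
            mapped = res.mapped
            sc = counts_from_arrays(
                res.contig_idx[mapped],
                np.full(int(mapped.sum()), res.read_length, dtype=np.int64),
                assembly, sid, group, n_unmapped=res.n_unmapped,
            )
            samples.append(sc)
            n_unmapped[sid] = res.n_unmapped
    return assembly, truth, samples, n_unmapped


def simulate_and_run(
    cfg: SimulationConfig,
    epsilon: float = DEFAULT_EPSILON,
    thresholds: ThresholdSet = ThresholdSet(),
    k: int = 31,
    similar_band: tuple[float, float] = (1.2, 2.0),
    soma_fpkm_floor: float = 1.0,
) -> SimulationRun:
    """Full synthetic pipeline: simulate, map, count, test, call."""
    assembly, truth, samples, n_unmapped = sample_counts_from_simulation(cfg, k=k)
    res = run_from_counts(
        samples, assembly, epsilon=epsilon, thresholds=thresholds,
        similar_band=similar_band, soma_fpkm_floor=soma_fpkm_floor,
    )
    return SimulationRun(
        diff=res.diff, calls=res.calls, size=res.size, samples=res.samples,
        germline_depths=res.germline_depths, cfg=cfg, assembly=assembly,
        truth=truth, n_unmapped=n_unmapped,
    )
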