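import numpy as np
import pytest

from grcfind import SimulationConfig, simulate_and_run
from grcfind.reference_io import ContigRecord, GenomeIndex


@pytest.fixture
def tiny_genome() -> GenomeIndex:
    return GenomeIndex(
        [
            ContigRecord("c1", "ACGTACGTAC"),
            ContigRecord("c2", "TTTTGGGGCCCCAAAA"),
            ContigRecord("c3", "ACGT"),
        ]
    )


@pytest.fixture(scope="session")
def default_run():
    """One full synthetic pipeline run under the default study design."""
    return simulate_and_run(SimulationConfig(seed=7))


def write_sam_text(path, sq, records):
    """Write a SAM file from (qname, flag, rname, pos1, mapq, cigar, seq) tuples."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in sq:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for qname, flag, rname, pos1, mapq, cigar, seq in records:
            qual = "I" * len(seq) if seq != "*" else "*"
            fh.write(
                f"{qname}\t{flag}\t{rname}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
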