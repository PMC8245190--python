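import numpy as np
import pysam
import pytest

from grcfind.alignment_counting import count_sample, counts_from_arrays
from grcfind.reference_io import ContigRecord, GenomeIndex, write_fasta
from grcfind.synthetic_data import (
    BestHitMapper,
    SimulationConfig,
    decode_seq,
    encode_seq,
    map_reads,
    mutate,
    read_fastq,
    simulate_genomes,
    simulate_reads,
    write_fastq,
    write_sam,
)


def small_cfg(**kw):
    base = dict(
        n_a_contigs=20, a_length_range=(1200, 1800), n_cat1=0, n_cat2=0, n_cat3=0,
        read_length=100, depth_per_haploid_copy=15.0, error_rate=0.0,
        n_germline=1, n_soma=1, seed=11, max_grc_fraction=1.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"error_rate": 1.5},
            {"divergence_cat2": -0.1},
            {"read_length": 10},
            {"n_cat1": -1},
            {"a_length_range": (500, 100)},
        ],
    )
    def test_invalid_fields(self, kw):
        with pytest.raises(ValueError):
            small_cfg(**kw)

    def test_grc_fraction_cap(self):
        # 5 GRC templates on a 10-contig A complement is far above 10%
        with pytest.raises(ValueError, match="fraction"):
            small_cfg(n_a_contigs=10, n_cat1=5, max_grc_fraction=0.10)

    def test_grc_without_a_contigs(self):
        with pytest.raises(ValueError):
            small_cfg(n_a_contigs=0, n_cat1=2)


class TestSimulateGenomes:
    def test_no_grc_plans_differ_only_in_nothing(self):
        assembly, gplan, splan, truth = simulate_genomes(small_cfg(n_a_contigs=10))
        assert len(assembly) == 10
        assert [(s.name, s.copies) for s in gplan] == [(s.name, s.copies) for s in splan]
        assert truth.grc_contigs() == []

    def test_category_bookkeeping(self):
        cfg = small_cfg(n_a_contigs=10, n_cat1=5)
        assembly, gplan, splan, truth = simulate_genomes(cfg)
        assert len(assembly) == 15
        assert len(truth.of_category("high_copy")) == 5
        assert all(truth.entries[c].soma_copies == 0 for c in truth.of_category("high_copy"))
        assert all(
            truth.entries[c].germline_copies >= cfg.cat1_copy_range[0]
            for c in truth.of_category("high_copy")
        )

    def test_cat3_allele_is_not_an_assembly_contig(self):
        cfg = small_cfg(n_a_contigs=10, n_cat3=2)
        assembly, gplan, _, truth = simulate_genomes(cfg)
        assert len(assembly) == 10  # collapsed: only the A paralog is assembled
        cat3 = truth.of_category("low_copy_similar")
        assert len(cat3) == 2
        for cid in cat3:
            assert truth.entries[cid].germline_copies == 3
            assert truth.entries[cid].soma_copies == 2
        allele_specs = [s for s in gplan if s.name.endswith("_grc_allele")]
        assert {s.target_contig for s in allele_specs} == set(cat3)

    def test_determinism(self, tmp_path):
        cfg = small_cfg(n_a_contigs=8, n_cat1=1, n_cat2=1)
        a1, g1, _, _ = simulate_genomes(cfg)
        a2, g2, _, _ = simulate_genomes(cfg)
        p1, p2 = tmp_path / "a1.fa", tmp_path / "a2.fa"
        write_fasta(a1, p1)
        write_fasta(a2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert all(np.array_equal(x.seq, y.seq) for x, y in zip(g1, g2))


class TestMutate:
    def test_rate_zero_is_identity(self):
        assert mutate("ACGTACGT", 0.0, 1) == "ACGTACGT"

    def test_rate_one_changes_every_base(self):
        s = "ACGT" * 25
        m = mutate(s, 1.0, 1)
        assert sum(a != b for a, b in zip(s, m)) == len(s)

    def test_substitution_count_is_binomial(self, rng):
        s = rng.integers(0, 4, size=10_000, dtype=np.int8)
        m = mutate(s, 0.05, rng)
        dist = int((s != m).sum())
        sd = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(dist - 500) < 4 * sd
        assert len(m) == len(s)


class TestSimulateReads:
    def test_library_size_matches_genomic_mass(self):
        cfg = small_cfg()
        _, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 5)
        mass = sum(s.copies * len(s.seq) for s in gplan)
        assert reads.n_reads == round(mass * cfg.depth_per_haploid_copy / cfg.read_length)

    def test_read_allocation_proportional_to_copies(self):
        """A template at 2 copies receives ~twice the reads of a 1-copy template."""
        cfg = small_cfg(n_a_contigs=2, a_length_range=(5000, 5000), depth_per_haploid_copy=30.0)
        assembly, gplan, _, _ = simulate_genomes(cfg)
        from grcfind.synthetic_data import CopySpec

        plan = [
            CopySpec("t2", "A0000", gplan[0].seq, 2),
            CopySpec("t1", "A0001", gplan[1].seq, 1),
        ]
        reads = simulate_reads(plan, cfg, 5)
        n2 = int((reads.source == 0).sum())
        n1 = int((reads.source == 1).sum())
        # multinomial sampling: 4 sd bound on the count of the 2-copy template
        n, p = reads.n_reads, 2 / 3
        assert abs(n2 - n * p) < 4 * np.sqrt(n * p * (1 - p))
        assert n1 + n2 == n

    def test_error_free_reads_are_exact_template_substrings(self):
        cfg = small_cfg(error_rate=0.0)
        _, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 9)
        L = cfg.read_length
        for i in range(0, reads.n_reads, 97):
            tpl = gplan[reads.source[i]].seq
            window = tpl[reads.pos[i] : reads.pos[i] + L]
            if reads.strand[i]:
                window = 3 - window[::-1]
            assert np.array_equal(reads.seqs[i], window)

    def test_short_template_skipped_with_warning(self, caplog):
        from grcfind.synthetic_data import CopySpec

        cfg = small_cfg()
        plan = [
            CopySpec("long", "c", np.zeros(500, dtype=np.int8), 1),
            CopySpec("short", "c", np.zeros(50, dtype=np.int8), 1),
        ]
        with caplog.at_level("WARNING"):
            reads = simulate_reads(plan, cfg, 1)
        assert "short" in caplog.text
        assert set(reads.templates) == {"long"}

    def test_expected_coverage_law(self):
        """Observed mean depth of a unique contig ≈ copies × per-copy depth."""
        cfg = small_cfg(n_a_contigs=12, depth_per_haploid_copy=12.0)
        assembly, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 3)
        res = BestHitMapper(assembly).map(reads.seqs)
        L = cfg.read_length
        for idx, contig in enumerate(assembly):
            n_c = int((res.contig_idx == idx).sum())
            mu = 2 * cfg.depth_per_haploid_copy * contig.length / L  # expected reads
            depth = n_c * L / contig.length
            tol = 4 * np.sqrt(mu) * L / contig.length
            assert abs(depth - 2 * cfg.depth_per_haploid_copy) < tol


class TestCollapsedAlleleRatio:
    def test_germline_to_soma_read_ratio_is_three_halves_before_mapping(self):
        """Truth-labeled read counts alone give the 3:2 coverage expectation."""
        cfg = small_cfg(n_a_contigs=20, n_cat3=3, depth_per_haploid_copy=25.0, seed=3)
        assembly, gplan, splan, truth = simulate_genomes(cfg)
        g = simulate_reads(gplan, cfg, 21)
        s = simulate_reads(splan, cfg, 22)
        for cid in truth.of_category("low_copy_similar"):
            ng = sum(
                int((g.source == i).sum())
                for i, t in enumerate(g.target_contig) if t == cid
            )
            ns = sum(
                int((s.source == i).sum())
                for i, t in enumerate(s.target_contig) if t == cid
            )
            # raw count ratio; 4 sd delta-method tolerance from expected counts
            L = assembly[cid].length
            e_ng = 3 * L * cfg.depth_per_haploid_copy / cfg.read_length
            e_ns = 2 * L * cfg.depth_per_haploid_copy / cfg.read_length
            tol = 4 * 1.5 * np.sqrt(1 / e_ng + 1 / e_ns)
            assert ng / ns == pytest.approx(1.5, abs=tol)

    def test_high_copy_ratio_far_exceeds_two(self):
        cfg = small_cfg(n_a_contigs=20, n_cat1=2, depth_per_haploid_copy=20.0, seed=4)
        assembly, gplan, splan, truth = simulate_genomes(cfg)
        g = simulate_reads(gplan, cfg, 31)
        for cid in truth.of_category("high_copy"):
            i = [j for j, t in enumerate(g.target_contig) if t == cid]
            ng = int(np.isin(g.source, i).sum())
            expected = truth.entries[cid].germline_copies
            depth = ng * cfg.read_length / assembly[cid].length
            assert depth / cfg.depth_per_haploid_copy > 2.0
            assert depth == pytest.approx(expected * cfg.depth_per_haploid_copy, rel=0.2)


def brute_force_best_hit(read, genome_arrays):
    """Exhaustive all-positions, both-strands Hamming scan with the mapper's
    tie-break order: fewest mismatches, lowest contig, leftmost, forward."""
    L = len(read)
    rc = 3 - read[::-1]
    best = None
    for strand, r in ((0, read), (1, rc)):
        for cidx, arr in enumerate(genome_arrays):
            if len(arr) < L:
                continue
            from numpy.lib.stride_tricks import sliding_window_view

            mm = (sliding_window_view(arr, L) != r).sum(axis=1)
            pos = int(np.argmin(mm))
            key = (int(mm[pos]), cidx, pos, strand)
            if best is None or key < best:
                best = key
    return best


class TestBestHitMapper:
    def test_error_free_reads_map_to_their_true_locus(self):
        cfg = small_cfg(error_rate=0.0, seed=12)
        assembly, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 41)
        res = map_reads(reads, assembly)
        name_to_idx = {c.id: i for i, c in enumerate(assembly)}
        true_idx = np.array([name_to_idx[reads.target_contig[s]] for s in reads.source])
        assert res.n_unmapped == 0
        assert np.array_equal(res.contig_idx, true_idx)
        assert np.array_equal(res.pos, reads.pos)
        assert np.array_equal(res.strand, reads.strand)
        assert np.all(res.n_mismatch == 0)

    def test_collapsed_allele_reads_map_to_the_a_paralog(self):
        cfg = small_cfg(n_a_contigs=10, n_cat3=2, error_rate=0.0, seed=13)
        assembly, gplan, _, truth = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 42)
        res = map_reads(reads, assembly)
        allele_idx = [i for i, n in enumerate(reads.templates) if n.endswith("_grc_allele")]
        sel = np.isin(reads.source, allele_idx)
        ids = assembly.ids
        mapped_to = {ids[c] for c in res.contig_idx[sel]}
        assert mapped_to == set(truth.of_category("low_copy_similar"))

    def test_agrees_with_exhaustive_hamming_scan(self, rng):
        """1,000 error-free reads: placements equal the brute-force oracle."""
        arrays = [rng.integers(0, 4, size=300, dtype=np.int8) for _ in range(5)]
        genome = GenomeIndex(
            [ContigRecord(f"c{i}", decode_seq(a)) for i, a in enumerate(arrays)]
        )
        L, n = 50, 1000
        cidx = rng.integers(0, 5, size=n)
        pos = rng.integers(0, 300 - L + 1, size=n)
        strand = rng.integers(0, 2, size=n)
        reads = np.empty((n, L), dtype=np.int8)
        for i in range(n):
            w = arrays[cidx[i]][pos[i] : pos[i] + L]
            reads[i] = (3 - w[::-1]) if strand[i] else w
        res = BestHitMapper(genome, k=31).map(reads)
        for i in range(n):
            expect = brute_force_best_hit(reads[i], arrays)
            got = (int(res.n_mismatch[i]), int(res.contig_idx[i]), int(res.pos[i]), int(res.strand[i]))
            assert got == expect

    def test_duplicate_contig_tie_breaks_to_lower_index(self, rng):
        seq = decode_seq(rng.integers(0, 4, size=200, dtype=np.int8))
        genome = GenomeIndex([ContigRecord("dupA", seq), ContigRecord("dupB", seq)])
        read = encode_seq(seq[40:90])[None, :]
        res = BestHitMapper(genome).map(read)
        assert (int(res.contig_idx[0]), int(res.pos[0]), int(res.strand[0])) == (0, 40, 0)

    def test_palindromic_read_tie_breaks_to_forward_strand(self, rng):
        half = rng.integers(0, 4, size=20, dtype=np.int8)
        pal = np.concatenate([half, 3 - half[::-1]])  # equals its own reverse complement
        flank = rng.integers(0, 4, size=100, dtype=np.int8)
        contig = np.concatenate([flank, pal, flank])
        genome = GenomeIndex([ContigRecord("c", decode_seq(contig))])
        res = BestHitMapper(genome, k=31).map(pal[None, :])
        assert (int(res.contig_idx[0]), int(res.pos[0]), int(res.strand[0])) == (0, 100, 0)

    def test_foreign_read_with_no_seed_hit_is_unmapped(self, rng):
        genome = GenomeIndex(
            [ContigRecord("c", decode_seq(rng.integers(0, 4, size=500, dtype=np.int8)))]
        )
        foreign = rng.integers(0, 4, size=(1, 100), dtype=np.int8)
        res = BestHitMapper(genome).map(foreign)
        assert res.n_unmapped == 1

    def test_k_larger_than_read_length_is_error(self):
        genome = GenomeIndex([ContigRecord("c", "ACGT" * 50)])
        with pytest.raises(ValueError):
            BestHitMapper(genome, k=31).map(np.zeros((1, 20), dtype=np.int8))


class TestFileOutput:
    def test_sam_round_trip_matches_in_memory_counts(self, tmp_path):
        cfg = small_cfg(n_a_contigs=6, depth_per_haploid_copy=3.0, error_rate=0.002, seed=6)
        assembly, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 61, sample_id="g1")
        res = BestHitMapper(assembly).map(reads.seqs)
        sam = tmp_path / "g1.sam"
        write_sam(res, reads, assembly, sam)

        from_file = count_sample(sam, assembly, "g1", "germline")
        mapped = res.mapped
        in_mem = counts_from_arrays(
            res.contig_idx[mapped],
            np.full(int(mapped.sum()), res.read_length, dtype=np.int64),
            assembly, "g1", "germline",
        )
        assert from_file.counts == in_mem.counts
        assert from_file.aligned_bases == in_mem.aligned_bases
        assert from_file.n_unmapped == res.n_unmapped

    def test_sam_sequences_are_reference_oriented(self, tmp_path):
        cfg = small_cfg(n_a_contigs=3, depth_per_haploid_copy=2.0, error_rate=0.0, seed=8)
        assembly, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 71)
        res = BestHitMapper(assembly).map(reads.seqs)
        sam = tmp_path / "x.sam"
        write_sam(res, reads, assembly, sam)
        with pysam.AlignmentFile(str(sam)) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                ref = assembly[rec.reference_name].sequence
                assert rec.query_sequence == ref[rec.reference_start : rec.reference_start + res.read_length]

    def test_fastq_round_trip(self, tmp_path):
        cfg = small_cfg(n_a_contigs=3, depth_per_haploid_copy=1.0, seed=9)
        _, gplan, _, _ = simulate_genomes(cfg)
        reads = simulate_reads(gplan, cfg, 81)
        p = tmp_path / "r.fastq"
        write_fastq(reads, p)
        back = read_fastq(p)
        assert np.array_equal(back.seqs, reads.seqs)
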