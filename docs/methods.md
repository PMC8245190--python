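# Methods

## Model and procedure

`grcfind` detects lineage-variable sequence — above all germline-restricted
chromosome (GRC) content — by comparing replicated germline and somatic DNA
read coverage on a germline assembly. The statistical unit is the assembly
contig: every contig is annotated as one full-length transcript, fragment
counts per contig are normalised to FPKM (fragments per kilobase per
million mapped fragments), and each contig's germline/soma contrast is
summarised by a linear fold change of mean FPKM and a two-group F-test on
`log2(FPKM + 1)` with Benjamini–Hochberg FDR control across all tested
contigs.

The method's assumptions, in order of importance:

1. **Single-end, best-hit mapping.** Each read contributes exactly one
   primary alignment; fragments equal reads. Counting ignores secondary
   and supplementary records and rejects paired-end flags outright.
2. **Coverage tracks copy number.** A diploid A-chromosome contig draws
   reads from two copies in both tissues; a germline-restricted contig
   draws germline reads only, in proportion to its (possibly collapsed)
   germline copy number.
3. **Mismapping is driven by paralogy.** Somatic reads land on
   GRC-derived contigs only insofar as a near-identical A-chromosome
   paralog exists; taking a germline/soma ratio per contig cancels both
   this mismapping and copy-number variation.
4. **Replication carries the inference.** The test is an ordinary
   two-group one-way F-test (identical to the squared pooled t statistic,
   df 1 and n − 2); at least two replicates per group are required and at
   least three are recommended — below that the pipeline warns and, with
   fewer than two, skips testing and flags records untested.

Calling: a contig is high-confidence GRC (hcGRC) when fold change ≥ 2
(inclusive), q < 0.05 (strict) and length > 2,000 bp (strict). The fold
bound is inclusive so a contig sitting exactly on the volcano plot's
vertical line is kept; the other two bounds are strict as stated.

## Sequence categories

* **high_copy** — hcGRC with estimated germline copy number ≥ 2. Detection
  is driven by the numerator (large germline FPKM on a collapsed contig).
* **low_copy_divergent** — hcGRC with copy number < 2 and mean somatic
  FPKM below a near-zero floor (default 1 FPKM). Detection is driven by
  the denominator: somatic reads cannot map onto the diverged sequence.
* **low_copy_similar** — *not* hcGRC. One haploid GRC allele next to two
  A alleles yields an expected 3:2 = 1.5-fold ratio, below the 2-fold
  cutoff; these contigs are flagged when their fold change falls in a
  configurable band (default [1.2, 2.0)) with q below the same q cutoff.
  The band's lower edge sits below 1.5 to admit sampling noise and the
  library-size shrinkage described below; its upper edge is the hcGRC
  cutoff.
* **ambiguous** — an hcGRC contig matching neither the high-copy nor the
  divergent signature (low copy, substantial somatic FPKM).
* **not_grc** — everything else.

## Copy number and GRC size

The per-haploid-copy baseline depth is the length-weighted median of
per-contig mean germline depth (aligned bases / contig length), averaged
over germline replicates, divided by the A-complement ploidy (default 2).
The weighted median is dominated by diploid A contigs and robust to the
minority of collapsed high-copy contigs; the ploidy division converts the
diploid-A coverage it measures into the coverage contributed by a single
genomic copy, so a diploid A contig estimates ≈ 2 copies and an 8-fold
collapsed contig ≈ 8. Per-contig copy number is raw germline depth over
baseline, unrounded. Total GRC size sums `length × max(1, copies)` over
hcGRC contigs: the floor of 1 ensures a detected low-copy contig
contributes at least its assembled length. This size estimate compensates
for assembly collapse but remains a lower bound on true GRC content,
because the low-copy-similar category is (by construction) invisible to a
2-fold threshold.

## Tunable parameters

| parameter | default | unit | role |
|---|---|---|---|
| `min_fold` | 2.0 | linear FPKM ratio | hcGRC fold cutoff (inclusive) |
| `max_q` | 0.05 | probability | hcGRC q cutoff (strict) |
| `min_length_bp` | 2000 | bp | hcGRC length cutoff (strict) |
| `epsilon` | 0.01 | FPKM | pseudocount guarding zero-soma denominators |
| `similar_band` | [1.2, 2.0) | ratio | low-copy-similar fold band |
| `soma_fpkm_floor` | 1.0 | FPKM | "near-zero denominator" bound for category 2 |
| `min_mapq` | 0 | MAPQ | counting filter (0 = none, matching a best-hit aligner at default settings) |
| `ploidy` | 2 | copies | A-complement ploidy used in the baseline |
| mapper `k` | 31 | bp | exact seed length of the internal mapper |

## The synthetic generator

The generator emulates exactly the structure the method reasons about: a
diploid A complement of i.i.d. uniform-ACGT contigs present in both
tissues, plus GRC sequence in the three categories — high-copy contigs
(diverged from an A paralog at 5% by default, present once in the assembly
but at 4–8 germline copies, explicitly modelling collapse), low-copy
divergent contigs (one germline copy, 5% divergence), and low-copy-similar
extra alleles (one germline copy, 0–0.5% divergence, **not** assembled
separately — their reads collapse onto the A paralog, which is what
produces the 3:2 ratio mechanically rather than by assertion).

Reads are single-end and fixed-length. The library size is total genomic
mass / read length; reads are assigned to genome copies multinomially in
proportion to copy number × length, placed uniformly, reverse-complemented
with probability 1/2, and given independent per-base substitution errors
(default 0.2%). Multinomial assignment makes per-contig counts fluctuate
like real library sampling (approximately Poisson), which is what gives
the replicate-level variance the F-test consumes.

Divergence is substitution-only (no indels) so the internal mapper can
score alignments by Hamming distance; the mapper finds candidate loci by
exact 31-mer lookups at three offsets per read on both strands, extends
each to a full-read ungapped comparison, and reports the single best
alignment with deterministic tie-breaking (fewest mismatches, then lowest
contig index, then leftmost position, then forward strand). With 0.2%
error and 100 bp reads, the chance that all three seed windows contain an
error is ≈ 10⁻⁴, so mapping losses are negligible and uniform.

**What the generator does not model:** indels and structural variation,
GC/composition bias, position-dependent error profiles and quality scores,
paired-end libraries, repeat families shared among A contigs, and
contamination. Passing tests therefore demonstrate that the statistical
machinery recovers truth when the coverage model holds — not that any
particular real dataset satisfies that model.

### Default study conditions

The default `SimulationConfig` is a replicated design of 4 germline + 4
somatic libraries at 20× depth per haploid copy on 130 A contigs of
2.5–4 kb, with 5 high-copy (4–8 copies), 4 divergent and 4 collapsed-allele
GRC sequences — GRC-derived contigs just under 10% of assembled length.
Contig lengths sit safely above the 2 kb calling threshold because a
contig exactly on the length boundary is a degenerate case of the
threshold, not of the coverage model. A config whose GRC-derived length
exceeds 10% of the assembly is rejected, keeping the library-size
distortion of expected ratios small (see below).

Two named variants serve specific experiments: `collapsed_allele_config`
(200 contigs, 5 collapsed alleles at 0% divergence and no other GRC, to
isolate the 3:2 ratio) and `power_config` (a deliberately small 40-contig,
10× design for replicate-number power curves over many seeds).

**Library-size shrinkage of expected ratios.** FPKM divides by total
mapped fragments, and germline libraries carry the extra GRC reads, so
every germline/soma ratio is shrunk by the germline:soma library-mass
ratio. In the collapsed-allele design this is ≈ 1.3%, leaving the measured
mean fold at ≈ 1.48 against the idealised 1.5; in the default design
(whose high-copy contigs add ≈ 15% germline mass) A contigs sit at ≈ 0.87
and collapsed alleles at ≈ 1.3. This is a faithful property of
FPKM-normalised comparative coverage on real data too, and is why the
similar-band's lower edge is 1.2.

## Numerical choices

* Test transform `log2(FPKM + 1)`; fold change reported from linear mean
  FPKM with pseudocount ε, because copy-ratio expectations (3:2 = 1.5) are
  exact on the linear scale. Both the statistic and the fold are emitted.
* Degenerate rows (total sum of squares < 10⁻¹²): F = 0, p = 1. Perfectly
  separated rows (zero within-group variance, nonzero between): p = 0.
* Contigs with zero counts everywhere are flagged `no_signal`, get fold
  change 1 (ε/ε) and are excluded from the single BH family.
* BH q-values delegate to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); the test suite cross-checks them against a brute-force
  step-up enumeration.
* Aligned reference length counts CIGAR M/=/X only by default (a flag
  admits deletions); depth is aligned bases / full contig length, with N
  bases retained in the denominator.
* GFF3 output is 1-based inclusive with one `transcript` plus one `exon`
  line per contig; all internal arithmetic is 0-based half-open.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; per-sample seeds are derived from the run
  seed, and identical configuration reproduces byte-identical outputs.

## Problem sizes used by the test and acceptance suites

The acceptance properties average over 20 seeds of the default design
(~1.1 M reads mapped per seed) and 20 seeds of the power design, and run
one collapsed-allele design of ~200 contigs (~2 M reads); the whole suite
completes in a few minutes on one CPU. These sizes were chosen as the
smallest at which the sampling tolerances stated in the tests (4 σ bounds,
10–15% recovery margins) are comfortably resolvable.

## Known limitations

* The two-group F-test assumes homoscedastic log-coverage across groups;
  with very low counts (< ~10 fragments per contig per sample) the normal
  approximation is poor and a count-based model would be preferable.
* The internal mapper is a verification tool, not a production aligner: it
  is ungapped, substitution-only, and its seed-and-extend scheme can miss
  the best alignment when every seed window is mutated. Real data should
  be mapped with a best-hit aligner and fed in as SAM/BAM.
* The size estimate depends linearly on the baseline depth; assemblies
  where more than half the length is multicopy would bias the weighted
  median upward and underestimate copy numbers.
* Category assignment is a heuristic layered on the calls; the
  `ambiguous` label is deliberately reported rather than forced into a
  category.
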