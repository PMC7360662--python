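# Methods

## Junction model

A known fusion is specified at the transcript level as an ordered gene pair
with exon variants: `GENE5:GENE3|e<rank5>:e<rank3>` means the spliced 5'
partner through exon `rank5` joined to the spliced 3' partner from exon
`rank3`. Exon ranks count in transcription order from 1, so genomic
coordinates decrease with rank on minus-strand genes; spliced sequences are
built by per-exon reverse complementation and concatenation. GTF input is
1-based inclusive; all internal offsets are 0-based half-open.

The scanner does not search transcripts but *junction contigs*: the last
`flank_target` bases of the 5' partner (truncated at the variant's exon end)
followed by the first `flank_target` bases of the 3' partner. The default
`flank_target` is 200 = 2 × read length, so every possible placement of a
breakpoint-crossing read lies fully inside the contig and there are no edge
effects. One exon chain per gene is assumed (exon numbering in variant names
presumes a canonical transcript); multi-transcript annotations require an
explicit transcript selection.

## Scanner

A read hits a contig iff some ungapped placement of the read or its reverse
complement satisfies, over the aligned span (clipping only at contig ends):

* breakpoint crossed with ≥ `min_overhang` bases on each side
  (default 10 — the minimum paired-end overlap that recovers
  short-overhang split reads lost by spliced alignment);
* ≥ `min_aligned_fraction` of the read aligned (default 0.5, the
  spliced-mate mapped-length minimum);
* ≤ `max_mismatches` Hamming mismatches (default 2, a tolerance for
  sequencing error on top of the exact-substring idea; `--strict-exact`
  sets 0). `N` never matches anything, including `N`.

Matching is ungapped by design: a junction-spanning cDNA read has no indel
at the splice boundary, and indel robustness is explicitly out of scope.
Base qualities are ignored for matching. Among qualifying placements the hit
records the one with fewest mismatches; ties break by smaller contig start,
forward before reverse complement, then leftmost placement — fixed so two
runs are byte-identical.

`scan_fastq` seeds candidates with exact `seed_length`-mers (default 12)
before verification. A qualifying placement aligns ≥ A bases with ≤ m
mismatches and therefore contains an exact run of ≥ ceil((A−m)/(m+1)) bases
(pigeonhole), so every read that can hit shares an exact k-mer with the
±read-length window around a contig breakpoint; read k-mers are sampled at
the largest stride that cannot skip such a run. Seeds are hashed 2 bits per
base and screened vectorized per chunk; the few seeded reads are then
verified by the exact placement enumeration. When `seed_length` exceeds the
guaranteed run length (tiny reads, extreme parameters) the stride falls back
to 1; seeding is then best-effort, which the oracle-equivalence tests take
into account by testing `scan_read` directly.

Support is the number of distinct fragments (read ids after mate-suffix
stripping) with at least one hit per junction, so overlapping mates count
once. PCR duplicates are kept unless `--dedup` collapses identical
(sequence1, sequence2) pairs. A read may hit several contigs that share a
flank (16:9 and 15:9 share the 3' flank); every qualifying junction records
the hit and the caller resolves variant-level summaries.

### Wildtype counter-evidence

In any realistic sample the *wildtype* partner transcripts are present, and
a read crossing a wildtype exon boundary (say KIAA1549 exon 16|17) aligns
perfectly to the contig's 5' flank; with a mismatch budget of 2, a ~10-base
random overhang clears the contract with probability ≈ 4 × 10⁻⁴. Across
tens of millions of reads this yields occasional spurious "support" for a
whitelisted fusion, where a single read suffices to report. `scan_fastq`
therefore accepts the wildtype partner transcripts as decoys and rejects a
hit whenever some full-length ungapped placement of the read on a decoy has
no more mismatches than the junction placement — i.e. whenever the
non-fusion explanation is at least as good. True spanning reads survive
easily (their off-partner segment mismatches the wildtype at ~75% of
positions), so the filter costs essentially no sensitivity while making
fusion-negative samples clean. This plays the role that re-alignment of
anchor segments plays in full fusion callers. The pipeline enables it by
default; `scan_read` itself stays a pure junction matcher.

## Caller

Per junction: support ≥ `min_support` (default 2) → `reported`;
0 < support < `min_support` → `reported` with `rescued=True` if the ordered
gene pair is whitelisted, else `discarded`; support 0 → `absent`. The
default threshold of 2 encodes that single-read events are by themselves
unreliable and only a curated known-fusion list justifies reporting them;
the full coverage-dependent statistical filters of production callers are
deliberately not reproduced. Whitelist matching is by ordered gene pair and
variant-agnostic by default (`--variant-strict` restricts rescue to listed
exon variants). Within a pair the variant with highest support is marked
primary (ties → lower 5' exon rank).

## Simulator

Each fragment picks its source transcript: the fusion transcript with
probability `fusion_fraction`, otherwise a wildtype transcript with
probability proportional to length (fragment-level mixing). Fragment length
is normal (mean 250, sd 30 by default), rounded and clamped to
[read length, transcript length] (clamping flagged in truth); the start is
uniform over valid placements; read 1 is the first `read_length` bases and
read 2 the reverse complement of the last, with the pair swapped with
probability 0.5 (unstranded — the emulated protocol is stranded, but the
scanner is orientation-agnostic, so strandedness carries no information
here). Substitution errors are applied per base at `error_rate`
(default 10⁻³); there are no indels, matching the ungapped scanner.
Qualities are constant `I`. Truth records carry source, per-read breakpoint
overhangs, start, fragment length and orientation, so every label is
recomputable from the geometry.

`fusion_fraction` is the single dial standing in for the two measured
detectability drivers — fusion-partner expression and tumor-cell content.
No per-sample fusion allele fractions are published for the emulated regime,
so benchmark values (10⁻⁴…10⁻²) were chosen to bracket the transition from
missed through rescued to comfortably reported and are fixed in the tests.

`expected_spanning_fragments` gives the closed-form expectation of fragments
with a read covering the breakpoint with ≥ o bases each side, for fixed
fragment length F: each read window contributes R − 2o + 1 starts at an
interior breakpoint; the overlap of the two start-sets and any clipping at
the valid-start bounds are removed exactly. It is the independent
calibration oracle for the simulator (and errors out near transcript ends
or with random fragment lengths, where it would be invalid).

## Synthetic reference

Real exon sequences are not bundled; `synthetic.write_synthetic_reference`
generates a seeded random chromosome whose annotation mirrors the structure
that matters: KIAA1549 and BRAF both on the minus strand, 18 exons each,
exon sizes 90–200 bp, whitelisted 16:9 and 15:9 variants. Because sequence
content is random, sequence-homology effects of the real locus (paralogs,
repeats) are *not* modeled — passing benchmarks demonstrate the method's
behavior under its stated noise model, not immunity to genomic repeat
structure. The random background transcriptome (20 transcripts, 0.6–3 kb)
plays the rest of the expressed genes; the wildtype partner transcripts are
always included in the mixture, which is what makes the specificity
benchmark non-trivial (see counter-evidence above).

## Benchmark problem sizes

Cohort benchmarks use 200,000 fragments per sample — enough that a
fusion fraction of 10⁻² yields ~90 spanning fragments and 10⁻⁴ sits at the
one-read rescue boundary, while a 50-sample negative cohort totals 2 × 10⁷
reads scanned for false positives. Simulator calibration pools 10 seeds of
10⁵ fragments with a fixed 250-bp fragment length and compares the pooled
spanning count to the closed form within 3 binomial standard errors.
Scanner correctness is checked against a brute-force all-offsets Hamming
oracle on 1000 randomized cases plus a derandomized property test.

## Known limitations

* Ungapped, substitution-only world: indels in reads (or FFPE-type damage
  beyond substitutions) are outside the model on both the simulator and
  scanner sides.
* One canonical transcript per gene; no multi-isoform junction enumeration
  and no genomic (intronic) breakpoint modeling of the 7q34 duplication.
* The caller is a fixed-threshold simplification; it does not reproduce
  production confidence models, blacklists or read-through detection.
* De novo fusion discovery is a non-goal: the tool only quantifies evidence
  for fusions it is told about.
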