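# junctionscan

Targeted detection of known gene fusions directly in raw RNA-seq reads, built
around the archetypal *KIAA1549:BRAF* fusion of pilocytic astrocytoma (PA).

## The problem

*KIAA1549:BRAF*, produced by a focal tandem duplication at 7q34 and expressed
as a chimeric transcript, is the most common driver alteration in PA and a
diagnostic and therapeutic target. It is also notoriously easy to miss in
RNA-seq: the fusion partners are expressed at low levels, tumor purity dilutes
the signal further, and general-purpose spliced aligners mishandle
breakpoint-spanning reads with short overhangs or overlapping mates — so
fusion callers downstream of the aligner never see the evidence, even when it
is present in the raw FASTQ.

`junctionscan` works the other way around. For a *known* fusion it builds the
breakpoint junction contig from the genome and annotation (e.g. *KIAA1549*
exon 16 joined to *BRAF* exon 9 — the "16:9" variant — and 15:9), then scans
the raw reads for sequences spanning that breakpoint, with explicit contracts
instead of aligner heuristics:

* a hit must cross the breakpoint with ≥ `min_overhang` bases on each side
  (default 10) and ≥ `min_aligned_fraction` of the read on the contig
  (default 0.5), with at most `max_mismatches` Hamming mismatches
  (default 2; exact matching is a flag);
* support is counted per fragment, so overlapping mate pairs are not
  double-counted;
* a read that a wildtype partner transcript explains at least as well as the
  junction contig is rejected — the counter-evidence check that keeps reads
  crossing ordinary wildtype exon boundaries from faking fusion support;
* calling uses a support threshold of 2 fragments, with a *whitelist rescue*:
  a fusion on a curated known-fusion list is reported from a single
  supporting fragment instead of being discarded.

A paired-end read simulator with per-fragment ground truth and an evaluation
module scoring samples as **reported / discarded / missed** (and
true-negative / false-positive) make the whole detectability regime —
low fusion expression, sequencing error, fusion-negative controls —
reproducible without any sequencing data.

## Worked example

```python
from pathlib import Path
from junctionscan import build_reference, run_sample, evaluate_sample

workdir = Path("example")
ref = build_reference(workdir / "reference", seed=1042)
print([j.junction_id for j in ref.junctions])
# ['KIAA1549:BRAF|e15:e9', 'KIAA1549:BRAF|e16:e9']

# a fusion-positive sample: 200,000 fragments, 1% from the fusion transcript
result = run_sample(ref, workdir, "pos1", seed=7,
                    n_fragments=200_000, fusion_fraction=0.01)
for c in result.calls:
    print(c.junction_id, c.support, c.status, "rescued" if c.rescued else "")
# KIAA1549:BRAF|e15:e9 0 absent
# KIAA1549:BRAF|e16:e9 87 reported

print(evaluate_sample(result.calls, True, ref.target_pair, "pos1").status)
# reported
```

87 distinct fragments produced a breakpoint-spanning read for the simulated
16:9 junction, so the fusion is reported outright; the 15:9 variant, absent
from this sample, shows zero support. Dropping `fusion_fraction` toward
10⁻⁴ pushes samples into the rescued (1-read) and eventually missed regimes.

The same workflow is available from the shell:

```bash
junctionscan make-reference --out-dir ref
junctionscan build-junctions --genome ref/synthetic_genome.fa \
    --annotation ref/synthetic_annotation.gtf \
    --whitelist ref/known_fusions.tsv --out junctions.fa
junctionscan scan --fastq1 s_1.fastq.gz --fastq2 s_2.fastq.gz \
    --junctions junctions.fa --out hits.tsv
junctionscan call --hits hits.tsv --junctions junctions.fa \
    --whitelist ref/known_fusions.tsv --out calls.tsv
junctionscan evaluate --manifest cohort.tsv --target KIAA1549:BRAF \
    --out-prefix cohort
```

## Layout

| module | role |
| --- | --- |
| `junction_reference` | GTF/FASTA → gene models, junction contigs, whitelist IO |
| `scanner` | seed-and-verify breakpoint scan, fragment-level support |
| `caller` | support thresholding and whitelist one-read rescue |
| `simulator` | paired-end read simulation with ground truth |
| `evaluation` | reported/discarded/missed scoring, cohort summaries |
| `pipeline` | end-to-end orchestration; `cli` exposes it as `junctionscan` |

See `docs/methods.md` for the model, parameter choices and limitations.
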