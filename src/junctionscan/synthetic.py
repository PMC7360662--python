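"""Synthetic genome, annotation and whitelist for self-contained runs.

Real KIAA1549 and BRAF exon sequences are not bundled; instead a seeded
random genome is generated whose annotation mirrors the salient structure of
the real locus: both genes on the minus strand of a 7q34-like chromosome,
18 exons each, with the whitelisted 16:9 and 15:9 fusion variants.  File
names carry a ``synthetic`` marker to make their provenance explicit.  The
sequence content is random; everything that matters to the toolkit (exon
chains, strand handling, splicing, junction construction, read simulation)
is exercised exactly as it would be on real references.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

CHROM = "chr7q34_synth"
TARGET_PAIR = ("KIAA1549", "BRAF")
WHITELIST_VARIANTS = ((16, 9), (15, 9))

# (gene, strand, exon count) — both partners sit on the minus strand, as at
# the real locus, so rank 1 is the rightmost exon
_GENE_PLANS = (
    ("KIAA1549", "-", 18),
    ("BRAF", "-", 18),
)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, n)]).decode("ascii")


@dataclass(frozen=True)
class SyntheticReferencePaths:
    genome_fasta: Path
    annotation_gtf: Path
    whitelist_tsv: Path


def write_synthetic_reference(
    outdir: str | Path, seed: int = 1042
) -> SyntheticReferencePaths:
    """Write ``synthetic_genome.fa``, ``synthetic_annotation.gtf`` and
    ``known_fusions.tsv`` into ``outdir``; deterministic in ``seed``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    gtf_rows: list[str] = []
    cursor = 1 + int(rng.integers(500, 1000))
    chrom_parts: list[tuple[int, int]] = []  # placeholder; sequence drawn at the end
    for gene, strand, n_exons in _GENE_PLANS:
        exon_sizes = rng.integers(90, 200, size=n_exons)
        intron_sizes = rng.integers(200, 500, size=n_exons - 1)
        # lay intervals left to right; on the minus strand rank counts from
        # the right, so the leftmost interval carries the highest rank
        intervals = []
        pos = cursor
        for i in range(n_exons):
            intervals.append((pos, pos + int(exon_sizes[i]) - 1))
            pos += int(exon_sizes[i])
            if i < n_exons - 1:
                pos += int(intron_sizes[i])
        ranks = range(n_exons, 0, -1) if strand == "-" else range(1, n_exons + 1)
        tid = f"{gene}-201"
        for (start, end), rank in zip(intervals, ranks):
            attrs = (
                f'gene_id "{gene}"; transcript_id "{tid}"; '
                f'gene_name "{gene}"; exon_number "{rank}";'
            )
            gtf_rows.append(
                f"{CHROM}\tsynthetic\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
            )
        cursor = pos + int(rng.integers(2000, 4000))
    chrom_len = cursor + int(rng.integers(500, 1000))
    genome_seq = random_dna(rng, chrom_len)

    genome_fasta = outdir / "synthetic_genome.fa"
    with open(genome_fasta, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, chrom_len, 80):
            fh.write(genome_seq[i : i + 80] + "\n")
    # drop any stale pyfaidx index from a previous seed
    fai = Path(str(genome_fasta) + ".fai")
    if fai.exists():
        fai.unlink()

    annotation_gtf = outdir / "synthetic_annotation.gtf"
    annotation_gtf.write_text("\n".join(gtf_rows) + "\n")

    whitelist_tsv = outdir / "known_fusions.tsv"
    variants = ";".join(f"e{a}:e{b}" for a, b in WHITELIST_VARIANTS)
    whitelist_tsv.write_text(
        "gene5\tgene3\tvariants\n" f"{TARGET_PAIR[0]}\t{TARGET_PAIR[1]}\t{variants}\n"
    )
    return SyntheticReferencePaths(genome_fasta, annotation_gtf, whitelist_tsv)


def background_transcripts(
    seed: int,
    n: int = 20,
    min_length: int = 600,
    max_length: int = 3000,
) -> dict[str, str]:
    """Random background transcriptome standing in for the rest of the
    expressed genes of a sample."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(min_length, max_length + 1, size=n)
    return {f"BG{i:03d}": random_dna(rng, int(lengths[i])) for i in range(n)}
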