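import numpy as np
import pytest

from junctionscan import GeneModel, Exon, build_reference


def make_model(spliced, exon_lengths, name="TOY", strand="+", chrom="chrT"):
    """GeneModel with the given spliced sequence split into exons of the
    given lengths; genomic coordinates are laid out consistently with the
    strand (decreasing with rank on the minus strand)."""
    assert sum(exon_lengths) == len(spliced)
    exons = []
    pos = 1
    coords = []
    for length in exon_lengths:
        coords.append((pos, pos + length - 1))
        pos += length + 50
    if strand == "-":
        coords = coords[::-1]
    for rank, (start, end) in enumerate(coords, start=1):
        exons.append(Exon(chrom=chrom, start=start, end=end, rank=rank))
    return GeneModel(
        gene_id=name,
        gene_name=name,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        spliced_seq=spliced,
    )


def write_fastq(path, records):
    """records: iterable of (read_id, sequence)."""
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def random_dna(rng, n):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def reference(tmp_path_factory):
    """The synthetic KIAA1549/BRAF reference shared by end-to-end tests."""
    return build_reference(tmp_path_factory.mktemp("reference"), seed=1042)
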