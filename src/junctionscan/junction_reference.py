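"""Gene models and breakpoint junction contigs for known gene fusions.

A fusion such as KIAA1549:BRAF 16:9 is described at the transcript level: the
spliced sequence of the 5' partner up to and including a given exon, joined to
the spliced sequence of the 3' partner from a given exon onwards.  This module
parses a genome FASTA plus a GTF exon annotation into per-gene spliced
transcript models and builds *junction contigs* — short sequences centred on
the breakpoint — that the scanner searches raw reads against.

Coordinate conventions
----------------------
GTF coordinates are 1-based inclusive at the file boundary; everything
internal (transcript offsets, breakpoint offsets) is 0-based half-open.
Exon ranks are 1-based and count in transcription order, matching the exon
numbering used in fusion variant names like "16:9".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
import pyfaidx
import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GeneNotFoundError(KeyError):
    """A requested gene name is absent from the annotation."""


class CoordinateError(ValueError):
    """An exon lies outside the bounds of its FASTA contig."""


@dataclass(frozen=True)
class Exon:
    """One exon in genomic coordinates (1-based inclusive) with its rank in
    transcription order."""

    chrom: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.rank < 1:
            raise ValueError(f"exon rank must be >= 1, got {self.rank}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """One gene's strand-ordered exon chain plus its spliced transcript
    sequence (uppercase, transcription orientation)."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[Exon, ...]
    spliced_seq: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        ranks = [e.rank for e in self.exons]
        if ranks != list(range(1, len(self.exons) + 1)):
            raise ValueError("exon ranks must be consecutive from 1")
        if len(self.spliced_seq) != sum(e.length for e in self.exons):
            raise ValueError("spliced_seq length does not match exon lengths")
        if self.strand == "-":
            starts = [e.start for e in self.exons]
            if starts != sorted(starts, reverse=True):
                raise ValueError("minus-strand exon coordinates must decrease with rank")

    @property
    def transcript_length(self) -> int:
        return len(self.spliced_seq)

    def _check_rank(self, rank: int) -> None:
        if not 1 <= rank <= len(self.exons):
            raise ValueError(
                f"exon rank {rank} out of range for {self.gene_name} "
                f"(1..{len(self.exons)})"
            )

    def transcript_end(self, rank: int) -> int:
        """0-based half-open transcript offset just past exon ``rank``."""
        self._check_rank(rank)
        return sum(e.length for e in self.exons[:rank])

    def transcript_start(self, rank: int) -> int:
        """0-based transcript offset of the first base of exon ``rank``."""
        self._check_rank(rank)
        return sum(e.length for e in self.exons[: rank - 1])


@dataclass(frozen=True)
class Junction:
    """A breakpoint contig: 3'-terminal flank of the 5' partner followed by
    the 5'-initial flank of the 3' partner.

    ``contig[:breakpoint_offset]`` is 5'-partner sequence,
    ``contig[breakpoint_offset:]`` is 3'-partner sequence.
    """

    gene5: str
    gene3: str
    exon5: int
    exon3: int
    seq5: str
    seq3: str
    flank_target: int

    def __post_init__(self) -> None:
        if not self.seq5 or not self.seq3:
            raise ValueError("junction flanks must be non-empty")
        if len(self.seq5) > self.flank_target or len(self.seq3) > self.flank_target:
            raise ValueError("flank longer than flank_target")

    @property
    def junction_id(self) -> str:
        return f"{self.gene5}:{self.gene3}|e{self.exon5}:e{self.exon3}"

    @property
    def contig(self) -> str:
        return self.seq5 + self.seq3

    @property
    def breakpoint_offset(self) -> int:
        return len(self.seq5)


@dataclass(frozen=True)
class FusionEntry:
    """One whitelist row: an ordered gene pair with optional exon variants.

    An empty ``variants`` tuple is a pair-level wildcard: it matches any exon
    combination during rescue but yields no junction contigs on its own.
    """

    gene5: str
    gene3: str
    variants: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.gene5 or not self.gene3:
            raise ValueError("whitelist gene names must be non-empty")


_VARIANT_RE = re.compile(r"^e?(\d+):e?(\d+)$")


@dataclass(frozen=True)
class KnownFusionList:
    """A curated list of known fusions, keyed by ordered (5', 3') gene pair."""

    entries: tuple[FusionEntry, ...]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, Iterable[tuple[int, int]]]]
    ) -> "KnownFusionList":
        merged: dict[tuple[str, str], set[tuple[int, int]]] = {}
        for gene5, gene3, variants in pairs:
            vs = merged.setdefault((gene5, gene3), set())
            vs.update((int(a), int(b)) for a, b in variants)
        entries = tuple(
            FusionEntry(g5, g3, tuple(sorted(merged[(g5, g3)])))
            for g5, g3 in sorted(merged)
        )
        return cls(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KnownFusionList":
        """Read a whitelist TSV with columns gene5, gene3 and an optional
        ``variants`` column of semicolon-separated ``e<rank5>:e<rank3>`` pairs."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("gene5", "gene3"):
            if col not in df.columns:
                raise ValueError(f"whitelist is missing required column {col!r}")
        pairs = []
        for _, row in df.iterrows():
            variants = []
            raw = row.get("variants", "")
            if raw:
                for token in raw.split(";"):
                    token = token.strip()
                    if not token:
                        continue
                    m = _VARIANT_RE.match(token)
                    if not m:
                        raise ValueError(f"malformed variant {token!r} in whitelist")
                    variants.append((int(m.group(1)), int(m.group(2))))
            pairs.append((row["gene5"], row["gene3"], variants))
        return cls.from_pairs(pairs)

    def contains_pair(self, gene5: str, gene3: str) -> bool:
        return any(e.gene5 == gene5 and e.gene3 == gene3 for e in self.entries)

    def matches(
        self,
        gene5: str,
        gene3: str,
        exon5: Optional[int] = None,
        exon3: Optional[int] = None,
        strict: bool = False,
    ) -> bool:
        """Whitelist membership test.

        Default (``strict=False``) matches on the ordered gene pair only,
        mirroring a known-fusion list keyed by partners.  With ``strict=True``
        the exon variant must be listed explicitly (wildcard entries still
        match any variant).
        """
        for e in self.entries:
            if (e.gene5, e.gene3) != (gene5, gene3):
                continue
            if not strict:
                return True
            if not e.variants:
                return True
            if exon5 is not None and (exon5, exon3) in e.variants:
                return True
        return False

    def gene_names(self) -> list[str]:
        names: set[str] = set()
        for e in self.entries:
            names.update((e.gene5, e.gene3))
        return sorted(names)


def _exon_attr(feature: gffutils.Feature, key: str) -> Optional[str]:
    values = feature.attributes.get(key)
    return values[0] if values else None


def parse_gene_models(
    annotation_path: str | Path,
    genome_path: str | Path,
    gene_names: Sequence[str],
    transcript_ids: Optional[Mapping[str, str]] = None,
) -> list[GeneModel]:
    """Parse GTF exon records plus a genome FASTA into one :class:`GeneModel`
    per requested gene.

    Exons are sorted into transcription order (ascending genomic start on the
    plus strand, descending on the minus strand) and the spliced sequence is
    the concatenation of per-exon sequences, reverse-complemented for
    minus-strand genes, uppercase-normalized.

    Parameters
    ----------
    transcript_ids
        Optional mapping gene_name -> transcript_id.  Required for any gene
        whose annotation carries more than one transcript; the tool operates
        on a single exon chain per gene.
    """
    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    wanted = set(gene_names)
    by_gene: dict[str, list[gffutils.Feature]] = {name: [] for name in gene_names}
    for feat in db.features_of_type("exon"):
        name = _exon_attr(feat, "gene_name")
        if name in wanted:
            by_gene[name].append(feat)

    fasta = pyfaidx.Fasta(str(genome_path), sequence_always_upper=True)
    models = []
    for name in gene_names:
        feats = by_gene[name]
        if not feats:
            raise GeneNotFoundError(f"gene not found in annotation: {name}")
        tids = sorted({_exon_attr(f, "transcript_id") or "" for f in feats})
        chosen = transcript_ids.get(name) if transcript_ids else None
        if chosen is not None:
            feats = [f for f in feats if _exon_attr(f, "transcript_id") == chosen]
            if not feats:
                raise GeneNotFoundError(
                    f"transcript {chosen!r} not found for gene {name}"
                )
        elif len(tids) > 1:
            raise ValueError(
                f"gene {name} has multiple transcripts {tids}; "
                "select one with a transcript_id filter"
            )
        strands = {f.strand for f in feats}
        chroms = {f.seqid for f in feats}
        if len(strands) != 1 or len(chroms) != 1:
            raise ValueError(f"gene {name} has inconsistent strand/chromosome records")
        strand = strands.pop()
        chrom = chroms.pop()
        if strand not in ("+", "-"):
            raise ValueError(f"gene {name} has no usable strand annotation")
        if chrom not in fasta:
            raise CoordinateError(f"chromosome {chrom!r} absent from genome FASTA")
        chrom_len = len(fasta[chrom])
        feats = sorted(feats, key=lambda f: f.start, reverse=(strand == "-"))
        exons = []
        pieces = []
        for rank, f in enumerate(feats, start=1):
            if f.start < 1 or f.end > chrom_len:
                raise CoordinateError(
                    f"exon {chrom}:{f.start}-{f.end} of {name} outside contig "
                    f"bounds (length {chrom_len})"
                )
            exons.append(Exon(chrom=chrom, start=f.start, end=f.end, rank=rank))
            seq = str(fasta[chrom][f.start - 1 : f.end]).upper()
            pieces.append(revcomp(seq) if strand == "-" else seq)
        gene_id = _exon_attr(feats[0], "gene_id") or name
        models.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=name,
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                spliced_seq="".join(pieces),
            )
        )
    return models


def build_junction(
    model5: GeneModel,
    exon5: int,
    model3: GeneModel,
    exon3: int,
    flank_target: int,
    min_overhang_hint: int = 10,
) -> Junction:
    """Build the breakpoint contig for a ``model5`` exon5 -> ``model3`` exon3
    fusion.

    ``seq5`` is the last ``flank_target`` bases of the 5' partner's spliced
    sequence, truncated at the end of ``exon5``; ``seq3`` is the first
    ``flank_target`` bases of the 3' partner starting at ``exon3``.  Both
    flanks are truncated at transcript bounds.
    """
    if flank_target < 1:
        raise ValueError("flank_target must be >= 1")
    if flank_target < min_overhang_hint:
        warnings.warn(
            f"flank_target {flank_target} below the scanner minimum overhang "
            f"{min_overhang_hint}: junction will be undetectable",
            stacklevel=2,
        )
    end5 = model5.transcript_end(exon5)
    start3 = model3.transcript_start(exon3)
    seq5 = model5.spliced_seq[max(0, end5 - flank_target) : end5]
    seq3 = model3.spliced_seq[start3 : start3 + flank_target]
    return Junction(
        gene5=model5.gene_name,
        gene3=model3.gene_name,
        exon5=exon5,
        exon3=exon3,
        seq5=seq5,
        seq3=seq3,
        flank_target=flank_target,
    )


def enumerate_known_junctions(
    known: KnownFusionList,
    models: Mapping[str, GeneModel],
    flank_target: int,
) -> list[Junction]:
    """One junction per (gene pair, exon variant) in the whitelist.

    Wildcard entries (no variants listed) contribute no contigs.  Duplicate
    variants collapse to a single junction.
    """
    seen: dict[str, Junction] = {}
    for entry in known.entries:
        if not entry.variants:
            continue
        for name in (entry.gene5, entry.gene3):
            if name not in models:
                raise GeneNotFoundError(f"no gene model for whitelisted gene {name}")
        for exon5, exon3 in entry.variants:
            j = build_junction(
                models[entry.gene5], exon5, models[entry.gene3], exon3, flank_target
            )
            seen.setdefault(j.junction_id, j)
    return [seen[k] for k in sorted(seen)]


_JUNCTION_ID_RE = re.compile(r"^([^:|]+):([^:|]+)\|e(\d+):e(\d+)$")


def parse_junction_id(junction_id: str) -> tuple[str, str, int, int]:
    m = _JUNCTION_ID_RE.match(junction_id)
    if not m:
        raise ValueError(f"malformed junction id {junction_id!r}")
    return m.group(1), m.group(2), int(m.group(3)), int(m.group(4))


def write_junction_fasta(junctions: Sequence[Junction], path: str | Path) -> None:
    """Write junction contigs as FASTA; the breakpoint offset and flank target
    are stored in the header so the file round-trips."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f">{j.junction_id} breakpoint_offset={j.breakpoint_offset} "
                f"flank={j.flank_target}\n{j.contig}\n"
            )


def read_junction_fasta(path: str | Path) -> list[Junction]:
    junctions = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            meta = dict(
                kv.split("=", 1) for kv in (rec.comment or "").split() if "=" in kv
            )
            if "breakpoint_offset" not in meta:
                raise ValueError(
                    f"junction record {rec.name!r} lacks breakpoint_offset metadata"
                )
            offset = int(meta["breakpoint_offset"])
            flank = int(meta.get("flank", max(offset, len(rec.sequence) - offset)))
            gene5, gene3, exon5, exon3 = parse_junction_id(rec.name)
            seq = rec.sequence.upper()
            junctions.append(
                Junction(
                    gene5=gene5,
                    gene3=gene3,
                    exon5=exon5,
                    exon3=exon3,
                    seq5=seq[:offset],
                    seq3=seq[offset:],
                    flank_target=flank,
                )
            )
    return junctions


def write_junction_metadata(junctions: Sequence[Junction], path: str | Path) -> None:
    rows = [
        {
            "junction_id": j.junction_id,
            "gene5": j.gene5,
            "gene3": j.gene3,
            "exon5": j.exon5,
            "exon3": j.exon3,
            "breakpoint_offset": j.breakpoint_offset,
            "contig_length": len(j.contig),
            "flank_target": j.flank_target,
        }
        for j in junctions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
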