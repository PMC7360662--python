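"""Find junction-spanning reads in raw FASTQ by seed-and-verify matching.

The matcher is deliberately simple and fully specified: a read hits a
junction contig iff some *ungapped* placement of the read (or its reverse
complement) on the contig

* crosses the breakpoint with at least ``min_overhang`` aligned bases on each
  side (the fix for short-overhang split reads that spliced aligners drop),
* has at most ``max_mismatches`` Hamming mismatches over the aligned span, and
* aligns at least ``min_aligned_fraction`` of the read within the contig
  (clipping is only allowed at contig ends).

``scan_read`` enumerates every breakpoint-crossing placement exactly.
``scan_fastq`` avoids doing that for every read by a k-mer seed prefilter:
a qualifying placement with at most ``m`` mismatches over an aligned span of
length ``A`` necessarily contains an exact run of at least
``ceil((A - m) / (m + 1))`` bases (pigeonhole), so any read that can hit
shares an exact ``seed_length``-mer with the contig region around the
breakpoint.  Only seeded reads are verified with ``scan_read``.

Support is counted per *fragment*: a pair whose two overlapping mates both
span the junction contributes one supporting fragment, not two.

``scan_fastq`` optionally takes wildtype transcript sequences as
counter-evidence (``decoys``): a junction hit is discarded when the read
matches a wildtype transcript with no more mismatches than the junction
contig, i.e. when the non-fusion explanation of the read is at least as good.
This is what keeps reads that merely cross a wildtype exon boundary of a
fusion partner from masquerading as breakpoint evidence.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import islice
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from numpy.lib.stride_tricks import sliding_window_view

from .junction_reference import Junction, revcomp

ORIENTATIONS = ("forward", "revcomp")

# byte -> 2-bit code; 4 flags anything that is not an unambiguous base
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGT"):
    _CODE[_ch] = _i
    _CODE[_ch + 32] = _i


class FastqFormatError(ValueError):
    """Malformed or desynchronized FASTQ input."""


@dataclass(frozen=True)
class ScanParams:
    """Matching contract of the scanner.

    min_overhang:
        Aligned bases required on each side of the breakpoint (default 10,
        the paired-end overlap minimum that rescued short-overhang split
        reads in the optimized alignment settings).
    max_mismatches:
        Hamming mismatch budget over the aligned span (default 2; 0 gives
        the strict exact-match mode).
    seed_length:
        Exact-match k-mer length that triggers verification (default 12).
    min_aligned_fraction:
        Minimum fraction of the read that must lie on the contig
        (default 0.5, the spliced-mate mapped-length minimum).
    both_orientations:
        Also match the reverse complement of each read (default True).
    """

    min_overhang: int = 10
    max_mismatches: int = 2
    seed_length: int = 12
    min_aligned_fraction: float = 0.5
    both_orientations: bool = True

    def __post_init__(self) -> None:
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.seed_length < 8:
            raise ValueError("seed_length must be >= 8")
        if not 0 < self.min_aligned_fraction <= 1:
            raise ValueError("min_aligned_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with its mate number; the mate suffix is stripped
    from the id so both mates of a fragment share ``read_id``."""

    read_id: str
    mate: int
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError("qualities length differs from sequence length")


@dataclass(frozen=True)
class JunctionHit:
    """One read's best qualifying placement on a junction contig."""

    read_id: str
    mate: int
    junction_id: str
    contig_start: int
    aligned_length: int
    mismatches: int
    overhang5: int
    overhang3: int
    orientation: str


@dataclass(frozen=True)
class FragmentSupport:
    """Distinct supporting fragments for one junction."""

    junction_id: str
    fragment_ids: frozenset[str]

    @property
    def support(self) -> int:
        return len(self.fragment_ids)


@dataclass
class ScanStats:
    reads_scanned: int = 0
    reads_too_short: int = 0
    reads_with_n: int = 0
    fragments_deduplicated: int = 0
    candidates_verified: int = 0
    hits_rejected_wildtype: int = 0
    hits_per_junction: dict[str, int] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def strip_mate_suffix(name: str) -> str:
    if len(name) > 2 and name[-2] == "/" and name[-1] in "12":
        return name[:-2]
    return name


def scan_read(
    read: ReadRecord, junction: Junction, params: ScanParams
) -> Optional[JunctionHit]:
    """Best qualifying ungapped placement of ``read`` on the junction contig,
    or None.

    Among qualifying placements the one with fewest mismatches wins; ties go
    to the smallest contig_start, then forward before reverse complement,
    then the leftmost (least clipped) placement.  N never matches any base.
    Reads shorter than ``2 * min_overhang`` cannot span and return None.
    """
    r = len(read.sequence)
    if r < 2 * params.min_overhang:
        return None
    contig = junction.contig
    b = junction.breakpoint_offset
    length = len(contig)
    min_alen = params.min_aligned_fraction * r
    limit = params.max_mismatches
    variants = [("forward", read.sequence.upper())]
    if params.both_orientations:
        variants.append(("revcomp", revcomp(read.sequence.upper())))
    best_key = None
    best_hit = None
    for orank, (orient, seq) in enumerate(variants):
        for p in range(b + params.min_overhang - r, b - params.min_overhang + 1):
            a_start = p if p > 0 else 0
            a_end = p + r if p + r < length else length
            alen = a_end - a_start
            if alen + 1e-9 < min_alen:
                continue
            o5 = b - a_start
            o3 = a_end - b
            if o5 < params.min_overhang or o3 < params.min_overhang:
                continue
            ro = a_start - p
            mm = 0
            for i in range(alen):
                x = seq[ro + i]
                y = contig[a_start + i]
                if x != y or x == "N" or y == "N":
                    mm += 1
                    if mm > limit:
                        break
            if mm > limit:
                continue
            key = (mm, a_start, orank, p)
            if best_key is None or key < best_key:
                best_key = key
                best_hit = JunctionHit(
                    read_id=read.read_id,
                    mate=read.mate,
                    junction_id=junction.junction_id,
                    contig_start=a_start,
                    aligned_length=alen,
                    mismatches=mm,
                    overhang5=o5,
                    overhang3=o3,
                    orientation=orient,
                )
    return best_hit


def _kmer_hash(kmer: str) -> int:
    h = 0
    for ch in kmer:
        c = "ACGT".find(ch)
        if c < 0:
            return -1
        h = h * 4 + c
    return h


class _SeedIndex:
    """Exact k-mer set over the breakpoint regions of all contigs, both
    orientations, hashed to base-4 integers."""

    def __init__(
        self, junctions: Sequence[Junction], seed_length: int, max_read_len: int
    ) -> None:
        self.seed_length = seed_length
        self.max_read_len = max_read_len
        hashes: set[int] = set()
        for j in junctions:
            contig = j.contig
            b = j.breakpoint_offset
            # any breakpoint-crossing aligned span lies within +-max_read_len
            lo = max(0, b - max_read_len)
            hi = min(len(contig), b + max_read_len)
            window = contig[lo:hi]
            for seq in (window, revcomp(window)):
                for i in range(len(seq) - seed_length + 1):
                    h = _kmer_hash(seq[i : i + seed_length])
                    if h >= 0:
                        hashes.add(h)
        self.hash_array = np.array(sorted(hashes), dtype=np.int64)


def _encode_padded(seqs: Sequence[str], width: int) -> np.ndarray:
    buf = bytearray()
    for s in seqs:
        buf += s.encode("ascii")
        buf += b"N" * (width - len(s))
    arr = np.frombuffer(bytes(buf), dtype=np.uint8).reshape(len(seqs), width)
    return _CODE[arr]


def _window_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 hashes of all k-windows per row; windows containing any
    ambiguous base get hash -1."""
    n, width = codes.shape
    w = width - k + 1
    if w <= 0:
        return np.empty((n, 0), dtype=np.int64)
    h = np.zeros((n, w), dtype=np.int64)
    bad = np.zeros((n, w), dtype=np.int64)
    for t in range(k):
        col = codes[:, t : t + w]
        h *= 4
        h += col & 3
        bad += col == 4
    h[bad > 0] = -1
    return h


def _seed_stride(params: ScanParams, read_len: int) -> int:
    """Largest read k-mer sampling stride that cannot miss a qualifying
    placement: any hit aligns >= A bases with <= m mismatches, hence contains
    an exact run of ceil((A - m)/(m + 1)) bases; a run of length L contains a
    sampled k-mer start whenever stride <= L - k + 1."""
    a_min = max(2 * params.min_overhang, math.ceil(params.min_aligned_fraction * read_len))
    m = params.max_mismatches
    run = -(-(a_min - m) // (m + 1))
    if run < params.seed_length:
        return 1
    return max(1, run - params.seed_length + 1)


def _min_decoy_mismatches(sequence: str, decoy_codes: Sequence[np.ndarray]) -> int:
    """Fewest mismatches of any full-length ungapped placement of the read
    (either orientation) on any decoy transcript."""
    arr = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    fwd = np.where(arr == 4, np.uint8(5), arr)  # read N: sentinel that never matches
    rev = np.where(fwd <= 3, 3 - fwd, fwd)[::-1]
    best = len(sequence) + 1
    for d in decoy_codes:
        if d.size < fwd.size:
            continue
        win = sliding_window_view(d, fwd.size)
        for q in (fwd, rev):
            mm = int((win != q).sum(axis=1).min())
            if mm < best:
                best = mm
    return best


def encode_decoys(decoys: Iterable[str]) -> list[np.ndarray]:
    return [
        _CODE[np.frombuffer(d.upper().encode("ascii"), dtype=np.uint8)] for d in decoys
    ]


def _paired_chunks(fastq1_path, fastq2_path, chunk_size):
    with pysam.FastxFile(str(fastq1_path)) as f1, pysam.FastxFile(str(fastq2_path)) as f2:
        record = 0
        while True:
            try:
                c1 = list(islice(f1, chunk_size))
                c2 = list(islice(f2, chunk_size))
            except Exception as exc:  # pysam raises on truncated records
                raise FastqFormatError(
                    f"malformed FASTQ near record {record + 1}: {exc}"
                ) from exc
            if not c1 and not c2:
                return
            if len(c1) != len(c2):
                raise FastqFormatError(
                    f"mate files desynchronized: one file ends near record "
                    f"{record + min(len(c1), len(c2)) + 1}"
                )
            record += len(c1)
            yield c1, c2


def scan_fastq(
    fastq1_path: str | Path,
    fastq2_path: str | Path,
    junctions: Sequence[Junction],
    params: Optional[ScanParams] = None,
    decoys: Optional[Sequence[str]] = None,
    dedup: bool = False,
    chunk_size: int = 20000,
) -> tuple[list[JunctionHit], ScanStats]:
    """Scan a record-synchronized, optionally gzipped FASTQ pair against all
    junction contigs.

    Output order is deterministic: file order, mate 1 before mate 2, then
    junction_id.  ``dedup=True`` collapses fragments with identical
    (sequence1, sequence2) before scanning (PCR duplicate removal).
    """
    params = params or ScanParams()
    junctions = sorted(junctions, key=lambda j: j.junction_id)
    stats = ScanStats(hits_per_junction={j.junction_id: 0 for j in junctions})
    hits: list[JunctionHit] = []
    decoy_codes = encode_decoys(decoys) if decoys else []
    index: Optional[_SeedIndex] = None
    seen_pairs: set[tuple[str, str]] = set()

    for c1, c2 in _paired_chunks(fastq1_path, fastq2_path, chunk_size):
        reads: list[ReadRecord] = []
        for r1, r2 in zip(c1, c2):
            id1 = strip_mate_suffix(r1.name)
            id2 = strip_mate_suffix(r2.name)
            if id1 != id2:
                raise FastqFormatError(
                    f"mate files desynchronized: {r1.name!r} paired with {r2.name!r}"
                )
            if dedup:
                key = (r1.sequence, r2.sequence)
                if key in seen_pairs:
                    stats.fragments_deduplicated += 1
                    stats.reads_scanned += 2
                    continue
                seen_pairs.add(key)
            reads.append(ReadRecord(id1, 1, r1.sequence.upper(), r1.quality))
            reads.append(ReadRecord(id2, 2, r2.sequence.upper(), r2.quality))
        stats.reads_scanned += len(reads)

        scannable: list[ReadRecord] = []
        for rr in reads:
            if "N" in rr.sequence:
                stats.reads_with_n += 1
            if len(rr.sequence) < 2 * params.min_overhang:
                stats.reads_too_short += 1
            else:
                scannable.append(rr)
        if not scannable:
            continue

        is_candidate = [False] * len(scannable)
        seed_rows = [
            i for i, rr in enumerate(scannable) if len(rr.sequence) >= params.seed_length
        ]
        for i, rr in enumerate(scannable):
            if len(rr.sequence) < params.seed_length:
                is_candidate[i] = True  # too short to seed: verify directly
        if seed_rows:
            rmax = max(len(scannable[i].sequence) for i in seed_rows)
            rmin = min(len(scannable[i].sequence) for i in seed_rows)
            if index is None or rmax > index.max_read_len:
                index = _SeedIndex(junctions, params.seed_length, rmax)
            if index.hash_array.size:
                codes = _encode_padded([scannable[i].sequence for i in seed_rows], rmax)
                h = _window_hashes(codes, params.seed_length)
                stride = _seed_stride(params, rmin)
                seeded = np.isin(h[:, ::stride], index.hash_array).any(axis=1)
                for row, flag in zip(seed_rows, seeded):
                    if flag:
                        is_candidate[row] = True

        for rr, flag in zip(scannable, is_candidate):
            if not flag:
                continue
            stats.candidates_verified += 1
            decoy_mm: Optional[int] = None
            for j in junctions:
                hit = scan_read(rr, j, params)
                if hit is None:
                    continue
                if decoy_codes:
                    if decoy_mm is None:
                        decoy_mm = _min_decoy_mismatches(rr.sequence, decoy_codes)
                    if decoy_mm <= hit.mismatches:
                        stats.hits_rejected_wildtype += 1
                        continue
                hits.append(hit)
                stats.hits_per_junction[j.junction_id] += 1
    return hits, stats


def compute_fragment_support(
    hits: Iterable[JunctionHit],
    junction_ids: Optional[Iterable[str]] = None,
) -> list[FragmentSupport]:
    """Per-junction distinct-fragment support.  A fragment whose two mates
    both hit a junction counts once.  When ``junction_ids`` is given, every
    listed junction appears in the output (zero-support junctions included)."""
    by_junction: dict[str, set[str]] = {}
    for h in hits:
        by_junction.setdefault(h.junction_id, set()).add(h.read_id)
    if junction_ids is None:
        ids = sorted(by_junction)
    else:
        ids = sorted(set(junction_ids))
        unknown = set(by_junction) - set(ids)
        if unknown:
            raise ValueError(f"hits reference unlisted junctions: {sorted(unknown)}")
    return [FragmentSupport(j, frozenset(by_junction.get(j, set()))) for j in ids]


_HIT_COLUMNS = [
    "read_id",
    "mate",
    "junction_id",
    "contig_start",
    "aligned_length",
    "mismatches",
    "overhang5",
    "overhang3",
    "orientation",
]


def write_hits_tsv(hits: Sequence[JunctionHit], path: str | Path) -> None:
    df = pd.DataFrame([asdict(h) for h in hits], columns=_HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[JunctionHit]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    return [JunctionHit(**{c: row[c] for c in _HIT_COLUMNS}) for row in df.to_dict("records")]
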