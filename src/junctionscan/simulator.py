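"""Paired-end RNA-seq read simulator with fusion ground truth.

Emulates the detectability regime of KIAA1549:BRAF fusions in pilocytic
astrocytoma RNA-seq: 2 x 100 bp paired-end reads sequenced from a transcript
mixture in which the chimeric fusion transcript accounts for only a small
fraction of fragments (``fusion_fraction``), standing in for low fusion
partner expression diluted further by non-tumor cells.

Model choices, in brief: fragments are drawn from a normal insert-size
distribution (rounded, clamped to [read_length, transcript length]); the
wildtype transcript a fragment comes from is picked with probability
proportional to transcript length, which makes the mixture fragment-level
rather than transcript-level; sequencing error is substitution-only (the
downstream matcher is ungapped); fragment orientation is random even though
the emulated protocol is stranded, because detection is orientation-agnostic;
base qualities are constant.

Every fragment gets a ground-truth record: its source transcript, whether
either read covers the breakpoint, and exact per-read breakpoint overhangs —
the labels the evaluation module scores detection against.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .junction_reference import GeneModel, revcomp


@dataclass
class SimulationConfig:
    """Study-design parameters of one simulated sample.

    transcripts maps transcript name -> spliced sequence and must contain
    the fusion transcript (named ``fusion_name``, breakpoint at 0-based
    ``fusion_breakpoint``) whenever ``fusion_fraction > 0``.
    """

    transcripts: dict[str, str]
    n_fragments: int
    fusion_name: Optional[str] = None
    fusion_breakpoint: Optional[int] = None
    fusion_fraction: float = 0.0
    read_length: int = 100
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 30.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fusion_fraction <= 1.0:
            raise ValueError("fusion_fraction must be in [0, 1]")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.fragment_length_mean < self.read_length:
            raise ValueError("fragment_length_mean must be >= read_length")
        if self.fragment_length_sd < 0:
            raise ValueError("fragment_length_sd must be >= 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.fusion_fraction > 0:
            if self.fusion_name is None or self.fusion_name not in self.transcripts:
                raise ValueError(
                    "fusion_fraction > 0 requires a fusion transcript in the mixture"
                )
            if self.fusion_breakpoint is None:
                raise ValueError("fusion transcript requires a breakpoint offset")
        if self.fusion_name is not None and self.fusion_breakpoint is not None:
            flen = len(self.transcripts[self.fusion_name])
            if not 0 < self.fusion_breakpoint < flen:
                raise ValueError("fusion_breakpoint must be interior to the transcript")
        for name, seq in self.transcripts.items():
            if len(seq) < self.read_length:
                raise ValueError(
                    f"transcript {name!r} shorter than read_length "
                    f"({len(seq)} < {self.read_length})"
                )

    def echo(self) -> dict:
        """JSON-serializable config summary (sequences replaced by lengths)."""
        return {
            "n_fragments": self.n_fragments,
            "fusion_name": self.fusion_name,
            "fusion_breakpoint": self.fusion_breakpoint,
            "fusion_fraction": self.fusion_fraction,
            "read_length": self.read_length,
            "fragment_length_mean": self.fragment_length_mean,
            "fragment_length_sd": self.fragment_length_sd,
            "error_rate": self.error_rate,
            "seed": self.seed,
            "transcript_lengths": {k: len(v) for k, v in sorted(self.transcripts.items())},
        }


@dataclass
class SimulatedSample:
    fastq1_path: Path
    fastq2_path: Path
    truth_path: Path
    config_path: Path
    config: SimulationConfig


TRUTH_COLUMNS = [
    "fragment_id",
    "source",
    "spans_junction",
    "read1_overhang5",
    "read1_overhang3",
    "read2_overhang5",
    "read2_overhang3",
    "start",
    "fragment_length",
    "flipped",
    "truncated",
]


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def build_fusion_transcript(
    model5: GeneModel, exon5: int, model3: GeneModel, exon3: int
) -> tuple[str, int]:
    """Full chimeric transcript: the 5' partner's spliced sequence through
    ``exon5`` joined to the 3' partner's from ``exon3`` onwards.  Returns
    (sequence, 0-based breakpoint offset)."""
    end5 = model5.transcript_end(exon5)
    start3 = model3.transcript_start(exon3)
    return model5.spliced_seq[:end5] + model3.spliced_seq[start3:], end5


def _window_overhangs(
    win_start: int, win_end: int, breakpoint: int
) -> Optional[tuple[int, int]]:
    """Overhangs of a read window [win_start, win_end) around an interior
    breakpoint, or None if the window does not cross it."""
    if win_start < breakpoint < win_end:
        return breakpoint - win_start, win_end - breakpoint
    return None


def simulate_sample(
    config: SimulationConfig,
    out_prefix: str | Path,
    gzip_output: bool = True,
) -> SimulatedSample:
    """Simulate one sample; writes ``<prefix>_1.fastq[.gz]``,
    ``<prefix>_2.fastq[.gz]``, ``<prefix>.truth.tsv`` and
    ``<prefix>.config.json``.  Byte-identical output for identical config."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    names = sorted(config.transcripts)
    seqs = [config.transcripts[n] for n in names]
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    fusion_idx = names.index(config.fusion_name) if config.fusion_name in names else -1
    wt_idx = np.array([i for i in range(len(names)) if i != fusion_idx], dtype=np.int64)

    n = config.n_fragments
    r = config.read_length
    if config.fusion_fraction < 1.0 and wt_idx.size == 0:
        raise ValueError("no wildtype transcripts to draw non-fusion fragments from")

    is_fusion = rng.random(n) < config.fusion_fraction
    if wt_idx.size:
        w = lens[wt_idx].astype(float)
        picks = wt_idx[rng.choice(wt_idx.size, size=n, p=w / w.sum())]
    else:
        picks = np.full(n, fusion_idx, dtype=np.int64)
    src = np.where(is_fusion, fusion_idx, picks)

    raw_len = np.rint(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, n)
    ).astype(np.int64)
    src_len = lens[src]
    frag = np.clip(raw_len, r, src_len)
    truncated = raw_len > src_len
    start = np.floor(rng.random(n) * (src_len - frag + 1)).astype(np.int64)
    flip = rng.random(n) < 0.5
    if config.error_rate > 0:
        nerr = rng.binomial(r, config.error_rate, size=(n, 2))
        total = int(nerr.sum())
        err_pos = rng.integers(0, r, size=total)
        err_sub = rng.integers(1, 4, size=total)
    else:
        nerr = np.zeros((n, 2), dtype=np.int64)
        err_pos = err_sub = np.empty(0, dtype=np.int64)

    qual = "I" * r
    width = max(6, len(str(max(n - 1, 0))))
    b = config.fusion_breakpoint
    lines1: list[str] = []
    lines2: list[str] = []
    truth: dict[str, list] = {c: [] for c in TRUTH_COLUMNS}
    ei = 0
    for i in range(n):
        s0 = int(start[i])
        f = int(frag[i])
        seq = seqs[src[i]]
        r1 = seq[s0 : s0 + r]
        r2 = revcomp(seq[s0 + f - r : s0 + f])
        if flip[i]:
            r1, r2 = r2, r1
        for mate in (0, 1):
            k = int(nerr[i, mate])
            if not k:
                continue
            target = list(r1 if mate == 0 else r2)
            for pos, off in zip(err_pos[ei : ei + k], err_sub[ei : ei + k]):
                c = "ACGT".find(target[pos])
                target[pos] = "ACGT"[(c + off) % 4] if c >= 0 else "ACGT"[off - 1]
            ei += k
            if mate == 0:
                r1 = "".join(target)
            else:
                r2 = "".join(target)

        fid = f"frag{i:0{width}d}"
        lines1.append(f"@{fid}/1\n{r1}\n+\n{qual}\n")
        lines2.append(f"@{fid}/2\n{r2}\n+\n{qual}\n")

        w1 = w2 = None
        if src[i] == fusion_idx and b is not None:
            w1 = _window_overhangs(s0, s0 + r, b)
            w2 = _window_overhangs(s0 + f - r, s0 + f, b)
        r1_ov, r2_ov = (w2, w1) if flip[i] else (w1, w2)
        truth["fragment_id"].append(fid)
        truth["source"].append(names[src[i]])
        truth["spans_junction"].append(bool(w1 or w2))
        truth["read1_overhang5"].append(r1_ov[0] if r1_ov else np.nan)
        truth["read1_overhang3"].append(r1_ov[1] if r1_ov else np.nan)
        truth["read2_overhang5"].append(r2_ov[0] if r2_ov else np.nan)
        truth["read2_overhang3"].append(r2_ov[1] if r2_ov else np.nan)
        truth["start"].append(s0)
        truth["fragment_length"].append(f)
        truth["flipped"].append(bool(flip[i]))
        truth["truncated"].append(bool(truncated[i]))

    suffix = ".fastq.gz" if gzip_output else ".fastq"
    fastq1 = out_prefix.parent / (out_prefix.name + "_1" + suffix)
    fastq2 = out_prefix.parent / (out_prefix.name + "_2" + suffix)
    for path, lines in ((fastq1, lines1), (fastq2, lines2)):
        data = "".join(lines).encode("ascii")
        if gzip_output:
            # fixed mtime keeps identical configs byte-identical on disk
            path.write_bytes(gzip.compress(data, compresslevel=1, mtime=0))
        else:
            path.write_bytes(data)

    truth_path = out_prefix.parent / (out_prefix.name + ".truth.tsv")
    pd.DataFrame(truth, columns=TRUTH_COLUMNS).to_csv(
        truth_path, sep="\t", index=False, float_format="%.0f"
    )
    config_path = out_prefix.parent / (out_prefix.name + ".config.json")
    with open(config_path, "w") as fh:
        json.dump(config.echo(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return SimulatedSample(fastq1, fastq2, truth_path, config_path, config)


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def expected_spanning_fragments(config: SimulationConfig, min_overhang: int) -> float:
    """Closed-form expected number of fragments with a read covering the
    breakpoint with at least ``min_overhang`` bases on each side.

    Valid for a fixed fragment length (sd = 0) and an interior breakpoint.
    With fragment length F, read length R and breakpoint b, read 1 covers the
    breakpoint for starts in [b + o - R, b - o] and read 2 for starts in
    [b + o - F, b + R - o - F]; both windows contribute R - 2o + 1 starts on
    an interior breakpoint, and their overlap (and any clipping at valid
    start bounds) is removed exactly.
    """
    if config.fragment_length_sd != 0:
        raise ValueError("closed form requires a fixed fragment length (sd = 0)")
    if config.fusion_name is None or config.fusion_breakpoint is None:
        raise ValueError("no fusion transcript configured")
    f = int(round(config.fragment_length_mean))
    r = config.read_length
    o = min_overhang
    length = len(config.transcripts[config.fusion_name])
    b = config.fusion_breakpoint
    if r < 2 * o:
        raise ValueError("read length must be >= 2 * min_overhang")
    if f < r:
        raise ValueError("fragment length must be >= read length")
    if length < f:
        raise ValueError("fusion transcript shorter than the fragment length")
    if b < r or length - b < r:
        raise ValueError("breakpoint too close to transcript ends for the closed form")
    valid = (0, length - f)
    read1 = (b + o - r, b - o)
    read2 = (b + o - f, b + r - o - f)
    n_starts = (
        _interval_overlap(read1, valid)
        + _interval_overlap(read2, valid)
        - _interval_overlap((max(read1[0], read2[0]), min(read1[1], read2[1])), valid)
    )
    return config.n_fragments * config.fusion_fraction * n_starts / (length - f + 1)
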