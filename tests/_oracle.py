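"""Independent brute-force oracles used to check the package's fast paths.

These deliberately enumerate everything (all offsets, all orientations, all
fragment starts) and share no code with the implementation under test.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_scan(read_seq, contig, breakpoint, params):
    """Exhaustive all-offsets Hamming scan.

    Returns (mismatches, contig_start, orientation_index, offset) of the best
    qualifying ungapped placement, or None.  Ordering: fewest mismatches,
    then smallest contig_start, then forward before reverse complement, then
    leftmost offset.
    """
    r = len(read_seq)
    length = len(contig)
    if r < 2 * params.min_overhang:
        return None
    variants = [read_seq]
    if params.both_orientations:
        variants.append(_revcomp(read_seq))
    best = None
    for orank, seq in enumerate(variants):
        for p in range(-r + 1, length):
            a_start = max(p, 0)
            a_end = min(p + r, length)
            if a_end <= a_start:
                continue
            alen = a_end - a_start
            if alen < params.min_aligned_fraction * r - 1e-9:
                continue
            if breakpoint - a_start < params.min_overhang:
                continue
            if a_end - breakpoint < params.min_overhang:
                continue
            mm = 0
            for i in range(alen):
                x = seq[a_start - p + i]
                y = contig[a_start + i]
                if x != y or x == "N" or y == "N":
                    mm += 1
            if mm <= params.max_mismatches:
                key = (mm, a_start, orank, p)
                if best is None or key < best:
                    best = key
    return best


def enumerate_spanning_starts(transcript_length, fragment_length, read_length, breakpoint, min_overhang):
    """Count fragment starts whose read 1 or read 2 window covers the
    breakpoint with >= min_overhang bases on each side (direct enumeration)."""
    count = 0
    for s in range(0, transcript_length - fragment_length + 1):
        windows = (
            (s, s + read_length),
            (s + fragment_length - read_length, s + fragment_length),
        )
        for w0, w1 in windows:
            if w0 <= breakpoint - min_overhang and w1 >= breakpoint + min_overhang:
                count += 1
                break
    return count
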