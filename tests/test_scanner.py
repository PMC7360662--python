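import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from junctionscan import (
    ReadRecord,
    ScanParams,
    compute_fragment_support,
    revcomp,
    scan_fastq,
    scan_read,
    simulate_sample,
)
from junctionscan.junction_reference import Junction
from junctionscan.scanner import FastqFormatError, write_hits_tsv
from junctionscan.pipeline import sample_config

from conftest import random_dna, write_fastq
from _oracle import brute_force_scan


def make_junction(contig, breakpoint):
    return Junction(
        gene5="G5",
        gene3="G3",
        exon5=1,
        exon3=1,
        seq5=contig[:breakpoint],
        seq3=contig[breakpoint:],
        flank_target=max(breakpoint, len(contig) - breakpoint),
    )


@pytest.fixture(scope="module")
def junction():
    rng = np.random.default_rng(7)
    contig = random_dna(rng, 400)
    return make_junction(contig, 200)


class TestScanRead:
    def test_exact_breakpoint_window_hits_with_symmetric_overhangs(self, junction):
        b = junction.breakpoint_offset
        read = ReadRecord("r1", 1, junction.contig[b - 20 : b + 20])
        hit = scan_read(read, junction, ScanParams())
        assert hit is not None
        assert (hit.overhang5, hit.overhang3, hit.mismatches) == (20, 20, 0)
        assert hit.orientation == "forward"

    def test_reverse_complement_window_hits_in_revcomp_orientation(self, junction):
        b = junction.breakpoint_offset
        read = ReadRecord("r1", 1, revcomp(junction.contig[b - 20 : b + 20]))
        hit = scan_read(read, junction, ScanParams())
        assert hit is not None
        assert (hit.overhang5, hit.overhang3) == (20, 20)
        assert hit.orientation == "revcomp"

    def test_short_overhang_below_minimum_is_rejected(self, junction):
        # 35 bases on the 5' side but only 5 on the 3' side of the breakpoint
        b = junction.breakpoint_offset
        read = ReadRecord("r1", 1, junction.contig[b - 35 : b + 5])
        assert scan_read(read, junction, ScanParams(min_overhang=10)) is None
        assert scan_read(read, junction, ScanParams(min_overhang=5)) is not None

    def test_read_too_short_to_span_returns_none(self, junction):
        b = junction.breakpoint_offset
        read = ReadRecord("r1", 1, junction.contig[b - 8 : b + 8])
        assert scan_read(read, junction, ScanParams(min_overhang=10)) is None

    def test_n_bases_count_as_mismatches_never_wildcards(self, junction):
        b = junction.breakpoint_offset
        window = list(junction.contig[b - 20 : b + 20])
        window[0] = window[1] = window[2] = "N"
        read = ReadRecord("r1", 1, "".join(window))
        assert scan_read(read, junction, ScanParams(max_mismatches=2)) is None
        hit = scan_read(read, junction, ScanParams(max_mismatches=3))
        assert hit is not None and hit.mismatches == 3

    def test_matches_brute_force_oracle_on_random_inputs(self):
        """Seeded random sweep of the full decision contract against the
        exhaustive all-offsets oracle."""
        rng = np.random.default_rng(20260921)
        n_hits = 0
        for _ in range(300):
            contig_len = int(rng.integers(20, 301))
            b = int(rng.integers(1, contig_len))
            contig = random_dna(rng, contig_len)
            read_len = int(rng.integers(10, 151))
            params = ScanParams(
                min_overhang=int(rng.integers(1, max(2, read_len // 2 + 1))),
                max_mismatches=int(rng.integers(0, 5)),
                seed_length=int(rng.integers(8, 21)),
                min_aligned_fraction=float(rng.uniform(0.1, 1.0)),
                both_orientations=bool(rng.random() < 0.8),
            )
            if rng.random() < 0.7:
                # breakpoint-crossing window with a few mutations
                p = int(rng.integers(b - read_len + 1, b + 1))
                window = [
                    contig[(p + i) % contig_len] for i in range(read_len)
                ]
                for _ in range(int(rng.integers(0, 4))):
                    window[int(rng.integers(0, read_len))] = "ACGTN"[
                        int(rng.integers(0, 5))
                    ]
                read_seq = "".join(window)
                if rng.random() < 0.5:
                    read_seq = revcomp(read_seq)
            else:
                read_seq = random_dna(rng, read_len)
            junction = make_junction(contig, b)
            hit = scan_read(ReadRecord("r", 1, read_seq), junction, params)
            oracle = brute_force_scan(read_seq, contig, b, params)
            assert (hit is None) == (oracle is None)
            if hit is not None:
                n_hits += 1
                assert hit.mismatches == oracle[0]
                assert hit.contig_start == oracle[1]
        assert n_hits > 25  # the sweep exercised real hits, not only rejections

    @settings(
        max_examples=150,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    )
    @given(data=st.data())
    def test_oracle_equivalence_property(self, data):
        contig = data.draw(
            st.text(alphabet="ACGT", min_size=20, max_size=120), label="contig"
        )
        b = data.draw(st.integers(1, len(contig) - 1), label="breakpoint")
        read = data.draw(
            st.text(alphabet="ACGTN", min_size=6, max_size=60), label="read"
        )
        params = ScanParams(
            min_overhang=data.draw(st.integers(1, 12)),
            max_mismatches=data.draw(st.integers(0, 3)),
            min_aligned_fraction=data.draw(
                st.floats(0.1, 1.0, allow_nan=False, allow_infinity=False)
            ),
            both_orientations=data.draw(st.booleans()),
        )
        junction = make_junction(contig, b)
        hit = scan_read(ReadRecord("r", 1, read), junction, params)
        oracle = brute_force_scan(read, contig, b, params)
        assert (hit is None) == (oracle is None)
        if hit is not None:
            assert (hit.mismatches, hit.contig_start) == oracle[:2]

    def test_tightening_parameters_never_adds_hits(self, junction):
        """Raising min_overhang or lowering max_mismatches is monotone."""
        rng = np.random.default_rng(11)
        b = junction.breakpoint_offset
        reads = []
        for i in range(200):
            p = int(rng.integers(b - 99, b))
            window = list(junction.contig[max(p, 0) : max(p, 0) + 100])
            for _ in range(int(rng.integers(0, 5))):
                window[int(rng.integers(0, len(window)))] = "ACGT"[
                    int(rng.integers(0, 4))
                ]
            reads.append(ReadRecord(f"r{i}", 1, "".join(window)))

        def n_hits(params):
            return sum(scan_read(r, junction, params) is not None for r in reads)

        base = ScanParams(min_overhang=5, max_mismatches=4)
        assert (
            n_hits(ScanParams(min_overhang=15, max_mismatches=4))
            <= n_hits(base)
        )
        assert (
            n_hits(ScanParams(min_overhang=5, max_mismatches=1))
            <= n_hits(base)
        )


class TestScanFastq:
    def test_single_spanning_read_yields_one_hit(self, tmp_path, junction):
        b = junction.breakpoint_offset
        rng = np.random.default_rng(3)
        write_fastq(
            tmp_path / "r1.fastq",
            [("frag0/1", junction.contig[b - 50 : b + 50]), ("frag1/1", random_dna(rng, 100))],
        )
        write_fastq(
            tmp_path / "r2.fastq",
            [("frag0/2", random_dna(rng, 100)), ("frag1/2", random_dna(rng, 100))],
        )
        hits, stats = scan_fastq(
            tmp_path / "r1.fastq", tmp_path / "r2.fastq", [junction]
        )
        assert stats.reads_scanned == 4
        assert len(hits) == 1
        assert hits[0].read_id == "frag0" and hits[0].mate == 1

    def test_empty_fastq_pair_yields_nothing(self, tmp_path, junction):
        write_fastq(tmp_path / "r1.fastq", [])
        write_fastq(tmp_path / "r2.fastq", [])
        hits, stats = scan_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq", [junction])
        assert hits == [] and stats.reads_scanned == 0

    def test_desynchronized_mates_raise(self, tmp_path, junction):
        write_fastq(tmp_path / "r1.fastq", [("a/1", "ACGT" * 25), ("b/1", "ACGT" * 25)])
        write_fastq(tmp_path / "r2.fastq", [("b/2", "ACGT" * 25), ("a/2", "ACGT" * 25)])
        with pytest.raises(FastqFormatError, match="desynchronized"):
            scan_fastq(tmp_path / "r1.fastq", tmp_path / "r2.fastq", [junction])

    def test_agrees_with_simulator_truth_at_zero_error_rate(
        self, tmp_path, reference
    ):
        """Every truth-labelled spanning fragment with both overhangs >= 10
        is recovered, and no non-spanning fragment produces a hit."""
        cfg = sample_config(
            reference, n_fragments=20000, fusion_fraction=0.05, seed=42, error_rate=0.0
        )
        sim = simulate_sample(cfg, tmp_path / "truthtest", gzip_output=False)
        hits, _ = scan_fastq(
            sim.fastq1_path, sim.fastq2_path, reference.junctions, ScanParams()
        )
        import pandas as pd

        truth = pd.read_csv(sim.truth_path, sep="\t")
        covered = (
            (truth["read1_overhang5"] >= 10) & (truth["read1_overhang3"] >= 10)
        ) | ((truth["read2_overhang5"] >= 10) & (truth["read2_overhang3"] >= 10))
        expected = set(truth.loc[covered.fillna(False), "fragment_id"])
        assert len(expected) > 20
        jid = cfg.fusion_name
        observed = {h.read_id for h in hits if h.junction_id == jid}
        assert observed == expected
        spanning = set(truth.loc[truth["spans_junction"], "fragment_id"])
        assert {h.read_id for h in hits} <= spanning

    def test_two_runs_produce_byte_identical_hit_tsvs(self, tmp_path, reference):
        cfg = sample_config(
            reference, n_fragments=5000, fusion_fraction=0.05, seed=5
        )
        sim = simulate_sample(cfg, tmp_path / "det", gzip_output=False)
        paths = []
        for run in (1, 2):
            hits, _ = scan_fastq(
                sim.fastq1_path, sim.fastq2_path, reference.junctions
            )
            out = tmp_path / f"hits{run}.tsv"
            write_hits_tsv(hits, out)
            paths.append(out)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_wildtype_counter_evidence_rejects_equally_explained_reads(
        self, tmp_path, reference
    ):
        """A breakpoint-matching read that a supplied wildtype transcript
        explains at least as well is not counted as fusion evidence."""
        rng = np.random.default_rng(99)
        junction = reference.fusion_junction((16, 9))
        b = junction.breakpoint_offset
        read = junction.contig[b - 90 : b + 10]  # passes the bare contract
        write_fastq(tmp_path / "w1.fastq", [("w0/1", read)])
        write_fastq(tmp_path / "w2.fastq", [("w0/2", "ACGT" * 25)])
        unrelated_decoy = random_dna(rng, 2000)
        hits_kept, _ = scan_fastq(
            tmp_path / "w1.fastq",
            tmp_path / "w2.fastq",
            [junction],
            decoys=[unrelated_decoy],
        )
        assert len(hits_kept) == 1
        # a transcript containing the read verbatim explains it perfectly
        explaining_decoy = random_dna(rng, 500) + read + random_dna(rng, 500)
        hits_dropped, stats = scan_fastq(
            tmp_path / "w1.fastq",
            tmp_path / "w2.fastq",
            [junction],
            decoys=[unrelated_decoy, explaining_decoy],
        )
        assert hits_dropped == []
        assert stats.hits_rejected_wildtype == 1

    def test_true_spanning_read_survives_wildtype_counter_evidence(
        self, tmp_path, reference
    ):
        junction = reference.fusion_junction((16, 9))
        b = junction.breakpoint_offset
        write_fastq(tmp_path / "t1.fastq", [("t0/1", junction.contig[b - 50 : b + 50])])
        write_fastq(tmp_path / "t2.fastq", [("t0/2", "ACGT" * 25)])
        hits, _ = scan_fastq(
            tmp_path / "t1.fastq",
            tmp_path / "t2.fastq",
            [junction],
            decoys=[m.spliced_seq for m in reference.models.values()],
        )
        assert len(hits) == 1


class TestFragmentSupport:
    def test_both_mates_of_one_fragment_count_once(self, junction):
        from junctionscan.scanner import JunctionHit

        hits = [
            JunctionHit("F", 1, junction.junction_id, 180, 100, 0, 20, 80, "forward"),
            JunctionHit("F", 2, junction.junction_id, 150, 100, 1, 50, 50, "revcomp"),
        ]
        (support,) = compute_fragment_support(hits)
        assert support.support == 1

    def test_distinct_fragments_accumulate(self, junction):
        from junctionscan.scanner import JunctionHit

        hits = [
            JunctionHit("F1", 1, junction.junction_id, 180, 100, 0, 20, 80, "forward"),
            JunctionHit("F2", 2, junction.junction_id, 150, 100, 1, 50, 50, "forward"),
        ]
        (support,) = compute_fragment_support(hits)
        assert support.support == 2

    def test_empty_hit_list_gives_empty_support(self):
        assert compute_fragment_support([]) == []

    def test_requested_junctions_include_zero_support_rows(self, junction):
        supports = compute_fragment_support([], [junction.junction_id, "X:Y|e1:e1"])
        assert [(s.junction_id, s.support) for s in supports] == [
            (junction.junction_id, 0),
            ("X:Y|e1:e1", 0),
        ]
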