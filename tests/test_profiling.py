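"""Mutation parser and counter, checked against a brute-force oracle."""

import numpy as np
import pytest

from icshapemap import profiling, simulate
from icshapemap.profiling import MutationEvent, parse_read_mutations
from icshapemap.simulate import SimulatedRead


def read_from_cigar(cigar: str, seq: str, ref_start: int = 0,
                    name: str = "r", mapq: int = 60,
                    flag: int = 0) -> SimulatedRead:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((SimulatedRead.CIGAR_OPS[ch], int(num)))
            num = ""
    return SimulatedRead(name, "ref", ref_start, ops, seq, mapq, flag)


# ---------------------------------------------------------------------------
# independent oracle: column-walk re-implementation of the parser


def oracle_events(read, reference, merge_spacer=2):
    """Brute-force re-derivation of classified events via alignment columns."""
    reference = reference.upper().replace("U", "T")  # SAM alphabet: T == U
    query = read.query_sequence.upper().replace("U", "T")
    prims = []  # (kind, ref_start, ref_end, bases)
    rpos, qpos = read.reference_start, 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            for k in range(ln):
                rb, qb = reference[rpos + k], query[qpos + k]
                if rb != qb:
                    prims.append(["mismatch", rpos + k + 1, rpos + k + 1, qb])
            rpos += ln
            qpos += ln
        elif op == 2:
            s, e = rpos + 1, rpos + ln
            while e < len(reference) and reference[s - 1] == reference[e]:
                s, e = s + 1, e + 1
            prims.append(["deletion", s, e, ""])
            rpos += ln
        elif op == 1:
            anchor = max(rpos, 1)
            prims.append(["insertion", anchor, anchor,
                          query[qpos:qpos + ln]])
            qpos += ln
        elif op == 4:
            qpos += ln
    prims.sort(key=lambda p: (p[1], p[2]))

    groups = []
    for p in prims:
        if groups and p[1] - groups[-1][-1][2] - 1 <= merge_spacer:
            groups[-1].append(p)
        else:
            groups.append([p])

    events = []
    for g in groups:
        kinds = {p[0] for p in g}
        pos = max(p[2] for p in g)
        bases = "".join(p[3] for p in g)
        span = 0 if kinds == {"insertion"} else pos - min(p[1] for p in g) + 1
        if kinds == {"mismatch"}:
            mtype = "mismatch" if len(g) == 1 else "multi-mismatch"
        elif kinds == {"deletion"}:
            total = sum(p[2] - p[1] + 1 for p in g)
            mtype = "deletion" if len(g) == 1 and total == 1 else "multi-deletion"
        elif kinds == {"insertion"}:
            total = sum(len(p[3]) for p in g)
            mtype = "insertion" if len(g) == 1 and total == 1 else "multi-insertion"
        else:
            ndel = sum(p[2] - p[1] + 1 for p in g if p[0] == "deletion")
            nins = sum(len(p[3]) for p in g if p[0] == "insertion")
            mtype = ("complex-deletion" if ndel > nins
                     else "complex-insertion" if nins > ndel
                     else "multi-mismatch")
        events.append(MutationEvent(pos, mtype, span, bases))
    return events


REF30 = "AGCUAGCUAGGCAUCGAUCGGCUAGCAUGC"


class TestParser:
    def test_perfect_match_no_events(self):
        read = read_from_cigar("30M", REF30)
        assert parse_read_mutations(read, REF30) == []

    def test_single_mismatch(self):
        seq = REF30[:11] + "A" + REF30[12:]  # position 12 is 'C' -> 'A'
        read = read_from_cigar("30M", seq)
        events = parse_read_mutations(read, REF30)
        assert events == [MutationEvent(12, "mismatch", 1, "A")]

    def test_two_nt_deletion_is_multi(self):
        # 5M2D5M against a repeat-free reference segment
        ref = "AGCUGACUGA"
        read = read_from_cigar("5M2D3M", ref[:5] + ref[7:])
        events = parse_read_mutations(read, ref)
        assert len(events) == 1
        assert events[0].mtype == "multi-deletion"
        assert events[0].ref_span == 2
        assert events[0].ref_position == 7  # 3'-most deleted base

    def test_two_mismatches_one_spacer_merge(self):
        # mismatches at 5 and 7 (one matched base between) merge;
        # homogeneous classes merge to multi-mismatch
        seq = REF30[:4] + "G" + REF30[5] + "G" + REF30[7:]
        assert REF30[4] != "G" and REF30[6] != "G"
        events = parse_read_mutations(read_from_cigar("30M", seq), REF30)
        assert events == [MutationEvent(7, "multi-mismatch", 3, "GG")]

    def test_mixed_event_net_loss_is_complex_deletion(self):
        # mismatch at 5 then 2-nt deletion at 7-8: net reference loss
        ref = "AGCUGACUGA"
        seq = ref[:4] + "U" + ref[5] + ref[8:]
        assert ref[4] != "U"
        events = parse_read_mutations(read_from_cigar("6M2D2M", seq), ref)
        assert len(events) == 1
        assert events[0].mtype == "complex-deletion"

    def test_insertion_anchored_5prime(self):
        seq = REF30[:10] + "AA" + REF30[10:]
        events = parse_read_mutations(read_from_cigar("10M2I20M", seq), REF30)
        assert events == [MutationEvent(10, "multi-insertion", 0, "AA")]

    def test_deletion_right_aligned_in_repeat(self):
        ref = "AGAAAAGCUA"  # deleting any of the A-run is equivalent
        read = read_from_cigar("2M1D7M", ref[:2] + ref[3:])
        events = parse_read_mutations(read, ref)
        assert events[0].ref_position == 6  # 3'-most equivalent placement

    def test_events_are_5prime_to_3prime(self):
        seq = "U" + REF30[1:15] + "A" + REF30[16:29] + "U"
        assert REF30[0] != "U" and REF30[15] != "A" and REF30[29] != "U"
        events = parse_read_mutations(read_from_cigar("30M", seq), REF30)
        assert [e.ref_position for e in events] == sorted(
            e.ref_position for e in events)

    def test_cigar_sequence_mismatch_names_read(self):
        read = read_from_cigar("30M", REF30[:20], name="bad_read")
        with pytest.raises(ValueError, match="bad_read"):
            parse_read_mutations(read, REF30)

    def test_spliced_alignment_rejected(self):
        read = read_from_cigar("5M10N5M", REF30[:5] + REF30[15:20])
        with pytest.raises(ValueError, match="spliced"):
            parse_read_mutations(read, REF30)

    def test_softclip_contributes_nothing(self):
        seq = "GGGG" + REF30[:26]
        events = parse_read_mutations(read_from_cigar("4S26M", seq), REF30)
        assert events == []

    def test_idempotent(self):
        seq = REF30[:4] + "G" + REF30[5:10] + REF30[12:]
        read = read_from_cigar("10M2D18M", seq)
        first = parse_read_mutations(read, REF30)
        assert parse_read_mutations(read, REF30) == first


class TestCounting:
    def test_perfect_reads_coverage_only(self):
        ref = "AGCU" * 12 + "GC"  # 50 nt
        reads = [read_from_cigar("50M", ref, name=f"r{i}") for i in range(100)]
        counts = profiling.count_mutations(reads, ref)
        assert np.all(counts.coverage == 100)
        assert np.all(counts.total_events == 0)

    def test_single_event_rate_components(self):
        ref = REF30
        reads = [read_from_cigar("30M", ref, name=f"r{i}") for i in range(9)]
        seq = ref[:6] + "A" + ref[7:]
        assert ref[6] != "A"
        reads.append(read_from_cigar("30M", seq, name="mut"))
        counts = profiling.count_mutations(reads, ref)
        assert counts.total_events[6] == 1
        assert counts.coverage[6] == 10

    def test_excludes_low_mapq_secondary_supplementary(self):
        ref = REF30
        reads = [
            read_from_cigar("30M", ref, mapq=0),
            read_from_cigar("30M", ref, flag=0x100),
            read_from_cigar("30M", ref, flag=0x800),
            read_from_cigar("30M", ref, flag=0x4),
            read_from_cigar("30M", ref),
        ]
        counts = profiling.count_mutations(reads, ref)
        assert np.all(counts.coverage == 1)

    def test_empty_read_set_zero_counts(self):
        counts = profiling.count_mutations([], REF30)
        assert np.all(counts.coverage == 0)
        assert np.all(counts.total_events == 0)

    def test_coverage_conservation(self, small_spec, small_hairpins):
        name, seq, db = small_hairpins[0]
        reads = simulate.simulate_map_reads(seq, db, small_spec, "NAI",
                                            name=name)
        counts = profiling.count_mutations(reads, seq, name)
        aligned = sum(sum(ln for op, ln in r.cigartuples if op in (0, 2))
                      for r in reads)
        assert int(counts.coverage.sum()) == aligned

    def test_counts_match_per_read_oracle(self, small_spec, small_hairpins):
        name, seq, db = small_hairpins[1]
        spec = simulate.SimSpec(n_transcripts=1, stem_len=6, loop_len=4,
                                mod_rate_ss=0.2, mod_rate_ds=0.05,
                                background_rate=0.05, depth=300, seed=8)
        reads = simulate.simulate_map_reads(seq, db, spec, "NAI", name=name)
        counts = profiling.count_mutations(reads, seq, name)
        expected = np.zeros(len(seq), dtype=int)
        for read in reads:
            for ev in oracle_events(read, seq):
                expected[ev.ref_position - 1] += 1
        assert np.array_equal(counts.total_events, expected)


class TestSamRoundTrip:
    def test_rna_references_survive_dna_sam_encoding(self, tmp_path):
        """SAM stores read bases in the DNA alphabet; U/T must not be
        counted as mismatches after a write/read round trip."""
        spec = simulate.SimSpec(mod_rate_ss=0.0, mod_rate_ds=0.0,
                                background_rate=0.0, depth=20, seed=0)
        seq, db = "UUUGGGGAAAACCCCUUU", "...((((....))))..."
        reads = simulate.simulate_map_reads(seq, db, spec, "NAI", name="rna")
        sam = tmp_path / "reads.sam"
        simulate.write_sam(sam, {"rna": seq}, reads)
        counts = profiling.count_mutations_sam(sam, {"rna": seq})["rna"]
        assert np.all(counts.coverage == 20)
        assert np.all(counts.total_events == 0)


class TestOracleEquivalence:
    def test_parser_matches_oracle_on_simulated_reads(self):
        """Event lists equal the independent column-walk on >=1000 reads
        drawn at exaggerated rates so indels and merges are frequent."""
        spec = simulate.SimSpec(n_transcripts=4, stem_len=12, loop_len=6,
                                mod_rate_ss=0.25, mod_rate_ds=0.10,
                                background_rate=0.05, depth=300, seed=77)
        total = 0
        for name, seq, db in simulate.make_hairpin_set(spec):
            for cond in ("NAI", "DMSO"):
                for read in simulate.simulate_map_reads(seq, db, spec, cond,
                                                        name=name):
                    assert parse_read_mutations(read, seq) \
                        == oracle_events(read, seq)
                    total += 1
        assert total >= 1000

    def test_all_eight_classes_reachable(self):
        """Hand-built reads produce every one of the 8 event classes."""
        ref = "AGCUGACUGACUGGCAUCAG"
        cases = {
            "mismatch": read_from_cigar("20M", "C" + ref[1:]),
            "insertion": read_from_cigar("5M1I15M", ref[:5] + "A" + ref[5:]),
            "deletion": read_from_cigar("5M1D14M", ref[:5] + ref[6:]),
            "multi-mismatch": read_from_cigar(
                "20M", "CC" + ref[2:]) if ref[0] != "C" else None,
            "multi-insertion": read_from_cigar("5M2I15M",
                                               ref[:5] + "AA" + ref[5:]),
            "multi-deletion": read_from_cigar("5M2D13M", ref[:5] + ref[7:]),
            "complex-deletion": read_from_cigar(
                "4M2D1M1I13M", ref[:4] + ref[6] + "U" + ref[7:]),
            "complex-insertion": read_from_cigar(
                "4M1D1M2I14M", ref[:4] + ref[5] + "UU" + ref[6:]),
        }
        for expected, read in cases.items():
            events = parse_read_mutations(read, ref)
            assert len(events) == 1, expected
            assert events[0].mtype == expected
            assert events == oracle_events(read, ref), expected


class TestMutationRate:
    def test_rate_arithmetic(self):
        counts = profiling.MutationCounts("t", 3)
        counts.coverage = np.array([100, 400, 100])
        counts.counts["mismatch"] = np.array([5, 0, 2])
        counts.counts["deletion"] = np.array([0, 0, 1])
        rate = profiling.mutation_rate(counts, min_coverage=1)
        assert rate[0] == pytest.approx(0.05)
        assert rate[2] == pytest.approx(0.03)

    def test_low_coverage_masked(self):
        counts = profiling.MutationCounts("t", 2)
        counts.coverage = np.array([400, 600])
        rate = profiling.mutation_rate(counts, min_coverage=500)
        assert np.isnan(rate[0]) and not np.isnan(rate[1])
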