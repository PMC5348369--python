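import random

import pysam
import pytest
from hypothesis import given, settings, strategies as st

from backsplice.detect import (
    AnchorAlignment,
    CircCandidate,
    KmerIndex,
    UnmappedRead,
    align_anchor,
    detect_head_to_tail,
    detect_sample,
    extract_unmapped,
    make_anchors,
    quantify,
    refine_breakpoint,
)
from backsplice.reference import Genome, GenomicInterval, reverse_complement
from backsplice.simulate import make_genome, plant_circles, simulate_reads


def write_sam(path, genome_lengths, records):
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(genome_lengths.items())],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, seq, ref_id, pos in records:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = name
            rec.flag = flag
            rec.query_sequence = seq
            if ref_id >= 0:
                rec.reference_id = ref_id
                rec.reference_start = pos
                rec.cigarstring = f"{len(seq)}M"
            out.write(rec)


class TestExtractUnmapped:
    def test_mixed_mapped_unmapped(self, tmp_path):
        path = tmp_path / "a.sam"
        write_sam(
            path,
            {"chr1": 1000},
            [
                ("m1", 0, "ACGT" * 10, 0, 10),
                ("m2", 0, "ACGT" * 10, 0, 50),
                ("m3", 16, "ACGT" * 10, 0, 90),
                ("u1", 4, "ACGT" * 10, -1, -1),
                ("u2", 4, "TTTT" * 10, -1, -1),
            ],
        )
        reads, n = extract_unmapped(path)
        assert n == 2
        assert [r.read_id for r in reads] == ["u1", "u2"]
        assert all(r.mate_index == 0 for r in reads)

    def test_paired_mate2_unmapped(self, tmp_path):
        path = tmp_path / "b.sam"
        # flag 0x1|0x8? -- mate1 mapped, mate2 unmapped: 0x1 paired + 0x80 read2 + 0x4
        write_sam(
            path,
            {"chr1": 1000},
            [
                ("p1", 0x1 | 0x40, "ACGT" * 10, 0, 10),
                ("p1", 0x1 | 0x80 | 0x4, "GGGG" * 10, -1, -1),
            ],
        )
        reads, n = extract_unmapped(path)
        assert n == 1
        assert reads[0].mate_index == 2

    def test_header_only(self, tmp_path):
        path = tmp_path / "c.sam"
        write_sam(path, {"chr1": 1000}, [])
        reads, n = extract_unmapped(path)
        assert reads == [] and n == 0


class TestMakeAnchors:
    def test_fifty_nt_read(self):
        read = UnmappedRead("r", "A" * 20 + "C" * 10 + "G" * 20)
        five, three = make_anchors(read)
        assert five == "A" * 20 and three == "G" * 20

    def test_forty_nt_read_partitions(self):
        read = UnmappedRead("r", "A" * 20 + "G" * 20)
        five, three = make_anchors(read)
        assert five + three == read.sequence

    def test_short_read_skipped(self):
        assert make_anchors(UnmappedRead("r", "A" * 39)) is None


def brute_force_scan(genome: Genome, anchor: str):
    """Independent oracle: scan both strands of every chromosome."""
    hits = []
    rc = reverse_complement(anchor)
    for chrom in sorted(genome.sequences):
        seq = genome.sequences[chrom]
        k = len(anchor)
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if window == anchor:
                hits.append((chrom, i + 1, "+"))
            if rc != anchor and window == rc:
                hits.append((chrom, i + 1, "-"))
    return sorted(hits)


@pytest.fixture(scope="module")
def anchor_genome():
    rng = random.Random(42)
    seq = "".join(rng.choice("ACGT") for _ in range(3_000))
    return Genome({"chrA": seq, "chrB": seq[:100] + seq})  # shared prefix


class TestAlignAnchor:

    def test_matches_brute_force_scan(self, anchor_genome):
        index = KmerIndex(anchor_genome, 20)
        rng = random.Random(7)
        for _ in range(25):
            chrom = rng.choice(["chrA", "chrB"])
            pos = rng.randrange(len(anchor_genome.sequences[chrom]) - 20)
            anchor = anchor_genome.sequences[chrom][pos : pos + 20]
            if rng.random() < 0.5:
                anchor = reverse_complement(anchor)
            got = [(a.chrom, a.start, a.strand) for a in align_anchor(anchor, index)]
            assert got == brute_force_scan(anchor_genome, anchor)

    def test_n_containing_anchor_never_aligns(self, anchor_genome):
        index = KmerIndex(anchor_genome, 20)
        anchor = anchor_genome.sequences["chrA"][:19] + "N"
        assert align_anchor(anchor, index) == []

    def test_deterministic_order(self, anchor_genome):
        index = KmerIndex(anchor_genome, 20)
        anchor = anchor_genome.sequences["chrB"][:20]
        hits = align_anchor(anchor, index)
        assert hits == sorted(hits, key=lambda a: (a.chrom, a.start, a.strand))


def aln(chrom, start, end, strand, which):
    return AnchorAlignment(chrom, start, end, strand, which)


class TestDetectHeadToTail:
    def test_back_splice_order_gives_seed(self):
        seeds = detect_head_to_tail(
            [aln("chr1", 261, 280, "+", "five_prime")],
            [aln("chr1", 101, 120, "+", "three_prime")],
        )
        assert len(seeds) == 1
        assert seeds[0].chrom == "chr1" and seeds[0].strand == "+"

    def test_collinear_order_rejected(self):
        assert (
            detect_head_to_tail(
                [aln("chr1", 101, 120, "+", "five_prime")],
                [aln("chr1", 261, 280, "+", "three_prime")],
            )
            == []
        )

    def test_different_chromosomes_rejected(self):
        assert (
            detect_head_to_tail(
                [aln("chr2", 261, 280, "+", "five_prime")],
                [aln("chr1", 101, 120, "+", "three_prime")],
            )
            == []
        )

    def test_multimapping_anchor_rejected(self):
        five = [
            aln("chr1", 261, 280, "+", "five_prime"),
            aln("chr1", 900, 919, "+", "five_prime"),
        ]
        assert detect_head_to_tail(five, [aln("chr1", 101, 120, "+", "three_prime")]) == []

    def test_span_cap(self):
        seeds = detect_head_to_tail(
            [aln("chr1", 300_000, 300_019, "+", "five_prime")],
            [aln("chr1", 101, 120, "+", "three_prime")],
            max_span=100_000,
        )
        assert seeds == []

    def test_minus_strand_order_reversed(self):
        # on '-', the read-5' (head) anchor must lie upstream
        seeds = detect_head_to_tail(
            [aln("chr1", 101, 120, "-", "five_prime")],
            [aln("chr1", 261, 280, "-", "three_prime")],
        )
        assert len(seeds) == 1
        assert (
            detect_head_to_tail(
                [aln("chr1", 261, 280, "-", "five_prime")],
                [aln("chr1", 101, 120, "-", "three_prime")],
            )
            == []
        )


def build_junction_genome(rng, s=301, e=600, length=1_000, signals=("AG", "GT")):
    seq = [rng.choice("ACGT") for _ in range(length)]
    seq[s - 3 : s - 1] = signals[0]
    seq[e : e + 2] = signals[1]
    # block breakpoint sliding
    seq[s - 1] = "A" if signals[1][0] != "A" else "T"
    seq[e - 1] = seq[s - 1]
    return Genome({"chr1": "".join(seq)})


def junction_read(genome, s, e, b, read_len=50):
    seq = genome.sequences["chr1"]
    return seq[e - b : e] + seq[s - 1 : s - 1 + read_len - b]


def brute_force_breakpoints(genome, read_seq, anchor_len=20):
    """Enumerate every (b, s, e) with a full-read exact match and AG/GT signals."""
    seq = genome.sequences["chr1"]
    n = len(read_seq)
    out = []
    for b in range(anchor_len, n - anchor_len + 1):
        left, right = read_seq[:b], read_seq[b:]
        for e in range(b, len(seq) + 1):  # e = 1-based end of left match
            if seq[e - b : e] != left:
                continue
            for s in range(1, len(seq) - len(right) + 2):
                if seq[s - 1 : s - 1 + len(right)] != right:
                    continue
                if s >= e or s < 3 or e + 2 > len(seq):
                    continue
                if seq[s - 3 : s - 1] == "AG" and seq[e : e + 2] == "GT":
                    out.append((b, s, e))
    return out


class TestRefineBreakpoint:
    def seed_for(self, genome, read_seq, index):
        five = align_anchor(read_seq[:20], index, "five_prime")
        three = align_anchor(read_seq[-20:], index, "three_prime")
        seeds = detect_head_to_tail(five, three)
        assert len(seeds) == 1
        return seeds[0]

    def test_planted_junction_recovered(self):
        rng = random.Random(11)
        genome = build_junction_genome(rng)
        read_seq = junction_read(genome, 301, 600, b=25)
        index = KmerIndex(genome, 20)
        seed = self.seed_for(genome, read_seq, index)
        cand = refine_breakpoint(seed, UnmappedRead("r1", read_seq), genome)
        assert cand is not None
        assert (cand.interval.start, cand.interval.end) == (301, 600)
        assert cand.splice_signal

    def test_no_signal_returns_none(self):
        rng = random.Random(12)
        genome = build_junction_genome(rng, signals=("TT", "CC"))
        read_seq = junction_read(genome, 301, 600, b=25)
        index = KmerIndex(genome, 20)
        seed = self.seed_for(genome, read_seq, index)
        assert refine_breakpoint(seed, UnmappedRead("r1", read_seq), genome) is None

    def test_ambiguous_breakpoint_takes_smallest_offset(self):
        # A junction can slide by 4 bases when a GTAG micro-homology follows
        # both the circle start and the circle end: both (s, e) and
        # (s+4, e+4) then carry valid AG/GT signals for the same read.
        rng = random.Random(13)
        s, e = 301, 600
        seq = [rng.choice("ACGT") for _ in range(1_000)]
        seq[s - 3 : s - 1] = "AG"
        seq[s - 1 : s + 3] = "GTAG"
        seq[e : e + 4] = "GTAG"
        seq[e + 4 : e + 6] = "GT"
        genome = Genome({"chr1": "".join(seq)})
        read_seq = junction_read(genome, s, e, b=25)
        all_bps = brute_force_breakpoints(genome, read_seq)
        assert {(25, s, e), (29, s + 4, e + 4)} <= set(all_bps)
        index = KmerIndex(genome, 20)
        seed = self.seed_for(genome, read_seq, index)
        cand = refine_breakpoint(seed, UnmappedRead("r1", read_seq), genome)
        b_min, s_min, e_min = min(all_bps)
        assert (cand.interval.start, cand.interval.end) == (s_min, e_min) == (s, e)

    def test_agrees_with_exhaustive_enumeration(self):
        rng = random.Random(17)
        for trial in range(10):
            genome = build_junction_genome(rng, s=201, e=520, length=800)
            b = rng.randrange(20, 31)
            read_seq = junction_read(genome, 201, 520, b=b)
            index = KmerIndex(genome, 20)
            seed = self.seed_for(genome, read_seq, index)
            cand = refine_breakpoint(seed, UnmappedRead("r", read_seq), genome)
            oracle = brute_force_breakpoints(genome, read_seq)
            assert oracle, "fixture must admit at least the planted breakpoint"
            b_min, s_min, e_min = min(oracle)
            assert cand is not None
            assert (cand.interval.start, cand.interval.end) == (s_min, e_min)


def cand(chrom, start, end, strand, ids):
    return CircCandidate(GenomicInterval(chrom, start, end, strand), set(ids))


class TestQuantify:
    def test_merges_identical_junctions(self):
        cands = [cand("chr1", 100, 400, "+", {f"r{i}"}) for i in range(7)]
        (merged,) = quantify(cands)
        assert merged.support == 7

    def test_read_id_counted_once(self):
        cands = [cand("chr1", 100, 400, "+", {"r1"}), cand("chr1", 100, 400, "+", {"r1"})]
        (merged,) = quantify(cands)
        assert merged.support == 1

    def test_distinct_junctions_kept_apart(self):
        cands = [cand("chr1", 100, 400, "+", {"a"}), cand("chr1", 100, 401, "+", {"b"})]
        assert len(quantify(cands)) == 2

    @given(st.permutations(list(range(6))))
    @settings(max_examples=20, deadline=None)
    def test_order_independent_and_idempotent(self, perm):
        base = [
            cand("chr1", 100, 400, "+", {"a"}),
            cand("chr1", 100, 400, "+", {"b"}),
            cand("chr2", 50, 90, "-", {"c"}),
            cand("chr1", 100, 401, "+", {"a"}),
            cand("chr1", 100, 400, "+", {"a"}),
            cand("chr2", 50, 90, "-", {"d"}),
        ]
        reference = quantify(base)
        permuted = quantify([base[i] for i in perm])
        as_tuples = lambda cs: [(c.key, frozenset(c.supporting_read_ids)) for c in cs]
        assert as_tuples(permuted) == as_tuples(reference)
        assert as_tuples(quantify(permuted)) == as_tuples(reference)


class TestPlantedRecovery:
    def test_exact_recovery_before_filtering(self, default_fixture):
        genome, truth, reads = default_fixture
        cands, _ = detect_sample(
            [UnmappedRead(rid, seq) for rid, seq in reads], genome
        )
        got = {(c.key, c.support) for c in cands}
        expected = {
            (
                (t.interval.chrom, t.interval.start, t.interval.end, t.interval.strand),
                t.n_reads,
            )
            for t in truth.circles
        }
        assert got == expected

    def test_linear_reads_yield_nothing(self, default_fixture):
        genome, truth, reads = default_fixture
        linear = [UnmappedRead(rid, seq) for rid, seq in reads if rid.startswith("lin")]
        assert len(linear) == 1_000
        cands, stats = detect_sample(linear, genome)
        assert cands == []
        assert stats["supporting"] == 0

    def test_strand_symmetry(self):
        plus = plant_circles(
            make_genome(31, 1, 50_000), 5, (80, 2_000), strand_mix=0.0, seed=32
        )
        minus = plant_circles(
            make_genome(31, 1, 50_000), 5, (80, 2_000), strand_mix=1.0, seed=32
        )
        coords = lambda truth: {
            (c.interval.chrom, c.interval.start, c.interval.end)
            for c in truth[1].circles
        }
        assert coords(plus) == coords(minus)
        results = {}
        for label, (genome, truth) in (("plus", plus), ("minus", minus)):
            reads = simulate_reads(genome, truth, seed=33)
            cands, _ = detect_sample(
                [UnmappedRead(r, s) for r, s in reads], genome
            )
            results[label] = {c.key for c in cands}
        flip = {
            (c, s, e, {"+": "-", "-": "+"}[st_]) for c, s, e, st_ in results["plus"]
        }
        assert results["minus"] == flip
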