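"""Tag detection/trimming, fragment mapping, SAM round trips, length filter."""

import numpy as np
import pytest

from oracles import oracle_map
from petag.genome import Genome
from petag.pegrna import DEFAULT_FULL_TAG, GenomeLocus
from petag.readproc import (
    KmerIndex,
    ReadMapping,
    default_tag_queries,
    detect_tag,
    detect_tag_all,
    filter_mappings,
    ingest_sam,
    map_fragment,
    trim_tag,
    write_sam,
)
from petag.sequtil import revcomp

SENSE_Q = "GTTTAATTGAGTTGTCATATGT"
ANTISENSE_Q = "TACCGTTATTAACATATGACAACTCAA"


def random_genome(seed, n, name="chr1"):
    rng = np.random.default_rng(seed)
    return Genome({name: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))})


class TestDetectTag:
    def test_sense_query_hit(self):
        read = "ACGT" * 5 + SENSE_Q + "TTGACCA"
        hit = detect_tag(read)
        assert hit is not None
        assert hit.library_orientation == "sense"
        assert read[slice(*hit.tag_span)] == SENSE_Q

    def test_antisense_query_hit(self):
        read = "CCA" * 6 + ANTISENSE_Q + "GGATC" * 4
        hit = detect_tag(read)
        assert hit is not None
        assert hit.library_orientation == "antisense"

    def test_homopolymer_read_has_no_tag(self):
        assert detect_tag("A" * 80) is None

    def test_read_shorter_than_queries(self):
        assert detect_tag("ACGTACGT") is None

    def test_longest_query_wins_on_full_tag(self):
        read = "C" * 20 + DEFAULT_FULL_TAG + "G" * 20
        hit = detect_tag(read)
        # both sense (22 nt) and antisense (27 nt) queries occur; longest wins
        assert len(SENSE_Q) < hit.tag_span[1] - hit.tag_span[0]

    def test_all_hits_reports_both_sides(self):
        read = "C" * 20 + DEFAULT_FULL_TAG + "G" * 20
        hits = detect_tag_all(read)
        assert {h.junction_side for h in hits} == {"left", "right"}

    def test_hamming_tolerance(self):
        mutated = SENSE_Q[:5] + ("A" if SENSE_Q[5] != "A" else "C") + SENSE_Q[6:]
        read = "T" * 10 + mutated + "T" * 10
        assert detect_tag(read, max_hamming=0) is None
        assert detect_tag(read, max_hamming=1) is not None

    def test_simulator_planted_tags_all_found(self, small_sim, pegrna):
        """Noise-free planted tag reads are detected completely."""
        import dataclasses

        from petag.simulate import example_target, make_genome, simulate_tape_reads

        peg, block, off = example_target()
        sim = dataclasses.replace(
            small_sim, error_rate=0.0, background_read_fraction=0.0
        )
        rng = np.random.default_rng(5)
        genome, planted = make_genome(peg, sim, rng=rng,
                                      on_target_block=block, on_target_proto_offset=off)
        reads, truth = simulate_tape_reads(genome, planted, peg, sim, rng=rng)
        assert all(detect_tag(seq) is not None for _, seq in reads)


class TestTrimTag:
    def test_tag_in_middle_keeps_declared_flank(self):
        left, right = "ACCGTTAGAC", "TTGGAACCTA"
        read = left + DEFAULT_FULL_TAG + right
        hit = detect_tag(read)
        fragment, side = trim_tag(read, hit)
        assert (fragment, side) in {(left, "left"), (right, "right")}

    def test_partial_tag_span_extended_before_trimming(self):
        # read covers the full tag; the 22-nt sense query must not leave
        # residual tag bases in the fragment
        left, right = "ACCGTTAGAC", "TTGGAACCTA"
        read = left + DEFAULT_FULL_TAG + right
        sense_only = [q for q in default_tag_queries() if q.name == "sense_fwd"]
        hit = detect_tag(read, sense_only)
        fragment, side = trim_tag(read, hit)
        assert side == "left" and fragment == left

    def test_tag_at_read_start(self):
        read = SENSE_Q + "GATTACAGATTACAGATTACA"
        hit = detect_tag(read)
        out = trim_tag(read, hit)
        if hit.junction_side == "left":
            assert out is None  # empty flank on the junction side
        else:
            assert out == ("GATTACAGATTACAGATTACA", "right")

    def test_simulator_round_trip(self):
        flank = "GATCCTGAAGTCCGATTACA"
        read = flank + DEFAULT_FULL_TAG
        sense_only = [q for q in default_tag_queries() if q.name == "sense_fwd"]
        fragment, side = trim_tag(read, detect_tag(read, sense_only))
        assert fragment == flank and side == "left"


class TestMapFragment:
    def test_exact_unique_substring(self):
        g = random_genome(1, 3000)
        idx = KmerIndex(g)
        frag = g["chr1"][500:560]
        m = map_fragment(frag, idx)
        assert m is not None and m.is_unique
        assert (m.locus.start, m.locus.end, m.locus.strand) == (500, 560, "+")
        assert m.n_mismatch == 0 and m.mapped_length == 60

    def test_two_planted_substitutions(self):
        g = random_genome(2, 3000)
        idx = KmerIndex(g)
        frag = list(g["chr1"][800:860])
        for p in (10, 40):
            frag[p] = "A" if frag[p] != "A" else "C"
        m = map_fragment("".join(frag), idx)
        assert m is not None and m.locus.start == 800 and m.n_mismatch == 2

    def test_duplicated_fragment_not_unique(self):
        core = random_genome(3, 400)["chr1"]
        g = Genome({"c": core + core})
        m = map_fragment(core[50:100], KmerIndex(g))
        assert m is not None and not m.is_unique

    def test_reverse_strand_fragment(self):
        g = random_genome(4, 2000)
        idx = KmerIndex(g)
        m = map_fragment(revcomp(g["chr1"][300:350]), idx)
        assert m is not None and m.locus.strand == "-" and m.locus.start == 300

    def test_non_acgtn_rejected(self):
        g = random_genome(5, 500)
        with pytest.raises(ValueError):
            map_fragment("ACGU" * 10, KmerIndex(g))

    def test_junction_on_tag_side(self):
        g = random_genome(6, 2000)
        idx = KmerIndex(g)
        frag = g["chr1"][700:760]
        assert map_fragment(frag, idx, tag_end="L").junction == 700
        assert map_fragment(frag, idx, tag_end="R").junction == 760
        rc = revcomp(frag)
        assert map_fragment(rc, idx, tag_end="L").junction == 760
        assert map_fragment(rc, idx, tag_end="R").junction == 700

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence(self, seed):
        """Seeded mapper agrees with the all-positions Hamming scan."""
        g = random_genome(seed + 30, 2500)
        rng = np.random.default_rng(seed)
        for _ in range(25):
            start = int(rng.integers(0, 2400))
            ln = int(rng.integers(25, 80))
            frag = list(g["chr1"][start : start + ln])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, len(frag)))
                frag[p] = "ACGT"[rng.integers(0, 4)]
            query = "".join(frag)
            if rng.random() < 0.5:
                query = revcomp(query)
            got = map_fragment(query, KmerIndex(g), max_mismatch=2)
            expected = oracle_map(query, g, max_mm=2)
            if expected is None:
                assert got is None
            else:
                contig, s, strand, mm, unique = expected
                assert got is not None
                assert (got.locus.contig, got.locus.start, got.locus.strand) == (
                    contig, s, strand,
                )
                assert (got.n_mismatch, got.is_unique) == (mm, unique)


class TestSamIO:
    def _mappings(self, g):
        idx = KmerIndex(g)
        out = []
        for i, (start, ln, strand, te) in enumerate(
            [(100, 60, "+", "L"), (400, 45, "+", "R"), (900, 50, "-", "L")]
        ):
            frag = g["chr1"][start : start + ln]
            if strand == "-":
                frag = revcomp(frag)
            m = map_fragment(frag, idx, read_id=f"r{i}", tag_end=te)
            assert m is not None
            out.append(m)
        return out

    def test_own_output_round_trips(self, tmp_path):
        g = random_genome(8, 2000)
        mappings = self._mappings(g)
        path = tmp_path / "m.sam"
        write_sam(mappings, g, path)
        back, counts = ingest_sam(path)
        assert counts["converted"] == len(mappings)
        assert back == mappings

    def test_unmapped_and_supplementary_skipped(self, tmp_path):
        g = random_genome(8, 2000)
        path = tmp_path / "m.sam"
        write_sam(self._mappings(g), g, path)
        text = path.read_text()
        lines = text.splitlines()
        body = [l for l in lines if not l.startswith("@")]
        f = body[0].split("\t")
        unmapped = "\t".join(["u1", "4", "*", "0", "0", "*", "*", "0", "0", "*", "*"])
        supp = body[1].split("\t")
        supp[0], supp[1] = "s1", str(int(supp[1]) | 2048)
        path.write_text("\n".join(lines + [unmapped, "\t".join(supp)]) + "\n")
        back, counts = ingest_sam(path)
        assert counts["unmapped"] == 1 and counts["supplementary"] == 1
        assert len(back) == 3

    def test_missing_header_is_error(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text("r1\t0\tc\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
        with pytest.raises(ValueError):
            ingest_sam(path)


class TestFilterMappings:
    def _mapping(self, length, unique=True):
        return ReadMapping(
            read_id="r", locus=GenomeLocus("c", 0, length, "+"),
            mapped_length=length, n_mismatch=0, is_unique=unique, junction=0,
        )

    def test_length_threshold_boundaries(self):
        kept = filter_mappings([self._mapping(29), self._mapping(30), self._mapping(31)])
        assert [m.mapped_length for m in kept] == [30, 31]

    def test_non_unique_dropped(self):
        assert filter_mappings([self._mapping(50, unique=False)]) == []

    def test_idempotent_and_order_preserving(self):
        ms = [self._mapping(45), self._mapping(33), self._mapping(60)]
        once = filter_mappings(ms)
        assert filter_mappings(once) == once == ms

    def test_empty_input(self):
        assert filter_mappings([]) == []
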