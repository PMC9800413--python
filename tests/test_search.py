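"""Candidate search: oracle equivalence, monotonicity, strand closure, I/O."""

import numpy as np
import pytest

from oracles import oracle_find_candidates, site_records
from petag.genome import Genome
from petag.pegrna import GenomeLocus
from petag.search import (
    CandidateSite,
    annotate_nick,
    collapse_by_nick,
    find_candidates,
    read_sites,
    write_bed,
    write_sites,
)
from petag.sequtil import revcomp

SPACER = "GATTACACGGTAGCCTAAGC"


def random_genome(seed, n, name="chr1"):
    rng = np.random.default_rng(seed)
    return Genome({name: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))})


class TestFindCandidates:
    def test_exact_hit_found_once(self):
        g = Genome({"c": "T" * 40 + SPACER + "AGG" + "T" * 40})
        sites = find_candidates(g, SPACER, "NGG", max_mismatch=0, max_bulge=0)
        assert len(sites) == 1
        (s,) = sites
        assert (s.locus.start, s.locus.end, s.strand) == (40, 60, "+")
        assert (s.n_mismatch, s.n_dna_bulge, s.n_rna_bulge) == (0, 0, 0)
        assert s.pam_seq == "AGG"
        assert s.ungapped_genome() == SPACER

    def test_dna_bulge_instance(self):
        # protospacer with one extra base inside it, intact PAM
        bulged = SPACER[:10] + "T" + SPACER[10:]
        g = Genome({"c": "C" * 30 + bulged + "TGG" + "C" * 30})
        sites = find_candidates(g, SPACER, "NGG", max_mismatch=0, max_bulge=2)
        hit = [s for s in sites if s.n_mismatch == 0]
        assert hit and hit[0].n_dna_bulge == 1 and hit[0].n_rna_bulge == 0

    def test_minus_strand_hit(self):
        g = Genome({"c": "A" * 35 + revcomp(SPACER + "TGG") + "A" * 35})
        sites = find_candidates(g, SPACER, "NGG", max_mismatch=0, max_bulge=0)
        assert any(s.strand == "-" and s.n_mismatch == 0 for s in sites)

    def test_short_spacer_refused(self):
        g = random_genome(0, 200)
        with pytest.raises(ValueError, match="degenerate"):
            find_candidates(g, "ACGTACGTA", "NGG")

    def test_bad_pam_refused(self):
        g = random_genome(0, 200)
        with pytest.raises(ValueError, match="IUPAC"):
            find_candidates(g, SPACER, "NQG")

    def test_ungapped_genome_row_matches_reference(self):
        g = random_genome(3, 1500)
        for s in find_candidates(g, SPACER, "NGG", 4, 1):
            ref = g.fetch(
                s.locus.contig, s.locus.start, s.locus.end, s.strand
            )
            assert s.ungapped_genome() == ref
            assert len(s.aligned_genome) == len(s.aligned_spacer)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_genomes(self, seed):
        """Search equals the exhaustive all-placements oracle on random DNA."""
        n = 600 + 150 * seed
        g = random_genome(seed, n)
        got = site_records(find_candidates(g, SPACER, "NGG", 4, 2))
        expected = oracle_find_candidates(g, SPACER, "NGG", 4, 2)
        assert got == expected

    def test_oracle_equivalence_planted_bulges(self):
        """Constructed mismatch+bulge sites agree with the oracle too."""
        rng = np.random.default_rng(99)
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, size=900))
        variants = [
            SPACER[:7] + "T" + SPACER[8:],                    # 1 mm
            SPACER[:5] + "A" + SPACER[5:],                    # dna bulge
            SPACER[:4] + SPACER[5:],                          # rna bulge
            SPACER[:3] + "GG" + SPACER[3:9] + SPACER[10:],    # 2 dna + 1 rna
        ]
        seq = base
        for i, v in enumerate(variants):
            pos = 120 + 200 * i
            block = v + "TGG" if i % 2 == 0 else revcomp(v + "AGG")
            seq = seq[:pos] + block + seq[pos + len(block) :]
        g = Genome({"c": seq})
        got = site_records(find_candidates(g, SPACER, "NGG", 4, 2))
        expected = oracle_find_candidates(g, SPACER, "NGG", 4, 2)
        assert got == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_monotonicity_in_caps(self, seed):
        g = random_genome(seed + 50, 800)

        def anchors(mm, b):
            return {
                (s.locus.contig, s.strand, s.locus.end if s.strand == "+" else s.locus.start)
                for s in find_candidates(g, SPACER, "NGG", mm, b)
            }

        assert anchors(2, 1) <= anchors(3, 1)
        assert anchors(2, 1) <= anchors(2, 2)
        assert anchors(3, 0) <= anchors(4, 0) <= anchors(4, 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_strand_closure(self, seed):
        """Searching the reverse-complemented genome mirrors the site set."""
        g = random_genome(seed + 70, 700)
        L = len(g["chr1"])
        rc = Genome({"chr1": revcomp(g["chr1"])})
        fwd = site_records(find_candidates(g, SPACER, "NGG", 4, 2))
        rev = site_records(find_candidates(rc, SPACER, "NGG", 4, 2))
        mirrored = {
            (c, "+" if st == "-" else "-", L - e, L - s, mm, nd, nr)
            for (c, st, s, e, mm, nd, nr) in rev
        }
        assert fwd == mirrored


class TestAnnotateNick:
    def test_nick_position_matches_annotate(self):
        from petag.search import nick_position

        g = Genome({"c": "T" * 40 + SPACER + "AGG" + "T" * 40})
        (site,) = find_candidates(g, SPACER, "NGG", 0, 0)
        assert nick_position(site) == site.locus.end - 3

    def test_ungapped_plus_and_minus(self):
        g = Genome(
            {"c": "T" * 40 + SPACER + "AGG" + "T" * 20 + revcomp(SPACER + "CGG") + "T" * 20}
        )
        sites = annotate_nick(find_candidates(g, SPACER, "NGG", 0, 0), cut_offset=3)
        plus = next(s for s in sites if s.strand == "+")
        minus = next(s for s in sites if s.strand == "-")
        assert plus.nick == plus.locus.end - 3
        assert minus.nick == minus.locus.start + 3

    def test_dna_bulge_between_nick_and_pam_shifts_junction(self):
        site = CandidateSite(
            locus=GenomeLocus("c", 100, 121, "+"),
            pam_seq="AGG",
            aligned_spacer=SPACER[:-2] + "-" + SPACER[-2:],
            aligned_genome=SPACER[:-2] + "TGC",  # extra genome base 2 cols from PAM
            n_mismatch=2,
            n_dna_bulge=1,
            n_rna_bulge=0,
        )
        (annotated,) = annotate_nick([site], cut_offset=3)
        # 4 genome bases consumed before 3 spacer bases are: junction shifts by 1
        assert annotated.nick == 121 - 4


class TestSerialization:
    def test_round_trip(self, tmp_path):
        g = random_genome(11, 1200)
        sites = annotate_nick(find_candidates(g, SPACER, "NGG", 4, 2))
        path = tmp_path / "sites.tsv"
        write_sites(sites, path)
        assert read_sites(path) == sites

    def test_empty_list_round_trip(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_sites([], path)
        assert read_sites(path) == []
        assert path.read_text().startswith("site_id\t")

    def test_cap_violation_warns_on_read(self, tmp_path):
        site = CandidateSite(
            locus=GenomeLocus("c", 10, 30, "+"), pam_seq="AGG",
            aligned_spacer=SPACER, aligned_genome=SPACER,
            n_mismatch=5, n_dna_bulge=0, n_rna_bulge=0,
        )
        path = tmp_path / "bad.tsv"
        write_sites([site], path)
        with pytest.warns(UserWarning, match="exceeds cap"):
            read_sites(path, max_mismatch=4)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "broken.tsv"
        good = tmp_path / "good.tsv"
        write_sites([], good)
        path.write_text(good.read_text() + "only\tthree\tfields\n")
        with pytest.raises(ValueError, match=":2"):
            read_sites(path)

    def test_bed_export(self, tmp_path):
        g = Genome({"c": "T" * 40 + SPACER + "AGG" + "T" * 40})
        sites = find_candidates(g, SPACER, "NGG", 0, 0)
        bed = tmp_path / "sites.bed"
        write_bed(sites, bed)
        fields = bed.read_text().split("\t")
        assert fields[0] == "c" and fields[1] == "40" and fields[5].strip() == "+"


def test_collapse_by_nick_keeps_minimal_cost():
    def mk(start, end, mm, nd, nick):
        pad = end - start - len(SPACER)
        return CandidateSite(
            locus=GenomeLocus("c", start, end, "+"), pam_seq="AGG",
            aligned_spacer=SPACER + "-" * pad,
            aligned_genome=SPACER + "T" * pad,
            n_mismatch=mm, n_dna_bulge=nd, n_rna_bulge=0, nick=nick,
        )

    a = mk(100, 120, 1, 0, 117)
    b = mk(99, 120, 2, 1, 117)
    c = mk(99, 119, 2, 0, 116)
    out = collapse_by_nick([b, a, c])
    assert a in out and c in out and b not in out
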