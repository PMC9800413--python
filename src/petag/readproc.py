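"""Tag-read detection, tag trimming, and fragment mapping.

Reads that carry the integration tag are found by literal substring search for
a configurable set of tag queries (defaults: the two sense-library and two
antisense-library sequences, which are segments of the 34-nt tag and their
reverse complements).  The matched span is extended across any further tag
bases present in the read, the junction-proximal genomic flank is kept, and
the flank is mapped back to the reference with a k-mer seeded, ungapped
mapper (or ingested from an external aligner's SAM).

The *junction* of a mapping is the genome coordinate of the tag-genome
boundary, i.e. the mapped coordinate of the fragment end that abutted the
tag; downstream it is compared with the expected nick position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam

from .genome import Genome
from .pegrna import DEFAULT_FULL_TAG, GenomeLocus
from .sequtil import revcomp

# The four default tag queries. Each query is a segment of the oriented full
# tag; ``tag_offset`` locates it inside ``parent_tag`` so a hit can be
# extended over neighbouring tag bases, and ``junction_side`` says on which
# side of the tag the nick-adjacent genomic sequence continues.
_SENSE_FWD = DEFAULT_FULL_TAG[:22]            # GTTTAATTGAGTTGTCATATGT
_ANTISENSE_FWD = DEFAULT_FULL_TAG[6:33]       # TTGAGTTGTCATATGTTAATAACGGTA


@dataclass(frozen=True)
class TagQuery:
    name: str
    seq: str
    library_orientation: str  # sense | antisense
    junction_side: str        # left | right: side where genomic sequence continues
    parent_tag: str           # oriented full tag this query is cut from
    tag_offset: int           # query start within parent_tag


def default_tag_queries(full_tag: str = DEFAULT_FULL_TAG) -> tuple[TagQuery, ...]:
    """The four literal queries used to collect tag-containing reads."""
    rc = revcomp(full_tag)
    sense_fwd = full_tag[:22]
    anti_fwd = full_tag[6:33]
    return (
        TagQuery("sense_fwd", sense_fwd, "sense", "left", full_tag, 0),
        TagQuery("sense_rev", revcomp(sense_fwd), "sense", "right",
                 rc, len(full_tag) - 22),
        TagQuery("antisense_fwd", anti_fwd, "antisense", "right", full_tag, 6),
        TagQuery("antisense_rev", revcomp(anti_fwd), "antisense", "left",
                 rc, len(full_tag) - 33),
    )


@dataclass(frozen=True)
class TagHit:
    read_id: str
    library_orientation: str
    query_matched: str
    tag_span: tuple[int, int]  # half-open interval on the read
    junction_side: str
    query: TagQuery = field(repr=False, compare=False, default=None)  # type: ignore[assignment]


def _find_hamming(read: str, query: str, max_hamming: int) -> int:
    """Leftmost occurrence of ``query`` in ``read`` within ``max_hamming`` subs."""
    if max_hamming == 0:
        return read.find(query)
    n, m = len(read), len(query)
    for i in range(n - m + 1):
        d = 0
        for a, b in zip(read[i : i + m], query):
            if a != b:
                d += 1
                if d > max_hamming:
                    break
        if d <= max_hamming:
            return i
    return -1


def detect_tag_all(
    read_seq: str,
    tag_queries: Sequence[TagQuery] = default_tag_queries(),
    max_hamming: int = 0,
    read_id: str = "",
) -> list[TagHit]:
    """All tag-query hits in a read, longest query first.

    A read spanning the whole integrated tag matches queries on both tag
    ends; downstream processing may fall back from one junction side to the
    other when the first flank fails to map.
    """
    read_seq = read_seq.upper()
    hits = []
    for q in sorted(tag_queries, key=lambda q: len(q.seq), reverse=True):
        pos = _find_hamming(read_seq, q.seq, max_hamming)
        if pos >= 0:
            hits.append(
                TagHit(
                    read_id=read_id,
                    library_orientation=q.library_orientation,
                    query_matched=q.name,
                    tag_span=(pos, pos + len(q.seq)),
                    junction_side=q.junction_side,
                    query=q,
                )
            )
    return hits


def detect_tag(
    read_seq: str,
    tag_queries: Sequence[TagQuery] = default_tag_queries(),
    max_hamming: int = 0,
    read_id: str = "",
) -> Optional[TagHit]:
    """Find the tag in a read; the longest matching query wins.

    Returns ``None`` when no query occurs (including reads shorter than every
    query).  Matching is exact by default, mirroring literal k-mer filtering.
    """
    hits = detect_tag_all(read_seq, tag_queries, max_hamming, read_id)
    return hits[0] if hits else None


def trim_tag(read_seq: str, hit: TagHit) -> Optional[tuple[str, str]]:
    """Remove the tag span and keep the junction-proximal genomic flank.

    The matched query span is first extended over any neighbouring bases that
    continue the oriented full tag (a query covers only part of the tag).
    Returns ``(genomic_fragment, junction_side)``, or ``None`` when the flank
    on the junction side is empty.
    """
    read_seq = read_seq.upper()
    start, end = hit.tag_span
    if not (0 <= start < end <= len(read_seq)):
        raise ValueError("tag span outside read bounds")
    q = hit.query
    if q is not None:
        off = q.tag_offset
        while start > 0 and off > 0 and read_seq[start - 1] == q.parent_tag[off - 1]:
            start -= 1
            off -= 1
        off_end = q.tag_offset + len(q.seq)
        while (
            end < len(read_seq)
            and off_end < len(q.parent_tag)
            and read_seq[end] == q.parent_tag[off_end]
        ):
            end += 1
            off_end += 1
    fragment = read_seq[:start] if hit.junction_side == "left" else read_seq[end:]
    if not fragment:
        return None
    return fragment, hit.junction_side


# ---------------------------------------------------------------------------
# mapping


@dataclass(frozen=True)
class ReadMapping:
    read_id: str
    locus: GenomeLocus
    mapped_length: int
    n_mismatch: int
    is_unique: bool
    junction: int       # genome coordinate of the tag-genome boundary
    tag_end: str = "R"  # which fragment end (read orientation) abutted the tag
    fragment: str = ""  # kept for SAM export; empty when ingested


def _junction_coord(locus: GenomeLocus, tag_end: str) -> int:
    """Genome coordinate of the fragment end that abutted the tag."""
    if locus.strand == "+":
        return locus.start if tag_end == "L" else locus.end
    return locus.end if tag_end == "L" else locus.start


class KmerIndex:
    """Exact k-mer index over the forward strand of every contig."""

    def __init__(self, genome: Genome, k: int = 12):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for contig in genome:
            seq = genome[contig]
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((contig, i))

    def seed_positions(self, query: str, max_mismatch: int) -> set[tuple[str, int]]:
        """Candidate start positions for an ungapped full-length placement.

        Pigeonhole seeding: the query is cut into ``max_mismatch + 1`` chunks
        so that any placement within the mismatch budget matches at least one
        chunk exactly.  Queries too short for that fall back to an exhaustive
        scan (every position of every contig).
        """
        n = len(query)
        k = self.k
        if n < (max_mismatch + 1) * k:
            return {
                (contig, i)
                for contig in self.genome
                for i in range(len(self.genome[contig]) - n + 1)
            }
        starts: set[tuple[str, int]] = set()
        n_chunks = max_mismatch + 1
        for c in range(n_chunks):
            off = (n * c) // n_chunks
            off = min(off, n - k)
            for contig, pos in self._index.get(query[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.genome[contig]) - n:
                    starts.add((contig, start))
        return starts


def map_fragment(
    fragment: str,
    index: KmerIndex,
    max_mismatch: int = 2,
    read_id: str = "",
    tag_end: str = "R",
) -> Optional[ReadMapping]:
    """Ungapped best-hit mapping of a trimmed genomic fragment.

    Returns the unique best placement (fewest mismatches over the full
    fragment length) on either strand, ``is_unique=False`` when several
    placements tie for best, and ``None`` when nothing maps within
    ``max_mismatch``.
    """
    fragment = fragment.upper()
    if any(c not in "ACGTN" for c in fragment):
        raise ValueError("fragment contains non-ACGTN characters")
    n = len(fragment)
    best_d = max_mismatch + 1
    best_hits: list[tuple[str, int, str]] = []
    for strand, query in (("+", fragment), ("-", revcomp(fragment))):
        for contig, start in index.seed_positions(query, max_mismatch):
            ref = index.genome[contig][start : start + n]
            d = 0
            for a, b in zip(ref, query):
                if a != b or a not in "ACGT":
                    d += 1
                    if d > best_d:
                        break
            if d < best_d:
                best_d = d
                best_hits = [(contig, start, strand)]
            elif d == best_d:
                best_hits.append((contig, start, strand))
    if not best_hits or best_d > max_mismatch:
        return None
    contig, start, strand = sorted(best_hits)[0]
    locus = GenomeLocus(contig, start, start + n, strand)
    return ReadMapping(
        read_id=read_id,
        locus=locus,
        mapped_length=n,
        n_mismatch=best_d,
        is_unique=len(best_hits) == 1,
        junction=_junction_coord(locus, tag_end),
        tag_end=tag_end,
        fragment=fragment,
    )


def filter_mappings(
    mappings: Iterable[ReadMapping], min_mapped_length: int = 30
) -> list[ReadMapping]:
    """Drop short-mapped (< ``min_mapped_length`` aligned bases) and non-unique hits."""
    return [m for m in mappings if m.mapped_length >= min_mapped_length and m.is_unique]


# ---------------------------------------------------------------------------
# SAM I/O
#
# Convention: the fragment end that abutted the tag is stored in the optional
# tag ``XE:A`` with value ``L`` or ``R`` (read orientation); a read-name
# suffix ``/TE=L`` or ``/TE=R`` is accepted as a fallback.  ``XU:i`` carries
# the unique-best flag; without it, MAPQ > 0 is treated as unique.


def write_sam(mappings: Sequence[ReadMapping], genome: Genome, path) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(genome[name])} for name in genome],
    }
    refs = list(genome)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mappings:
            a = pysam.AlignedSegment(out.header)
            a.query_name = m.read_id
            a.flag = 16 if m.locus.strand == "-" else 0
            a.reference_id = refs.index(m.locus.contig)
            a.reference_start = m.locus.start
            a.mapping_quality = 60 if m.is_unique else 0
            a.cigarstring = f"{m.mapped_length}M"
            if m.fragment:
                a.query_sequence = (
                    m.fragment if m.locus.strand == "+" else revcomp(m.fragment)
                )
            a.set_tag("NM", m.n_mismatch)
            a.set_tag("XE", m.tag_end, value_type="A")
            a.set_tag("XU", 1 if m.is_unique else 0)
            out.write(a)


def ingest_sam(path) -> tuple[list[ReadMapping], dict[str, int]]:
    """Convert primary, mapped SAM records to :class:`ReadMapping` objects.

    Unmapped, secondary and supplementary records are skipped and counted in
    the returned disposition dict.
    """
    mappings: list[ReadMapping] = []
    counts = {"converted": 0, "unmapped": 0, "secondary": 0, "supplementary": 0}
    with pysam.AlignmentFile(str(path), "r") as sam:
        if not sam.header.references:
            raise ValueError(f"{path}: SAM header lacks @SQ lines")
        for rec in sam:
            if rec.is_unmapped:
                counts["unmapped"] += 1
                continue
            if rec.is_secondary:
                counts["secondary"] += 1
                continue
            if rec.is_supplementary:
                counts["supplementary"] += 1
                continue
            strand = "-" if rec.is_reverse else "+"
            # aligned columns of the query, soft clips excluded
            mapped_len = sum(
                length for op, length in (rec.cigartuples or ()) if op in (0, 7, 8)
            )
            name = rec.query_name or ""
            tag_end = "R"
            if rec.has_tag("XE"):
                tag_end = str(rec.get_tag("XE"))
            elif "/TE=" in name:
                name, _, te = name.rpartition("/TE=")
                tag_end = te or "R"
            unique = bool(rec.get_tag("XU")) if rec.has_tag("XU") else rec.mapping_quality > 0
            locus = GenomeLocus(
                rec.reference_name, rec.reference_start, rec.reference_end, strand
            )
            seq = rec.query_sequence or ""
            if seq and strand == "-":
                seq = revcomp(seq)
            mappings.append(
                ReadMapping(
                    read_id=name,
                    locus=locus,
                    mapped_length=mapped_len,
                    n_mismatch=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    is_unique=unique,
                    junction=_junction_coord(locus, tag_end),
                    tag_end=tag_end,
                    fragment=seq,
                )
            )
            counts["converted"] += 1
    return mappings, counts
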