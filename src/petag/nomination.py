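"""Junction aggregation around candidate sites and off-target nomination.

Filtered tag-read mappings are assigned to the candidate site whose expected
nick is nearest (within a ±``flank`` window); junctions farther than
``nick_tolerance`` from the nick are *false tagmentation* events and are
excluded.  The surviving events are deduplicated by (junction, strand) into
the site's copy number, the ranking metric for nomination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .readproc import ReadMapping
from .search import CandidateSite

DEFAULT_FLANK = 150
DEFAULT_NICK_TOLERANCE = 10
DEFAULT_MIN_COPY = 1


@dataclass(frozen=True)
class IntegrationEvent:
    """One tag-genome junction observation attached to a candidate site."""

    read_id: str
    junction: int
    strand: str
    distance_to_nick: int  # signed, junction - nick
    nick_consistent: Optional[bool] = None


@dataclass(frozen=True)
class SiteReport:
    site: CandidateSite
    window_depth: int   # mappings overlapping the ±flank window
    n_tag_reads: int    # events assigned to this site's window
    copy_number: int    # deduplicated nick-consistent events
    n_reads_consistent: int  # raw (non-deduplicated) nick-consistent reads
    nominated: bool


def assign_events(
    mappings: Iterable[ReadMapping],
    sites: Sequence[CandidateSite],
    flank: int = DEFAULT_FLANK,
) -> tuple[dict[str, list[IntegrationEvent]], dict[str, int], int]:
    """Attach each mapping to the candidate site with the nearest nick.

    A mapping is eligible for a site when its junction lies within
    ``[nick - flank, nick + flank]`` on the same contig.  A junction
    equidistant from two nicks is ambiguous and excluded.  Returns
    ``(events per site id, window depth per site id, n ambiguous)``.
    """
    for s in sites:
        if s.nick is None:
            raise ValueError(f"site {s.site_id} has no nick annotation")
    by_contig: dict[str, list[CandidateSite]] = {}
    for s in sites:
        by_contig.setdefault(s.locus.contig, []).append(s)

    events: dict[str, list[IntegrationEvent]] = {s.site_id: [] for s in sites}
    depth: dict[str, int] = {s.site_id: 0 for s in sites}
    n_ambiguous = 0
    for m in mappings:
        candidates = by_contig.get(m.locus.contig, ())
        # window depth: any overlap of the mapped interval with the window
        for s in candidates:
            if m.locus.start <= s.nick + flank and m.locus.end >= s.nick - flank:
                depth[s.site_id] += 1
        eligible = [
            (abs(m.junction - s.nick), s) for s in candidates
            if abs(m.junction - s.nick) <= flank
        ]
        if not eligible:
            continue
        eligible.sort(key=lambda t: t[0])
        if len(eligible) > 1 and eligible[0][0] == eligible[1][0] and (
            eligible[0][1].site_id != eligible[1][1].site_id
        ):
            n_ambiguous += 1
            continue
        dist, site = eligible[0]
        events[site.site_id].append(
            IntegrationEvent(
                read_id=m.read_id,
                junction=m.junction,
                strand=m.locus.strand,
                distance_to_nick=m.junction - site.nick,
            )
        )
    return events, depth, n_ambiguous


def filter_false_tagmentation(
    events: Iterable[IntegrationEvent], nick_tolerance: int = DEFAULT_NICK_TOLERANCE
) -> list[IntegrationEvent]:
    """Keep only nick-consistent events (|junction - nick| <= tolerance)."""
    out = []
    for e in events:
        if abs(e.distance_to_nick) <= nick_tolerance:
            out.append(
                IntegrationEvent(
                    e.read_id, e.junction, e.strand, e.distance_to_nick, True
                )
            )
    return out


def copy_number(events: Iterable[IntegrationEvent]) -> int:
    """Deduplicated evidence count: distinct (junction, strand) pairs."""
    return len({(e.junction, e.strand) for e in events})


def build_site_reports(
    mappings: Iterable[ReadMapping],
    sites: Sequence[CandidateSite],
    flank: int = DEFAULT_FLANK,
    nick_tolerance: int = DEFAULT_NICK_TOLERANCE,
    min_copy: int = DEFAULT_MIN_COPY,
) -> tuple[list[SiteReport], int]:
    """Full aggregation: assignment, nick filter, copy number, nomination flag."""
    events, depth, n_ambiguous = assign_events(mappings, sites, flank)
    reports = []
    for s in sites:
        consistent = filter_false_tagmentation(events[s.site_id], nick_tolerance)
        cn = copy_number(consistent)
        reports.append(
            SiteReport(
                site=s,
                window_depth=depth[s.site_id],
                n_tag_reads=len(events[s.site_id]),
                copy_number=cn,
                n_reads_consistent=len(consistent),
                nominated=cn >= min_copy,
            )
        )
    return reports, n_ambiguous


def nominate(
    site_reports: Iterable[SiteReport], min_copy: int = DEFAULT_MIN_COPY
) -> list[SiteReport]:
    """Nominated sites (copy number >= ``min_copy``), highest copy number first."""
    chosen = [
        SiteReport(
            r.site, r.window_depth, r.n_tag_reads, r.copy_number,
            r.n_reads_consistent, True,
        )
        for r in site_reports
        if r.copy_number >= min_copy
    ]
    chosen.sort(key=lambda r: (-r.copy_number, r.site.locus.contig, r.site.locus.start))
    return chosen


_REPORT_COLUMNS = [
    "site_id", "contig", "start", "end", "strand", "n_mismatch", "n_dna_bulge",
    "n_rna_bulge", "nick", "window_depth", "n_tag_reads", "n_reads_consistent",
    "copy_number", "nominated",
]


def write_site_reports(reports: Sequence[SiteReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in reports:
            s = r.site
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        s.site_id, s.locus.contig, s.locus.start, s.locus.end,
                        s.strand, s.n_mismatch, s.n_dna_bulge, s.n_rna_bulge,
                        s.nick, r.window_depth, r.n_tag_reads,
                        r.n_reads_consistent, r.copy_number, int(r.nominated),
                    ]
                )
                + "\n"
            )


def write_nominated_bed(reports: Sequence[SiteReport], path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            if r.nominated:
                s = r.site
                fh.write(
                    f"{s.locus.contig}\t{s.locus.start}\t{s.locus.end}\t"
                    f"{s.site_id}\t{r.copy_number}\t{s.strand}\n"
                )
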