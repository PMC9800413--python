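"""Genome-wide candidate off-target search with mismatches and bulges.

Every IUPAC-PAM match on either strand anchors a banded, gapped alignment of
the spacer against the adjacent genomic sequence.  A *DNA bulge* is an extra
genome base (gap in the spacer row); an *RNA bulge* is an extra spacer base
(gap in the genome row).  A locus is reported when its best alignment has at
most ``max_mismatch`` mismatches and at most ``max_bulge`` total bulges — the
two caps are independent and jointly allowed.

Conventions (documented, config-independent):

* bulges may not occupy the first or last alignment column, so the
  PAM-proximal and PAM-distal ends of the protospacer are always paired;
* per PAM anchor the minimal-cost alignment is kept, cost ordered
  lexicographically as (mismatches, total bulges, DNA bulges);
* ``N`` in the genome never matches a spacer base, and matches a PAM position
  only where the PAM pattern itself has ``N``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .genome import Genome
from .pegrna import DEFAULT_CUT_OFFSET, GenomeLocus
from .sequtil import is_dna, is_iupac, pam_matches, revcomp

GAP = "-"


class SiteParseError(ValueError):
    """Malformed site-table row."""


@dataclass(frozen=True)
class CandidateSite:
    """A candidate protospacer locus with its alignment to the spacer."""

    locus: GenomeLocus
    pam_seq: str
    aligned_genome: str  # protospacer-strand orientation, with '-' gaps
    aligned_spacer: str
    n_mismatch: int
    n_dna_bulge: int  # extra genome bases
    n_rna_bulge: int  # extra spacer bases
    nick: Optional[int] = None  # inter-base junction, reference-forward

    @property
    def strand(self) -> str:
        return self.locus.strand

    @property
    def site_id(self) -> str:
        return f"{self.locus.contig}:{self.locus.start}-{self.locus.end}({self.locus.strand})"

    @property
    def n_bulge(self) -> int:
        return self.n_dna_bulge + self.n_rna_bulge

    def ungapped_genome(self) -> str:
        return self.aligned_genome.replace(GAP, "")


def _char_mismatch(spacer_base: str, genome_base: str) -> int:
    # ambiguous genome bases never count as matches
    return 0 if (genome_base in "ACGT" and spacer_base == genome_base) else 1


def _align_anchor(
    seq: str,
    pam_pos: int,
    spacer: str,
    max_mismatch: int,
    max_bulge: int,
):
    """Best gapped alignment of ``spacer`` ending at ``pam_pos`` on ``seq``.

    Returns ``(cost, genome_len, aligned_spacer, aligned_genome)`` for the
    minimal (mm, bulges, dna_bulges) alignment within the caps, or ``None``.
    Works in PAM-proximal-first (reversed) coordinates internally.
    """
    k = len(spacer)
    avail = min(pam_pos, k + max_bulge)
    if avail < k - max_bulge or avail == 0:
        return None
    rs = spacer[::-1]
    g = seq[pam_pos - avail : pam_pos][::-1]

    DIAG, GAPM = 0, 1
    # bulge count is part of the state (the caps make lexicographic cost
    # non-separable otherwise); dp[(i, j, m, nb)] = minimal mismatches
    dp = {(0, 0, DIAG, 0): 0}
    parent: dict = {}

    def relax(key, mm, par, move):
        if mm <= max_mismatch and (key not in dp or mm < dp[key]):
            dp[key] = mm
            parent[key] = (*par, move)

    for i in range(k + 1):
        jlo = max(0, i - max_bulge)
        jhi = min(avail, i + max_bulge)
        for j in range(jlo, jhi + 1):
            for m in (DIAG, GAPM):
                for nb in range(max_bulge + 1):
                    mm = dp.get((i, j, m, nb))
                    if mm is None:
                        continue
                    # diagonal: consume one spacer and one genome base
                    if i < k and j < avail:
                        relax(
                            (i + 1, j + 1, DIAG, nb),
                            mm + _char_mismatch(rs[i], g[j]),
                            (i, j, m, nb), "D",
                        )
                    # gaps: not out of the PAM-proximal corner (terminal rule)
                    if (i, j) != (0, 0) and nb < max_bulge:
                        if i < k:  # RNA bulge: extra spacer base
                            relax((i + 1, j, GAPM, nb + 1), mm, (i, j, m, nb), "R")
                        if j < avail:  # DNA bulge: extra genome base
                            relax((i, j + 1, GAPM, nb + 1), mm, (i, j, m, nb), "G")

    # final state: all spacer consumed, last column diagonal (no terminal gap);
    # nd is determined by (j, nb): j - k = nd - nr, nb = nd + nr
    best = None
    for j in range(max(0, k - max_bulge), min(avail, k + max_bulge) + 1):
        for nb in range(max_bulge + 1):
            mm = dp.get((k, j, DIAG, nb))
            if mm is None:
                continue
            nd2 = nb + (j - k)
            if nd2 < 0 or nd2 % 2:
                continue
            cost = (mm, nb, nd2 // 2)
            if best is None or cost < best[0]:
                best = (cost, j, nb)
    if best is None:
        return None
    cost, j_end, nb_end = best

    # traceback
    state = (k, j_end, DIAG, nb_end)
    cols: list[tuple[str, str]] = []
    while state != (0, 0, DIAG, 0):
        pi, pj, pm, pnb, move = parent[state]
        if move == "D":
            cols.append((rs[pi], g[pj]))
        elif move == "R":
            cols.append((rs[pi], GAP))
        else:
            cols.append((GAP, g[pj]))
        state = (pi, pj, pm, pnb)
    # cols were collected PAM-proximal-last reversed; restore 5'->3' spacer order
    aligned_spacer = "".join(s for s, _ in cols)
    aligned_genome = "".join(gg for _, gg in cols)
    return cost, j_end, aligned_spacer, aligned_genome


def _search_strand(
    contig: str,
    seq: str,
    strand: str,
    contig_len: int,
    spacer: str,
    pam_pattern: str,
    max_mismatch: int,
    max_bulge: int,
) -> list[CandidateSite]:
    lp = len(pam_pattern)
    out = []
    for p in range(0, len(seq) - lp + 1):
        pam = seq[p : p + lp]
        if not pam_matches(pam, pam_pattern):
            continue
        res = _align_anchor(seq, p, spacer, max_mismatch, max_bulge)
        if res is None:
            continue
        (mm, nb, nd), glen, a_sp, a_gn = res
        if strand == "+":
            locus = GenomeLocus(contig, p - glen, p, "+")
        else:
            locus = GenomeLocus(contig, contig_len - p, contig_len - p + glen, "-")
        out.append(
            CandidateSite(
                locus=locus,
                pam_seq=pam,
                aligned_genome=a_gn,
                aligned_spacer=a_sp,
                n_mismatch=mm,
                n_dna_bulge=nd,
                n_rna_bulge=nb - nd,
            )
        )
    return out


def find_candidates(
    genome: Genome,
    spacer: str,
    pam_pattern: str = "NGG",
    max_mismatch: int = 4,
    max_bulge: int = 2,
) -> list[CandidateSite]:
    """Enumerate candidate protospacer loci on both strands of every contig.

    Each PAM anchor is reported at most once, with its minimal-cost alignment.
    Sites are sorted by (contig, start, strand).
    """
    spacer = spacer.upper()
    if len(spacer) < 10:
        raise ValueError("spacer shorter than 10 nt: search would degenerate")
    if not is_dna(spacer):
        raise ValueError("spacer must be ACGT-only")
    if not is_iupac(pam_pattern):
        raise ValueError(f"PAM pattern {pam_pattern!r} is not IUPAC")
    pam_pattern = pam_pattern.upper()

    sites: list[CandidateSite] = []
    for contig in genome:
        fwd = genome[contig]
        L = len(fwd)
        sites.extend(
            _search_strand(contig, fwd, "+", L, spacer, pam_pattern, max_mismatch, max_bulge)
        )
        sites.extend(
            _search_strand(
                contig, revcomp(fwd), "-", L, spacer, pam_pattern, max_mismatch, max_bulge
            )
        )
    sites.sort(key=lambda s: (s.locus.contig, s.locus.start, s.locus.strand))
    return sites


def nick_position(site: CandidateSite, cut_offset: int = DEFAULT_CUT_OFFSET) -> int:
    """Nick junction of a candidate site, from its gapped alignment.

    The nickase cuts ``cut_offset`` nt 5' of the PAM on the protospacer
    strand; DNA-bulge columns between the cut and the PAM shift the genome
    coordinate accordingly (see :func:`annotate_nick`).
    """
    (annotated,) = annotate_nick([site], cut_offset)
    assert annotated.nick is not None
    return annotated.nick


def annotate_nick(
    sites: Iterable[CandidateSite], cut_offset: int = DEFAULT_CUT_OFFSET
) -> list[CandidateSite]:
    """Fill each site's nick junction from its gapped alignment.

    Walking from the PAM-proximal end of the alignment, the junction sits
    after ``cut_offset`` spacer bases have been consumed; DNA-bulge columns in
    that stretch consume an extra genome base and shift the junction away from
    the PAM accordingly.
    """
    out = []
    for site in sites:
        spacer_seen = 0
        genome_seen = 0
        for s_ch, g_ch in zip(site.aligned_spacer[::-1], site.aligned_genome[::-1]):
            if spacer_seen >= cut_offset:
                break
            if s_ch != GAP:
                spacer_seen += 1
            if g_ch != GAP:
                genome_seen += 1
        if spacer_seen < cut_offset:
            raise ValueError(f"site {site.site_id} shorter than cut_offset")
        if site.strand == "+":
            nick = site.locus.end - genome_seen
        else:
            nick = site.locus.start + genome_seen
        out.append(replace(site, nick=nick))
    return out


def collapse_by_nick(sites: Iterable[CandidateSite]) -> list[CandidateSite]:
    """One candidate per cut site: collapse records sharing (contig, strand, nick).

    Neighbouring PAM anchors can describe the same physical protospacer with
    shifted bulge placements; junction evidence cannot distinguish them, so
    for nomination the minimal-cost record (mismatches, bulges, leftmost)
    represents the nick.  Requires nick-annotated sites.
    """
    best: dict[tuple[str, str, int], CandidateSite] = {}
    for s in sites:
        if s.nick is None:
            raise ValueError(f"site {s.site_id} has no nick annotation")
        key = (s.locus.contig, s.locus.strand, s.nick)
        cost = (s.n_mismatch, s.n_bulge, s.locus.start)
        cur = best.get(key)
        if cur is None or cost < (cur.n_mismatch, cur.n_bulge, cur.locus.start):
            best[key] = s
    out = list(best.values())
    out.sort(key=lambda s: (s.locus.contig, s.locus.start, s.locus.strand))
    return out


# ---------------------------------------------------------------------------
# serialization

_COLUMNS = [
    "site_id",
    "contig",
    "start",
    "end",
    "strand",
    "pam_seq",
    "aligned_spacer",
    "aligned_genome",
    "n_mismatch",
    "n_dna_bulge",
    "n_rna_bulge",
    "nick",
]


def write_sites(sites: Sequence[CandidateSite], path) -> None:
    """Write candidate sites as TSV (one row per site, fixed header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for s in sites:
            row = [
                s.site_id,
                s.locus.contig,
                str(s.locus.start),
                str(s.locus.end),
                s.strand,
                s.pam_seq,
                s.aligned_spacer,
                s.aligned_genome,
                str(s.n_mismatch),
                str(s.n_dna_bulge),
                str(s.n_rna_bulge),
                "." if s.nick is None else str(s.nick),
            ]
            fh.write("\t".join(row) + "\n")


def read_sites(path, max_mismatch: Optional[int] = None, max_bulge: Optional[int] = None) -> list[CandidateSite]:
    """Read a site TSV back; lossless inverse of :func:`write_sites`.

    If caps are given, rows exceeding them trigger a validation warning (the
    row is still returned).
    """
    sites = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _COLUMNS:
            raise SiteParseError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_COLUMNS):
                raise SiteParseError(f"{path}:{lineno}: expected {len(_COLUMNS)} fields")
            try:
                rec = dict(zip(_COLUMNS, fields))
                site = CandidateSite(
                    locus=GenomeLocus(
                        rec["contig"], int(rec["start"]), int(rec["end"]), rec["strand"]
                    ),
                    pam_seq=rec["pam_seq"],
                    aligned_spacer=rec["aligned_spacer"],
                    aligned_genome=rec["aligned_genome"],
                    n_mismatch=int(rec["n_mismatch"]),
                    n_dna_bulge=int(rec["n_dna_bulge"]),
                    n_rna_bulge=int(rec["n_rna_bulge"]),
                    nick=None if rec["nick"] == "." else int(rec["nick"]),
                )
            except (ValueError, KeyError) as exc:
                raise SiteParseError(f"{path}:{lineno}: {exc}") from exc
            if max_mismatch is not None and site.n_mismatch > max_mismatch:
                warnings.warn(
                    f"{path}:{lineno}: n_mismatch={site.n_mismatch} exceeds cap {max_mismatch}"
                )
            if max_bulge is not None and site.n_bulge > max_bulge:
                warnings.warn(
                    f"{path}:{lineno}: bulges={site.n_bulge} exceed cap {max_bulge}"
                )
            sites.append(site)
    return sites


def write_bed(sites: Sequence[CandidateSite], path) -> None:
    """BED6 export: name = site id, score = mismatch count."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.locus.contig}\t{s.locus.start}\t{s.locus.end}\t"
                f"{s.site_id}\t{s.n_mismatch}\t{s.strand}\n"
            )
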