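"""pegRNA data model and nick-relative coordinate arithmetic.

A prime-editing guide RNA (pegRNA) carries a spacer (which determines the
protospacer match and the nick site), a primer binding site (PBS) that anneals
to the nicked strand, and a reverse-transcriptase (RT) template that encodes
the programmed edit.  A tag-bearing pegRNA additionally carries a short tag
sequence between the PBS and the RT template, so that prime editing writes the
tag into the genome at the nick; the integrated tag is what the sequencing
pipeline detects.

Coordinate conventions used throughout the package:

* genome intervals are 0-based, half-open;
* nick junctions are inter-base coordinates on the reference-forward strand;
* edit positions are numbered from the nick on the protospacer strand,
  ``+1`` being the first base 3' of the nick.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import yaml

from .sequtil import is_dna, is_iupac, revcomp

#: default full-length integration tag (34 nt) and its accepted truncations
DEFAULT_FULL_TAG = "GTTTAATTGAGTTGTCATATGTTAATAACGGTAT"
DEFAULT_VARIANT_TAGS = (
    DEFAULT_FULL_TAG[:29],  # 29-nt truncation
    DEFAULT_FULL_TAG[:24],  # 24-nt truncation
    DEFAULT_FULL_TAG[:19],  # 19-nt truncation
)

#: distance of the nick 5' of the PAM on the protospacer strand (SpCas9 nickase)
DEFAULT_CUT_OFFSET = 3


class PegRNAError(ValueError):
    """Invalid pegRNA/edit/tag definition or misuse of one."""


@dataclass(frozen=True)
class GenomeLocus:
    """A stranded genome interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise PegRNAError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise PegRNAError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EditSpec:
    """The programmed edit, in nick-relative coordinates.

    ``position`` is >= 1 and counts from the nick on the protospacer strand.
    A substitution replaces ``ref`` by the equal-length ``alt`` starting at
    ``position``; an insertion places ``alt`` immediately after ``position``;
    a deletion removes ``ref`` starting at ``position``.
    """

    position: int
    kind: str  # substitution | insertion | deletion
    ref: str = ""
    alt: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise PegRNAError("edit position must be >= 1 (counted from the nick)")
        if self.kind == "substitution":
            if not self.ref or len(self.ref) != len(self.alt):
                raise PegRNAError("substitution needs equal-length non-empty ref/alt")
        elif self.kind == "insertion":
            if self.ref or not self.alt:
                raise PegRNAError("insertion needs empty ref and non-empty alt")
        elif self.kind == "deletion":
            if self.alt or not self.ref:
                raise PegRNAError("deletion needs non-empty ref and empty alt")
        else:
            raise PegRNAError(f"unknown edit kind {self.kind!r}")
        for s in (self.ref, self.alt):
            if s and not is_dna(s):
                raise PegRNAError("edit alleles must be ACGT-only")


@dataclass(frozen=True)
class TagSpec:
    """Integration tag: the full-length tag plus accepted truncations.

    ``integrated_orientation`` states how ``full_tag`` appears on the
    reference-forward strand at a plus-strand site: ``as_given`` (the printed
    tag reads on the protospacer strand) or ``reverse_complement``.
    """

    full_tag: str = DEFAULT_FULL_TAG
    variant_tags: tuple[str, ...] = DEFAULT_VARIANT_TAGS
    integrated_orientation: str = "as_given"

    def __post_init__(self) -> None:
        if not is_dna(self.full_tag):
            raise PegRNAError("full_tag must be ACGT-only")
        for v in self.variant_tags:
            if not self.full_tag.startswith(v):
                raise PegRNAError(f"variant tag {v!r} is not a prefix of the full tag")
        if self.integrated_orientation not in ("as_given", "reverse_complement"):
            raise PegRNAError(
                f"unknown integrated_orientation {self.integrated_orientation!r}"
            )

    @property
    def oriented_tag(self) -> str:
        """The tag as it appears on the protospacer strand of the edited locus."""
        if self.integrated_orientation == "as_given":
            return self.full_tag
        return revcomp(self.full_tag)

    def all_tags(self) -> tuple[str, ...]:
        """Full tag plus variants, longest first (the detection precedence)."""
        tags = {self.full_tag, *self.variant_tags}
        return tuple(sorted(tags, key=len, reverse=True))


@dataclass(frozen=True)
class PegRNA:
    name: str
    spacer: str
    pbs: str
    rt_template: str
    pam_pattern: str = "NGG"
    edit: Optional[EditSpec] = None
    tag: Optional[TagSpec] = None

    def __post_init__(self) -> None:
        if not (17 <= len(self.spacer) <= 24) or not is_dna(self.spacer):
            raise PegRNAError("spacer must be 17-24 nt of ACGT")
        if not (8 <= len(self.pbs) <= 17) or not is_dna(self.pbs):
            raise PegRNAError("PBS must be 8-17 nt of ACGT")
        if not is_dna(self.rt_template):
            raise PegRNAError("RT template must be non-empty ACGT")
        if not is_iupac(self.pam_pattern):
            raise PegRNAError(f"PAM pattern {self.pam_pattern!r} is not IUPAC")

    def with_tag(self, tag: TagSpec) -> "PegRNA":
        return replace(self, tag=tag)


# ---------------------------------------------------------------------------
# nick arithmetic


def nick_position_from_locus(locus: GenomeLocus, cut_offset: int = DEFAULT_CUT_OFFSET) -> int:
    """Nick junction (inter-base, reference-forward) for an ungapped protospacer.

    The nickase cuts the protospacer strand ``cut_offset`` nt 5' of the PAM.
    For a plus-strand protospacer occupying ``[start, end)`` with the PAM at
    ``end``, the junction is ``end - cut_offset``; the minus-strand case is the
    mirror image.
    """
    if len(locus) < cut_offset:
        raise PegRNAError("site interval shorter than cut_offset")
    if locus.strand == "+":
        return locus.end - cut_offset
    return locus.start + cut_offset


# ---------------------------------------------------------------------------
# expected alleles


def _apply_edit(window: str, nick: int, edit: EditSpec) -> str:
    """Apply a nick-relative edit to a protospacer-strand window.

    ``nick`` is the junction index inside ``window`` (number of bases 5' of
    the nick).  Raises if a substitution/deletion reference allele disagrees
    with the window.
    """
    i = nick + edit.position - 1  # index of nick-relative position +N
    if edit.kind == "substitution":
        j = i + len(edit.ref)
        if j > len(window):
            raise PegRNAError("edit runs past the end of the window")
        if window[i:j].upper() != edit.ref.upper():
            raise PegRNAError(
                f"reference mismatch at edit position: window has {window[i:j]!r}, "
                f"edit expects {edit.ref!r}"
            )
        return window[:i] + edit.alt + window[j:]
    if edit.kind == "insertion":
        # inserted immediately after nick-relative position N
        if i + 1 > len(window):
            raise PegRNAError("edit runs past the end of the window")
        return window[: i + 1] + edit.alt + window[i + 1 :]
    # deletion
    j = i + len(edit.ref)
    if j > len(window):
        raise PegRNAError("edit runs past the end of the window")
    if window[i:j].upper() != edit.ref.upper():
        raise PegRNAError(
            f"reference mismatch at deletion: window has {window[i:j]!r}, "
            f"edit expects {edit.ref!r}"
        )
    return window[:i] + window[j:]


def expected_edited_allele(pegrna: PegRNA, ref_window: str, nick_offset_in_window: int) -> str:
    """The major edited sequence: ``ref_window`` with the programmed edit applied.

    ``ref_window`` is given on the protospacer strand;
    ``nick_offset_in_window`` is the junction index within it.
    """
    if not 0 <= nick_offset_in_window <= len(ref_window):
        raise PegRNAError("nick offset outside the window")
    if pegrna.edit is None:
        return ref_window
    return _apply_edit(ref_window, nick_offset_in_window, pegrna.edit)


def flap_edited_allele(pegrna: PegRNA, ref_window: str, nick_offset_in_window: int) -> str:
    """Edited allele by RT-flap replacement, valid at any locus.

    Reverse transcription writes the reverse complement of the RT template as
    a new 3' flap from the nick, which then replaces the corresponding
    genomic stretch.  Unlike :func:`expected_edited_allele` this makes no
    assumption about the reference base at the edit position, so it applies
    to off-target loci whose sequence differs from the on-target; at the
    on-target the two constructions coincide.
    """
    n = nick_offset_in_window
    if not 0 <= n <= len(ref_window):
        raise PegRNAError("nick offset outside the window")
    flap = revcomp(pegrna.rt_template)
    net = 0
    if pegrna.edit is not None:
        net = len(pegrna.edit.alt) - len(pegrna.edit.ref)
    replaced = len(flap) - net  # genomic bases displaced by the flap
    if n + replaced > len(ref_window):
        raise PegRNAError("RT flap runs past the end of the window")
    return ref_window[:n] + flap + ref_window[n + replaced :]


def expected_tagmented_allele(pegrna: PegRNA, ref_window: str, nick_offset_in_window: int) -> str:
    """The Case 1 tag+edit allele: the edited window with the tag at the nick.

    The tag is inserted exactly at the nick junction, oriented per the
    pegRNA's ``TagSpec.integrated_orientation``.  Because programmed edits sit
    3' of the nick, excising the tag from the output recovers
    :func:`expected_edited_allele` exactly.
    """
    if pegrna.tag is None:
        raise PegRNAError(f"pegRNA {pegrna.name!r} has no tag configured")
    edited = expected_edited_allele(pegrna, ref_window, nick_offset_in_window)
    n = nick_offset_in_window
    return edited[:n] + pegrna.tag.oriented_tag + edited[n:]


# ---------------------------------------------------------------------------
# config I/O


def _edit_from_dict(d: dict) -> EditSpec:
    return EditSpec(
        position=int(d["position"]),
        kind=str(d["kind"]),
        ref=str(d.get("ref", "") or ""),
        alt=str(d.get("alt", "") or ""),
    )


def _tag_from_dict(d: dict) -> TagSpec:
    full = str(d.get("full", DEFAULT_FULL_TAG)).upper()
    variants = d.get("variants")
    if variants is None:
        variants = tuple(v for v in DEFAULT_VARIANT_TAGS if full.startswith(v)) or (
            full[: max(len(full) - 5, 1)],
        )
    return TagSpec(
        full_tag=full,
        variant_tags=tuple(str(v).upper() for v in variants),
        integrated_orientation=str(d.get("orientation", "as_given")),
    )


def pegrna_from_dict(d: dict) -> PegRNA:
    """Build a :class:`PegRNA` from a parsed config mapping."""
    edit = d.get("edit")
    tag = d.get("tag")
    return PegRNA(
        name=str(d["name"]),
        spacer=str(d["spacer"]).upper(),
        pbs=str(d["pbs"]).upper(),
        rt_template=str(d["rt_template"]).upper(),
        pam_pattern=str(d.get("pam", "NGG")).upper(),
        edit=_edit_from_dict(edit) if edit else None,
        tag=_tag_from_dict(tag) if tag is not None else None,
    )


def load_pegrna(path) -> PegRNA:
    """Read a pegRNA definition from a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PegRNAError(f"{path}: expected a mapping of pegRNA fields")
    return pegrna_from_dict(data)
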