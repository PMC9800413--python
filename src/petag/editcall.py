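"""Amplicon editing-outcome classification and off-target validation calls.

Each amplicon read at a locus is classified against the expected reference
and major-edited alleles with the precedence

    tagmented > major edited > insertion/deletion > substitution > wild type.

Tagmentation is defined by literal presence of any configured tag variant.
Reads carrying exactly one full-length tag are further split into *Case 1*
(after in-silico tag excision the residue matches a pattern producible
without the tag — with or without the programmed edit) and *Case 2* (the
integration perturbed the surrounding pattern).  Reads with only a truncated
tag, or with several full tags, are tagmented but ineligible for the case
analysis and are counted separately as ``tagmented_partial``.

A candidate locus is a *validated off-target* when (1) at least one event
class is more frequent in the treated sample than in the untreated control
and (2) the major edited sequence — producible only by prime editing — is
present in the treated sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

# outcome class names, in reporting order
WT = "wt"
MAJOR_EDITED = "major_edited"
TAG_CASE1_WITH_EDIT = "tagmented_case1_with_edit"
TAG_CASE1_TAG_ONLY = "tagmented_case1_tag_only"
TAG_CASE2 = "tagmented_case2"
TAG_PARTIAL = "tagmented_partial"
INSERTION = "insertion"
DELETION = "deletion"
SUBSTITUTION = "substitution"
UNCLASSIFIED = "unclassified"

OUTCOME_CLASSES = (
    WT, MAJOR_EDITED, TAG_CASE1_WITH_EDIT, TAG_CASE1_TAG_ONLY, TAG_CASE2,
    TAG_PARTIAL, INSERTION, DELETION, SUBSTITUTION, UNCLASSIFIED,
)

#: classes that count as "tagmented" at the coarse level
TAGMENTED_CLASSES = frozenset(
    {TAG_CASE1_WITH_EDIT, TAG_CASE1_TAG_ONLY, TAG_CASE2, TAG_PARTIAL}
)


@dataclass
class EditOutcomeTable:
    """Per-locus classification counts over an amplicon read set."""

    locus_id: str
    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in OUTCOME_CLASSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequency(self, cls: str) -> float:
        t = self.total
        return self.counts.get(cls, 0) / t if t else math.nan

    def frequencies(self) -> dict[str, float]:
        return {c: self.frequency(c) for c in OUTCOME_CLASSES}

    def tagmented_count(self) -> int:
        return sum(self.counts.get(c, 0) for c in TAGMENTED_CLASSES)


def classify_read(
    read: str,
    ref_allele: str,
    edited_allele: str,
    tag_variants: Sequence[str],
    min_read_fraction: float = 0.5,
) -> str:
    """Coarse outcome class of one amplicon read.

    Returns one of ``tagmented``, ``major_edited``, ``insertion``,
    ``deletion``, ``substitution``, ``wt`` or ``unclassified``.  Reads
    shorter than ``min_read_fraction`` of the reference window are
    unclassified (they do not cover the comparison window).
    """
    read = read.upper()
    if any(tag in read for tag in tag_variants):
        return "tagmented"
    if read == edited_allele.upper():
        return MAJOR_EDITED
    if read == ref_allele.upper():
        return WT
    if len(read) < min_read_fraction * len(ref_allele):
        return UNCLASSIFIED
    if len(read) > len(ref_allele):
        return INSERTION
    if len(read) < len(ref_allele):
        return DELETION
    return SUBSTITUTION


@dataclass(frozen=True)
class CaseCall:
    case: str                      # case1 | case2
    subclass: Optional[str] = None  # with_edit | tag_only | None


def _tag_occurrences(read: str, tag: str, max_mismatch: int) -> list[int]:
    """Start positions of (possibly inexact) full-tag occurrences, non-overlapping."""
    hits = []
    i = 0
    n, m = len(read), len(tag)
    while i <= n - m:
        d = 0
        for a, b in zip(read[i : i + m], tag):
            if a != b:
                d += 1
                if d > max_mismatch:
                    break
        if d <= max_mismatch:
            hits.append(i)
            i += m
        else:
            i += 1
    return hits


def classify_case(
    tag_read: str,
    reference_pattern_set: Iterable[str],
    full_tag: str,
    ref_allele: Optional[str] = None,
    edited_allele: Optional[str] = None,
    max_tag_mismatch: int = 0,
) -> Optional[CaseCall]:
    """Case 1 / Case 2 call for a read carrying the full-length tag.

    The full tag must occur exactly once (located allowing up to
    ``max_tag_mismatch`` substitutions, excised by coordinates); otherwise
    the read is ineligible and ``None`` is returned.  After excision, a
    residue found in ``reference_pattern_set`` is Case 1 — subclassified
    ``with_edit``/``tag_only`` by comparison with the edited and reference
    alleles — and anything else is Case 2.
    """
    tag_read = tag_read.upper()
    full_tag = full_tag.upper()
    hits = _tag_occurrences(tag_read, full_tag, max_tag_mismatch)
    if len(hits) != 1:
        return None
    i = hits[0]
    residue = tag_read[:i] + tag_read[i + len(full_tag) :]
    patterns = {p.upper() for p in reference_pattern_set}
    if residue not in patterns:
        return CaseCall("case2")
    if edited_allele is not None and residue == edited_allele.upper():
        return CaseCall("case1", "with_edit")
    if ref_allele is not None and residue == ref_allele.upper():
        return CaseCall("case1", "tag_only")
    return CaseCall("case1")


def build_outcome_table(
    locus_id: str,
    reads: Iterable[str],
    ref_allele: str,
    edited_allele: str,
    tag_variants: Sequence[str],
    full_tag: str,
    reference_pattern_set: Optional[Iterable[str]] = None,
    max_tag_mismatch: int = 0,
    min_read_fraction: float = 0.5,
) -> EditOutcomeTable:
    """Classify a full amplicon read set into an :class:`EditOutcomeTable`."""
    patterns = (
        set(reference_pattern_set)
        if reference_pattern_set is not None
        else {ref_allele.upper(), edited_allele.upper()}
    )
    table = EditOutcomeTable(locus_id)
    for read in reads:
        cls = classify_read(read, ref_allele, edited_allele, tag_variants, min_read_fraction)
        if cls == "tagmented":
            call = classify_case(
                read, patterns, full_tag, ref_allele, edited_allele, max_tag_mismatch
            )
            if call is None:
                cls = TAG_PARTIAL
            elif call.case == "case2":
                cls = TAG_CASE2
            elif call.subclass == "tag_only":
                cls = TAG_CASE1_TAG_ONLY
            else:
                cls = TAG_CASE1_WITH_EDIT
        table.counts[cls] = table.counts.get(cls, 0) + 1
    return table


# ---------------------------------------------------------------------------
# validation calls

#: event classes compared between treated and control for condition 1
CONDITION1_CLASSES = ("mutation", INSERTION, DELETION, SUBSTITUTION, MAJOR_EDITED)


@dataclass(frozen=True)
class ValidationRecord:
    site_id: str
    label: str  # validated | false_positive | not_analyzed
    condition1_met: bool
    condition2_met: bool
    treated_freqs: dict[str, float] = field(default_factory=dict, compare=False)
    control_freqs: dict[str, float] = field(default_factory=dict, compare=False)


def _class_frequency(table: EditOutcomeTable, cls: str) -> float:
    if cls == "mutation":
        # any non-wild-type, non-tagmented outcome
        n = sum(
            table.counts.get(c, 0)
            for c in (MAJOR_EDITED, INSERTION, DELETION, SUBSTITUTION, UNCLASSIFIED)
        )
        return n / table.total if table.total else math.nan
    return table.frequency(cls)


def validate_site(
    treated: Sequence[EditOutcomeTable],
    control: Sequence[EditOutcomeTable],
    site_id: Optional[str] = None,
    aggregation: str = "mean",
    min_freq: float = 0.0,
) -> ValidationRecord:
    """Two-condition validation call for one locus.

    Condition 1: some event class (mutation, insertion, deletion,
    substitution or major editing) is more frequent in treated than in
    control; replicates are combined by their mean frequency
    (``aggregation="all"`` instead requires every treated replicate to exceed
    the control mean).  Condition 2: the major edited sequence is present in
    treated.  Loci with no reads are not analyzed.  ``min_freq`` is an
    optional floor guarding against sequencing/PCR noise: a class whose mean
    treated frequency is below it cannot satisfy condition 1 (no floor by
    default).
    """
    sid = site_id or (treated[0].locus_id if treated else "")
    if not treated or not control or any(t.total == 0 for t in treated) or any(
        c.total == 0 for c in control
    ):
        return ValidationRecord(sid, "not_analyzed", False, False)

    treated_freqs: dict[str, float] = {}
    control_freqs: dict[str, float] = {}
    cond1 = False
    for cls in CONDITION1_CLASSES:
        tf = [_class_frequency(t, cls) for t in treated]
        cf = [_class_frequency(c, cls) for c in control]
        treated_freqs[cls] = sum(tf) / len(tf)
        control_freqs[cls] = sum(cf) / len(cf)
        if aggregation == "all":
            exceeded = all(f > control_freqs[cls] for f in tf)
        else:
            exceeded = treated_freqs[cls] > control_freqs[cls]
        if treated_freqs[cls] < min_freq:
            exceeded = False
        cond1 = cond1 or exceeded
    cond2 = sum(t.counts.get(MAJOR_EDITED, 0) for t in treated) > 0
    label = "validated" if (cond1 and cond2) else "false_positive"
    return ValidationRecord(sid, label, cond1, cond2, treated_freqs, control_freqs)


def validation_rate(records: Iterable[ValidationRecord]) -> Optional[float]:
    """validated / (validated + false positive); not-analyzed excluded; None if empty."""
    v = sum(1 for r in records if r.label == "validated")
    f = sum(1 for r in records if r.label == "false_positive")
    return v / (v + f) if (v + f) else None


# ---------------------------------------------------------------------------
# TSV output


def write_outcome_tables(tables: Sequence[EditOutcomeTable], path) -> None:
    cols = ["locus_id", "total", *OUTCOME_CLASSES, *(f"freq_{c}" for c in OUTCOME_CLASSES)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in tables:
            row = [t.locus_id, str(t.total)]
            row += [str(t.counts.get(c, 0)) for c in OUTCOME_CLASSES]
            row += [f"{t.frequency(c):.6g}" for c in OUTCOME_CLASSES]
            fh.write("\t".join(row) + "\n")


def write_validation_records(records: Sequence[ValidationRecord], path) -> None:
    cols = ["site_id", "label", "condition1_met", "condition2_met"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write(
                f"{r.site_id}\t{r.label}\t{int(r.condition1_met)}\t{int(r.condition2_met)}\n"
            )
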