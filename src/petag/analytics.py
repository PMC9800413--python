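"""Diagnostics: pegRNA-region mismatch profiles, ROC/AUC, miss rate, overlaps.

The pegRNA pairs with a candidate locus in three regions: the spacer
(protospacer match), the PBS (anneals to the protospacer strand immediately
5' of the nick) and the RT template (templates the new 3' flap written from
the nick).  Counting mismatches per region against the genome asks how well
each pegRNA segment is supported at the locus; validated off-targets tend to
carry fewer mismatches, so mismatch counts are scored with
lower-is-positive ROC direction, while copy number is scored
higher-is-positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .genome import Genome
from .pegrna import PegRNA
from .search import CandidateSite
from .sequtil import revcomp

SiteKey = tuple[str, int, str]  # (contig, nick, strand)

DEFAULT_MATCH_TOLERANCE = 5


# ---------------------------------------------------------------------------
# region mismatch profiles


@dataclass(frozen=True)
class RegionMismatchProfile:
    site_id: str
    target_mismatch: int
    pbs_mismatch: Optional[int]  # None when excluded (bulged alignment) or off-contig
    rt_mismatch: Optional[int]
    has_bulge: bool
    pbs_excluded: bool
    pbs_length: int = 0
    rt_length: int = 0

    def rates(self) -> dict[str, Optional[float]]:
        """Mismatches per region base (region length as denominator)."""
        out: dict[str, Optional[float]] = {}
        out["pbs"] = (
            None if self.pbs_mismatch is None or not self.pbs_length
            else self.pbs_mismatch / self.pbs_length
        )
        out["rt"] = (
            None if self.rt_mismatch is None or not self.rt_length
            else self.rt_mismatch / self.rt_length
        )
        return out


def _rt_reference_expectation(pegrna: PegRNA) -> tuple[str, frozenset[int]]:
    """Protospacer-strand sequence the RT homology implies on the *reference*.

    The new 3' flap written from the nick is the reverse complement of the RT
    template and already carries the programmed edit; inverting the edit
    yields the sequence expected on the unedited genome, with the edit
    positions masked so the intended change never counts as a mismatch.
    """
    flap = revcomp(pegrna.rt_template)
    edit = pegrna.edit
    if edit is None:
        return flap, frozenset()
    n = edit.position
    if edit.kind == "substitution":
        return flap, frozenset(range(n - 1, n - 1 + len(edit.ref)))
    if edit.kind == "insertion":
        m = len(edit.alt)
        return flap[:n] + flap[n + m :], frozenset()
    # deletion: restore the deleted reference bases, masked
    m = len(edit.ref)
    return flap[: n - 1] + edit.ref + flap[n - 1 :], frozenset(range(n - 1, n - 1 + m))


def _masked_hamming(genomic: str, expected: str, mask: frozenset[int]) -> int:
    d = 0
    for i, (a, b) in enumerate(zip(genomic.upper(), expected.upper())):
        if i in mask:
            continue
        if a != b or a not in "ACGT":
            d += 1
    return d


def region_mismatches(
    site: CandidateSite, pegrna: PegRNA, genome: Genome
) -> RegionMismatchProfile:
    """Mismatch counts of the spacer, PBS and RT regions at a candidate locus.

    All comparisons are made on the protospacer strand.  Sites whose spacer
    alignment contains a bulge are excluded from the PBS count; regions
    running off the contig end give ``None`` with a warning.
    """
    if site.nick is None:
        raise ValueError(f"site {site.site_id} has no nick annotation")
    contig = site.locus.contig
    clen = genome.contig_length(contig)
    q = site.nick
    strand = site.strand

    has_bulge = site.n_bulge > 0
    pbs_len = len(pegrna.pbs)
    rt_expected, rt_mask = _rt_reference_expectation(pegrna)
    rt_len = len(rt_expected)

    pbs_mismatch: Optional[int] = None
    if not has_bulge:
        if strand == "+":
            lo, hi = q - pbs_len, q
            ok = lo >= 0
            region = genome.fetch(contig, lo, hi, "+") if ok else ""
        else:
            lo, hi = q, q + pbs_len
            ok = hi <= clen
            region = genome.fetch(contig, lo, hi, "-") if ok else ""
        if ok:
            pbs_mismatch = _masked_hamming(region, revcomp(pegrna.pbs), frozenset())
        else:
            warnings.warn(f"{site.site_id}: PBS region runs off the contig end")

    rt_mismatch: Optional[int] = None
    if strand == "+":
        lo, hi = q, q + rt_len
        ok = hi <= clen
        region = genome.fetch(contig, lo, hi, "+") if ok else ""
    else:
        lo, hi = q - rt_len, q
        ok = lo >= 0
        region = genome.fetch(contig, lo, hi, "-") if ok else ""
    if ok:
        rt_mismatch = _masked_hamming(region, rt_expected, rt_mask)
    else:
        warnings.warn(f"{site.site_id}: RT region runs off the contig end")

    return RegionMismatchProfile(
        site_id=site.site_id,
        target_mismatch=site.n_mismatch,
        pbs_mismatch=pbs_mismatch,
        rt_mismatch=rt_mismatch,
        has_bulge=has_bulge,
        pbs_excluded=has_bulge,
        pbs_length=pbs_len,
        rt_length=rt_len,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    points: tuple[tuple[float, float], ...]  # (FPR, TPR), (0,0) .. (1,1)
    auc: float
    n_pos: int
    n_neg: int


def _as_binary(labels: Sequence) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, str):
            out.append(1 if lab == "validated" else 0)
        else:
            out.append(int(bool(lab)))
    return np.asarray(out, dtype=int)


def roc(scores: Sequence[float], labels: Sequence, direction: str = "higher") -> RocResult:
    """ROC over a threshold sweep of the distinct scores.

    ``direction="higher"`` treats larger scores as more positive (copy
    number); ``direction="lower"`` treats smaller scores as more positive
    (mismatch counts).  The AUC equals the tie-corrected rank statistic: the
    probability that a random positive outscores a random negative, ties
    counting one half.
    """
    if direction not in ("higher", "lower"):
        raise ValueError(f"unknown direction {direction!r}")
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=float)
    if len(s) != len(y):
        raise ValueError("scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one positive and one negative")
    oriented = s if direction == "higher" else -s
    fpr, tpr, _ = _sk_roc_curve(y, oriented, drop_intermediate=False)
    area = float(_sk_auc(fpr, tpr))
    return RocResult(tuple(zip(fpr.tolist(), tpr.tolist())), area, n_pos, n_neg)


# ---------------------------------------------------------------------------
# miss rate & overlaps


def match_site(key: SiteKey, others: Iterable[SiteKey], tolerance: int) -> bool:
    """Is ``key`` within ``tolerance`` nt of any site in ``others`` (same contig+strand)?"""
    contig, nick, strand = key
    return any(
        c == contig and s == strand and abs(n - nick) <= tolerance
        for c, n, s in others
    )


def miss_rate(
    predicted: Iterable[SiteKey],
    validated: Iterable[SiteKey],
    tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> Optional[float]:
    """Missed validated sites over all validated sites; ``None`` if none validated.

    Sites are identified by (contig, nick, strand); a validated site counts
    as found when a predicted site lies within ``tolerance`` nt on the same
    contig and strand.
    """
    predicted = list(predicted)
    validated = list(validated)
    if not validated:
        return None
    missed = sum(1 for v in validated if not match_site(v, predicted, tolerance))
    return missed / len(validated)


def recall(
    predicted: Iterable[SiteKey],
    validated: Iterable[SiteKey],
    tolerance: int = DEFAULT_MATCH_TOLERANCE,
) -> Optional[float]:
    m = miss_rate(predicted, validated, tolerance)
    return None if m is None else 1.0 - m


def union_sites(*site_sets: Iterable[SiteKey]) -> set[SiteKey]:
    """Set union of site lists (e.g. combining replicate predictions)."""
    out: set[SiteKey] = set()
    for s in site_sets:
        out.update(s)
    return out


def overlap_summary(site_sets: Dict[str, Iterable[SiteKey]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a 2-4 set Venn decomposition.

    Returns a mapping from each non-empty combination of set names (sorted
    tuple) to the number of sites belonging to exactly those sets.
    Duplicates within a set are removed with a warning.
    """
    if not 2 <= len(site_sets) <= 4:
        raise ValueError("overlap_summary expects 2-4 named site sets")
    dedup: dict[str, set[SiteKey]] = {}
    for name, sites in site_sets.items():
        sites = list(sites)
        uniq = set(sites)
        if len(uniq) < len(sites):
            warnings.warn(f"site set {name!r} contained duplicate ids; deduplicated")
        dedup[name] = uniq
    names = sorted(dedup)
    counts: dict[tuple[str, ...], int] = {}
    for key in set().union(*dedup.values()):
        members = tuple(n for n in names if key in dedup[n])
        counts[members] = counts.get(members, 0) + 1
    return counts
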