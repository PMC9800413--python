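"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: the search oracle
enumerates every PAM anchor and every gap placement exhaustively, the
mapping oracle scans every genome position, and the AUC oracle compares all
positive/negative pairs.
"""

from __future__ import annotations

import itertools

from petag.sequtil import pam_matches, revcomp

GAP = "-"


def _placements(k: int, d: int, r: int):
    """All ways to place d genome-gap and r spacer-gap columns.

    Column layout has ``k + d`` columns; the first and last column must be
    diagonal (no terminal gaps).  Yields (set of DNA-bulge columns, set of
    RNA-bulge columns).
    """
    ncol = k + d
    interior = range(1, ncol - 1)
    for gpos in itertools.combinations(interior, d):
        remaining = [c for c in interior if c not in gpos]
        for rpos in itertools.combinations(remaining, r):
            yield set(gpos), set(rpos)


def _best_alignment_at_anchor(seq, p, spacer, max_mm, max_bulge):
    """Minimal (mm, bulges, dna) alignment of spacer ending at p, or None."""
    k = len(spacer)
    best = None
    for d in range(max_bulge + 1):
        for r in range(max_bulge + 1 - d):
            lam = k + d - r
            if lam <= 0 or lam > p:
                continue
            gg = seq[p - lam : p]
            for gpos, rpos in _placements(k, d, r):
                i = j = mm = 0
                for col in range(k + d):
                    if col in gpos:       # DNA bulge: extra genome base
                        j += 1
                    elif col in rpos:     # RNA bulge: extra spacer base
                        i += 1
                    else:
                        gb = gg[j]
                        if gb not in "ACGT" or spacer[i] != gb:
                            mm += 1
                        i += 1
                        j += 1
                if mm <= max_mm:
                    cost = (mm, d + r, d)
                    if best is None or cost < best:
                        best = cost
    return best


def oracle_find_candidates(genome, spacer, pam_pattern, max_mm=4, max_bulge=2):
    """Exhaustive candidate search; returns a set of comparable records.

    Records are (contig, strand, start, end, mm, n_dna, n_rna) with loci in
    reference-forward coordinates, one per PAM anchor at minimal cost.
    """
    spacer = spacer.upper()
    k = len(spacer)
    lp = len(pam_pattern)
    records = set()
    for contig in genome:
        fwd = genome[contig]
        L = len(fwd)
        for strand, seq in (("+", fwd), ("-", revcomp(fwd))):
            for p in range(len(seq) - lp + 1):
                if not pam_matches(seq[p : p + lp], pam_pattern):
                    continue
                best = _best_alignment_at_anchor(seq, p, spacer, max_mm, max_bulge)
                if best is None:
                    continue
                mm, nb, nd = best
                lam = k + nd - (nb - nd)
                if strand == "+":
                    start, end = p - lam, p
                else:
                    start, end = L - p, L - p + lam
                records.add((contig, strand, start, end, mm, nd, nb - nd))
    return records


def site_records(sites):
    """Comparable record set from the implementation's CandidateSite list."""
    return {
        (
            s.locus.contig, s.locus.strand, s.locus.start, s.locus.end,
            s.n_mismatch, s.n_dna_bulge, s.n_rna_bulge,
        )
        for s in sites
    }


def oracle_map(fragment, genome, max_mm=2):
    """All-positions Hamming scan; returns (contig, start, strand, mm, unique) or None."""
    fragment = fragment.upper()
    n = len(fragment)
    best = max_mm + 1
    hits = []
    for contig in genome:
        seq = genome[contig]
        for strand, query in (("+", fragment), ("-", revcomp(fragment))):
            for start in range(len(seq) - n + 1):
                ref = seq[start : start + n]
                d = sum(
                    1
                    for a, b in zip(ref, query)
                    if a != b or a not in "ACGT"
                )
                if d < best:
                    best = d
                    hits = [(contig, start, strand)]
                elif d == best:
                    hits.append((contig, start, strand))
    if not hits or best > max_mm:
        return None
    contig, start, strand = sorted(hits)[0]
    return contig, start, strand, best, len(hits) == 1


def oracle_auc(scores, labels, direction="higher"):
    """All-pairs tie-corrected rank statistic."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if direction == "lower":
                p_, n_ = -p, -n
            else:
                p_, n_ = p, n
            if p_ > n_:
                total += 1.0
            elif p_ == n_:
                total += 0.5
    return total / (len(pos) * len(neg))
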