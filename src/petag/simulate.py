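"""Synthetic data: genomes with planted target sites, tag-integration reads,
and amplicon read sets with controlled outcome frequencies.

The generator emulates the data the pipeline consumes: a random genome with
the on-target protospacer and a configurable number of mismatched/bulged
off-target sites planted on both strands; tag-enriched reads whose tag-genome
junction sits at the prime-editing nick (Case 1 with or without the
programmed edit, or Case 2 with a small indel next to the integration),
plus *false tagmentation* reads with the junction planted off the nick and
tag-free background reads; and per-locus amplicon read sets drawn from
specified outcome-class frequencies.  Every read carries a truth label, and
every draw flows from one seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import Genome
from .pegrna import (
    DEFAULT_CUT_OFFSET,
    PegRNA,
    expected_tagmented_allele,
    flap_edited_allele,
)
from .sequtil import IUPAC, revcomp

_BASES = "ACGT"
CONTIG = "chr_sim"

#: truth categories for tag-enrichment reads
TRUE_CASE1_WITH_EDIT = "true_case1_with_edit"
TRUE_CASE1_TAG_ONLY = "true_case1_tag_only"
TRUE_CASE2 = "true_case2"
FALSE_TAGMENTATION = "false_tagmentation"
BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults: ten planted off-targets under the search caps (4 mismatches /
    2 bulges); 30 true tag reads per site; a 20% admixture of false
    tagmentation reads whose junction sits 60 nt off the nick; 80% Case 1
    integrations of which 10% carry the tag without the edit; fragments
    averaging 325 nt; 150 nt reads with a 0.1% per-base substitution error.
    """

    seed: int = 0
    genome_length: int = 20_000
    n_offtargets: int = 10
    # per-off-target (mismatches, dna bulges, rna bulges); cycled when shorter
    planted_profiles: tuple[tuple[int, int, int], ...] = (
        (1, 0, 0), (2, 0, 0), (3, 0, 0), (4, 0, 0), (2, 1, 0),
        (2, 0, 1), (1, 1, 1), (3, 1, 0), (4, 0, 2), (2, 0, 0),
    )
    reads_per_site: int = 30
    tagmentation_rate: float = 0.02   # default amplicon tagmentation frequency
    case1_fraction: float = 0.8
    tag_only_fraction: float = 0.1    # fraction of Case 1 without the edit
    false_tagmentation_rate: float = 0.2
    false_offset: int = 60            # |junction - nick| of false events (nt)
    false_site_activity: float = 0.15  # read-count multiplier at non-edited sites
    false_site_false_rate: float = 0.7  # off-nick fraction at non-edited sites
    background_read_fraction: float = 0.2
    fragment_mean: float = 325.0
    fragment_sd: float = 50.0
    read_length: int = 150
    error_rate: float = 0.001
    site_spacing: int = 500           # minimum distance between planted nicks
    cut_offset: int = DEFAULT_CUT_OFFSET

    def __post_init__(self) -> None:
        for name in (
            "tagmentation_rate", "case1_fraction", "tag_only_fraction",
            "false_tagmentation_rate", "background_read_fraction", "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.genome_length < (self.n_offtargets + 1) * self.site_spacing:
            raise ValueError("genome too short for the requested planted sites")


@dataclass(frozen=True)
class PlantedSite:
    name: str
    contig: str
    start: int   # protospacer span, reference-forward
    end: int
    strand: str
    nick: int
    n_mismatch: int
    n_dna_bulge: int
    n_rna_bulge: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.nick, self.strand)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    category: str
    site: str          # planted-site name, or "" for background
    junction: int = -1  # forward-strand junction coordinate, -1 for background


@dataclass
class TruthTable:
    sites: list[PlantedSite] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)

    def read_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.reads:
            out[r.category] = out.get(r.category, 0) + 1
        return out

    def site_read_counts(self, category: Optional[str] = None) -> dict[str, int]:
        out = {s.name: 0 for s in self.sites}
        for r in self.reads:
            if r.site and (category is None or r.category == category):
                out[r.site] = out.get(r.site, 0) + 1
        return out


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# built-in example target: a fixed genomic context with a toy pegRNA
# programming a +2 G-to-T edit.  The context is planted verbatim at the
# on-target locus so PBS/RT homology there is perfect by construction.

TOY_LEFT = "CCTGTAACTGGAAGCTTCACTGGAGTACCA"    # 30 nt 5' of the protospacer
TOY_SPACER = "GATTACACGGTAGCCTAAGC"            # 20 nt protospacer
TOY_PAM = "TGG"
TOY_RIGHT = "ACGGATTCAACCGGTATCTGAGCATGGTAC"   # 30 nt 3' of the PAM


def example_target(
    pbs_len: int = 13, flap_len: int = 13, with_tag: bool = True
) -> tuple[PegRNA, str, int]:
    """Toy pegRNA plus its genomic context block.

    Returns ``(pegrna, context_block, protospacer_offset_in_block)``.  The
    pegRNA programs a +2 G-to-T substitution; PBS and RT template are derived
    from the context so that the on-target locus has zero mismatches in every
    region.
    """
    from .pegrna import EditSpec, TagSpec  # local import to avoid cycle noise

    block = TOY_LEFT + TOY_SPACER + TOY_PAM + TOY_RIGHT
    proto_off = len(TOY_LEFT)
    nick_in_block = proto_off + len(TOY_SPACER) - DEFAULT_CUT_OFFSET
    pbs = revcomp(block[nick_in_block - pbs_len : nick_in_block])
    ref_flap = block[nick_in_block : nick_in_block + flap_len]
    edit = EditSpec(position=2, kind="substitution", ref="G", alt="T")
    edited_flap = ref_flap[:1] + edit.alt + ref_flap[2:]
    assert ref_flap[1] == edit.ref
    pegrna = PegRNA(
        name="toy_peg",
        spacer=TOY_SPACER,
        pbs=pbs,
        rt_template=revcomp(edited_flap),
        pam_pattern="NGG",
        edit=edit,
        tag=TagSpec() if with_tag else None,
    )
    return pegrna, block, proto_off


def _concrete_pam(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for code in pattern:
        choices = [b for b in IUPAC[code] if b != "N"]
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


def _mutate_site(
    rng: np.random.Generator, spacer: str, mm: int, dn: int, rn: int, cut_offset: int
) -> str:
    """Protospacer-strand site sequence differing from the spacer as requested.

    Substitutions may fall anywhere; bulge edits are kept in the interior and
    away from the ``cut_offset`` PAM-proximal bases so the planted nick stays
    at the ungapped position.
    """
    k = len(spacer)
    seq = list(spacer)
    sub_pos = rng.choice(k, size=mm, replace=False) if mm else []
    for p in sub_pos:
        alternatives = [b for b in _BASES if b != seq[p]]
        seq[p] = alternatives[rng.integers(0, 3)]
    # interior positions eligible for bulge edits (terminal columns must pair)
    lo, hi = 2, k - cut_offset - 2
    for _ in range(rn):  # RNA bulge: spacer base absent from the genome
        p = int(rng.integers(lo, hi))
        del seq[p]
    for _ in range(dn):  # DNA bulge: extra genome base
        p = int(rng.integers(lo, hi))
        seq.insert(p, _BASES[rng.integers(0, 4)])
    return "".join(seq)


def make_genome(
    pegrna: PegRNA,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    on_target_block: Optional[str] = None,
    on_target_proto_offset: int = 0,
) -> tuple[Genome, list[PlantedSite]]:
    """Random genome with the on-target and ``n_offtargets`` planted sites.

    Sites alternate strand, sit at least ``site_spacing`` apart and are
    written into an i.i.d. random background; each off-target carries the
    mismatch/bulge profile from ``planted_profiles``.  Deterministic given
    the generator state.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_sites = config.n_offtargets + 1
    seq = list(_random_seq(rng, config.genome_length))
    lp = len(pegrna.pam_pattern)
    k = len(pegrna.spacer)

    # evenly spaced slots, jittered
    span = config.genome_length - 2 * config.site_spacing
    positions = sorted(
        config.site_spacing
        + (span * i) // n_sites
        + int(rng.integers(0, max(config.site_spacing // 4, 1)))
        for i in range(n_sites)
    )
    planted: list[PlantedSite] = []
    for i, pos in enumerate(positions):
        if i == 0:
            name, (mm, dn, rn) = "on_target", (0, 0, 0)
        else:
            name = f"off_{i}"
            mm, dn, rn = config.planted_profiles[(i - 1) % len(config.planted_profiles)]
        strand = "+" if i % 2 == 0 else "-"
        if i == 0 and on_target_block is not None:
            # plant the full genomic context so PBS/RT homology is perfect
            proto = pegrna.spacer
            block = on_target_block
            proto_off = on_target_proto_offset
        else:
            proto = _mutate_site(rng, pegrna.spacer, mm, dn, rn, config.cut_offset)
            pam = _concrete_pam(rng, pegrna.pam_pattern)
            block = proto + pam  # protospacer-strand layout: protospacer then PAM
            proto_off = 0
        if strand == "-":
            block = revcomp(block)
        start = pos
        end = pos + len(block)
        seq[start:end] = list(block)
        if strand == "+":
            p_start = start + proto_off
            p_end = p_start + len(proto)
            nick = p_end - config.cut_offset
        else:
            p_end = end - proto_off
            p_start = p_end - len(proto)
            nick = p_start + config.cut_offset
        planted.append(
            PlantedSite(name, CONTIG, p_start, p_end, strand, nick, mm, dn, rn)
        )
    genome = Genome({CONTIG: "".join(seq)})
    return genome, planted


def _add_errors(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
    for i in hits:
        alternatives = [b for b in _BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_tape_reads(
    genome: Genome,
    planted: Sequence[PlantedSite],
    pegrna: PegRNA,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    site_activity: Optional[dict[str, float]] = None,
    site_false_rate: Optional[dict[str, float]] = None,
) -> tuple[list[tuple[str, str]], TruthTable]:
    """Tag-enrichment reads with per-read truth labels.

    Per planted site, ``reads_per_site`` tag reads are drawn (scaled by the
    per-site activity multiplier when given): each is a false
    tagmentation event with probability ``false_tagmentation_rate`` (junction
    at nick ± ``false_offset``), otherwise a true event split into Case 1
    (with the edit or tag-only) and Case 2 per the configured fractions.
    Reads are ``read_length`` nt, centred on the integrated tag with a small
    jitter, emitted on a random sequencing strand, with per-base
    substitution errors.  Background reads carry no tag.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    if pegrna.tag is None:
        raise ValueError("tag-read simulation needs a tag-bearing pegRNA")
    W = 250  # protospacer-strand context half-window around the nick
    tag_len = len(pegrna.tag.full_tag)
    reads: list[tuple[str, str]] = []
    truth = TruthTable(sites=list(planted))
    no_edit = dataclasses.replace(pegrna, edit=None)
    ridx = 0

    for site in planted:
        lo, hi = site.nick - W, site.nick + W
        if lo < 0 or hi > genome.contig_length(site.contig):
            raise ValueError(f"planted site {site.name} too close to the contig end")
        window = genome.fetch(site.contig, lo, hi, site.strand)
        nick_in_window = W  # by construction on either strand
        activity = 1.0 if site_activity is None else site_activity.get(site.name, 1.0)
        false_rate = config.false_tagmentation_rate
        if site_false_rate is not None:
            false_rate = site_false_rate.get(site.name, false_rate)
        n_reads = max(1, int(round(config.reads_per_site * activity)))
        for _ in range(n_reads):
            u = rng.random()
            if u < false_rate:
                category = FALSE_TAGMENTATION
                delta = int(config.false_offset) * (1 if rng.random() < 0.5 else -1)
                j = nick_in_window + delta
                allele = window[:j] + pegrna.tag.oriented_tag + window[j:]
                tag_at = j
                junction_fwd = site.nick + (delta if site.strand == "+" else -delta)
            else:
                edited = flap_edited_allele(pegrna, window, nick_in_window)
                tagged = (
                    edited[:nick_in_window]
                    + pegrna.tag.oriented_tag
                    + edited[nick_in_window:]
                )
                tag_at = nick_in_window
                junction_fwd = site.nick
                if rng.random() < config.case1_fraction:
                    if rng.random() < config.tag_only_fraction:
                        category = TRUE_CASE1_TAG_ONLY
                        allele = expected_tagmented_allele(no_edit, window, nick_in_window)
                    else:
                        category = TRUE_CASE1_WITH_EDIT
                        allele = tagged
                else:
                    # Case 2: 1-5 nt deleted adjacent to the tag, on the 5'
                    # or 3' side; a 5'-side deletion shifts the junction
                    category = TRUE_CASE2
                    d = int(rng.integers(1, 6))
                    if rng.random() < 0.5:
                        allele = tagged[: tag_at - d] + tagged[tag_at:]
                        tag_at -= d
                        junction_fwd = site.nick + (-d if site.strand == "+" else d)
                    else:
                        cut = tag_at + tag_len
                        allele = tagged[:cut] + tagged[cut + d :]
            # sheared fragment length bounds the read; the read is centred on
            # the tag (with jitter) so every emitted tag read is informative
            frag_len = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
            rl = min(config.read_length, max(frag_len, tag_len + 62))
            centre = tag_at + tag_len // 2
            jitter = int(rng.integers(-15, 16))
            start = max(0, min(centre - rl // 2 + jitter, len(allele) - rl))
            read = allele[start : start + rl]
            if rng.random() < 0.5:
                read = revcomp(read)
            read = _add_errors(rng, read, config.error_rate)
            rid = f"r{ridx:06d}"
            ridx += 1
            reads.append((rid, read))
            truth.reads.append(ReadTruth(rid, category, site.name, junction_fwd))

    n_background = int(round(config.background_read_fraction * len(reads)))
    clen = genome.contig_length(CONTIG)
    for _ in range(n_background):
        start = int(rng.integers(0, clen - config.read_length))
        read = genome.fetch(CONTIG, start, start + config.read_length,
                            "+" if rng.random() < 0.5 else "-")
        read = _add_errors(rng, read, config.error_rate)
        rid = f"r{ridx:06d}"
        ridx += 1
        reads.append((rid, read))
        truth.reads.append(ReadTruth(rid, BACKGROUND, "", -1))
    return reads, truth


# ---------------------------------------------------------------------------
# amplicon simulation

AMPLICON_CLASSES = (
    "major_edited", "tagmented_case1_with_edit", "tagmented_case1_tag_only",
    "tagmented_case2", "insertion", "deletion", "substitution",
)


def simulate_amplicon_reads(
    pegrna: PegRNA,
    ref_window: str,
    nick_offset: int,
    frequencies: dict[str, float],
    n_reads: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> tuple[list[str], dict[str, int]]:
    """Amplicon reads drawn from outcome-class frequencies (remainder wild type).

    Classes: ``major_edited``, the three tagmented classes, ``insertion``,
    ``deletion`` and ``substitution``; counts are multinomial and returned as
    the truth table.  Deterministic given ``seed``.
    """
    unknown = set(frequencies) - set(AMPLICON_CLASSES)
    if unknown:
        raise ValueError(f"unknown amplicon classes: {sorted(unknown)}")
    fsum = sum(frequencies.values())
    if fsum > 1.0 + 1e-9:
        raise ValueError(f"outcome frequencies sum to {fsum} > 1")
    rng = np.random.default_rng(seed)
    probs = [frequencies.get(c, 0.0) for c in AMPLICON_CLASSES]
    probs.append(max(0.0, 1.0 - fsum))
    counts = rng.multinomial(n_reads, probs)
    truth = dict(zip((*AMPLICON_CLASSES, "wt"), (int(c) for c in counts)))

    edited = flap_edited_allele(pegrna, ref_window, nick_offset)
    alleles: dict[str, str] = {"wt": ref_window, "major_edited": edited}
    if pegrna.tag is not None:
        tagged = edited[:nick_offset] + pegrna.tag.oriented_tag + edited[nick_offset:]
        no_edit = dataclasses.replace(pegrna, edit=None)
        tag_only = expected_tagmented_allele(no_edit, ref_window, nick_offset)
        cut = nick_offset + len(pegrna.tag.full_tag)
        alleles["tagmented_case1_with_edit"] = tagged
        alleles["tagmented_case1_tag_only"] = tag_only
        alleles["tagmented_case2"] = tagged[:cut] + tagged[cut + 2 :]
    # non-PE mutations, placed 5' of the nick so they cannot match the edit
    p = nick_offset - 6
    deletion = ref_window[: p - 3] + ref_window[p:]
    insertion = ref_window[:p] + "TG" + ref_window[p:]
    base = ref_window[p]
    substitution = ref_window[:p] + ("A" if base != "A" else "C") + ref_window[p + 1 :]
    alleles.update(insertion=insertion, deletion=deletion, substitution=substitution)

    for cls in truth:
        if truth[cls] and cls not in alleles:
            raise ValueError(f"class {cls!r} requires a tag-bearing pegRNA")
    reads: list[str] = []
    for cls in (*AMPLICON_CLASSES, "wt"):
        reads.extend([alleles.get(cls, ref_window)] * truth[cls])
    order = rng.permutation(len(reads))
    reads = [_add_errors(rng, reads[i], error_rate) for i in order]
    return reads, truth


# ---------------------------------------------------------------------------
# text output


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Constant high-quality FASTQ (the pipeline is quality-agnostic)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: TruthTable, sites_path, reads_path) -> None:
    with open(sites_path, "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\tnick\tn_mismatch\tn_dna_bulge\tn_rna_bulge\n")
        for s in truth.sites:
            fh.write(
                f"{s.name}\t{s.contig}\t{s.start}\t{s.end}\t{s.strand}\t{s.nick}\t"
                f"{s.n_mismatch}\t{s.n_dna_bulge}\t{s.n_rna_bulge}\n"
            )
    with open(reads_path, "w") as fh:
        fh.write("read_id\tcategory\tsite\tjunction\n")
        for r in truth.reads:
            fh.write(f"{r.read_id}\t{r.category}\t{r.site}\t{r.junction}\n")
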