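# Methods

`petag` reimplements, at desk scale, a tag-integration strategy for mapping
prime-editor off-target activity genome-wide. A prime editor (PE) is a Cas9
nickase fused to a reverse transcriptase (RT), programmed by a pegRNA whose
3′ extension carries a primer binding site (PBS) and an RT template. When the
pegRNA additionally carries a short tag between the PBS and the RT template,
prime editing writes the tag into the genome at every locus the editor acts
on. Sequencing tag-enriched libraries then reveals candidate off-target loci
as tag–genome junctions, and targeted amplicon sequencing validates them.

## Coordinate and model conventions

* Genome intervals are 0-based half-open; nick junctions are inter-base
  coordinates on the reference-forward strand.
* The nickase cut sits `cut_offset` nt 5′ of the PAM on the protospacer
  strand. The offset is a convention of SpCas9 biology, default 3,
  configurable everywhere it matters. This makes "+1" the first base 3′ of
  the nick, the numbering used for edits ("+2 G→T" substitutes the second
  base after the nick).
* "+N X ins" inserts X immediately after nick-relative position N;
  deletions remove `ref` starting at position N counted on the reference
  strand. Both conventions are fixed here because the field's shorthand does
  not pin them down.
* The integrated tag appears on the protospacer strand either as the printed
  34-mer (`as_given`, default) or reverse-complemented; this is an explicit
  config field (`TagSpec.integrated_orientation`) because tagmentation is
  *defined* by literal presence of the printed tag strings.
* Two edited-allele constructions exist. `expected_edited_allele` applies
  the nick-relative edit and errors if the reference disagrees — correct at
  the on-target and for amplicon bookkeeping. `flap_edited_allele` models
  what the enzyme actually writes anywhere: the reverse complement of the RT
  template replaces the corresponding genomic stretch from the nick. The two
  coincide at the on-target; the simulator and pipeline use the flap form at
  off-target loci whose sequence differs from the on-target.

## Candidate search

Every IUPAC-PAM match on either strand anchors a banded gapped alignment of
the spacer against the adjacent genome. A DNA bulge is an extra genome base
(gap in the spacer row); an RNA bulge is an extra spacer base (gap in the
genome row). The caps — default 4 mismatches and 2 total bulges — are
independent and jointly allowed. Bulges may not occupy the first or last
alignment column, so both protospacer ends pair; genomic `N` never matches a
spacer base and matches only an `N` PAM position. Per anchor the minimal
alignment under the lexicographic cost (mismatches, total bulges, DNA
bulges) is reported; the DP carries the bulge count in its state because the
bulge cap makes a plain lexicographic cell-minimum unsound. Ground truth for
this artifact is an exhaustive oracle (every anchor, every gap placement)
kept in the test suite; the search is asserted set-identical to it on dozens
of seeded random genomes and on constructed mismatch/bulge instances.

Neighbouring PAM anchors can describe the same physical cut site with
shifted bulge placements. `find_candidates` reports each anchor (matching
the external-tool convention and the oracle); for nomination the pipeline
collapses records sharing (contig, strand, nick) to the minimal-cost one,
since junction evidence cannot distinguish them — without this, the
equidistant-tie rule would discard their reads as ambiguous.

## Read processing

Tag reads are found by literal substring search for four queries — two
sense-library and two antisense-library sequences, each a segment of the
34-nt tag or its reverse complement — with a configurable Hamming tolerance
(default 0, mirroring literal k-mer filtering; the upstream tools' error
parameters are not public, so exactness is the conservative default). The
matched span is extended across any further tag bases in the read, the
junction-proximal flank is kept, and the flank is mapped with a k-mer-seeded
(pigeonhole-complete), ungapped, unique-best-hit mapper; fragments shorter
than the seeding bound fall back to exhaustive scanning, and the mapper is
asserted equal to an all-positions Hamming oracle. Gapped alignment is out
of scope for the built-in mapper; a SAM ingest path accepts any external
aligner's primary records (tag side carried in an `XE:A:{L,R}` tag or a
`/TE=` read-name suffix; `XU` or MAPQ>0 marks uniqueness). A read spanning
the whole tag has two flanks; the pipeline keeps the first junction side
that maps, because the flank containing the RT-written flap is unmappable at
diverged off-target loci under an ungapped model (an external aligner would
soft-clip it). Mappings shorter than 30 aligned bases or non-unique are
discarded.

## Nomination

Each mapping's junction (the mapped coordinate of the tag-abutting fragment
end) is assigned to the candidate site with the nearest nick within ±150 nt;
exact ties between distinct nicks are ambiguous and dropped. Junctions more
than `nick_tolerance` (default 10 nt) from the nick are false tagmentation
— integration away from the PE nick — and are excluded. The tolerance is a
documented parameter because the operational definition of "outside the
nick site" is not fixed by convention; 10 nt keeps Case 2 junctions (small
indels at the integration) while rejecting the simulator's 60-nt off-nick
events by a wide margin. Copy number is the count of distinct
(junction, strand) pairs — deduplication without UMIs, since no UMI scheme
applies — and a site is nominated when copy number ≥ `min_copy` (default 1;
nomination is deliberately permissive, validation does the filtering).

## Outcome classification and validation

Amplicon reads classify with precedence tagmented > major edited >
insertion/deletion > substitution > wild type; tagmented means any of the
34/29/24/19-nt tag variants occurs literally. Reads carrying exactly one
full-length tag are eligible for the Case analysis: excise the tag by
coordinates and compare the residue with the patterns producible without the
tag — a match is Case 1 (subclassified with-edit / tag-only), anything else
is Case 2. Variant-only or multi-tag reads are counted as
`tagmented_partial`, a class added so the classification stays a partition.
The comparison window default is nick ± 20 nt plus the edit span.

A locus is a validated off-target when (1) at least one event class
(mutation = any non-wt non-tagmented outcome, insertion, deletion,
substitution, or major editing) is more frequent in treated than control —
replicates combined by mean, with an "all replicates must exceed" switch —
and (2) the major edited sequence, producible only by prime editing, is
present in treated. Zero-read loci are not analyzed. The validation rate is
validated / (validated + false positive), not-analyzed excluded; the miss
rate is missed validated sites over all validated sites, with site identity
(contig, nick, strand) matched within 5 nt.

## Diagnostics

Region mismatch profiles count, on the protospacer strand, the spacer
mismatches (from the site alignment), the PBS mismatches (genomic stretch
ending at the nick vs. the reverse complement of the PBS) and the RT
mismatches (genomic stretch from the nick vs. the reverse complement of the
RT template with the programmed-edit positions masked — the intended edit is
by design absent from the genome and never counts). Sites with bulged
alignments are excluded from the PBS count, since the bulge makes the
PBS-pairing frame ambiguous. Mismatch rates divide by region length. ROC
curves sweep thresholds over the scores (copy number: higher is positive;
mismatch counts: lower is positive); the AUC is the trapezoidal area, equal
to the tie-corrected rank statistic, computed via scikit-learn and asserted
against an all-pairs oracle to 1e-12. Venn-style overlap summaries use exact
site-key membership; tolerant matching is reserved for the miss rate.

## Synthetic data

The generator emulates what the assay produces, with defaults chosen as the
study conditions where stated and as field-plausible values otherwise:

* genome: 20 kb i.i.d. random sequence, the on-target planted inside a
  fixed 83-nt context (so on-target PBS/RT homology is perfect) and 10
  off-targets with cycling mismatch/bulge profiles within the (4, 2) caps,
  alternating strands, ≥500 nt apart;
* tag reads: 30 per site, each false (junction at nick ± 60 nt) with
  probability 0.2, otherwise true with 80% Case 1 (10% of those tag-only)
  and 20% Case 2 (1–5 nt indel adjacent to the tag, either side); read
  length 150 nt bounded by a Normal(325, 50) sheared-fragment length; reads
  centred on the tag so each is informative; per-base substitution error
  0.1%; 20% tag-free background reads;
* in the pipeline's ROC scenario, sites designated non-validated emit 15%
  of the read depth with a 70% off-nick fraction — weak, largely
  nick-independent background tagmentation, which is what separates copy
  number between validated and false sites;
* amplicons: multinomial draws over outcome classes (5% major edit, 2%
  tagmentation split 70/10/20 across Case 1 with-edit / tag-only / Case 2,
  1% indels in treated; all zero in controls), 2000 reads × 3 replicates.

What this does not model: PCR and GC bias, platform error profiles, paired
mates, chromatin context, and genuine genomic repeat structure. Passing
tests therefore demonstrate the pipeline's logic and bookkeeping — filters
applied at the stated thresholds, truth recovered when present, oracle
agreement — not performance on real libraries, where mapping ambiguity and
background integration are harsher.

## Numerics and determinism

All randomness flows from one seed through spawned NumPy generator streams;
reruns are byte-identical (summary JSON, FASTA, FASTQ). Tie-breaks are
deterministic: equal-cost alignments resolve by fewer DNA bulges then a
fixed traceback preference; equal-mismatch mapper hits resolve to
`is_unique=False`; equidistant junction assignments are excluded rather
than arbitrated. Degenerate inputs have defined behaviour: empty read sets
classify to empty tables, single-class labels make the AUC an error rather
than a number, zero validated sites make miss rate and validation rate NA.

## Problem sizes

The shipped configuration runs the whole pipeline in under a second and the
complete test suite (including the exhaustive search oracle on 50 genomes of
0.5–2 kb and the 100-table AUC oracle) in about a minute on one CPU. Genome
length, site count, read depth and amplicon depth are ordinary config fields
for larger runs; genome-scale performance engineering is explicitly out of
scope.

## Known limitations

The built-in mapper is ungapped (indel-bearing genomic fragments need the
SAM path); tag detection at Hamming 0 loses reads with sequencing errors
inside the matched query; copy number saturates quickly at strong sites
because true junctions concentrate at the nick; overlap summaries require
exact key agreement between methods' site lists.
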