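"""Amplicon outcome classification, Case 1/2 calls, validation logic."""

import numpy as np
import pytest

from petag.editcall import (
    EditOutcomeTable,
    build_outcome_table,
    classify_case,
    classify_read,
    validate_site,
    validation_rate,
)
from petag.pegrna import DEFAULT_FULL_TAG, TagSpec, flap_edited_allele
from petag.simulate import simulate_amplicon_reads

TAG19 = DEFAULT_FULL_TAG[:19]
TAGS = TagSpec().all_tags()


@pytest.fixture(scope="module")
def alleles(toy):
    peg, block, off = toy
    nick = off + len(peg.spacer) - 3
    ref = block
    edited = flap_edited_allele(peg, block, nick)
    tagged = edited[:nick] + DEFAULT_FULL_TAG + edited[nick:]
    tag_only = ref[:nick] + DEFAULT_FULL_TAG + ref[nick:]
    return peg, ref, edited, tagged, tag_only, nick


class TestClassifyRead:
    def test_reference_read_is_wt(self, alleles):
        _, ref, edited, *_ = alleles
        assert classify_read(ref, ref, edited, TAGS) == "wt"

    def test_edited_read_is_major(self, alleles):
        _, ref, edited, *_ = alleles
        assert classify_read(edited, ref, edited, TAGS) == "major_edited"

    def test_19nt_tag_variant_is_tagmented(self, alleles):
        _, ref, edited, _, _, nick = alleles
        read = ref[:nick] + TAG19 + ref[nick:]
        assert classify_read(read, ref, edited, TAGS) == "tagmented"

    def test_indels_and_substitutions(self, alleles):
        _, ref, edited, *_ = alleles
        assert classify_read(ref[:10] + "AA" + ref[10:], ref, edited, TAGS) == "insertion"
        assert classify_read(ref[:10] + ref[13:], ref, edited, TAGS) == "deletion"
        sub = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        assert classify_read(sub, ref, edited, TAGS) == "substitution"

    def test_short_read_unclassified(self, alleles):
        _, ref, edited, *_ = alleles
        assert classify_read(ref[:10], ref, edited, TAGS) == "unclassified"

    def test_partition_sums_to_total(self, alleles):
        """Any read set is partitioned: class counts sum to the total."""
        peg, ref, edited, tagged, tag_only, nick = alleles
        rng = np.random.default_rng(3)
        reads = []
        for _ in range(200):
            choice = rng.integers(0, 5)
            base = [ref, edited, tagged, tag_only, ref[: nick] + ref[nick + 2 :]][choice]
            reads.append(base)
        table = build_outcome_table(
            "locus", reads, ref, edited, TAGS, DEFAULT_FULL_TAG
        )
        assert table.total == 200
        assert sum(table.counts.values()) == 200
        freqs = table.frequencies()
        assert abs(sum(freqs.values()) - 1.0) < 1e-12


class TestClassifyCase:
    def test_tagmented_allele_is_case1_with_edit(self, alleles):
        _, ref, edited, tagged, _, _ = alleles
        call = classify_case(tagged, {ref, edited}, DEFAULT_FULL_TAG, ref, edited)
        assert (call.case, call.subclass) == ("case1", "with_edit")

    def test_tag_without_edit_is_case1_tag_only(self, alleles):
        _, ref, edited, _, tag_only, _ = alleles
        call = classify_case(tag_only, {ref, edited}, DEFAULT_FULL_TAG, ref, edited)
        assert (call.case, call.subclass) == ("case1", "tag_only")

    def test_perturbed_flank_is_case2(self, alleles):
        _, ref, edited, tagged, _, nick = alleles
        i = tagged.index(DEFAULT_FULL_TAG) + len(DEFAULT_FULL_TAG)
        perturbed = tagged[:i] + tagged[i + 2 :]  # 2-nt deletion after the tag
        call = classify_case(perturbed, {ref, edited}, DEFAULT_FULL_TAG, ref, edited)
        assert call.case == "case2"

    def test_truncated_tag_ineligible(self, alleles):
        _, ref, edited, _, _, nick = alleles
        read = ref[:nick] + DEFAULT_FULL_TAG[:24] + ref[nick:]
        assert classify_case(read, {ref, edited}, DEFAULT_FULL_TAG) is None

    def test_double_tag_ineligible(self, alleles):
        _, ref, *_ = alleles
        read = ref[:30] + DEFAULT_FULL_TAG + ref[30:60] + DEFAULT_FULL_TAG + ref[60:]
        assert classify_case(read, {ref}, DEFAULT_FULL_TAG) is None

    def test_exact_on_constructed_mixture(self, alleles):
        """Noise-free constructed reads are assigned with zero error."""
        _, ref, edited, tagged, tag_only, _ = alleles
        i = tagged.index(DEFAULT_FULL_TAG) + len(DEFAULT_FULL_TAG)
        case2 = tagged[:i] + tagged[i + 3 :]
        for read, expected in [
            (tagged, "case1"), (tag_only, "case1"), (case2, "case2"),
        ]:
            assert classify_case(read, {ref, edited}, DEFAULT_FULL_TAG).case == expected

    def test_planted_fraction_recovered(self, alleles):
        """Estimated Case 1 fraction lies within 3 SE of the planted 0.8."""
        peg, ref, edited, *_ , nick = alleles
        n = 1000
        planted = 0.8
        tag_freq = 0.9
        reads, truth = simulate_amplicon_reads(
            peg, ref, nick,
            {
                "tagmented_case1_with_edit": tag_freq * planted * 0.9,
                "tagmented_case1_tag_only": tag_freq * planted * 0.1,
                "tagmented_case2": tag_freq * (1 - planted),
            },
            n_reads=n, seed=42,
        )
        calls = [
            classify_case(r, {ref, edited}, DEFAULT_FULL_TAG, ref, edited)
            for r in reads
        ]
        calls = [c for c in calls if c is not None]
        est = sum(c.case == "case1" for c in calls) / len(calls)
        se = (planted * (1 - planted) / len(calls)) ** 0.5
        assert abs(est - planted) <= 3 * se


def table(locus="L", **counts) -> EditOutcomeTable:
    t = EditOutcomeTable(locus)
    for k, v in counts.items():
        t.counts[k] = v
    return t


class TestValidateSite:
    def test_identical_to_control_is_false_positive(self):
        t = table(wt=95, substitution=5)
        rec = validate_site([t], [table(wt=95, substitution=5)])
        assert rec.label == "false_positive"
        assert not rec.condition1_met and not rec.condition2_met

    def test_major_edit_signal_validates(self):
        rec = validate_site(
            [table(wt=95, major_edited=5)], [table(wt=100)]
        )
        assert rec.label == "validated"
        assert rec.condition1_met and rec.condition2_met

    def test_indel_excess_without_major_edit_fails_condition2(self):
        rec = validate_site(
            [table(wt=98, deletion=2)], [table(wt=99, deletion=1)]
        )
        assert rec.condition1_met and not rec.condition2_met
        assert rec.label == "false_positive"

    def test_major_edit_without_excess_fails_condition1(self):
        # control has MORE of every event class than treated
        rec = validate_site(
            [table(wt=98, major_edited=1, deletion=1)],
            [table(wt=80, major_edited=10, deletion=10)],
        )
        assert rec.condition2_met and not rec.condition1_met
        assert rec.label == "false_positive"

    def test_zero_read_table_not_analyzed(self):
        rec = validate_site([table()], [table(wt=10)])
        assert rec.label == "not_analyzed"

    def test_min_freq_floor_suppresses_weak_signal(self):
        treated = [table(wt=9990, deletion=10)]  # 0.1% excess indels
        control = [table(wt=10000)]
        assert validate_site(treated, control).condition1_met
        rec = validate_site(treated, control, min_freq=0.005)
        assert not rec.condition1_met

    def test_replicate_mean_aggregation(self):
        treated = [table(wt=99, major_edited=1), table(wt=90, major_edited=10)]
        control = [table(wt=98, major_edited=2)]
        rec = validate_site(treated, control, aggregation="mean")
        assert rec.label == "validated"  # mean 5.5% > 2%
        rec_all = validate_site(treated, control, aggregation="all")
        assert rec_all.condition1_met is False  # 1% replicate does not exceed

    def test_monotone_in_major_edited(self):
        """Adding major-edited reads never flips validated -> false positive."""
        control = [table(wt=100)]
        prev_validated = False
        for n_major in range(0, 30, 3):
            rec = validate_site([table(wt=100, major_edited=n_major)], control)
            if prev_validated:
                assert rec.label == "validated"
            prev_validated = rec.label == "validated"


class TestValidationRate:
    def _rec(self, label):
        from petag.editcall import ValidationRecord

        return ValidationRecord("s", label, label == "validated", label == "validated")

    def test_printed_formula(self):
        recs = [self._rec("validated")] * 3 + [self._rec("false_positive")] + [
            self._rec("not_analyzed")
        ] * 2
        assert validation_rate(recs) == pytest.approx(0.75)

    def test_empty_denominator_is_none(self):
        assert validation_rate([self._rec("not_analyzed")] * 2) is None

    def test_all_validated(self):
        assert validation_rate([self._rec("validated")] * 4) == 1.0
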