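"""Line derivation: regimen windows, end rules, completion flags."""

from datetime import date, timedelta

import pytest

from conftest import day, rx_frame
from crclot.lines import (
    annotate_lines,
    assemble_regimen,
    completion_status,
    derive_lines,
    expected_final_dose_date,
)

FAR_END = day(5000)


def biweekly(drugs, start, n_cycles, cycle=14):
    rows = []
    for c in range(n_cycles):
        for drug in drugs:
            rows.append((start + timedelta(days=c * cycle), drug))
    return rows


class TestExpectedFinalDoseDate:
    def test_vocabulary_default_cycle(self, vocab):
        assert expected_final_dose_date(vocab, "bevacizumab", day(100)) == day(114)

    def test_days_supplied_overrides(self, vocab):
        assert expected_final_dose_date(vocab, "capecitabine", day(50), 21) == day(71)

    def test_non_antitumor_drug_rejected(self, vocab):
        with pytest.raises(ValueError, match="antihypertensive"):
            expected_final_dose_date(vocab, "amlodipine", day(10))


class TestAssembleRegimen:
    def test_drug_on_day_14_inside_window(self, vocab):
        rx = rx_frame([(day(0), "fluorouracil"), (day(0), "leucovorin"),
                       (day(0), "oxaliplatin"), (day(14), "bevacizumab")])
        reg = assemble_regimen(rx, day(0), vocab)
        assert reg.base_drugs == {"fluorouracil", "leucovorin", "oxaliplatin",
                                  "bevacizumab"}
        assert reg.label(vocab).display == "FOLFOX+BEV"

    def test_day_30_outside_window(self, vocab):
        rx = rx_frame([(day(0), "fluorouracil"), (day(0), "leucovorin"),
                       (day(0), "irinotecan"), (day(30), "ramucirumab")])
        reg = assemble_regimen(rx, day(0), vocab)
        assert reg.label(vocab).display == "FOLFIRI"

    def test_day_27_is_last_day_in_and_28_out(self, vocab):
        inside = assemble_regimen(
            rx_frame([(day(0), "capecitabine"), (day(27), "oxaliplatin")]), day(0), vocab
        )
        outside = assemble_regimen(
            rx_frame([(day(0), "capecitabine"), (day(28), "oxaliplatin")]), day(0), vocab
        )
        assert "oxaliplatin" in inside.base_drugs
        assert "oxaliplatin" not in outside.base_drugs

    def test_singleton(self, vocab):
        reg = assemble_regimen(rx_frame([(day(0), "capecitabine")]), day(0), vocab)
        assert reg.base_drugs == {"capecitabine"}

    def test_empty_window_is_an_error(self, vocab):
        with pytest.raises(ValueError):
            assemble_regimen(rx_frame([(day(40), "capecitabine")]), day(0), vocab)


class TestDeriveLines:
    def test_new_drug_rule_splits_two_lines(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "oxaliplatin", "bevacizumab"],
                     day(0), 7)
            + biweekly(["fluorouracil", "leucovorin", "irinotecan", "ramucirumab"],
                       day(200), 4)
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab)
        assert [l.line_number for l in lines] == [1, 2]
        assert lines[0].end_reason == "new_drug"
        assert lines[0].start_date == day(0) and lines[0].end_date == day(200)
        assert lines[1].start_date == day(200)
        assert lines[1].regimen.label(vocab).display == "FOLFIRI+RAM"

    def test_gap_rule_splits_even_with_identical_drugs(self, vocab):
        rows = []
        for c in (0, 21, 42, 63):
            rows += [(day(c), "capecitabine", None, 28), (day(c), "oxaliplatin")]
        rows += [(day(300), "capecitabine", None, 28), (day(300), "oxaliplatin")]
        lines = derive_lines(rx_frame(rows), day(0), FAR_END, vocab,
                             first_line_number=0)
        # exposure runs to day 63+28=91; 300-91 >= 180 so the gap rule fires
        assert [l.line_number for l in lines] == [0, 2]
        assert lines[0].end_reason == "gap_180"
        assert lines[0].end_date == day(91)
        assert lines[1].start_date == day(300)
        assert lines[1].regimen.base_drugs == lines[0].regimen.base_drugs

    def test_gap_boundary_pair(self, vocab):
        """Exactly 180 days from covered end fires the rule; 179 does not."""
        for gap, n_lines in ((180, 2), (179, 1)):
            rx = rx_frame([(day(0), "irinotecan"), (day(14 + gap), "irinotecan")])
            lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=2)
            assert len(lines) == n_lines, gap

    def test_biologic_addition_to_chemo_only_second_line(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(0), 6)
            + [(day(28), "bevacizumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=2)
        assert len(lines) == 1
        assert lines[0].regimen.additions == [(day(28), "bevacizumab")]
        assert lines[0].regimen.label(vocab).display == "FOLFIRI+BEV"

    def test_biologic_addition_not_applicable_to_first_line(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(0), 6)
            + [(day(28), "bevacizumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=1)
        assert [l.line_number for l in lines] == [1, 2]
        assert lines[0].end_reason == "new_drug"
        assert lines[0].end_date == day(28)

    def test_biologic_addition_not_applicable_to_adjuvant(self, vocab):
        rx = rx_frame(
            biweekly(["capecitabine", "oxaliplatin"], day(0), 3, cycle=28)
            + [(day(56 + 14), "bevacizumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=0)
        assert [l.line_number for l in lines] == [0, 2]

    def test_simultaneous_biologic_and_new_chemo_is_a_new_line(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(0), 4)
            + [(day(42), "oxaliplatin"), (day(42), "bevacizumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=2)
        assert [l.end_reason for l in lines] == ["new_drug", "data_end"]
        assert lines[1].start_date == day(42)

    def test_second_biologic_into_biologic_regimen_is_a_new_line(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "irinotecan", "bevacizumab"],
                     day(0), 4)
            + [(day(42), "ramucirumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=2)
        assert len(lines) == 2
        assert lines[0].end_reason == "new_drug"

    def test_second_biologic_after_addition_is_a_new_line(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(0), 8)
            + [(day(28), "bevacizumab"), (day(70), "ramucirumab")]
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab, first_line_number=2)
        assert len(lines) == 2
        assert lines[0].regimen.additions == [(day(28), "bevacizumab")]

    def test_last_line_censored_at_data_end(self, vocab):
        rx = rx_frame(biweekly(["capecitabine"], day(0), 2, cycle=28))
        lines = derive_lines(rx, day(0), day(40), vocab)
        assert lines[-1].end_reason == "data_end"
        assert lines[-1].end_date == day(40)  # data ends before covered end
        lines = derive_lines(rx, day(0), FAR_END, vocab)
        assert lines[-1].end_date == day(56)  # capecitabine covers 28 days from day 28

    def test_empty_prescriptions_gives_no_lines(self, vocab):
        assert derive_lines(rx_frame([]), day(0), FAR_END, vocab) == []

    def test_leucovorin_alone_never_starts_or_extends_therapy(self, vocab):
        rx = rx_frame([(day(0), "irinotecan"), (day(100), "leucovorin"),
                       (day(300), "irinotecan")])
        lines = derive_lines(rx, day(0), FAR_END, vocab)
        # gap measured from irinotecan cover (day 14), not the leucovorin claim
        assert len(lines) == 2
        assert lines[0].end_reason == "gap_180"
        assert lines[0].end_date == day(14)

    def test_partition_no_prescription_between_lines(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "oxaliplatin"], day(0), 5)
            + biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(100), 5)
            + biweekly(["trifluridine_tipiracil"], day(400), 3, cycle=21)
        )
        lines = derive_lines(rx, day(0), FAR_END, vocab)
        assert len(lines) == 3
        for r in rx.itertuples(index=False):
            covering = [
                l for l in lines
                if l.start_date <= r.date
                and (r.date < l.end_date
                     or (l.end_reason != "new_drug" and r.date <= l.end_date))
            ]
            assert len(covering) == 1, r

    def test_monotonicity_in_regimen_refill_does_not_move_boundaries(self, vocab):
        base = (biweekly(["fluorouracil", "leucovorin", "oxaliplatin"], day(0), 5)
                + biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(100), 5))
        with_refill = base + [(day(35), "fluorouracil")]
        a = derive_lines(rx_frame(base), day(0), FAR_END, vocab)
        b = derive_lines(rx_frame(with_refill), day(0), FAR_END, vocab)
        assert [(l.start_date, l.end_date, l.end_reason) for l in a] == \
            [(l.start_date, l.end_date, l.end_reason) for l in b]


class TestCompletionStatus:
    def make_line(self, vocab, end, efd):
        rx = rx_frame([(day(0), "irinotecan")])
        [line] = derive_lines(rx, day(0), FAR_END, vocab)
        line.end_date = end
        line.expected_final_dose_date = efd
        return line

    def test_evaluability_needs_strictly_more_than_60_days(self, vocab):
        line = self.make_line(vocab, day(200), day(200))
        assert completion_status(line, False, day(261))[1] is True  # 61 days
        assert completion_status(line, False, day(260))[1] is False  # exactly 60

    def test_subsequent_line_makes_evaluable_regardless_of_margin(self, vocab):
        line = self.make_line(vocab, day(200), day(200))
        assert completion_status(line, True, day(201))[1] is True

    def test_completion_needs_60_days_or_more(self, vocab):
        line = self.make_line(vocab, day(300), day(300))
        assert completion_status(line, False, day(360))[0] is True  # exactly 60
        assert completion_status(line, False, day(359))[0] is False  # 59

    def test_annotate_sets_transition_flags(self, vocab):
        rx = rx_frame(
            biweekly(["fluorouracil", "leucovorin", "oxaliplatin"], day(0), 3)
            + biweekly(["fluorouracil", "leucovorin", "irinotecan"], day(80), 3)
        )
        lines = annotate_lines(derive_lines(rx, day(0), day(130), vocab), day(130))
        assert lines[0].transitioned and lines[0].evaluable_for_transition
        assert not lines[1].transitioned
        # line 2 ends at min(EFD day 80+28+14=122, data_end 130) = 122; margin 8
        assert not lines[1].evaluable_for_transition
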