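"""Cohort selection: inclusion, exclusions, windows, RAS proxy, subpopulation."""

from datetime import date, timedelta

from crclot.cohorts import (
    build_cohorts,
    first_crc_diagnosis,
    presume_ras_status,
)
from crclot.io import make_bundle


def bundle_of(patients, diagnoses=(), prescriptions=(), procedures=()):
    pats = []
    for pid, birth_year in patients:
        pats.append({"patient_id": pid, "sex": "male", "birth_year": birth_year,
                     "hospital_id": "H1", "data_end": date(2021, 12, 31)})
    return make_bundle(
        patients=pats,
        hospitals=[{"hospital_id": "H1", "bed_class": "200-499",
                    "designated_cancer": True}],
        diagnoses=[{"patient_id": p, "date": d, "icd10": c, "confirmed": conf}
                   for p, d, c, conf in diagnoses] or None,
        prescriptions=[{"patient_id": p, "date": d, "drug_id": drug, "dose": None,
                        "route": "intravenous", "days_supplied": sup}
                       for p, d, drug, sup in prescriptions] or None,
        procedures=[{"patient_id": p, "date": d, "kind": k}
                    for p, d, k in procedures] or None,
    )


def folfox_bev(pid, start, n_cycles):
    rows = []
    for c in range(n_cycles):
        d = start + timedelta(days=14 * c)
        for drug in ("fluorouracil", "leucovorin", "oxaliplatin", "bevacizumab"):
            rows.append((pid, d, drug, None))
    return rows


class TestFirstCrcDiagnosis:
    def test_earliest_confirmed_in_window(self):
        b = bundle_of([("P1", 1960)], diagnoses=[
            ("P1", date(2016, 1, 10), "C18.2", True),
            ("P1", date(2015, 6, 1), "C20", True),
        ])
        assert first_crc_diagnosis(b, "P1") == date(2015, 6, 1)

    def test_non_crc_codes_ignored(self):
        b = bundle_of([("P1", 1960)],
                      diagnoses=[("P1", date(2016, 1, 1), "C17.9", True)])
        assert first_crc_diagnosis(b, "P1") is None

    def test_unconfirmed_diagnoses_ignored(self):
        b = bundle_of([("P1", 1960)],
                      diagnoses=[("P1", date(2016, 1, 1), "C19", False)])
        assert first_crc_diagnosis(b, "P1") is None

    def test_diagnosis_window_bounds(self):
        b = bundle_of([("P1", 1960)], diagnoses=[
            ("P1", date(2014, 4, 30), "C18.0", True),
            ("P1", date(2019, 9, 1), "C18.0", True),
        ])
        assert first_crc_diagnosis(b, "P1") is None


class TestFirstLineSelection:
    def included(self, vocab, prescriptions, birth_year=1962, diagnoses=None):
        b = bundle_of([("P1", birth_year)],
                      diagnoses=diagnoses or [("P1", date(2016, 12, 1), "C18.2", True)],
                      prescriptions=prescriptions)
        return build_cohorts(b, vocab=vocab)

    def test_qualifying_patient_included_with_antibody_anchor(self, vocab):
        res = self.included(vocab, folfox_bev("P1", date(2017, 3, 1), 4))
        [m] = res.members
        assert m.population == "first_line"
        assert m.anchor_date == date(2017, 3, 1)
        assert m.therapy_start_date == date(2017, 3, 1)

    def test_prior_antibody_within_washout_excludes(self, vocab):
        rx = folfox_bev("P1", date(2017, 3, 1), 4)
        rx.append(("P1", date(2016, 8, 1), "cetuximab", None))
        res = self.included(vocab, rx)
        assert res.members == []
        steps = dict(res.logs["first_line"].steps)
        assert steps["no_prior_antibody_within_365d"] == 0

    def test_washout_is_365_days_closed(self, vocab):
        # the probe antibody predates the diagnosis, so the anchor stays put
        anchor = date(2017, 3, 1)
        # exactly 365 days before the anchor: inside the washout window
        rx = folfox_bev("P1", anchor, 4)
        rx.append(("P1", anchor - timedelta(days=365), "bevacizumab", None))
        assert self.included(vocab, rx).members == []
        # 366 days before: outside
        rx = folfox_bev("P1", anchor, 4)
        rx.append(("P1", anchor - timedelta(days=366), "bevacizumab", None))
        assert len(self.included(vocab, rx).members) == 1

    def test_age_19_excluded_and_20_included(self, vocab):
        # anchor 2017-03-01 is before July 1, so age = 2017 - birth_year - 1
        assert self.included(vocab, folfox_bev("P1", date(2017, 3, 1), 4),
                             birth_year=1997).members == []
        assert len(self.included(vocab, folfox_bev("P1", date(2017, 3, 1), 4),
                                 birth_year=1996).members) == 1

    def test_non_jsccr_antitumor_drug_excludes(self, vocab):
        rx = folfox_bev("P1", date(2017, 3, 1), 4)
        rx.append(("P1", date(2017, 5, 1), "sorafenib", 28))
        assert self.included(vocab, rx).members == []

    def test_pre_enrollment_start_excludes(self, vocab):
        res = self.included(vocab, folfox_bev("P1", date(2016, 4, 1), 4),
                            diagnoses=[("P1", date(2016, 1, 1), "C18.2", True)])
        assert res.members == []
        steps = dict(res.logs["first_line"].steps)
        assert steps["therapy_start_on_after_enrollment_start"] == 0


class TestEarlyRecurrenceSelection:
    def run(self, vocab, prescriptions, procedures, diagnoses=None, birth_year=1960):
        b = bundle_of([("P1", birth_year)],
                      diagnoses=diagnoses or [("P1", date(2016, 12, 1), "C19", True)],
                      prescriptions=prescriptions, procedures=procedures)
        return build_cohorts(b, vocab=vocab)

    def adjuvant_then_switch(self, surgery, adj_offset, switch_date):
        rx = []
        adj_start = surgery + timedelta(days=adj_offset)
        for c in range(5):
            rx.append(("P1", adj_start + timedelta(days=30 * c), "capecitabine", 21))
        rx += folfox_bev("P1", switch_date, 4)
        # swap to an irinotecan doublet so the switch introduces new drugs
        rx = [(p, d, drug if drug != "oxaliplatin" else "irinotecan", s)
              for p, d, drug, s in rx]
        return rx

    def test_early_recurrence_included_with_index_at_switch(self, vocab):
        surgery = date(2017, 1, 10)
        switch = surgery + timedelta(days=240)
        res = self.run(vocab, self.adjuvant_then_switch(surgery, 30, switch),
                       [("P1", surgery, "colorectal_resection")])
        [m] = res.members
        assert m.population == "early_recurrence"
        assert m.anchor_date == surgery
        assert m.therapy_start_date == surgery + timedelta(days=30)
        assert m.index_date == switch
        # adjuvant line, then second line
        assert [l.line_number for l in res.lines["P1"]] == [0, 2]

    def test_adjuvant_after_91_days_excluded(self, vocab):
        surgery = date(2017, 1, 10)
        res = self.run(vocab, self.adjuvant_then_switch(surgery, 100,
                                                        surgery + timedelta(days=300)),
                       [("P1", surgery, "colorectal_resection")])
        assert all(m.population != "early_recurrence" for m in res.members)

    def test_adjuvant_on_day_91_included(self, vocab):
        surgery = date(2017, 1, 10)
        res = self.run(vocab, self.adjuvant_then_switch(surgery, 91,
                                                        surgery + timedelta(days=330)),
                       [("P1", surgery, "colorectal_resection")])
        assert res.members[0].population == "early_recurrence"

    def test_biologic_within_91_days_of_chemo_start_excluded(self, vocab):
        surgery = date(2017, 1, 10)
        rx = [("P1", surgery + timedelta(days=20), "fluorouracil", None),
              ("P1", surgery + timedelta(days=34), "fluorouracil", None),
              ("P1", surgery + timedelta(days=60), "bevacizumab", None)]
        res = self.run(vocab, rx, [("P1", surgery, "colorectal_resection")])
        assert all(m.population != "early_recurrence" for m in res.members)

    def test_biologic_before_resection_excluded(self, vocab):
        surgery = date(2017, 3, 1)
        rx = self.adjuvant_then_switch(surgery, 30, surgery + timedelta(days=240))
        rx.append(("P1", surgery - timedelta(days=30), "bevacizumab", None))
        res = self.run(vocab, rx, [("P1", surgery, "colorectal_resection")],
                       diagnoses=[("P1", date(2017, 1, 1), "C19", True)])
        assert all(m.population != "early_recurrence" for m in res.members)

    def test_switch_window_183_days_boundary(self, vocab):
        surgery = date(2017, 1, 10)
        adj_start = surgery + timedelta(days=30)
        # single adjuvant prescription covering 21 days -> covered end known
        def rx_with_gap(gap):
            rx = [("P1", adj_start, "capecitabine", 21)]
            rx += folfox_bev("P1", adj_start + timedelta(days=21 + gap), 4)
            return rx
        res = self.run(vocab, rx_with_gap(183),
                       [("P1", surgery, "colorectal_resection")])
        assert res.members[0].population == "early_recurrence"
        res = self.run(vocab, rx_with_gap(184),
                       [("P1", surgery, "colorectal_resection")])
        assert all(m.population != "early_recurrence" for m in res.members)


class TestRasPresumption:
    def test_anti_egfr_in_any_line_means_wild_type(self, vocab):
        b = bundle_of([("P1", 1960)],
                      prescriptions=[("P1", date(2018, 5, 1), "panitumumab", None)])
        assert presume_ras_status(b.prescriptions, "P1",
                                  (date(2014, 5, 1), date(2019, 9, 30))) == "wild_type"

    def test_antiangiogenics_alone_mean_mutant(self, vocab):
        b = bundle_of([("P1", 1960)], prescriptions=[
            ("P1", date(2018, 5, 1), "bevacizumab", None),
            ("P1", date(2018, 8, 1), "ramucirumab", None),
        ])
        assert presume_ras_status(b.prescriptions, "P1",
                                  (date(2014, 5, 1), date(2019, 9, 30))) == "mutant"

    def test_anti_egfr_after_window_end_means_mutant(self, vocab):
        b = bundle_of([("P1", 1960)],
                      prescriptions=[("P1", date(2019, 10, 15), "cetuximab", None)])
        assert presume_ras_status(b.prescriptions, "P1",
                                  (date(2014, 5, 1), date(2019, 9, 30))) == "mutant"


class TestFolfiriAASubpopulation:
    def second_line_bundle(self, vocab, second_line_rows):
        rx = folfox_bev("P1", date(2017, 3, 1), 4)
        rx += second_line_rows
        b = bundle_of([("P1", 1960)],
                      diagnoses=[("P1", date(2016, 12, 1), "C18.2", True)],
                      prescriptions=rx)
        return build_cohorts(b, vocab=vocab)

    def test_folfiri_plus_ramucirumab_in_subpop(self, vocab):
        start = date(2017, 8, 1)
        rows = [("P1", start, d, None)
                for d in ("fluorouracil", "leucovorin", "irinotecan", "ramucirumab")]
        res = self.second_line_bundle(vocab, rows)
        [m] = res.members
        assert m.in_folfiri_aa_subpop and m.second_line_aa_drug == "ramucirumab"

    def test_wrong_backbone_not_in_subpop(self, vocab):
        start = date(2017, 8, 1)
        rows = [("P1", start, d, None)
                for d in ("capecitabine", "irinotecan", "bevacizumab")]
        res = self.second_line_bundle(vocab, rows)
        [m] = res.members
        assert not m.in_folfiri_aa_subpop and m.second_line_aa_drug is None

    def test_multi_antiangiogenic_tie_goes_to_earliest(self, vocab):
        start = date(2017, 8, 1)
        rows = [("P1", start, d, None)
                for d in ("fluorouracil", "leucovorin", "irinotecan", "bevacizumab")]
        rows.append(("P1", start + timedelta(days=14), "ramucirumab", None))
        res = self.second_line_bundle(vocab, rows)
        [m] = res.members
        # ramucirumab at day 14 is a second biologic: a new line starts there,
        # so the second line's window holds bevacizumab only
        assert m.second_line_aa_drug == "bevacizumab"

    def test_same_day_tie_broken_by_fixed_drug_order(self, vocab):
        start = date(2017, 8, 1)
        rows = [("P1", start, d, None)
                for d in ("fluorouracil", "leucovorin", "irinotecan",
                          "ramucirumab", "bevacizumab")]
        res = self.second_line_bundle(vocab, rows)
        [m] = res.members
        assert m.second_line_aa_drug == "bevacizumab"
        assert m.multi_aa


def test_populations_disjoint_and_logs_monotone(vocab):
    from crclot.simulate import SimulationConfig, analysis_config_for_simulation, \
        simulate_bundle

    cfg = SimulationConfig(n_patients=150, seed=42)
    bundle, _ = simulate_bundle(cfg)
    res = build_cohorts(bundle, vocab, analysis_config_for_simulation(cfg))
    pops = {}
    for m in res.members:
        assert m.patient_id not in pops
        pops[m.patient_id] = m.population
    for log in res.logs.values():
        counts = [n for _, n in log.steps]
        assert counts == sorted(counts, reverse=True)
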