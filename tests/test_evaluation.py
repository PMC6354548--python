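"""Contingency construction, agreement metrics, kappa, majority voting,
and the discrepancy decision tree."""

from __future__ import annotations

import math

import numpy as np
import pytest

from volscribe import (
    ClinicalKnowledgeFilter,
    CodedFinding,
    ContingencyCounts,
    DiscrepancyRecord,
    agreement_metrics,
    build_contingency,
    categorize_discrepancy,
    cohen_kappa,
    majority_vote,
)
from volscribe.io import load_reader_study_counts

UNIVERSE23 = [f"term{i}" for i in range(23)]
CASES92 = [f"case{i}" for i in range(92)]


def _findings(source, positives):
    return [
        CodedFinding(case_id=c, structure_term=t, polarity="positive", source=source)
        for c, t in positives
    ]


class TestContingency:
    def test_empty_findings_are_all_true_negative(self):
        c = build_contingency([], [], UNIVERSE23, CASES92)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 2116)
        assert c.total == 92 * 23

    def test_single_agreeing_positive(self):
        ref = _findings("RR1", [("case0", "term0")])
        test = _findings("AS", [("case0", "term0")])
        c = build_contingency(ref, test, ["term0"], ["case0"])
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(31)
        universe, cases = UNIVERSE23[:7], CASES92[:15]
        ref_pos = {(c, t) for c in cases for t in universe if rng.random() < 0.2}
        test_pos = {(c, t) for c in cases for t in universe if rng.random() < 0.2}
        c = build_contingency(
            _findings("RR1", ref_pos), _findings("AS", test_pos), universe, cases
        )
        tp = fp = fn = tn = 0
        for case in cases:
            for term in universe:
                r, t = (case, term) in ref_pos, (case, term) in test_pos
                tp += r and t
                fp += t and not r
                fn += r and not t
                tn += not r and not t
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_out_of_universe_terms_are_excluded(self):
        test = _findings("AS", [("case0", "not_a_term")])
        c = build_contingency([], test, ["term0"], ["case0"])
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 1)

    def test_case_order_is_irrelevant(self):
        rng = np.random.default_rng(8)
        pos = {(c, t) for c in CASES92 for t in UNIVERSE23 if rng.random() < 0.05}
        a = build_contingency(_findings("RR1", pos), [], UNIVERSE23, CASES92)
        b = build_contingency(_findings("RR1", pos), [], UNIVERSE23, CASES92[::-1])
        assert a == b


class TestMetrics:
    def test_tissue_presence_metrics(self):
        m = agreement_metrics(ContingencyCounts(45, 12, 15, 20))
        assert round(100 * m["accuracy"], 1) == 70.7
        assert round(100 * m["sensitivity"], 1) == 75.0
        assert round(100 * m["precision"], 1) == 78.9
        assert round(100 * m["specificity"], 1) == 62.5

    def test_ventricle_metrics_saturated_sensitivity(self):
        m = agreement_metrics(ContingencyCounts(5, 30, 0, 57))
        assert round(100 * m["sensitivity"], 1) == 100.0
        assert round(100 * m["precision"], 1) == 14.3

    def test_degenerate_all_negative(self):
        m = agreement_metrics(ContingencyCounts(0, 0, 0, 10))
        assert m["accuracy"] == 1.0
        assert math.isnan(m["sensitivity"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            agreement_metrics(ContingencyCounts(0, 0, 0, 0))


class TestKappa:
    def test_printed_tables(self):
        assert round(cohen_kappa(ContingencyCounts(23, 94, 98, 1901)), 2) == 0.15
        assert round(cohen_kappa(ContingencyCounts(39, 82, 82, 1913)), 2) == 0.28

    def test_perfect_agreement(self):
        assert cohen_kappa(ContingencyCounts(7, 0, 0, 13)) == pytest.approx(1.0)

    def test_degenerate_marginals_are_not_a_value(self):
        assert math.isnan(cohen_kappa(ContingencyCounts(0, 0, 0, 5)))

    def test_matches_sklearn_on_random_tables(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(13)
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 50, size=4)
            c = ContingencyCounts(int(tp), int(fp), int(fn), int(tn))
            ref = np.r_[np.ones(tp), np.zeros(fp), np.ones(fn), np.zeros(tn)]
            test = np.r_[np.ones(tp), np.ones(fp), np.zeros(fn), np.zeros(tn)]
            assert cohen_kappa(c) == pytest.approx(
                sk.cohen_kappa_score(ref, test), rel=1e-12
            )

    def test_sign_agrees_with_observed_vs_expected_on_all_printed_tables(self):
        bundle = load_reader_study_counts()
        for section in ("tissue_presence", "ventricle_presence", "structure_level"):
            for tp, fp, fn, tn in bundle[section].values():
                c = ContingencyCounts(tp, fp, fn, tn)
                n = c.total
                p_o = (tp + tn) / n
                p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
                assert (cohen_kappa(c) >= 0) == (p_o >= p_e)


class TestMajorityVote:
    def test_two_of_three_is_positive(self):
        findings = _findings("RR1", [("c", "t")]) + _findings("RR2", [("c", "t")]) + [
            CodedFinding("c", "other", "positive", "RR3")
        ]
        out = majority_vote(findings, ["t", "other"], ["c"])
        assert [(f.case_id, f.structure_term) for f in out] == [("c", "t")]
        assert all(f.source == "RRm" for f in out)

    def test_single_rater_is_negative(self):
        findings = (
            _findings("RR3", [("c", "t")])
            + [CodedFinding("c", "u", "negative", "RR1")]
            + [CodedFinding("c", "u", "negative", "RR2")]
        )
        assert majority_vote(findings, ["t", "u"], ["c"]) == []

    def test_wrong_source_count_rejected(self):
        findings = _findings("RR1", [("c", "t")]) + _findings("RR2", [("c", "t")])
        with pytest.raises(ValueError, match="exactly 3"):
            majority_vote(findings, ["t"], ["c"])

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(99)
        universe, cases = UNIVERSE23[:6], CASES92[:20]
        per_rater = {
            s: {(c, t) for c in cases for t in universe if rng.random() < 0.3}
            for s in ("RR1", "RR2", "RR3")
        }
        findings = [f for s, pos in per_rater.items() for f in _findings(s, pos)]
        out = {(f.case_id, f.structure_term) for f in majority_vote(findings, universe, cases)}
        expected = {
            (c, t)
            for c in cases
            for t in universe
            if sum((c, t) in per_rater[s] for s in per_rater) >= 2
        }
        assert out == expected


@pytest.fixture(scope="module")
def ckf():
    return ClinicalKnowledgeFilter.default()


class TestDiscrepancyTree:
    def test_unrepresentable_term_is_category_1(self, hierarchy, ckf):
        rec = DiscrepancyRecord("c", "FN", "medial temporal lobe")
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "1"

    def test_structure_never_used_by_raters_is_2_1(self, hierarchy, ckf):
        rec = DiscrepancyRecord(
            "c", "FP", "left occipital lobe",
            rater_vocabulary=frozenset({"left hippocampus", "left hemisphere"}),
        )
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "2-1"

    def test_structure_outside_filter_is_2_2(self, hierarchy, ckf):
        rec = DiscrepancyRecord("c", "FN", "left amygdala")
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "2-2"

    def test_supported_but_suppressed_finding_is_category_3(self, hierarchy, ckf):
        rec = DiscrepancyRecord("c", "FN", "left frontal lobe", z_value=-2.24)
        out = categorize_discrepancy(rec, hierarchy, ckf)
        assert out.category == "3"
        assert "-2.24" in out.rationale

    def test_hierarchy_extent_mismatch_is_category_4(self, hierarchy, ckf):
        rec = DiscrepancyRecord(
            "c", "FP", "left hemisphere",
            counterpart_terms=("left front-temporal lobe",),
        )
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "4"

    def test_segmentation_flag_is_category_5(self, hierarchy, ckf):
        rec = DiscrepancyRecord(
            "c", "FN", "left hippocampus", z_value=-1.2,
            annotations=frozenset({"segmentation_error"}),
        )
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "5"

    def test_remaining_discrepancies_fall_to_category_6_by_direction(self, hierarchy, ckf):
        fp = DiscrepancyRecord("c", "FP", "left temporal lobe")
        fn = DiscrepancyRecord("c", "FN", "left temporal lobe", z_value=-1.4)
        assert categorize_discrepancy(fp, hierarchy, ckf).category == "6-FP"
        assert categorize_discrepancy(fn, hierarchy, ckf).category == "6-FN"

    def test_tree_order_category_1_wins_over_annotations(self, hierarchy, ckf):
        rec = DiscrepancyRecord(
            "c", "FN", "global", annotations=frozenset({"segmentation_error"})
        )
        assert categorize_discrepancy(rec, hierarchy, ckf).category == "1"

    def test_concordant_cells_rejected(self):
        with pytest.raises(ValueError, match="FP or FN"):
            DiscrepancyRecord("c", "TP", "left hippocampus")
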