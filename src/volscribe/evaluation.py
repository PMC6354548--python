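"""Agreement evaluation between automated sentences and coded human findings.

The human radiologic report (RR) is treated as the gold standard.  Findings
from two sources are compared over a fixed universe of structure terms and a
fixed case list: each (case, term) cell is a true positive, false positive,
false negative, or true negative, so the counts always sum to
``len(cases) * len(universe)``.  From the 2x2 table the module computes
accuracy, sensitivity, precision, specificity and Cohen's kappa, builds a
2-of-3 majority-vote consensus rater, and classifies each discrepant cell
into the six-branch error taxonomy:

1      the term cannot be represented in the anatomy hierarchy;
2-1    the automated system reported a structure the raters never evaluate;
2-2    the raters used a structure the clinical knowledge filter dropped;
3      the quantitative z-score supports the finding but relational rule
       logic suppressed the sentence;
4      the two sources used terms that differ only in hierarchy extent
       (ancestor vs descendant);
5      a rater attributed the discrepancy to segmentation quality
       (supplied as an annotation flag -- it encodes visual judgment);
6-FP / 6-FN   remaining threshold-attributable disagreements.

Branches are evaluated strictly in this order, so the categories are
mutually exclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .anatomy import LOBES, SIDES, SIDE_SUFFIX, OntologyHierarchy
from .reporting import ClinicalKnowledgeFilter

__all__ = [
    "CodedFinding",
    "ContingencyCounts",
    "ErrorCategory",
    "DiscrepancyRecord",
    "build_contingency",
    "agreement_metrics",
    "cohen_kappa",
    "majority_vote",
    "categorize_discrepancy",
    "default_term_aliases",
]

logger = logging.getLogger(__name__)

SOURCES = ("AS", "RR1", "RR2", "RR3", "RRm")


@dataclass(frozen=True)
class CodedFinding:
    """One coded per-structure assertion from one source for one case."""

    case_id: str
    structure_term: str
    polarity: str  # positive | negative
    source: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


def _positives(
    findings: Iterable[CodedFinding],
    universe: Sequence[str],
    cases: Sequence[str],
) -> set[tuple[str, str]]:
    uni = set(universe)
    case_set = set(cases)
    pos = set()
    for f in findings:
        if f.structure_term not in uni:
            logger.info(
                "finding %r for case %s (source %s) outside universe; excluded",
                f.structure_term, f.case_id, f.source,
            )
            continue
        if f.case_id not in case_set:
            logger.info("case %s outside case list; excluded", f.case_id)
            continue
        if f.polarity == "positive":
            pos.add((f.case_id, f.structure_term))
    return pos


def build_contingency(
    ref_findings: Iterable[CodedFinding],
    test_findings: Iterable[CodedFinding],
    universe: Sequence[str],
    cases: Sequence[str],
) -> ContingencyCounts:
    """2x2 counts of ``test_findings`` against the ``ref_findings`` gold
    standard over every (case, term) cell."""
    if not universe:
        raise ValueError("structure universe is empty")
    ref_pos = _positives(ref_findings, universe, cases)
    test_pos = _positives(test_findings, universe, cases)
    n_cells = len(set(cases)) * len(set(universe))
    tp = len(ref_pos & test_pos)
    fp = len(test_pos - ref_pos)
    fn = len(ref_pos - test_pos)
    return ContingencyCounts(tp=tp, fp=fp, fn=fn, tn=n_cells - tp - fp - fn)


def agreement_metrics(c: ContingencyCounts) -> dict[str, float]:
    """Accuracy, sensitivity, precision, specificity as fractions in [0, 1].

    A metric whose denominator is zero is returned as NaN (an explicit
    not-a-value marker), never as a silent 0.
    """
    if c.total == 0:
        raise ValueError("empty contingency table")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "precision": ratio(c.tp, c.tp + c.fp),
        "specificity": ratio(c.tn, c.tn + c.fp),
    }


def cohen_kappa(c: ContingencyCounts) -> float:
    """Chance-corrected agreement from a 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with marginal-product expected
    agreement; NaN when p_e == 1 (degenerate marginals).
    """
    n = c.total
    if n == 0:
        raise ValueError("empty contingency table")
    p_o = (c.tp + c.tn) / n
    p_test_pos = (c.tp + c.fp) / n
    p_ref_pos = (c.tp + c.fn) / n
    p_e = p_test_pos * p_ref_pos + (1 - p_test_pos) * (1 - p_ref_pos)
    if p_e == 1.0:
        return math.nan
    return (p_o - p_e) / (1 - p_e)


def majority_vote(
    findings: Iterable[CodedFinding],
    universe: Sequence[str],
    cases: Sequence[str],
) -> list[CodedFinding]:
    """Consensus findings (source ``RRm``): positive when at least two of
    exactly three rater sources are positive."""
    findings = list(findings)
    sources = sorted({f.source for f in findings})
    if len(sources) != 3:
        raise ValueError(f"majority voting needs exactly 3 rater sources, got {sources}")
    uni = set(universe)
    case_set = set(cases)
    votes: dict[tuple[str, str], set[str]] = {}
    for f in findings:
        if f.polarity == "positive" and f.structure_term in uni and f.case_id in case_set:
            votes.setdefault((f.case_id, f.structure_term), set()).add(f.source)
    return [
        CodedFinding(case_id=cid, structure_term=term, polarity="positive", source="RRm")
        for (cid, term), srcs in sorted(votes.items())
        if len(srcs) >= 2
    ]


# ---------------------------------------------------------------------------
# discrepancy categorization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorCategory:
    category: str  # 1 | 2-1 | 2-2 | 3 | 4 | 5 | 6-FP | 6-FN
    rationale: str


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One FP or FN cell prepared for the decision tree.

    ``term`` is the discrepant structure term (the automated term for an FP,
    the rater term for an FN); ``counterpart_terms`` are the other source's
    positive terms for the same case (used for the hierarchy-extent branch);
    ``z_value`` is the case z-score for the term's structure, when it maps
    into the hierarchy; ``rater_vocabulary`` is the set of terms the raters
    ever used across the study; annotation flags carry human judgments such
    as ``segmentation_error``.
    """

    case_id: str
    direction: str  # FP | FN
    term: str
    counterpart_terms: tuple[str, ...] = ()
    z_value: float | None = None
    rater_vocabulary: frozenset[str] | None = None
    annotations: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.direction not in ("FP", "FN"):
            raise ValueError(
                f"discrepancy records must be FP or FN, got {self.direction!r}"
            )


def default_term_aliases() -> dict[str, tuple[str, ...]]:
    """Map common report phrasing onto hierarchy structure ids.

    Multi-lobe phrases map to the id set they span, so hierarchy-extent
    comparisons can treat e.g. "left front-temporal lobe" as
    {frontal_L, temporal_L}.
    """
    aliases: dict[str, tuple[str, ...]] = {}
    for side in SIDES:
        sfx = SIDE_SUFFIX[side]
        aliases[f"{side} hemisphere"] = (f"hemisphere_{sfx}",)
        for lobe in LOBES:
            aliases[f"{side} {lobe} lobe"] = (f"{lobe}_{sfx}",)
        aliases[f"{side} front-temporal lobe"] = (f"frontal_{sfx}", f"temporal_{sfx}")
        aliases[f"{side} hippocampus"] = (f"hippocampus_{sfx}",)
        aliases[f"{side} caudate"] = (f"caudate_{sfx}",)
        aliases[f"{side} amygdala"] = (f"amygdala_{sfx}",)
        aliases[f"{side} lateral ventricle"] = (f"lateral_ventricle_{sfx}",)
    aliases["third ventricle"] = ("third_ventricle",)
    aliases["deep sulci"] = ("deep_sulci",)
    aliases["cerebellum"] = ("cerebellum",)
    aliases["brainstem"] = ("brainstem",)
    return aliases


def _resolve(
    term: str, h: OntologyHierarchy, aliases: Mapping[str, tuple[str, ...]]
) -> tuple[str, ...] | None:
    if term in h:
        return (term,)
    ids = aliases.get(term)
    if ids and all(sid in h for sid in ids):
        return tuple(ids)
    return None


def _base_span(ids: Sequence[str], h: OntologyHierarchy) -> frozenset[str]:
    span: set[str] = set()
    for sid in ids:
        span |= h.base_descendants(sid)
    return frozenset(span)


def categorize_discrepancy(
    record: DiscrepancyRecord,
    hierarchy: OntologyHierarchy,
    ckf: ClinicalKnowledgeFilter,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> ErrorCategory:
    """Classify one FP/FN cell with the ordered six-branch decision tree."""
    aliases = aliases if aliases is not None else default_term_aliases()
    ids = _resolve(record.term, hierarchy, aliases)

    if ids is None:
        return ErrorCategory(
            "1", f"term {record.term!r} is not representable in the hierarchy"
        )

    if record.direction == "FP" and record.rater_vocabulary is not None:
        if record.term not in record.rater_vocabulary:
            return ErrorCategory(
                "2-1",
                f"automated term {record.term!r} was never used by any rater",
            )

    if record.direction == "FN":
        reported = set(ckf.reported_structures)
        if not any(sid in reported for sid in ids):
            return ErrorCategory(
                "2-2",
                f"rater term {record.term!r} maps to structures outside the "
                "clinical knowledge filter",
            )
        if record.z_value is not None:
            direction = ckf.directions.get(ids[0], "atrophy")
            supported = (
                record.z_value < -ckf.threshold
                if direction == "atrophy"
                else record.z_value > ckf.threshold
            )
            if supported:
                return ErrorCategory(
                    "3",
                    f"z = {record.z_value:.2f} supports {record.term!r} but the "
                    "relational rule logic suppressed the sentence",
                )

    span = _base_span(ids, hierarchy)
    for other in record.counterpart_terms:
        other_ids = _resolve(other, hierarchy, aliases)
        if other_ids is None:
            continue
        other_span = _base_span(other_ids, hierarchy)
        if span != other_span and (span <= other_span or other_span <= span):
            return ErrorCategory(
                "4",
                f"{record.term!r} and {other!r} differ only in hierarchy extent",
            )

    if "segmentation_error" in record.annotations:
        return ErrorCategory("5", "rater attributed the discrepancy to segmentation")

    return ErrorCategory(
        f"6-{record.direction}",
        "threshold-attributable disagreement "
        f"({'sentence over-triggered' if record.direction == 'FP' else 'sentence not triggered'})",
    )
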