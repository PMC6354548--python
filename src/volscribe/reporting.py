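"""Clinical knowledge filter: thresholded findings and sentence rendering.

Of the full structure list only a curated subset (20 by default) can ever
produce a sentence.  Three trigger classes exist:

* *direct* -- a single non-lobar structure crosses the threshold, e.g.
  ``z(hippocampus_L) < -2.0`` -> "The left hippocampus has atrophy.";
* *relational* -- hemisphere-level atrophy ("left"/"right"/"bilateral"),
  optionally with a nested "prominent" clause when the atrophy within an
  atrophic hemisphere is localized to a small proper subset of its lobes;
* *combination* -- "specific" lobar-combination sentences that fire only
  when there is NO hemispheric atrophy (hemispheric atrophy suppresses
  them: atrophy is no longer specific to those lobes).

Ventricular and sulcal structures trigger on enlargement (``z > +T``),
tissue structures on atrophy (``z < -T``); the threshold T is 2.0 z-score
units by default.

``enumerate_rule_table`` expands the relational logic into an explicit
Boolean rule table over the 12 hemisphere/lobe indicators so that the
detection algorithm can be audited and tested for exact equivalence by
exhaustive enumeration of all 4,096 indicator assignments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations, product
from typing import Mapping, Sequence

from .anatomy import LOBES, SIDES, SIDE_SUFFIX, OntologyHierarchy
from .normative import ZScoreTable

__all__ = [
    "ClinicalKnowledgeFilter",
    "FindingPattern",
    "Assertion",
    "SentenceReport",
    "Rule",
    "detect_pattern",
    "sentence_keys",
    "enumerate_rule_table",
    "render_report",
    "default_dictionary",
    "load_dictionary",
]

HEMISPHERES = {"left": "hemisphere_L", "right": "hemisphere_R"}
#: The 12 relational indicator structures (2 hemispheres + 10 lobes).
INDICATORS = tuple(HEMISPHERES.values()) + tuple(
    f"{lobe}_{SIDE_SUFFIX[side]}" for side in SIDES for lobe in LOBES
)

DEFAULT_REPORTED_STRUCTURES = (
    # 16 brain-tissue entries
    "hemisphere_L", "hemisphere_R",
    "frontal_L", "frontal_R",
    "parietal_L", "parietal_R",
    "temporal_L", "temporal_R",
    "occipital_L", "occipital_R",
    "limbic_L", "limbic_R",
    "hippocampus_L", "hippocampus_R",
    "caudate_L", "caudate_R",
    # 4 non-tissue entries (ventricles and deep sulci)
    "lateral_ventricle_L", "lateral_ventricle_R",
    "third_ventricle", "deep_sulci",
)

DEFAULT_DIRECTIONS = {
    sid: ("enlargement" if sid in (
        "lateral_ventricle_L", "lateral_ventricle_R", "third_ventricle", "deep_sulci"
    ) else "atrophy")
    for sid in DEFAULT_REPORTED_STRUCTURES
}


@dataclass(frozen=True)
class ClinicalKnowledgeFilter:
    """Which structures may be reported, in which direction, at what threshold."""

    reported_structures: tuple[str, ...] = DEFAULT_REPORTED_STRUCTURES
    directions: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_DIRECTIONS)
    )
    threshold: float = 2.0
    prominence_max_lobes: int = 2

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if self.prominence_max_lobes < 0:
            raise ValueError("prominence_max_lobes must be >= 0")
        for sid in self.reported_structures:
            if self.directions.get(sid) not in ("atrophy", "enlargement"):
                raise ValueError(f"no trigger direction for reported structure {sid!r}")

    @classmethod
    def default(cls) -> "ClinicalKnowledgeFilter":
        return cls()

    def validate_against(self, h: OntologyHierarchy) -> None:
        unknown = [sid for sid in self.reported_structures if sid not in h]
        if unknown:
            raise ValueError(f"reported structures missing from hierarchy: {unknown}")

    @property
    def direct_structures(self) -> tuple[str, ...]:
        """Reported structures handled by direct (non-relational) triggering."""
        return tuple(
            sid for sid in self.reported_structures
            if sid not in INDICATORS and self.directions[sid] == "atrophy"
        )

    @property
    def enlargement_structures(self) -> tuple[str, ...]:
        return tuple(
            sid for sid in self.reported_structures
            if self.directions[sid] == "enlargement"
        )


@dataclass(frozen=True)
class FindingPattern:
    """Machine-readable abnormality pattern for one case.

    ``prominent_lobes`` is populated only under hemispheric atrophy;
    ``specific_combo`` only in its absence (the suppression rule).
    Direct and ventricular findings are ordered tuples following the
    filter's reported-structure order.
    """

    hemispheric_state: str = "none"  # none | left | right | bilateral
    affected_lobes: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {"left": frozenset(), "right": frozenset()}
    )
    prominent_lobes: Mapping[str, frozenset[str]] = field(default_factory=dict)
    specific_combo: Mapping[str, frozenset[str]] = field(default_factory=dict)
    direct_findings: tuple[tuple[str, str], ...] = ()
    ventricular_findings: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.specific_combo and self.hemispheric_state != "none":
            raise ValueError("specific combinations are suppressed under hemispheric atrophy")
        if self.prominent_lobes and self.hemispheric_state == "none":
            raise ValueError("prominence requires hemispheric atrophy")

    @property
    def is_empty(self) -> bool:
        return (
            self.hemispheric_state == "none"
            and not self.specific_combo
            and not self.direct_findings
            and not self.ventricular_findings
        )


def _zmap(z: ZScoreTable | Mapping[str, float]) -> Mapping[str, float]:
    return z.z if isinstance(z, ZScoreTable) else z


def detect_pattern(
    z: ZScoreTable | Mapping[str, float], ckf: ClinicalKnowledgeFilter
) -> FindingPattern:
    """Apply the clinical knowledge filter to a z-score table."""
    zs = _zmap(z)
    missing = [sid for sid in INDICATORS
               if sid not in zs or not math.isfinite(zs[sid])]
    if missing:
        raise ValueError(f"z-scores missing for indicator structures: {missing}")
    T = ckf.threshold

    hemi = {side: zs[HEMISPHERES[side]] < -T for side in SIDES}
    if hemi["left"] and hemi["right"]:
        state = "bilateral"
    elif hemi["left"]:
        state = "left"
    elif hemi["right"]:
        state = "right"
    else:
        state = "none"

    affected = {
        side: frozenset(
            lobe for lobe in LOBES if zs[f"{lobe}_{SIDE_SUFFIX[side]}"] < -T
        )
        for side in SIDES
    }

    prominent: dict[str, frozenset[str]] = {}
    specific: dict[str, frozenset[str]] = {}
    if state != "none":
        for side in SIDES:
            if hemi[side]:
                aff = affected[side]
                if 0 < len(aff) < len(LOBES) and len(aff) <= ckf.prominence_max_lobes:
                    prominent[side] = aff
    else:
        for side in SIDES:
            if affected[side]:
                specific[side] = affected[side]

    direct = tuple(
        (sid, "atrophy")
        for sid in ckf.direct_structures
        if sid in zs and math.isfinite(zs[sid]) and zs[sid] < -T
    )
    ventricular = tuple(
        (sid, "enlargement")
        for sid in ckf.enlargement_structures
        if sid in zs and math.isfinite(zs[sid]) and zs[sid] > T
    )
    return FindingPattern(
        hemispheric_state=state,
        affected_lobes=affected,
        prominent_lobes=prominent,
        specific_combo=specific,
        direct_findings=direct,
        ventricular_findings=ventricular,
    )


def _lobe_tuple(lobes: frozenset[str]) -> tuple[str, ...]:
    return tuple(l for l in LOBES if l in lobes)


def sentence_keys(p: FindingPattern) -> tuple[tuple, ...]:
    """Canonical ordered sentence keys for a pattern.

    Order: hemispheric, prominence clauses, specific combinations, direct
    findings, ventricular/sulcal findings.  Rendering maps each key to
    exactly one sentence.
    """
    keys: list[tuple] = []
    if p.hemispheric_state != "none":
        keys.append(("hemispheric", p.hemispheric_state))
        for side in SIDES:
            if side in p.prominent_lobes:
                keys.append(("prominent", side, _lobe_tuple(p.prominent_lobes[side])))
    else:
        left = p.specific_combo.get("left")
        right = p.specific_combo.get("right")
        if left and left == right:
            keys.append(("specific", "bilateral", _lobe_tuple(left)))
        else:
            for side in SIDES:
                combo = p.specific_combo.get(side)
                if combo:
                    keys.append(("specific", side, _lobe_tuple(combo)))
    keys.extend(("direct", sid) for sid, _ in p.direct_findings)
    keys.extend(("ventricular", sid) for sid, _ in p.ventricular_findings)
    return tuple(keys)


# ---------------------------------------------------------------------------
# explicit rule table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """A conjunction over thresholded indicators and the key it triggers.

    ``condition`` maps indicator id -> required atrophy state; indicators
    absent from the map are unconstrained.
    """

    condition: tuple[tuple[str, bool], ...]
    key: tuple

    def fires(self, assignment: Mapping[str, bool]) -> bool:
        return all(assignment[sid] is want for sid, want in self.condition)


def enumerate_rule_table(ckf: ClinicalKnowledgeFilter) -> list[Rule]:
    """Expand the relational/combination logic into explicit Boolean rules.

    The table is generated from the sentence definitions, not from
    :func:`detect_pattern`, so exhaustive agreement between the two over all
    2^12 indicator assignments is a meaningful audit.
    """
    rules: list[Rule] = []
    hemi_l, hemi_r = HEMISPHERES["left"], HEMISPHERES["right"]

    # hemispheric atrophy: left / right / bilateral
    rules.append(Rule(((hemi_l, True), (hemi_r, False)), ("hemispheric", "left")))
    rules.append(Rule(((hemi_l, False), (hemi_r, True)), ("hemispheric", "right")))
    rules.append(Rule(((hemi_l, True), (hemi_r, True)), ("hemispheric", "bilateral")))

    # nested prominence: within an atrophic hemisphere, the affected lobes
    # form a nonempty proper subset of bounded size
    max_k = min(ckf.prominence_max_lobes, len(LOBES) - 1)
    for side in SIDES:
        hemi_id = HEMISPHERES[side]
        sfx = SIDE_SUFFIX[side]
        for k in range(1, max_k + 1):
            for subset in combinations(LOBES, k):
                cond = [(hemi_id, True)]
                cond += [(f"{lobe}_{sfx}", lobe in subset) for lobe in LOBES]
                rules.append(Rule(tuple(cond), ("prominent", side, subset)))

    # specific lobar combinations: only without hemispheric atrophy; the
    # full joint assignment of all ten lobes determines the emitted keys
    for left_bits, right_bits in product(
        product((False, True), repeat=len(LOBES)), repeat=2
    ):
        left = tuple(l for l, b in zip(LOBES, left_bits) if b)
        right = tuple(l for l, b in zip(LOBES, right_bits) if b)
        if not left and not right:
            continue
        cond = [(hemi_l, False), (hemi_r, False)]
        cond += [(f"{lobe}_L", b) for lobe, b in zip(LOBES, left_bits)]
        cond += [(f"{lobe}_R", b) for lobe, b in zip(LOBES, right_bits)]
        if left and left == right:
            emitted = [("specific", "bilateral", left)]
        else:
            emitted = []
            if left:
                emitted.append(("specific", "left", left))
            if right:
                emitted.append(("specific", "right", right))
        for key in emitted:
            rules.append(Rule(tuple(cond), key))
    return rules


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assertion:
    """Machine-readable counterpart of one rendered sentence."""

    term: str
    qualifier: str  # plain | prominent | specific
    polarity: str  # atrophy | enlargement
    structures: tuple[str, ...]


@dataclass(frozen=True)
class SentenceReport:
    sentences: tuple[str, ...]
    assertions: tuple[Assertion, ...]

    def to_text(self) -> str:
        return "\n".join(self.sentences)

    def to_json_payload(self) -> list[dict]:
        return [
            {
                "sentence": s,
                "term": a.term,
                "qualifier": a.qualifier,
                "polarity": a.polarity,
                "structures": list(a.structures),
            }
            for s, a in zip(self.sentences, self.assertions)
        ]


#: Hyphenated stems for multi-lobe phrases ("front-temporal", "parieto-occipital").
_LOBE_STEMS = {
    "frontal": "front",
    "parietal": "parieto",
    "temporal": "temporo",
    "occipital": "occipito",
    "limbic": "limbo",
}

_HEMI_TERMS = {
    "left": "left hemisphere",
    "right": "right hemisphere",
    "bilateral": "bilateral hemispheres",
}


def lobe_phrase(lobes: Sequence[str]) -> str:
    """Human phrase for a lobe combination: ``('frontal','temporal')`` ->
    ``'front-temporal'``; a single lobe keeps its full adjective."""
    ordered = [l for l in LOBES if l in lobes]
    if not ordered:
        raise ValueError("empty lobe combination")
    if len(ordered) == 1:
        return ordered[0]
    return "-".join([_LOBE_STEMS[l] for l in ordered[:-1]] + [ordered[-1]])


def default_dictionary() -> dict:
    """The packaged sentence dictionary (templates + structure terms)."""
    text = resources.files("volscribe").joinpath("data/sentence_dictionary.json").read_text()
    return json.loads(text)


def load_dictionary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _template(dictionary: dict, key: str, structure: str | None = None) -> str:
    templates = dictionary.get("templates", {})
    if structure is not None and f"{key}:{structure}" in templates:
        return templates[f"{key}:{structure}"]
    if key not in templates:
        raise KeyError(f"sentence dictionary has no template for key {key!r}")
    return templates[key]


def _term(dictionary: dict, sid: str) -> str:
    terms = dictionary.get("terms", {})
    if sid not in terms:
        raise KeyError(f"sentence dictionary has no term for structure {sid!r}")
    return terms[sid]


def render_report(p: FindingPattern, dictionary: dict | None = None) -> SentenceReport:
    """Render a finding pattern into ordered sentences plus assertions."""
    d = dictionary if dictionary is not None else default_dictionary()
    sentences: list[str] = []
    assertions: list[Assertion] = []

    for key in sentence_keys(p):
        kind = key[0]
        if kind == "hemispheric":
            state = key[1]
            sentences.append(_template(d, "hemispheric").format(side=state))
            structures = (
                tuple(HEMISPHERES.values()) if state == "bilateral"
                else (HEMISPHERES[state],)
            )
            assertions.append(Assertion(_HEMI_TERMS[state], "plain", "atrophy", structures))
        elif kind == "prominent":
            _, side, lobes = key
            phrase = lobe_phrase(lobes)
            tmpl_key = "prominent_sided" if p.hemispheric_state == "bilateral" else "prominent"
            sentences.append(_template(d, tmpl_key).format(side=side, lobes=phrase))
            structures = tuple(f"{lobe}_{SIDE_SUFFIX[side]}" for lobe in lobes)
            assertions.append(
                Assertion(f"{side} {phrase} lobe", "prominent", "atrophy", structures)
            )
        elif kind == "specific":
            _, side, lobes = key
            phrase = lobe_phrase(lobes)
            sentences.append(_template(d, "specific").format(side=side, lobes=phrase))
            if side == "bilateral":
                structures = tuple(
                    f"{lobe}_{SIDE_SUFFIX[s]}" for s in SIDES for lobe in lobes
                )
            else:
                structures = tuple(f"{lobe}_{SIDE_SUFFIX[side]}" for lobe in lobes)
            assertions.append(
                Assertion(f"{side} {phrase} lobe", "specific", "atrophy", structures)
            )
        elif kind == "direct":
            sid = key[1]
            term = _term(d, sid)
            sentences.append(_template(d, "direct_atrophy", sid).format(structure=term))
            assertions.append(Assertion(term, "plain", "atrophy", (sid,)))
        elif kind == "ventricular":
            sid = key[1]
            term = _term(d, sid)
            sentences.append(_template(d, "enlargement", sid).format(structure=term))
            assertions.append(Assertion(term, "plain", "enlargement", (sid,)))
    return SentenceReport(tuple(sentences), tuple(assertions))
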