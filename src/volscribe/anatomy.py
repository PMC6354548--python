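"""Anatomic structure vocabulary, hierarchy handling, and volume aggregation.

Whole-brain segmentation yields volumes for fine-grained *base* structures
(gyri, subcortical nuclei, ventricles, deep sulci).  Radiologic language
works at coarser granularity -- lobes, hemispheres -- so base structures are
merged into *superstructures* defined by an ontology hierarchy: each
superstructure's volume is the sum of its children's volumes, computed
bottom-up.  This data reduction step turns a segmentation label map into the
anatomic units radiologists actually name.

The hierarchy is a directed acyclic graph rather than a strict tree: a base
label may sit under several independent superstructures (for example a gyrus
under both its lobe and a whole-brain composite), but the children of any
single superstructure must cover pairwise-disjoint sets of base structures,
so no volume is counted twice within one superstructure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping

__all__ = [
    "StructureLabel",
    "VolumeTable",
    "OntologyHierarchy",
    "aggregate_superstructures",
    "default_hierarchy",
]

LATERALITIES = ("left", "right", "midline")
TISSUE_CLASSES = ("tissue", "ventricle", "sulcus")

#: Canonical lobe names, in the order they are listed in reports.
LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic")
SIDES = ("left", "right")
SIDE_SUFFIX = {"left": "L", "right": "R"}


@dataclass(frozen=True)
class StructureLabel:
    """One entry of the structure vocabulary.

    ``level`` is the granularity level: 0 for base (segmentation) labels,
    ``1 + max(child levels)`` for superstructures.  It is recomputed from the
    child graph when a hierarchy is built, so callers may leave the default.
    """

    id: str
    display_name: str
    laterality: str
    tissue_class: str
    level: int = 0

    def __post_init__(self) -> None:
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"label {self.id!r}: laterality must be one of {LATERALITIES}, "
                f"got {self.laterality!r}"
            )
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"label {self.id!r}: tissue_class must be one of {TISSUE_CLASSES}, "
                f"got {self.tissue_class!r}"
            )
        if self.level < 0:
            raise ValueError(f"label {self.id!r}: level must be >= 0")


@dataclass(frozen=True)
class VolumeTable:
    """One case's structure -> volume map.

    Volumes are mm^3 for raw tables and dimensionless after normalization to
    the total-brain denominator (the same container is reused for both; the
    interpretation is up to the caller).
    """

    case_id: str
    age: float
    volumes: dict[str, float]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValueError(f"case {self.case_id!r}: age must be positive, got {self.age}")
        for sid, vol in self.volumes.items():
            if not math.isfinite(vol) or vol < 0:
                raise ValueError(
                    f"case {self.case_id!r}: volume of {sid!r} must be a "
                    f"non-negative finite number, got {vol}"
                )


class OntologyHierarchy:
    """Structure vocabulary plus the superstructure child graph.

    Parameters
    ----------
    labels
        The structure labels.  Ids must be unique.
    children
        Map superstructure id -> iterable of child ids.  Ids present here
        must exist in ``labels``; labels absent from this map are base
        (level-0) structures.
    """

    def __init__(
        self,
        labels: Iterable[StructureLabel],
        children: Mapping[str, Iterable[str]],
    ) -> None:
        label_map: dict[str, StructureLabel] = {}
        for lab in labels:
            if lab.id in label_map:
                raise ValueError(f"duplicate label id {lab.id!r}")
            label_map[lab.id] = lab
        child_map = {sid: tuple(kids) for sid, kids in children.items() if kids}
        for sid, kids in child_map.items():
            if sid not in label_map:
                raise ValueError(f"superstructure {sid!r} is not a defined label")
            for kid in kids:
                if kid not in label_map:
                    raise ValueError(f"child {kid!r} of {sid!r} is not a defined label")
            if len(set(kids)) != len(kids):
                raise ValueError(f"superstructure {sid!r} lists a child twice")

        sorter = TopologicalSorter({sid: kids for sid, kids in child_map.items()})
        for sid in label_map:
            sorter.add(sid)
        try:
            # children precede parents in this order
            order = tuple(sorter.static_order())
        except CycleError as exc:
            raise ValueError(f"hierarchy contains a cycle: {exc.args[1]}") from exc

        self._children = child_map
        self._topo_order = order

        # base-descendant sets, bottom-up
        desc: dict[str, frozenset[str]] = {}
        for sid in order:
            kids = child_map.get(sid, ())
            if not kids:
                desc[sid] = frozenset((sid,))
            else:
                union: set[str] = set()
                total = 0
                for kid in kids:
                    union |= desc[kid]
                    total += len(desc[kid])
                if total != len(union):
                    raise ValueError(
                        f"superstructure {sid!r}: children overlap; base structures "
                        "must be counted at most once per superstructure"
                    )
                desc[sid] = frozenset(union)
        self._base_descendants = desc

        levels = {
            sid: (0 if sid not in child_map
                  else 1 + max(self._level_of(kid, child_map) for kid in child_map[sid]))
            for sid in order
        }
        self.labels: dict[str, StructureLabel] = {
            sid: replace(label_map[sid], level=levels[sid]) for sid in label_map
        }
        self.base_ids: tuple[str, ...] = tuple(
            sid for sid in label_map if sid not in child_map
        )
        self.super_ids: tuple[str, ...] = tuple(
            sid for sid in label_map if sid in child_map
        )

    def _level_of(self, sid: str, child_map: Mapping[str, tuple[str, ...]]) -> int:
        kids = child_map.get(sid, ())
        if not kids:
            return 0
        return 1 + max(self._level_of(k, child_map) for k in kids)

    # -- queries ---------------------------------------------------------

    def children(self, sid: str) -> tuple[str, ...]:
        return self._children.get(sid, ())

    def base_descendants(self, sid: str) -> frozenset[str]:
        """All level-0 structures under ``sid`` (itself, if it is base)."""
        return self._base_descendants[sid]

    def topological_order(self) -> tuple[str, ...]:
        """All label ids with every child preceding its parents."""
        return self._topo_order

    def tissue_class(self, sid: str) -> str:
        return self.labels[sid].tissue_class

    def __contains__(self, sid: str) -> bool:
        return sid in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    # -- serialization ---------------------------------------------------

    def to_records(self) -> list[dict]:
        return [
            {
                "id": lab.id,
                "name": lab.display_name,
                "laterality": lab.laterality,
                "tissue_class": lab.tissue_class,
                "children": list(self._children.get(lab.id, ())),
            }
            for lab in self.labels.values()
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "OntologyHierarchy":
        labels = []
        children = {}
        for rec in records:
            labels.append(
                StructureLabel(
                    id=rec["id"],
                    display_name=rec.get("name", rec["id"]),
                    laterality=rec["laterality"],
                    tissue_class=rec["tissue_class"],
                )
            )
            kids = rec.get("children") or []
            if kids:
                children[rec["id"]] = tuple(kids)
        return cls(labels, children)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_records(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OntologyHierarchy":
        with open(path) as fh:
            return cls.from_records(json.load(fh))


def aggregate_superstructures(base: VolumeTable, h: OntologyHierarchy) -> VolumeTable:
    """Fill in superstructure volumes as bottom-up sums over children.

    Every level-0 label of ``h`` must be present in ``base``; superstructure
    entries already present are recomputed from their children, which makes
    the operation idempotent.  Entries not in the hierarchy pass through
    unchanged.
    """
    missing = [sid for sid in h.base_ids if sid not in base.volumes]
    if missing:
        raise ValueError(
            f"case {base.case_id!r}: missing base-structure volumes for {missing}"
        )
    volumes = dict(base.volumes)
    for sid in h.topological_order():
        kids = h.children(sid)
        if kids:
            volumes[sid] = sum(volumes[kid] for kid in kids)
    return VolumeTable(case_id=base.case_id, age=base.age, volumes=volumes)


# ---------------------------------------------------------------------------
# default fixture hierarchy
# ---------------------------------------------------------------------------

#: Gyral (and subcortical) base labels per lobe, one copy per hemisphere.
LOBE_MEMBERS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "superior_frontal_gyrus",
        "middle_frontal_gyrus",
        "inferior_frontal_gyrus",
        "precentral_gyrus",
    ),
    "parietal": (
        "postcentral_gyrus",
        "superior_parietal_lobule",
        "angular_gyrus",
    ),
    "temporal": (
        "superior_temporal_gyrus",
        "middle_temporal_gyrus",
        "inferior_temporal_gyrus",
    ),
    "occipital": (
        "superior_occipital_gyrus",
        "lingual_gyrus",
    ),
    "limbic": (
        "cingulate_gyrus",
        "parahippocampal_gyrus",
        "hippocampus",
        "amygdala",
    ),
}


def _pretty(stem: str) -> str:
    return stem.replace("_", " ")


def default_hierarchy() -> OntologyHierarchy:
    """A deterministic fixture hierarchy at lobar/hemispheric granularity.

    Base level: per-hemisphere gyri grouped into the five classic lobes, the
    caudate nucleus, lateral and third ventricles, deep sulci, cerebellum and
    brainstem.  Superstructures: ten lobes and two hemispheres.  This stands
    in for a full multi-atlas parcellation while exercising every level the
    reporting rules consume.
    """
    labels: list[StructureLabel] = []
    children: dict[str, tuple[str, ...]] = {}

    for side in SIDES:
        sfx = SIDE_SUFFIX[side]
        lobe_ids = []
        for lobe in LOBES:
            member_ids = tuple(f"{stem}_{sfx}" for stem in LOBE_MEMBERS[lobe])
            for stem, mid in zip(LOBE_MEMBERS[lobe], member_ids):
                labels.append(
                    StructureLabel(mid, f"{side} {_pretty(stem)}", side, "tissue")
                )
            lobe_id = f"{lobe}_{sfx}"
            labels.append(StructureLabel(lobe_id, f"{side} {lobe} lobe", side, "tissue"))
            children[lobe_id] = member_ids
            lobe_ids.append(lobe_id)
        caudate_id = f"caudate_{sfx}"
        labels.append(StructureLabel(caudate_id, f"{side} caudate", side, "tissue"))
        hemi_id = f"hemisphere_{sfx}"
        labels.append(StructureLabel(hemi_id, f"{side} hemisphere", side, "tissue"))
        children[hemi_id] = tuple(lobe_ids) + (caudate_id,)
        labels.append(
            StructureLabel(
                f"lateral_ventricle_{sfx}", f"{side} lateral ventricle", side, "ventricle"
            )
        )

    labels.append(StructureLabel("third_ventricle", "third ventricle", "midline", "ventricle"))
    labels.append(StructureLabel("deep_sulci", "deep sulci", "midline", "sulcus"))
    labels.append(StructureLabel("cerebellum", "cerebellum", "midline", "tissue"))
    labels.append(StructureLabel("brainstem", "brainstem", "midline", "tissue"))

    return OntologyHierarchy(labels, children)
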