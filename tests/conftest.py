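from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from volscribe import CohortSpec, OntologyHierarchy, StructureLabel, default_hierarchy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hierarchy() -> OntologyHierarchy:
    return default_hierarchy()


@pytest.fixture(scope="session")
def cohort_spec() -> CohortSpec:
    return CohortSpec.default()


def make_random_hierarchy(
    rng: np.random.Generator, n_base: int, layer_sizes: tuple[int, ...]
) -> OntologyHierarchy:
    """A random layered DAG hierarchy: each layer partitions the one below."""
    labels = [
        StructureLabel(f"b{i:03d}", f"base {i}", "midline", "tissue")
        for i in range(n_base)
    ]
    children: dict[str, tuple[str, ...]] = {}
    below = [lab.id for lab in labels]
    for li, size in enumerate(layer_sizes):
        ids = list(below)
        rng.shuffle(ids)
        groups = np.array_split(np.array(ids), size)
        layer = []
        for gi, group in enumerate(groups):
            sid = f"s{li}_{gi:03d}"
            labels.append(StructureLabel(sid, sid, "midline", "tissue"))
            children[sid] = tuple(group.tolist())
            layer.append(sid)
        below = layer
    return OntologyHierarchy(labels, children)


def brute_force_descendants(h: OntologyHierarchy, sid: str) -> set[str]:
    """Independent recursive enumeration of base descendants."""
    kids = h.children(sid)
    if not kids:
        return {sid}
    out: set[str] = set()
    for kid in kids:
        out |= brute_force_descendants(h, kid)
    return out
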