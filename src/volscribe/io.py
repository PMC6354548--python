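"""Readers and writers for the pipeline's tabular and image formats.

Volume tables are CSV/TSV with columns ``case_id, age, structure_id,
volume_mm3`` (delimiter chosen by extension); coded report findings are TSV
with ``case_id, source, structure_term, polarity`` and an optional ``flags``
column.  Label-map ingestion converts an integer NIfTI segmentation to a
volume table as voxel count times voxel volume.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .anatomy import VolumeTable
from .evaluation import CodedFinding
from .normative import ZScoreTable

__all__ = [
    "read_volume_tables",
    "write_volume_tables",
    "volumes_from_labelmap",
    "read_coded_findings",
    "write_coded_findings",
    "write_zscore_tables",
    "read_zscore_tables",
    "load_reader_study_counts",
]

logger = logging.getLogger(__name__)

VOLUME_COLUMNS = ("case_id", "age", "structure_id", "volume_mm3")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_volume_tables(path) -> list[VolumeTable]:
    """Parse a volume-table file into one :class:`VolumeTable` per case."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    dup = df.duplicated(subset=["case_id", "structure_id"])
    if dup.any():
        rows = [i + 2 for i in df.index[dup]]  # +2: header line + 1-based
        raise ValueError(f"{path}: duplicate (case_id, structure_id) rows at lines {rows}")
    tables = []
    for case_id, grp in df.groupby("case_id", sort=False):
        ages = grp["age"].unique()
        if len(ages) != 1:
            raise ValueError(f"{path}: case {case_id!r} has inconsistent ages {ages}")
        try:
            age = float(ages[0])
            volumes = {
                str(sid): float(v)
                for sid, v in zip(grp["structure_id"], grp["volume_mm3"])
            }
            tables.append(VolumeTable(case_id=str(case_id), age=age, volumes=volumes))
        except (TypeError, ValueError) as exc:
            first = grp.index[0] + 2
            raise ValueError(f"{path}: case {case_id!r} (from line {first}): {exc}") from None
    return tables


def write_volume_tables(tables: Iterable[VolumeTable], path) -> None:
    rows = [
        {"case_id": t.case_id, "age": t.age, "structure_id": sid, "volume_mm3": vol}
        for t in tables
        for sid, vol in t.volumes.items()
    ]
    pd.DataFrame(rows, columns=list(VOLUME_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def volumes_from_labelmap(
    path, label_lookup: Mapping[int, str], case_id: str, age: float
) -> VolumeTable:
    """Volume table from an integer NIfTI label map.

    Per label, volume = voxel count x voxel volume (mm^3) from the header
    zooms.  Labels present in the image but absent from ``label_lookup`` are
    ignored and logged; background (0) is always ignored.
    """
    import nibabel as nib  # deferred: only label-map ingestion needs imaging support

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label map must be integer-valued")
        data = np.round(data).astype(np.int64)
    voxel_volume = float(np.prod(img.header.get_zooms()[:3]))
    labels, counts = np.unique(data, return_counts=True)
    volumes: dict[str, float] = {}
    for label, count in zip(labels, counts):
        if label == 0:
            continue
        sid = label_lookup.get(int(label))
        if sid is None:
            logger.warning("%s: label %d has no lookup entry; ignored", path, label)
            continue
        volumes[sid] = float(count) * voxel_volume
    return VolumeTable(case_id=case_id, age=age, volumes=volumes)


def read_coded_findings(path) -> list[CodedFinding]:
    df = pd.read_csv(path, sep="\t")
    required = {"case_id", "source", "structure_term", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    seen = set()
    findings = []
    for i, row in df.iterrows():
        key = (row["case_id"], row["source"], row["structure_term"])
        if key in seen:
            raise ValueError(f"{path}: duplicate finding {key} at line {i + 2}")
        seen.add(key)
        flags = frozenset(
            str(row["flags"]).split(",")
        ) if "flags" in df.columns and pd.notna(row.get("flags")) and str(row["flags"]) else frozenset()
        findings.append(
            CodedFinding(
                case_id=str(row["case_id"]),
                structure_term=str(row["structure_term"]),
                polarity=str(row["polarity"]),
                source=str(row["source"]),
                flags=flags,
            )
        )
    return findings


def write_coded_findings(findings: Iterable[CodedFinding], path) -> None:
    rows = [
        {
            "case_id": f.case_id,
            "source": f.source,
            "structure_term": f.structure_term,
            "polarity": f.polarity,
            "flags": ",".join(sorted(f.flags)),
        }
        for f in findings
    ]
    pd.DataFrame(
        rows, columns=["case_id", "source", "structure_term", "polarity", "flags"]
    ).to_csv(path, sep="\t", index=False)


def write_zscore_tables(tables: Iterable[ZScoreTable], path) -> None:
    df = pd.concat([t.as_dataframe() for t in tables], ignore_index=True)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_zscore_tables(path) -> list[ZScoreTable]:
    df = pd.read_csv(path, sep=_sep_for(path))
    tables = []
    for case_id, grp in df.groupby("case_id", sort=False):
        z = dict(zip(grp["structure_id"], grp["z"].astype(float)))
        ratio = dict(zip(grp["structure_id"], grp["ratio"].astype(float)))
        tables.append(
            ZScoreTable(
                case_id=str(case_id),
                age=float(grp["age"].iloc[0]),
                ratio=ratio,
                z=z,
                extrapolated=bool(grp["extrapolated"].iloc[0]),
                missing=frozenset(s for s, v in z.items() if not np.isfinite(v)),
            )
        )
    return tables


def load_reader_study_counts() -> dict:
    """Bundled contingency counts from a reader-agreement study (92 cases,
    23-term structure universe) comparing automated sentences with three
    radiologists and their majority vote."""
    text = resources.files("volscribe").joinpath("data/reader_study_counts.json").read_text()
    return json.loads(text)
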