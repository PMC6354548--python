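"""Age-linear normative modeling of structure volume ratios and z-scoring.

The abnormality judgment works on *volume ratios*: each structure's volume
divided by the case's total brain volume, where the denominator is the sum
of all base-level tissue segments, ventricles, and deep sulci.  Ratios are
used rather than raw volumes because their normal-range variability across
scanners and head sizes is substantially smaller.

For every structure the normative model is an ordinary least-squares fit of
ratio on age over a control cohort,

    ratio ~ intercept + slope * age + eps,   eps ~ N(0, residual_sd^2),

with a single homoscedastic residual SD per structure (``sqrt(RSS/(n-2))``).
A patient's z-score is then

    z = (ratio - (intercept + slope * age)) / residual_sd,

so atrophy of a tissue structure gives negative z and ventricular or sulcal
enlargement gives positive z.  Scoring outside the control age range is an
extrapolation: it is flagged but still returned, since clinical cases need
not fall inside the normative cohort's span.

The model object follows the construct/fit/results convention: build a
:class:`NormativeVolumeModel` from control volume tables (or a long-format
data frame), call :meth:`~NormativeVolumeModel.fit`, and use the returned
:class:`NormativeResults` for prediction, scoring, and serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anatomy import OntologyHierarchy, VolumeTable, aggregate_superstructures

__all__ = [
    "compute_ratios",
    "NormativeVolumeModel",
    "NormativeResults",
    "ZScoreTable",
    "fit_normative",
    "zscore_case",
]

#: Floor applied to fitted residual SDs so that z-scores stay finite even on
#: degenerate (noise-free) training data.
RESIDUAL_SD_FLOOR = 1e-12


def compute_ratios(v: VolumeTable, h: OntologyHierarchy) -> VolumeTable:
    """Normalize a volume table by the total-brain denominator.

    The denominator D is the sum of all base-level volumes (tissue segments
    plus ventricles plus deep sulci), computed once per case; every entry of
    the table is divided by it.  The input must already be aggregated so the
    base level is complete.
    """
    try:
        denom = sum(v.volumes[sid] for sid in h.base_ids)
    except KeyError as exc:
        raise ValueError(
            f"case {v.case_id!r}: base structure {exc.args[0]!r} missing; "
            "aggregate the table before computing ratios"
        ) from None
    if not denom > 0:
        raise ValueError(f"case {v.case_id!r}: total brain denominator is {denom}")
    return VolumeTable(
        case_id=v.case_id,
        age=v.age,
        volumes={sid: vol / denom for sid, vol in v.volumes.items()},
    )


@dataclass(frozen=True)
class ZScoreTable:
    """Per-structure ratios and z-scores for one case.

    ``missing`` lists structures requested but absent from the model (their
    z is NaN); ``extrapolated`` is set when the case age falls outside the
    control cohort's age range.
    """

    case_id: str
    age: float
    ratio: dict[str, float]
    z: dict[str, float]
    extrapolated: bool = False
    missing: frozenset[str] = frozenset()

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": self.case_id,
                "age": self.age,
                "structure_id": list(self.z),
                "ratio": [self.ratio[s] for s in self.z],
                "z": [self.z[s] for s in self.z],
                "extrapolated": self.extrapolated,
            }
        )


class NormativeVolumeModel:
    """Normative age model of structure volume ratios, fitted on controls.

    Parameters
    ----------
    controls
        Control-cohort volume tables (raw mm^3, base level at minimum).
    hierarchy
        Structure hierarchy; used for aggregation and the ratio denominator.
    use_ratio
        Model total-brain-normalized ratios (default) instead of raw volumes.
    """

    def __init__(
        self,
        controls: Sequence[VolumeTable],
        hierarchy: OntologyHierarchy,
        use_ratio: bool = True,
    ) -> None:
        if len(controls) < 3:
            raise ValueError(f"need at least 3 controls, got {len(controls)}")
        self.controls = list(controls)
        self.hierarchy = hierarchy
        self.use_ratio = use_ratio

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        hierarchy: OntologyHierarchy,
        use_ratio: bool = True,
    ) -> "NormativeVolumeModel":
        """Build from a long-format frame with columns
        ``case_id, age, structure_id, volume_mm3``."""
        required = {"case_id", "age", "structure_id", "volume_mm3"}
        if not required.issubset(df.columns):
            raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
        controls = []
        for case_id, grp in df.groupby("case_id", sort=False):
            ages = grp["age"].unique()
            if len(ages) != 1:
                raise ValueError(f"case {case_id!r} has inconsistent ages {ages}")
            controls.append(
                VolumeTable(
                    case_id=str(case_id),
                    age=float(ages[0]),
                    volumes=dict(zip(grp["structure_id"], grp["volume_mm3"].astype(float))),
                )
            )
        return cls(controls, hierarchy, use_ratio=use_ratio)

    def fit(self) -> "NormativeResults":
        """OLS of ratio on age, per structure, solved jointly."""
        h = self.hierarchy
        tables = [aggregate_superstructures(c, h) for c in self.controls]
        if self.use_ratio:
            tables = [compute_ratios(t, h) for t in tables]
        structures = list(h.topological_order())
        ages = np.array([t.age for t in tables], float)
        if np.ptp(ages) == 0:
            raise ValueError("control cohort has constant age; cannot fit an age slope")
        try:
            Y = np.array(
                [[t.volumes[sid] for sid in structures] for t in tables], float
            )
        except KeyError as exc:  # pragma: no cover - aggregation already checks base
            raise ValueError(f"structure {exc.args[0]!r} missing from a control") from None
        return _fit_ratio_matrix(
            ages, Y, structures, case_ids=[t.case_id for t in tables]
        )


def _fit_ratio_matrix(
    ages: np.ndarray,
    Y: np.ndarray,
    structures: Sequence[str],
    case_ids: Sequence[str] | None = None,
) -> "NormativeResults":
    """Fit every structure's age line at once from an (n_cases x p) matrix."""
    n = ages.size
    X = np.column_stack([np.ones(n), ages])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    dof = n - 2
    residual_sd = np.sqrt(np.maximum(rss, 0.0) / dof)
    residual_sd = np.maximum(residual_sd, RESIDUAL_SD_FLOOR)
    # classical OLS standard errors, useful for recovery diagnostics
    sxx = np.sum((ages - ages.mean()) ** 2)
    slope_se = residual_sd / math.sqrt(sxx)
    intercept_se = residual_sd * math.sqrt(1.0 / n + ages.mean() ** 2 / sxx)
    params = pd.DataFrame(
        {
            "intercept": beta[0],
            "slope": beta[1],
            "residual_sd": residual_sd,
            "intercept_se": intercept_se,
            "slope_se": slope_se,
        },
        index=pd.Index(structures, name="structure_id"),
    )
    return NormativeResults(
        params=params,
        n_controls=n,
        age_range=(float(ages.min()), float(ages.max())),
    )


class NormativeResults:
    """Fitted per-structure age lines with residual spread.

    ``params`` is a data frame indexed by structure id with columns
    ``intercept``, ``slope``, ``residual_sd`` and the OLS standard errors.
    """

    def __init__(
        self,
        params: pd.DataFrame,
        n_controls: int,
        age_range: tuple[float, float],
        hierarchy: OntologyHierarchy | None = None,
    ) -> None:
        if n_controls < 3:
            raise ValueError("n_controls must be >= 3")
        if (params["residual_sd"] <= 0).any():
            raise ValueError("residual_sd must be positive for every structure")
        self.params = params
        self.n_controls = int(n_controls)
        self.age_range = (float(age_range[0]), float(age_range[1]))
        self.hierarchy = hierarchy

    @property
    def structures(self) -> list[str]:
        return list(self.params.index)

    def predict(self, age: float, structures: Iterable[str] | None = None) -> pd.Series:
        """Age-matched mean ratio per structure."""
        p = self.params if structures is None else self.params.loc[list(structures)]
        return p["intercept"] + p["slope"] * age

    def zscore(
        self, case: VolumeTable, hierarchy: OntologyHierarchy | None = None
    ) -> ZScoreTable:
        """Score one case against the normative model.

        The case is aggregated and ratio-normalized internally (both are
        idempotent), so raw base-level tables can be passed directly.
        Structures in the case but not in the model are marked missing
        rather than raising.
        """
        h = hierarchy or self.hierarchy
        if h is None:
            raise ValueError("a hierarchy is required for aggregation/ratio scoring")
        table = compute_ratios(aggregate_superstructures(case, h), h)
        pred = self.predict(table.age)
        sd = self.params["residual_sd"]
        z: dict[str, float] = {}
        missing = set()
        for sid, ratio in table.volumes.items():
            if sid in pred.index:
                z[sid] = (ratio - pred[sid]) / sd[sid]
            else:
                z[sid] = float("nan")
                missing.add(sid)
        lo, hi = self.age_range
        return ZScoreTable(
            case_id=table.case_id,
            age=table.age,
            ratio=dict(table.volumes),
            z=z,
            extrapolated=not (lo <= table.age <= hi),
            missing=frozenset(missing),
        )

    def summary(self) -> str:
        lines = [
            "Normative volume-ratio model (OLS, ratio ~ age)",
            f"  controls: n = {self.n_controls}, "
            f"age range {self.age_range[0]:.1f}-{self.age_range[1]:.1f} y",
            f"  structures: {len(self.params)}",
            "",
            f"{'structure':<28}{'intercept':>12}{'slope':>12}"
            f"{'slope_se':>12}{'resid_sd':>12}",
        ]
        for sid, row in self.params.iterrows():
            lines.append(
                f"{sid:<28}{row['intercept']:>12.3e}{row['slope']:>12.3e}"
                f"{row['slope_se']:>12.3e}{row['residual_sd']:>12.3e}"
            )
        return "\n".join(lines)

    # -- serialization (lossless JSON round-trip) ------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_controls": self.n_controls,
            "age_range": list(self.age_range),
            "structures": [
                {"structure_id": sid, **{k: float(v) for k, v in row.items()}}
                for sid, row in self.params.iterrows()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path, hierarchy: OntologyHierarchy | None = None) -> "NormativeResults":
        with open(path) as fh:
            payload = json.load(fh)
        params = pd.DataFrame(payload["structures"]).set_index("structure_id")
        return cls(
            params=params,
            n_controls=payload["n_controls"],
            age_range=tuple(payload["age_range"]),
            hierarchy=hierarchy,
        )


def fit_normative(
    controls: Sequence[VolumeTable], h: OntologyHierarchy, use_ratio: bool = True
) -> NormativeResults:
    """Convenience wrapper: build and fit a :class:`NormativeVolumeModel`."""
    results = NormativeVolumeModel(controls, h, use_ratio=use_ratio).fit()
    results.hierarchy = h
    return results


def zscore_case(
    case: VolumeTable, m: NormativeResults, h: OntologyHierarchy | None = None
) -> ZScoreTable:
    """Convenience wrapper for :meth:`NormativeResults.zscore`."""
    return m.zscore(case, h)
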