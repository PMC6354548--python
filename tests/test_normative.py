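"""Ratio normalization, normative OLS fitting, and z-scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from volscribe import (
    NormativeVolumeModel,
    OntologyHierarchy,
    StructureLabel,
    VolumeTable,
    compute_ratios,
    fit_normative,
    zscore_case,
)
from volscribe.normative import NormativeResults, RESIDUAL_SD_FLOOR


def _flat_hierarchy():
    """Two tissue bases, a ventricle and a sulcus; no superstructures."""
    return OntologyHierarchy(
        [
            StructureLabel("hip", "hippocampus", "left", "tissue"),
            StructureLabel("rest", "rest of brain", "midline", "tissue"),
            StructureLabel("vent", "ventricles", "midline", "ventricle"),
            StructureLabel("sulci", "deep sulci", "midline", "sulcus"),
        ],
        {},
    )


def _line_cohort(h, n=200, seed=0, intercept=0.0030, slope=-1e-5, sd=2e-4):
    """Controls whose 'hip' ratio follows an exact age-linear Gaussian model."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 95, n)
    r = intercept + slope * ages + (rng.standard_normal(n) * sd if sd else 0.0)
    controls = []
    for i in range(n):
        tbv = 1.6e6
        vols = {
            "hip": r[i] * tbv,
            "rest": (0.95 - r[i]) * tbv,
            "vent": 0.03 * tbv,
            "sulci": 0.02 * tbv,
        }
        controls.append(VolumeTable(f"c{i}", float(ages[i]), vols))
    return controls, ages, r


class TestRatios:
    def test_ratio_by_definition(self):
        h = _flat_hierarchy()
        vols = {"hip": 4000.0, "rest": 1_560_000.0, "vent": 26_000.0, "sulci": 10_000.0}
        out = compute_ratios(VolumeTable("c", 70.0, vols), h)
        assert out.volumes["hip"] == pytest.approx(4000.0 / 1.6e6)
        assert out.volumes["hip"] == pytest.approx(0.0025)

    def test_uniform_scaling_leaves_ratios_unchanged(self):
        h = _flat_hierarchy()
        vols = {"hip": 4000.0, "rest": 1_560_000.0, "vent": 26_000.0, "sulci": 10_000.0}
        a = compute_ratios(VolumeTable("c", 70.0, vols), h)
        b = compute_ratios(
            VolumeTable("c", 70.0, {k: 2 * v for k, v in vols.items()}), h
        )
        assert a.volumes == pytest.approx(b.volumes)

    def test_base_ratios_partition_to_one(self, hierarchy, cohort_spec):
        from volscribe import simulate_controls

        case = simulate_controls(cohort_spec, hierarchy)[0]
        ratios = compute_ratios(case, hierarchy)
        assert sum(ratios.volumes[b] for b in hierarchy.base_ids) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self):
        h = _flat_hierarchy()
        with pytest.raises(ValueError, match="denominator"):
            compute_ratios(
                VolumeTable("c", 70.0, {k: 0.0 for k in ("hip", "rest", "vent", "sulci")}), h
            )


class TestFit:
    def test_parameter_recovery_on_synthetic_line(self):
        h = _flat_hierarchy()
        controls, _, _ = _line_cohort(h, n=200, seed=3)
        res = fit_normative(controls, h)
        row = res.params.loc["hip"]
        assert abs(row["slope"] - (-1e-5)) < 3 * row["slope_se"]
        assert row["residual_sd"] == pytest.approx(2e-4, rel=0.10)
        assert res.age_range[0] >= 20 and res.age_range[1] <= 95

    def test_ols_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        h = _flat_hierarchy()
        controls, ages, r = _line_cohort(h, n=50, seed=9)
        res = fit_normative(controls, h)
        X = sm.add_constant(ages)
        ref = sm.OLS(r, X).fit()
        assert res.params.loc["hip", "intercept"] == pytest.approx(ref.params[0], rel=1e-8)
        assert res.params.loc["hip", "slope"] == pytest.approx(ref.params[1], rel=1e-8)
        assert res.params.loc["hip", "residual_sd"] == pytest.approx(
            np.sqrt(ref.ssr / ref.df_resid), rel=1e-8
        )

    def test_noiseless_line_gives_floored_sd_and_exact_predictions(self):
        h = _flat_hierarchy()
        controls, _, _ = _line_cohort(h, n=20, seed=1, sd=0.0)
        res = fit_normative(controls, h)
        assert res.params.loc["hip", "residual_sd"] == RESIDUAL_SD_FLOOR
        assert res.predict(50.0)["hip"] == pytest.approx(0.0030 - 1e-5 * 50.0, rel=1e-9)

    def test_identical_structures_get_identical_parameters(self):
        h = OntologyHierarchy(
            [
                StructureLabel("a", "a", "midline", "tissue"),
                StructureLabel("b", "b", "midline", "tissue"),
                StructureLabel("c", "c", "midline", "tissue"),
            ],
            {},
        )
        rng = np.random.default_rng(5)
        controls = []
        for i in range(30):
            age = float(rng.uniform(20, 90))
            v = float(rng.uniform(1000, 2000))
            controls.append(VolumeTable(f"c{i}", age, {"a": v, "b": v, "c": 3e5}))
        res = fit_normative(controls, h)
        pd.testing.assert_series_equal(
            res.params.loc["a"], res.params.loc["b"], check_names=False
        )

    def test_fit_is_reproducible(self):
        h = _flat_hierarchy()
        controls, _, _ = _line_cohort(h, n=50, seed=2)
        a = fit_normative(controls, h).params
        b = fit_normative(controls, h).params
        pd.testing.assert_frame_equal(a, b)

    def test_constant_age_rejected(self):
        h = _flat_hierarchy()
        controls = [
            VolumeTable(f"c{i}", 60.0, {"hip": 4e3, "rest": 1.5e6, "vent": 3e4, "sulci": 2e4})
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="constant age"):
            fit_normative(controls, h)

    def test_too_few_controls_rejected(self):
        h = _flat_hierarchy()
        controls, _, _ = _line_cohort(h, n=2, seed=0)
        with pytest.raises(ValueError, match="3 controls"):
            NormativeVolumeModel(controls, h)

    def test_from_dataframe_equivalent_to_tables(self):
        h = _flat_hierarchy()
        controls, _, _ = _line_cohort(h, n=30, seed=4)
        rows = [
            {"case_id": c.case_id, "age": c.age, "structure_id": s, "volume_mm3": v}
            for c in controls
            for s, v in c.volumes.items()
        ]
        res_df = NormativeVolumeModel.from_dataframe(pd.DataFrame(rows), h).fit()
        res_tb = fit_normative(controls, h)
        pd.testing.assert_frame_equal(res_df.params, res_tb.params)


@pytest.fixture(scope="module")
def fitted():
    h = _flat_hierarchy()
    controls, _, _ = _line_cohort(h, n=100, seed=6)
    return h, fit_normative(controls, h)


class TestZScore:
    def _case_at(self, res, h, age, z_target):
        """A case whose 'hip' ratio sits exactly z_target SDs from the mean."""
        row = res.params.loc["hip"]
        r = row["intercept"] + row["slope"] * age + z_target * row["residual_sd"]
        tbv = 1.6e6
        return VolumeTable(
            "case", age,
            {"hip": r * tbv, "rest": (0.95 - r) * tbv, "vent": 0.03 * tbv, "sulci": 0.02 * tbv},
        )

    def test_zero_and_minus_two(self, fitted):
        h, res = fitted
        assert res.zscore(self._case_at(res, h, 60.0, 0.0), h).z["hip"] == pytest.approx(0.0, abs=1e-9)
        assert res.zscore(self._case_at(res, h, 60.0, -2.0), h).z["hip"] == pytest.approx(-2.0, abs=1e-9)

    def test_z_invariant_to_uniform_rescaling(self, fitted):
        h, res = fitted
        case = self._case_at(res, h, 55.0, -1.3)
        scaled = VolumeTable(case.case_id, case.age, {k: 3.7 * v for k, v in case.volumes.items()})
        assert res.zscore(scaled, h).z["hip"] == pytest.approx(res.zscore(case, h).z["hip"])

    def test_shrinking_tissue_never_raises_its_z(self, fitted):
        h, res = fitted
        case = self._case_at(res, h, 60.0, 0.5)
        z0 = res.zscore(case, h).z["hip"]
        for frac in (0.95, 0.8, 0.5):
            smaller = dict(case.volumes)
            smaller["hip"] = case.volumes["hip"] * frac
            z = res.zscore(VolumeTable("c", 60.0, smaller), h).z["hip"]
            assert z < z0
            z0 = z

    def test_extrapolation_flagged_but_scored(self, fitted):
        h, res = fitted
        case = self._case_at(res, h, 98.0, -1.0)
        out = res.zscore(case, h)
        assert out.extrapolated
        assert np.isfinite(out.z["hip"])

    def test_structure_absent_from_model_marked_missing(self, fitted):
        h, res = fitted
        trimmed = NormativeResults(
            res.params.drop(index="vent"), res.n_controls, res.age_range, h
        )
        out = trimmed.zscore(self._case_at(res, h, 60.0, 0.0), h)
        assert "vent" in out.missing
        assert np.isnan(out.z["vent"])
        assert np.isfinite(out.z["hip"])

    def test_null_trigger_rate_matches_normal_tail(self, hierarchy, cohort_spec):
        # 10,000 null cases against a model fitted on 500 controls: the
        # fraction beyond |z| = 2 should sit near the normal tail 0.0228
        from volscribe import null_trigger_rates, simulate_and_fit

        rng = np.random.default_rng(2024)
        res = simulate_and_fit(cohort_spec, hierarchy, 500, rng)
        rates = null_trigger_rates(cohort_spec, hierarchy, res, n_cases=10_000, seed=77)
        assert rates["hippocampus_L"] == pytest.approx(0.0228, abs=0.006)
        assert rates.mean() == pytest.approx(0.0228, abs=0.006)

    def test_json_round_trip_lossless(self, fitted, tmp_path):
        h, res = fitted
        path = tmp_path / "model.json"
        res.to_json(path)
        back = NormativeResults.from_json(path, hierarchy=h)
        pd.testing.assert_frame_equal(back.params, res.params)
        assert back.age_range == res.age_range
        assert back.n_controls == res.n_controls

    def test_summary_mentions_cohort_and_structures(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "n = 100" in text
        assert "hip" in text


def test_zscore_case_wrapper_matches_method(hierarchy, cohort_spec):
    from volscribe import simulate_controls

    controls = simulate_controls(cohort_spec, hierarchy)[:50]
    res = fit_normative(controls, hierarchy)
    case = controls[0]
    assert zscore_case(case, res, hierarchy).z == res.zscore(case, hierarchy).z
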