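import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orbitmorph.cohort import CohortGenParams, make_cohort
from orbitmorph.errors import DegenerateInputError
from orbitmorph.stats import (
    AsymmetryRule,
    build_stats_report,
    compare_groups,
    correlations,
    fit_volume_model,
    gender_volume_difference,
    icc,
    screen_asymmetry,
    volume_area_ratio,
)
from orbitmorph.stats import test_normality as normality_test
from orbitmorph.schemas import validate_report


def bilateral_table(vl, vr, gender=None, **extra):
    n = len(vl)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "gender": gender if gender is not None else ["male"] * n,
            "age": 40.0,
            "volume_ml_left": vl,
            "volume_ml_right": vr,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestScreen:
    def test_published_average_difference_is_flagged(self):
        # 27.5 vs 26.7 mL: the 0.8 mL skull-study average exceeds 0.2 mL
        t = bilateral_table([27.5], [26.7])
        retained, excluded = screen_asymmetry(t)
        assert len(excluded) == 1 and len(retained) == 0

    def test_threshold_is_strict(self):
        t = bilateral_table([25.2], [25.0])
        retained, excluded = screen_asymmetry(t, AsymmetryRule(0.2))
        assert len(retained) == 1 and len(excluded) == 0

    def test_186_with_12_flagged_leaves_174(self):
        rng = np.random.default_rng(0)
        base = rng.normal(27, 3, 186)
        delta = np.full(186, 0.05)
        delta[:12] = 0.8  # constructed asymmetric subjects
        t = bilateral_table(base + delta / 2, base - delta / 2)
        retained, excluded = screen_asymmetry(t)
        assert len(retained) == 174 and len(excluded) == 12

    def test_scale_consistency_mm3(self):
        rng = np.random.default_rng(1)
        base = rng.normal(27, 3, 50)
        delta = rng.normal(0, 0.2, 50)
        t_ml = bilateral_table(base + delta, base)
        t_mm3 = bilateral_table((base + delta) * 1000, base * 1000)
        f_ml = screen_asymmetry(t_ml, AsymmetryRule(0.2))[1].subject_id.tolist()
        f_mm3 = screen_asymmetry(t_mm3, AsymmetryRule(200.0))[1].subject_id.tolist()
        assert f_ml == f_mm3

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 99_999))
    def test_partition_exhaustive_and_disjoint(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        t = bilateral_table(rng.normal(27, 3, n), rng.normal(27, 3, n))
        retained, excluded = screen_asymmetry(t)
        assert len(retained) + len(excluded) == n
        assert not set(retained.subject_id) & set(excluded.subject_id)

    def test_missing_side_raises(self):
        t = bilateral_table([25.0], [np.nan])
        with pytest.raises(DegenerateInputError):
            screen_asymmetry(t)


class TestNormality:
    def test_type_i_error_rate(self):
        rng = np.random.default_rng(0)
        rej = sum(normality_test(rng.normal(size=91))[1] < 0.05 for _ in range(1000))
        assert rej / 1000 == pytest.approx(0.05, abs=0.02)

    def test_power_against_exponential(self):
        rng = np.random.default_rng(1)
        rej = sum(
            normality_test(rng.exponential(size=91))[1] < 0.05 for _ in range(400)
        )
        assert rej / 400 > 0.95

    def test_constant_sample_raises(self):
        with pytest.raises(DegenerateInputError):
            normality_test([3.0, 3.0, 3.0, 3.0])


class TestCompareGroups:
    def test_identical_sides_degenerate_paired(self):
        v = np.linspace(20, 30, 10)
        t = bilateral_table(v, v, depth_mm_left=v, depth_mm_right=v,
                            area_mm2_left=v, area_mm2_right=v,
                            gender=["male"] * 5 + ["female"] * 5)
        out = compare_groups(t, "volume_ml", "left_vs_right")
        assert out["male"]["degenerate"] and math.isnan(out["male"]["p_paired"])

    def test_null_unpaired_rejection_rate(self):
        # two samples from one distribution, n = 91 / 83
        rej = 0
        n_rep = 500
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            a = rng.normal(27, 3, 91)
            b = rng.normal(27, 3, 83)
            t = bilateral_table(
                np.concatenate([a, b]), np.concatenate([a, b]),
                gender=["male"] * 91 + ["female"] * 83,
            )
            p = compare_groups(t, "volume_ml", "male_vs_female")["left"]["p_unpaired"]
            rej += p < 0.05
        assert rej / n_rep == pytest.approx(0.05, abs=0.025)

    def test_larger_smaller_paired_vs_unpaired_pattern(self):
        # the within-subject max/min contrast: paired overwhelming, unpaired null
        paired_hits = unpaired_null = 0
        lr_paired_p = []
        for s in range(100):
            table, _ = make_cohort(CohortGenParams(rng_seed=1000 + s),
                                   make_specs=False)
            retained, _ = screen_asymmetry(table)
            ls = compare_groups(retained, "volume_ml", "larger_vs_smaller")
            paired_hits += all(ls[g]["p_paired"] < 1e-10 for g in ("male", "female"))
            unpaired_null += all(ls[g]["p_unpaired"] > 0.1 for g in ("male", "female"))
            lr = compare_groups(retained, "volume_ml", "left_vs_right")
            lr_paired_p.append(lr["male"]["p_paired"])
        assert paired_hits >= 90
        assert unpaired_null >= 90
        # left-right paired p is uniform under the symmetric generator
        assert 0.4 < np.mean(lr_paired_p) < 0.6


class TestVolumeModel:
    def test_shared_slope_recovered(self):
        rng = np.random.default_rng(0)
        n = 120
        depth = np.concatenate([rng.normal(40, 3, n), rng.normal(37, 3, n)])
        volume = 2.0 + 0.7 * depth + rng.normal(0, 0.01, 2 * n)
        t = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(2 * n)],
                "gender": ["male"] * n + ["female"] * n,
                "volume_ml_left": volume,
                "depth_mm_left": depth,
            }
        )
        fit = fit_volume_model(t, "left")
        assert fit.loc["Depth", "p"] < 1e-50
        assert fit.loc["Depth", "coef"] == pytest.approx(0.7, abs=0.01)
        assert fit.loc["Gender", "p"] > 0.05
        assert fit.loc["Gender:Depth", "p"] > 0.05

    def test_small_n_raises(self):
        t = pd.DataFrame(
            {
                "subject_id": list("abcd"),
                "gender": ["male", "male", "female", "female"],
                "volume_ml_left": [25, 26, 24, 23.0],
                "depth_mm_left": [38, 39, 37, 36.0],
            }
        )
        with pytest.raises(DegenerateInputError):
            fit_volume_model(t, "left")

    def test_depth_only_significant_across_seeds(self):
        hits = 0
        for s in range(100):
            table, _ = make_cohort(CohortGenParams(rng_seed=1000 + s),
                                   make_specs=False)
            retained, _ = screen_asymmetry(table)
            fit = fit_volume_model(retained, "left")
            hits += (fit.loc["Depth", "p"] < 1e-5
                     and fit.loc["Gender:Depth", "p"] > 0.05)
        assert hits >= 90


class TestCorrelations:
    def test_exact_linear_relation(self):
        x = np.linspace(30, 45, 20)
        t = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(20)],
                "gender": ["male"] * 10 + ["female"] * 10,
                "depth_mm_left": x, "depth_mm_right": x,
                "volume_ml_left": 2 * x + 1, "volume_ml_right": 2 * x + 1,
                "area_mm2_left": 3 * x - 5, "area_mm2_right": 3 * x - 5,
            }
        )
        corr = correlations(t)
        assert np.allclose(corr.r2, 1.0)

    def test_null_r2_mean_is_one_over_n_minus_one(self):
        rng = np.random.default_rng(0)
        r2 = [
            np.corrcoef(rng.normal(size=91), rng.normal(size=91))[0, 1] ** 2
            for _ in range(1000)
        ]
        assert np.mean(r2) == pytest.approx(1 / 90, abs=0.0015)

    def test_zero_variance_raises(self):
        t = pd.DataFrame(
            {
                "subject_id": list("abc"), "gender": ["male"] * 3,
                "depth_mm_left": [1.0, 1.0, 1.0], "depth_mm_right": [1, 2, 3.0],
                "volume_ml_left": [1, 2, 3.0], "volume_ml_right": [1, 2, 3.0],
                "area_mm2_left": [1, 2, 3.0], "area_mm2_right": [1, 2, 3.0],
            }
        )
        t = pd.concat([t, t.assign(gender="female")], ignore_index=True)
        with pytest.raises(DegenerateInputError):
            correlations(t)


class TestICC:
    def test_identical_columns_give_exactly_one(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 6))
        assert icc(m) == 1.0

    def test_column_offsets_separate_forms(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 4)) + np.array([0, 1, 2, 3.0])
        assert icc(m, "consistency") == pytest.approx(1.0)
        assert icc(m, "agreement") < 1.0

    @pytest.mark.parametrize("shape,seed", [((10, 6), 0), ((7, 3), 1), ((25, 4), 2)])
    def test_matches_pingouin_oracle(self, shape, seed):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(seed)
        m = rng.normal(size=shape)
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(shape[0]), shape[1]),
                "rater": np.tile(np.arange(shape[1]), shape[0]),
                "y": m.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        ref_a = float(ref[ref.Type == "ICC(A,1)"].ICC.iloc[0])
        ref_c = float(ref[ref.Type == "ICC(C,1)"].ICC.iloc[0])
        assert icc(m, "agreement") == pytest.approx(ref_a, abs=1e-10)
        assert icc(m, "consistency") == pytest.approx(ref_c, abs=1e-10)

    def test_zero_subject_variance_warns(self):
        m = np.ones((5, 3))
        with pytest.warns(UserWarning):
            assert icc(m) == 0.0

    def test_too_small_raises(self):
        with pytest.raises(DegenerateInputError):
            icc(np.ones((1, 3)))


def reference_like_table():
    """Four-subject table whose gender/side means equal the reference means."""
    rows = []
    cells = {
        ("male", "left"): (28.95, 3878.68, 39.74),
        ("male", "right"): (29.02, 3871.49, 39.83),
        ("female", "left"): (25.39, 3492.22, 37.41),
        ("female", "right"): (25.48, 3490.72, 37.27),
    }
    for i, gender in enumerate(["male", "male", "female", "female"]):
        row = dict(subject_id=f"S{i}", gender=gender, age=40.0)
        for side in ("left", "right"):
            v, a, d = cells[(gender, side)]
            row[f"volume_ml_{side}"] = v
            row[f"area_mm2_{side}"] = a
            row[f"depth_mm_{side}"] = d
        rows.append(row)
    return pd.DataFrame(rows)


class TestDerivedRatios:
    def test_gender_volume_difference_matches_reference(self):
        assert gender_volume_difference(reference_like_table()) == pytest.approx(
            13.96, abs=0.01
        )

    def test_equal_means_give_zero(self):
        t = reference_like_table()
        for side in ("left", "right"):
            t[f"volume_ml_{side}"] = 27.0
        assert gender_volume_difference(t) == 0.0

    def test_reference_cell_ratio(self):
        r = volume_area_ratio(reference_like_table())
        assert r["male_left"] == pytest.approx(28.95 / 38.7868, abs=1e-4)

    def test_sphere_ratio_is_radius_over_30(self):
        r_mm = 22.5
        t = reference_like_table()
        for side in ("left", "right"):
            t[f"volume_ml_{side}"] = 4 / 3 * math.pi * r_mm**3 / 1000
            t[f"area_mm2_{side}"] = 4 * math.pi * r_mm**2
        r = volume_area_ratio(t)
        assert r["average"] == pytest.approx(0.75, abs=1e-12)


class TestReport:
    def test_report_validates_against_schema(self):
        table, _ = make_cohort(CohortGenParams(rng_seed=7), make_specs=False)
        report = build_stats_report(table)
        validate_report(report)
        assert report["n_screened"] == 174
        assert report["n_retained"] + report["n_excluded"] == 174
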