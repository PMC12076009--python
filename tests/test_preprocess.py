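"""Wave collapse, sample filters, dummy coding, and standardization."""

import numpy as np
import pandas as pd
import pytest

import ineqop as iq
from ineqop.preprocess import (
    EmptySampleError,
    FilterCriteria,
    PreprocessError,
    RoleMap,
    RoleMapError,
    collapse_waves,
    encode_categoricals,
    filter_sample,
    standardize,
)


@pytest.fixture
def toy_rolemap():
    return RoleMap(
        {
            "pid": "id",
            "w": "wave",
            "age": "age",
            "edu": "outcome",
            "cog": "skill",
            "father_edu": "ascribed",
            "sex": "ascribed",
            "g1": "pgi",
        }
    )


@pytest.fixture
def toy_long(toy_rolemap):
    # 3 individuals x 3 waves
    return pd.DataFrame(
        {
            "pid": [1, 1, 1, 2, 2, 2, 3, 3, 3],
            "w": [1, 2, 3] * 3,
            "age": [30.0] * 3 + [50.0] * 3 + [70.0] * 3,
            "edu": [2300.0, 2500.0, np.nan, 12, 11, 13, np.nan, np.nan, np.nan],
            "cog": [0.2, 0.5, 0.1, -1.0, np.nan, -0.5, 0.0, 0.0, 0.0],
            "father_edu": [8.0] * 3 + [12.0] * 3 + [10.0] * 3,
            "sex": ["F"] * 3 + ["M"] * 3 + ["F"] * 3,
            "g1": [0.1] * 3 + [-0.2] * 3 + [0.3] * 3,
        }
    )


class TestRoleMap:
    def test_requires_exactly_one_id(self):
        with pytest.raises(RoleMapError, match="id"):
            RoleMap({"y": "outcome"})

    def test_requires_an_outcome(self):
        with pytest.raises(RoleMapError, match="outcome"):
            RoleMap({"pid": "id", "x": "ascribed"})

    def test_rejects_unknown_roles(self):
        with pytest.raises(RoleMapError, match="unknown roles"):
            RoleMap({"pid": "id", "y": "outcome", "x": "confounder"})

    def test_yaml_round_trip(self, toy_rolemap, tmp_path):
        path = tmp_path / "rm.yaml"
        toy_rolemap.to_yaml(path)
        back = RoleMap.from_yaml(path)
        assert back.mapping == toy_rolemap.mapping
        assert back.talent_measure == toy_rolemap.talent_measure


class TestCollapseWaves:
    def test_max_rule_with_missing(self, toy_long, toy_rolemap):
        out = collapse_waves(toy_long, toy_rolemap)
        assert out.loc[out.pid == 1, "edu"].item() == 2500.0
        assert out.loc[out.pid == 2, "edu"].item() == 13.0
        assert np.isnan(out.loc[out.pid == 3, "edu"].item())

    def test_hand_computed_toy_maxima(self, toy_long, toy_rolemap):
        out = collapse_waves(toy_long, toy_rolemap).set_index("pid")
        # brute force: per id, per wave-varying column, max of non-missing
        for pid in (1, 2, 3):
            rows = toy_long[toy_long.pid == pid]
            for col in ("edu", "cog"):
                expect = rows[col].max()  # pandas max skips NaN
                got = out.loc[pid, col]
                assert (np.isnan(expect) and np.isnan(got)) or got == expect

    def test_time_invariant_taken_and_validated(self, toy_long, toy_rolemap):
        out = collapse_waves(toy_long, toy_rolemap).set_index("pid")
        assert out.loc[2, "father_edu"] == 12.0
        bad = toy_long.copy()
        bad.loc[0, "father_edu"] = 99.0
        with pytest.raises(PreprocessError, match=r"ids: \[1\]"):
            collapse_waves(bad, toy_rolemap)

    def test_single_wave_passthrough(self, toy_rolemap):
        df = pd.DataFrame(
            {"pid": [1, 2], "edu": [10.0, 12.0], "age": [30, 40],
             "cog": [0.0, 1.0], "father_edu": [8, 9], "sex": ["F", "M"],
             "g1": [0.0, 0.1]}
        )
        out = collapse_waves(df, toy_rolemap)
        pd.testing.assert_frame_equal(out, df)

    def test_idempotent(self, toy_long, toy_rolemap):
        once = collapse_waves(toy_long, toy_rolemap)
        twice = collapse_waves(once, toy_rolemap)
        pd.testing.assert_frame_equal(once, twice)

    def test_duplicate_ids_without_wave_column_rejected(self, toy_rolemap):
        df = pd.DataFrame({"pid": [1, 1], "edu": [1.0, 2.0], "age": [30, 30],
                           "cog": [0, 0], "father_edu": [8, 8],
                           "sex": ["F", "F"], "g1": [0, 0]})
        with pytest.raises(PreprocessError, match="duplicate ids"):
            collapse_waves(df, toy_rolemap)


class TestFilterSample:
    def make(self, ages):
        return pd.DataFrame({"pid": range(len(ages)), "age": ages,
                             "edu": [10.0] * len(ages)})

    def rm(self):
        return RoleMap({"pid": "id", "age": "age", "edu": "outcome"})

    def test_working_age_bounds_inclusive(self):
        df = self.make([24, 25, 65, 66])
        out, report = filter_sample(df, FilterCriteria(age_range=(25, 65)), self.rm())
        assert out["age"].tolist() == [25, 65]
        assert report[-1]["removed"] == 2

    def test_no_criteria_identity(self):
        df = self.make([30, 40])
        out, report = filter_sample(df, FilterCriteria(), self.rm())
        pd.testing.assert_frame_equal(out, df)
        assert len(report) == 1

    def test_missingness_counts_match_manual_tally(self):
        df = pd.DataFrame(
            {"pid": range(5), "age": [30] * 5,
             "edu": [1.0, np.nan, 2.0, np.nan, 3.0],
             "x": [1.0, 1.0, np.nan, np.nan, 2.0]}
        )
        rm = RoleMap({"pid": "id", "age": "age", "edu": "outcome", "x": "ascribed"})
        out, report = filter_sample(
            df, FilterCriteria(required_columns=("edu", "x")), rm
        )
        assert len(out) == 2 and report[-1]["removed"] == 3

    def test_exclusion_list(self):
        df = self.make([30, 40, 50])
        out, _ = filter_sample(df, FilterCriteria(exclude_ids=(1,)), self.rm())
        assert out["pid"].tolist() == [0, 2]

    def test_order_independent_row_set(self):
        df = pd.DataFrame(
            {"pid": range(6), "age": [20, 30, 40, 50, 70, 35],
             "edu": [1.0, np.nan, 2.0, 3.0, 4.0, 5.0]}
        )
        a_then_b, _ = filter_sample(
            *filter_sample(df, FilterCriteria(age_range=(25, 65)), self.rm())[:1],
            FilterCriteria(required_columns=("edu",)), self.rm(),
        )
        b_then_a, _ = filter_sample(
            *filter_sample(df, FilterCriteria(required_columns=("edu",)), self.rm())[:1],
            FilterCriteria(age_range=(25, 65)), self.rm(),
        )
        both, _ = filter_sample(
            df, FilterCriteria(age_range=(25, 65), required_columns=("edu",)),
            self.rm(),
        )
        assert set(a_then_b.pid) == set(b_then_a.pid) == set(both.pid)

    def test_empty_result_raises(self):
        df = self.make([20, 21])
        with pytest.raises(EmptySampleError):
            filter_sample(df, FilterCriteria(age_range=(25, 65)), self.rm())


class TestEncodeCategoricals:
    def test_binary_gives_single_dummy(self):
        rm = RoleMap({"pid": "id", "y": "outcome", "sex": "ascribed"})
        df = pd.DataFrame({"pid": [1, 2], "y": [1.0, 2.0], "sex": ["F", "M"]})
        out, rm2 = encode_categoricals(df, rm)
        assert "sex=M" in out.columns and "sex" not in out.columns
        assert rm2.mapping["sex=M"] == "ascribed"
        assert out["sex=M"].tolist() == [0.0, 1.0]

    def test_k_levels_give_k_minus_1_dummies(self):
        rm = RoleMap({"pid": "id", "y": "outcome", "mig": "ascribed"})
        df = pd.DataFrame({"pid": range(3), "y": [1.0, 2.0, 3.0],
                           "mig": ["a", "b", "c"]})
        out, _ = encode_categoricals(df, rm)
        assert sorted(c for c in out.columns if c.startswith("mig")) == [
            "mig=b", "mig=c"
        ]  # reference = first level alphabetically

    def test_mixed_table_column_count(self):
        rm = RoleMap({"pid": "id", "y": "outcome", "s": "ascribed",
                      "m": "ascribed", "x": "ascribed"})
        df = pd.DataFrame({"pid": range(4), "y": [1.0, 2, 3, 4],
                           "s": ["F", "M", "F", "M"],
                           "m": ["a", "b", "c", "a"],
                           "x": [0.1, 0.2, 0.3, 0.4]})
        out, _ = encode_categoricals(df, rm)
        # numeric (pid, y, x) + (2-1) + (3-1) dummies
        assert out.shape[1] == 3 + 1 + 2

    def test_missing_values_propagate_to_dummies(self):
        rm = RoleMap({"pid": "id", "y": "outcome", "s": "ascribed"})
        df = pd.DataFrame({"pid": range(3), "y": [1.0, 2, 3],
                           "s": ["F", None, "M"]})
        out, _ = encode_categoricals(df, rm)
        assert np.isnan(out.loc[1, "s=M"])

    def test_single_level_dropped_with_warning(self):
        rm = RoleMap({"pid": "id", "y": "outcome", "s": "ascribed"})
        df = pd.DataFrame({"pid": [1, 2], "y": [1.0, 2.0], "s": ["F", "F"]})
        with pytest.warns(UserWarning, match="single observed level"):
            out, rm2 = encode_categoricals(df, rm)
        assert "s" not in out.columns and "s" not in rm2.mapping


class TestStandardize:
    def rm(self):
        return RoleMap({"pid": "id", "y": "outcome", "x": "ascribed"})

    def test_simple_column(self):
        df = pd.DataFrame({"pid": [1, 2, 3], "y": [1.0, 2.0, 3.0],
                           "x": [4.0, 5.0, 6.0]})
        frame = standardize(df, self.rm())
        assert frame.data["y"].tolist() == [-1.0, 0.0, 1.0]  # ddof=1 scaling

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"pid": range(50), "y": x, "x": rng.normal(size=50)})
        frame = standardize(df, self.rm())
        assert np.allclose(frame.data["y"], x, atol=1e-12)

    def test_moments_after_scaling(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"pid": range(100), "y": rng.normal(2, 7, 100),
                           "x": rng.uniform(size=100)})
        frame = standardize(df, self.rm())
        for c in ("y", "x"):
            assert abs(frame.data[c].mean()) < 1e-10
            assert abs(frame.data[c].std(ddof=1) - 1) < 1e-10
        # scaling parameters retained for reporting
        assert frame.scaling.loc["y", "sd"] == pytest.approx(df["y"].std(ddof=1))

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"pid": [1, 2], "y": [1.0, 2.0], "x": [3.0, 3.0]})
        with pytest.raises(PreprocessError, match=r"\['x'\]"):
            standardize(df, self.rm())

    def test_fewer_than_two_rows_rejected(self):
        df = pd.DataFrame({"pid": [1], "y": [1.0], "x": [2.0]})
        with pytest.raises(PreprocessError, match="2 rows"):
            standardize(df, self.rm())

    def test_remaining_missing_rejected(self):
        df = pd.DataFrame({"pid": [1, 2], "y": [1.0, np.nan], "x": [1.0, 2.0]})
        with pytest.raises(PreprocessError, match="missing"):
            standardize(df, self.rm())


def test_r2_invariant_to_affine_raw_inputs(small_cohort):
    """End-to-end: rescaling raw inputs must not move downstream R2."""
    from ineqop.decomposition import ols_r2

    params, long, rolemap = small_cohort
    frame1 = iq.prepare(long, rolemap)
    shifted = long.copy()
    shifted["paternal_education"] = 7.3 * shifted["paternal_education"] - 2.0
    shifted["education"] = 0.5 * shifted["education"] + 100.0
    frame2 = iq.prepare(shifted, rolemap)
    cols = [c for c in frame1.data.columns
            if frame1.rolemap.mapping[c] in ("ascribed", "pc", "pgi")]
    r2_1 = ols_r2(frame1.data["education"], frame1.data[cols])
    r2_2 = ols_r2(frame2.data["education"], frame2.data[cols])
    assert r2_1 == pytest.approx(r2_2, abs=1e-10)
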