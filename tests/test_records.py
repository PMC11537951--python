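"""Data model: CSV parsing, validation, age groups, replicate views."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anthro_reliability import records as rec
from anthro_reliability.records import (
    DuplicateRecordError,
    SchemaError,
    Stratum,
    assign_age_group,
    build_inter_view,
    build_intra_view,
    read_measurements,
    validate,
    write_measurements,
)


class TestReadMeasurements:
    def test_identity_parse(self, measurement_csv):
        df, errors = read_measurements(measurement_csv)
        assert errors == []
        assert len(df) == 10
        assert set(df["volunteer_id"]) == {"A", "B"}
        assert df["value"].dtype == float

    def test_bad_rows_reported_not_dropped_silently(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "volunteer_id,rater_id,rater_group,parameter,round,value,age_years\n"
            "A,r1,fieldworker,weight,1,10.0,5\n"
            "A,r1,fieldworker,weight,3,10.1,5\n"      # bad round
            "A,r2,fieldworker,weight,1,oops,5\n"       # bad value
            "A,r3,fieldworker,weight,1,-2,5\n"         # non-positive value
            "A,r4,sitelead,weight,1,10.0,5\n"          # unknown rater group
        )
        df, errors = read_measurements(path)
        assert len(df) == 1
        assert sorted(e["row"] for e in errors) == [2, 3, 4, 5]

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("volunteer_id,rater_id,parameter,round,value,age_years\nA,r,weight,1,1,1\n")
        with pytest.raises(SchemaError, match="rater_group"):
            read_measurements(path)

    def test_empty_file_is_fatal(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(SchemaError):
            read_measurements(path)

    def test_case_insensitive_headers_and_column_map(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "Volunteer_ID,rater_id,rater_group,measure,round,value,age_years\n"
            "A,r1,fieldworker,weight,1,10.0,5\n"
        )
        df, errors = read_measurements(path, column_map={"measure": "parameter"})
        assert errors == [] and len(df) == 1

    def test_round_trip_is_value_identical(self, measurement_csv, tmp_path):
        df, _ = read_measurements(measurement_csv)
        out = tmp_path / "roundtrip.csv"
        write_measurements(df, out)
        df2, errors = read_measurements(out)
        assert errors == []
        pd.testing.assert_frame_equal(
            df.reset_index(drop=True)[df2.columns], df2.reset_index(drop=True)
        )


class TestValidate:
    def test_off_grid_value_is_warning_not_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "volunteer_id,rater_id,rater_group,parameter,round,value,age_years\n"
            "A,r1,fieldworker,weight,1,6.005,5\n"   # off the 0.01 kg grid
            "A,r2,fieldworker,weight,1,6.01,5\n"    # on grid
        )
        df, errors = read_measurements(path)
        assert errors == []
        df, report = validate(df)
        assert len(report.off_grid) == 1
        assert report.off_grid[0]["value"] == 6.005

    def test_duplicate_record_fatal_by_default(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(DuplicateRecordError):
            validate(dup)

    def test_duplicate_keep_first(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        cleaned, report = validate(dup, on_duplicate="keep_first")
        assert len(cleaned) == len(df)
        assert len(report.duplicates) == 1

    def test_single_rater_volunteers_listed(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        solo = df[(df["rater_id"] == "r1") & (df["volunteer_id"] == "A")].copy()
        solo["volunteer_id"] = "C"
        df = pd.concat([df, solo], ignore_index=True)
        _, report = validate(df)
        assert report.single_rater_volunteers == {"muac/fieldworker": ["C"]}


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (0.0, "under2"), (0.8, "under2"), (1.999, "under2"),
            (2.0, "two_to_12"), (7.0, "two_to_12"), (12.0, "two_to_12"),
            (12.01, "over12"), (65.0, "over12"),
        ],
    )
    def test_boundary_convention(self, age, expected):
        assert assign_age_group(age) == expected

    def test_negative_age_fatal(self):
        with pytest.raises(ValueError):
            assign_age_group(-0.1)

    @given(st.floats(min_value=0, max_value=120, allow_nan=False))
    def test_partition_of_nonnegative_ages(self, age):
        assert assign_age_group(age) in rec.AGE_GROUPS


class TestViews:
    def test_inter_uses_first_round_only(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        view = build_inter_view(df, "muac")
        groups = dict(view.groups)
        np.testing.assert_allclose(groups["A"], [10.0, 10.2, 10.4])
        np.testing.assert_allclose(groups["B"], [20.0, 20.3])
        assert view.n_obs == 5

    def test_inter_excludes_single_rater_volunteers(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        solo = df[(df["rater_id"] == "r1") & (df["round"] == 1)].copy()
        solo["volunteer_id"] = "C"
        df = pd.concat([df, solo], ignore_index=True)
        view = build_inter_view(df, "muac")
        assert "C" not in dict(view.groups)

    def test_intra_pairs_ordered_and_incomplete_dropped(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        # remove round 2 of (B, r2): that pair must vanish
        df = df[~((df["volunteer_id"] == "B") & (df["rater_id"] == "r2") & (df["round"] == 2))]
        view = build_intra_view(df, "muac")
        keys = {k for k, _ in view.groups}
        assert ("B", "r2") not in keys
        assert len(view.groups) == 4
        np.testing.assert_allclose(dict(view.groups)[("A", "r1")], [10.0, 10.2])

    def test_intra_n_is_even_and_inter_bounded_by_round1(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        inter = build_inter_view(df, "muac")
        intra = build_intra_view(df, "muac")
        assert intra.n_obs % 2 == 0
        assert inter.n_obs <= (df["round"] == 1).sum()

    def test_stratum_filters(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        under2 = build_inter_view(df, "muac", Stratum("fieldworker", "under2"))
        assert {k for k, _ in under2.groups} == {"A"}
        empty = build_inter_view(df, "muac", Stratum("site_lead", None))
        assert empty.n_groups == 0

    def test_error_df_counts(self, measurement_csv):
        df, _ = read_measurements(measurement_csv)
        inter = build_inter_view(df, "muac")
        assert inter.error_df == (3 - 1) + (2 - 1)
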