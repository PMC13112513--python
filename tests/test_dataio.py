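import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecsbmr import (
    ParseError,
    SchemaError,
    ValidationError,
    extract_controls,
    generate_database,
    normalize_daily_dose,
    read_database,
    read_json,
    write_database,
    write_json,
    SyntheticConfig,
)
from ecsbmr.dataio import canonical_technology

from conftest import make_dataset


class TestReadDatabase:
    def test_minimal_csv(self, tiny_csv):
        db = read_database(tiny_csv)
        assert len(db) == 1
        ds = db.get("d1")
        assert len(ds.groups) == 2
        assert ds.control.n == 2
        assert ds.groups[1].n == 1
        assert ds.technology == "DupSeq"

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("dataset_id,technology,chemical,dose_mg_kg_day\nd1,DupSeq,X,0\n")
        with pytest.raises(SchemaError, match="mf_per_1e8bp"):
            read_database(p)

    def test_schema_config_maps_columns(self, tmp_path):
        p = tmp_path / "alt.csv"
        p.write_text(
            "id,tech,chemical,dose,mf\n"
            "d1,DupSeq,X,0,1.0\nd1,DupSeq,X,0,1.1\nd1,DupSeq,X,10,2.0\n"
        )
        db = read_database(
            p,
            schema_config={
                "dataset_id": "id",
                "technology": "tech",
                "dose_mg_kg_day": "dose",
                "mf_per_1e8bp": "mf",
            },
        )
        assert len(db) == 1

    def test_missing_control_lists_dataset(self, tmp_path):
        p = tmp_path / "noctrl.csv"
        p.write_text(
            "dataset_id,technology,chemical,dose_mg_kg_day,mf_per_1e8bp\n"
            "d9,DupSeq,X,10,1.0\nd9,DupSeq,X,50,2.0\n"
        )
        with pytest.raises(ValidationError, match="d9"):
            read_database(p)

    def test_non_numeric_dose_reports_row(self, tmp_path):
        p = tmp_path / "nan.csv"
        p.write_text(
            "dataset_id,technology,chemical,dose_mg_kg_day,mf_per_1e8bp\n"
            "d1,DupSeq,X,0,1.0\nd1,DupSeq,X,oops,2.0\n"
        )
        with pytest.raises(ParseError, match="row 3"):
            read_database(p)

    def test_zero_response_policies(self, tmp_path):
        p = tmp_path / "zero.csv"
        p.write_text(
            "dataset_id,technology,chemical,dose_mg_kg_day,mf_per_1e8bp\n"
            "d1,DupSeq,X,0,0\nd1,DupSeq,X,0,1.0\nd1,DupSeq,X,10,2.0\n"
        )
        with pytest.raises(ValidationError, match="zero"):
            read_database(p)
        db = read_database(p, zero_policy="half_min")
        assert sorted(db.get("d1").control.responses) == [0.5, 1.0]


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, two_study_db):
        path = tmp_path / "db.csv"
        write_database(two_study_db, path)
        back = read_database(path)
        assert len(back) == len(two_study_db)
        for ds in two_study_db:
            got = back.get(ds.dataset_id)
            assert got.technology == ds.technology
            for g1, g2 in zip(ds.groups, got.groups):
                assert g1.dose == g2.dose
                np.testing.assert_array_equal(np.sort(g1.responses), np.sort(g2.responses))

    def test_synthetic_fixture_round_trip(self, tmp_path):
        db = generate_database(SyntheticConfig(seed=3))
        path = tmp_path / "synth.csv"
        write_database(db, path)
        back = read_database(path)
        assert len(back) == 47
        for ds in db:
            got = back.get(ds.dataset_id)
            assert got.covariates == ds.covariates
            d1, r1 = ds.observations()
            d2, r2 = got.observations()
            np.testing.assert_array_equal(np.sort(r1), np.sort(r2))

    def test_unicode_chemical(self, tmp_path):
        ds = make_dataset({0.0: [1.0, 1.1], 5.0: [2.0]}, chemical="β-propiolactone")
        from ecsbmr import StudyDatabase

        db = StudyDatabase(datasets=[ds])
        path = tmp_path / "uni.csv"
        write_database(db, path)
        assert read_database(path).datasets[0].chemical == "β-propiolactone"

    def test_json_round_trip(self, tmp_path, two_study_db):
        path = tmp_path / "db.json"
        write_json(two_study_db, path)
        back = read_json(path)
        assert [d.dataset_id for d in back] == [d.dataset_id for d in two_study_db]


class TestControls:
    def test_pooled_count_conservation(self, two_study_db):
        pooled = extract_controls(two_study_db, "DupSeq")
        assert pooled.size == 8

    def test_per_study_keys_and_sizes(self, two_study_db):
        per = extract_controls(two_study_db, "DupSeq", per_study=True)
        assert {k: v.size for k, v in per.items()} == {"s1": 3, "s2": 5}
        assert sum(v.size for v in per.values()) == extract_controls(
            two_study_db, "DupSeq"
        ).size

    def test_absent_technology_warns_empty(self, two_study_db):
        with pytest.warns(UserWarning, match="HiFi"):
            out = extract_controls(two_study_db, "HiFi")
        assert out.size == 0

    def test_generator_bookkeeping_216_controls(self):
        cfg = SyntheticConfig(control_n_total=216, seed=2)
        db = generate_database(cfg)
        assert extract_controls(db, "DupSeq").size == 216


class TestNormalizeDailyDose:
    @pytest.mark.parametrize(
        "cum,dur,expected", [(280, 28, 10.0), (0, 28, 0.0), (100, 3, 100 / 3)]
    )
    def test_examples(self, cum, dur, expected):
        assert normalize_daily_dose(cum, dur) == pytest.approx(expected, rel=1e-12)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            normalize_daily_dose(10, 0)

    @given(
        cum=st.floats(0.1, 1e4),
        dur=st.floats(0.1, 1e3),
        k=st.floats(0.1, 100),
    )
    def test_linearity(self, cum, dur, k):
        base = normalize_daily_dose(cum, dur)
        assert normalize_daily_dose(k * cum, dur) == pytest.approx(k * base, rel=1e-9)
        assert normalize_daily_dose(cum, k * dur) == pytest.approx(base / k, rel=1e-9)


def test_technology_aliases():
    assert canonical_technology("Hawk-Seq") == "HawkSeq"
    assert canonical_technology("duplex sequencing") == "DupSeq"
    with pytest.raises(ValidationError):
        canonical_technology("nanopore")


def test_dataset_invariants():
    with pytest.raises(ValidationError, match="dose-0"):
        make_dataset({10.0: [1.0], 50.0: [2.0]})
    with pytest.raises(ValidationError, match="2 distinct"):
        make_dataset({0.0: [1.0, 1.2]})
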