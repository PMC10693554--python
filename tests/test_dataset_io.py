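import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ch4pred.dataset_io import (
    ConfigurationError,
    EmptyFeatureError,
    SchemaError,
    ValidationError,
    build_design,
    destandardize,
    filter_genera,
    load_dataset,
    load_matrix,
    log_transform_abundances,
    prepare_matrix,
    save_matrix,
    standardize_train_apply_test,
)

from conftest import make_matrix


class TestLoadDataset:
    def test_parses_records_and_animals(self, toy_csv):
        table = load_dataset(toy_csv)
        assert table.n_obs == 3
        assert table.n_animals == 2
        assert table.genus_columns == (
            "bacteria__Prevotella",
            "archaea__Methanobrevibacter",
        )
        recs = list(table.records())
        assert recs[0].animal_id == "A1" and recs[0].round_index == 1
        assert recs[2].abundances["bacteria__Prevotella"] == pytest.approx(0.45)

    def test_deterministic_reload(self, toy_csv):
        t1, t2 = load_dataset(toy_csv), load_dataset(toy_csv)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_missing_bw_names_row(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv)
        df.loc[1, "bw"] = np.nan
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValidationError, match=r"bw.*\[1\]"):
            load_dataset(bad)

    def test_negative_covariate_rejected(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv)
        df.loc[0, "dmi"] = -0.5
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValidationError, match="dmi"):
            load_dataset(bad)

    def test_duplicate_animal_round_rejected(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv)
        df.loc[1, "round_index"] = 1
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            load_dataset(bad)

    def test_schema_mapping_and_missing_column(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv).rename(columns={"animal_id": "sheep"})
        renamed = tmp_path / "renamed.csv"
        df.to_csv(renamed, index=False)
        table = load_dataset(renamed, schema={"animal_id": "sheep"})
        assert table.n_animals == 2
        with pytest.raises(SchemaError):
            load_dataset(renamed)

    def test_malformed_genus_column(self, toy_csv, tmp_path):
        df = pd.read_csv(toy_csv).rename(columns={"bacteria__Prevotella": "Prevotella"})
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(SchemaError, match="Prevotella"):
            load_dataset(bad)


def _table_with_abundances(ab: np.ndarray, genus_names):
    """Build a minimal valid table around a given abundance block."""
    n = ab.shape[0]
    data = pd.DataFrame(
        {
            "animal_id": [f"A{i}" for i in range(n)],
            "round_index": [1] * n,
            "ch4_production": 20.0,
            "ch4_yield": 14.0,
            "dmi": 1.4,
            "bw": 40.0,
            "ap_ratio": 3.0,
            "sex": "F",
            "breed": "Romney",
        }
    )
    for j, g in enumerate(genus_names):
        data[g] = ab[:, j]
    from ch4pred.dataset_io import ObservationTable

    return ObservationTable(
        data=data,
        genus_columns=tuple(genus_names),
        genus_domains={g: g.split("__")[0] for g in genus_names},
    )


class TestFilterGenera:
    names5 = [f"bacteria__g{j}" for j in range(5)]

    def test_all_rule_drops_genus_below_threshold_once(self):
        ab = np.array([[0.02, 0.02], [0.005, 0.02], [0.02, 0.02]])
        table = _table_with_abundances(ab, ["bacteria__low", "bacteria__hi"])
        out, dropped = filter_genera(table, 0.01, "all")
        assert dropped == ["bacteria__low"]
        assert out.genus_columns == ("bacteria__hi",)

    def test_zero_threshold_any_keeps_everything(self, small_data):
        table, _ = small_data
        out, dropped = filter_genera(table, 0.0, "any")
        assert dropped == []
        assert out.genus_columns == table.genus_columns

    def test_fraction_rule_exact_count(self):
        # 4 samples; a genus passes (1%, p=0.5) iff >1% in at least 2 samples
        ab = np.array(
            [
                [0.05, 0.05, 0.005, 0.005, 0.005],
                [0.05, 0.05, 0.005, 0.005, 0.005],
                [0.005, 0.05, 0.005, 0.05, 0.005],
                [0.005, 0.005, 0.005, 0.005, 0.005],
            ]
        )
        table = _table_with_abundances(ab, self.names5)
        out, dropped = filter_genera(table, 0.01, 0.5)
        assert out.genus_columns == ("bacteria__g0", "bacteria__g1")
        assert len(dropped) == 3

    def test_empty_result_is_error(self):
        ab = np.full((3, 2), 0.001)
        table = _table_with_abundances(ab, ["bacteria__a", "bacteria__b"])
        with pytest.raises(EmptyFeatureError):
            filter_genera(table, 0.5, "all")

    def test_input_not_mutated(self, small_data):
        table, _ = small_data
        before = table.data.copy()
        filter_genera(table, 0.001, "any")
        pd.testing.assert_frame_equal(table.data, before)


class TestLogTransform:
    def test_closed_form_values(self):
        ab = np.array([[0.01, 0.99]])
        table = _table_with_abundances(ab, ["bacteria__a", "bacteria__b"])
        out = log_transform_abundances(table, pseudocount=0.0)
        assert out.data["bacteria__a"].iloc[0] == pytest.approx(-4.60517, abs=1e-5)

    def test_zero_with_pseudocount(self):
        ab = np.array([[0.0, 1.0]])
        table = _table_with_abundances(ab, ["bacteria__a", "bacteria__b"])
        out = log_transform_abundances(table, pseudocount=1e-6)
        assert out.data["bacteria__a"].iloc[0] == pytest.approx(np.log(1e-6), abs=1e-4)

    def test_zero_without_pseudocount_is_error(self):
        ab = np.array([[0.0, 1.0]])
        table = _table_with_abundances(ab, ["bacteria__a", "bacteria__b"])
        with pytest.raises(ValidationError):
            log_transform_abundances(table, pseudocount=0.0)

    def test_double_transform_refused(self, small_data):
        table, _ = small_data
        once = log_transform_abundances(table)
        with pytest.raises(ConfigurationError):
            log_transform_abundances(once)

    def test_monotone_per_column(self, small_data):
        table, _ = small_data
        out = log_transform_abundances(table)
        for g in table.genus_columns[:5]:
            order_in = np.argsort(table.data[g].to_numpy())
            order_out = np.argsort(out.data[g].to_numpy())
            assert np.array_equal(order_in, order_out)


class TestBuildDesign:
    def test_family_columns(self, small_data):
        table, _ = small_data
        logged = log_transform_abundances(table)
        anim = build_design(logged, "ANIM-B")
        n_gen = len(table.genus_columns)
        assert anim.columns[:3] == ("dmi", "bw", "ap_ratio")
        assert anim.n_features == 3 + n_gen
        assert anim.response == "ch4_production"
        dmi_b = build_design(logged, "DMI-B")
        assert "dmi" not in dmi_b.columns
        assert dmi_b.n_features == 2 + n_gen
        assert dmi_b.response == "ch4_yield"
        for mm in (anim, dmi_b):
            assert "sex" not in mm.columns and "breed" not in mm.columns

    def test_column_kinds(self, small_data):
        table, _ = small_data
        mm = build_design(log_transform_abundances(table), "ANIM-B")
        assert set(mm.column_kind[:3]) == {"animal"}
        assert set(mm.column_kind[3:]) == {"microbial"}

    def test_requires_log_transform(self, small_data):
        table, _ = small_data
        with pytest.raises(ConfigurationError, match="log"):
            build_design(table, "ANIM-B")

    def test_family_response_mismatch(self, small_data):
        table, _ = small_data
        logged = log_transform_abundances(table)
        with pytest.raises(ConfigurationError):
            build_design(logged, "ANIM-B", response_choice="ch4_yield")


class TestStandardize:
    def test_unit_scaling(self):
        train = make_matrix([[1.0], [2.0], [3.0]], [0, 0, 0], ["a", "a", "b"])
        out, _ = standardize_train_apply_test(train)
        np.testing.assert_allclose(out.X[:, 0], [-1.0, 0.0, 1.0])

    def test_test_uses_train_statistics(self):
        train = make_matrix([[1.0], [2.0], [3.0]], [0, 0, 0], ["a", "a", "b"])
        test = make_matrix([[2.0], [5.0]], [0, 0], ["c", "c"])
        _, test_s = standardize_train_apply_test(train, test)
        assert test_s.X[0, 0] == pytest.approx(0.0)  # equals the train mean
        assert test_s.X[1, 0] == pytest.approx(3.0)

    def test_constant_column_error_names_column(self):
        train = make_matrix(
            [[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], [0, 0, 0], ["a", "a", "b"],
            columns=["ok", "flat"],
        )
        with pytest.raises(ValidationError, match="flat"):
            standardize_train_apply_test(train)

    @given(st.integers(0, 2**31 - 1))
    def test_roundtrip_recovers_inputs(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3)) * rng.uniform(0.5, 20.0, 3)
        mm = make_matrix(X, np.zeros(8), ["a"] * 4 + ["b"] * 4)
        out, _ = standardize_train_apply_test(mm)
        back = destandardize(out)
        np.testing.assert_allclose(back.X, X, atol=1e-12 * max(1, np.abs(X).max()))

    def test_mismatched_columns_rejected(self):
        train = make_matrix([[1.0], [2.0], [3.0]], [0, 0, 0], list("aab"))
        test = make_matrix([[1.0], [2.0]], [0, 0], list("cc"), columns=["other"])
        with pytest.raises(ConfigurationError):
            standardize_train_apply_test(train, test)


def test_prepare_matrix_pipeline_counts(small_data):
    table, _ = small_data
    mm = prepare_matrix(table, "ANIM-B", min_abundance=1e-4, prevalence_rule="any")
    filtered, dropped = filter_genera(table, 1e-4, "any")
    assert mm.n_features == 3 + len(filtered.genus_columns)
    assert mm.n_obs == table.n_obs


def test_matrix_save_load_roundtrip(tmp_path, small_data):
    table, _ = small_data
    mm = prepare_matrix(table, "ANIM-B")
    mm_s, _ = standardize_train_apply_test(mm)
    prefix = str(tmp_path / "mat")
    save_matrix(mm_s, prefix)
    back = load_matrix(prefix)
    np.testing.assert_allclose(back.X, mm_s.X)
    np.testing.assert_allclose(back.y, mm_s.y)
    assert back.columns == mm_s.columns
    np.testing.assert_allclose(back.center, mm_s.center)
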