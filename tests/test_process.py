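"""Pruning, summarization, the four-element bundle and the pipeline wrapper."""

import numpy as np
import pandas as pd
import pytest

from wormwell import (
    EdgeConfig,
    ProcessedBundle,
    ValidationError,
    edge_flag,
    join_design,
    process_bundle,
    prune,
    rank_models_by_frequency,
    read_design,
    read_object_data,
    select_models,
    set_flags,
    summarize,
    xpress,
)

from conftest import make_objects


def flagged_table(n=100, n_cluster=7, n_edge=5, n_outlier=3):
    df = make_objects([("p01", "A01", i, "L1", 250.0 + i) for i in range(n)])
    df["cluster_flag"] = [i < n_cluster for i in range(n)]
    df["well_edge_flag"] = [n_cluster <= i < n_cluster + n_edge for i in range(n)]
    df["flag_outlier"] = [
        n_cluster + n_edge <= i < n_cluster + n_edge + n_outlier for i in range(n)
    ]
    return df


class TestPrune:
    def test_disjoint_flags_drop_additively(self):
        out = prune(flagged_table(100, 7, 5, 3))
        assert len(out) == 85

    def test_partial_drop_set_retains_other_flags(self):
        out = prune(flagged_table(100, 7, 5, 3), drop_flags=("cluster", "outlier"))
        assert len(out) == 90
        assert out["well_edge_flag"].sum() == 5

    def test_no_flags_is_identity(self):
        df = flagged_table(20, 0, 0, 0)
        pd.testing.assert_frame_equal(prune(df), df)

    def test_empty_drop_set_is_identity(self):
        df = flagged_table(50, 5, 5, 5)
        pd.testing.assert_frame_equal(prune(df, drop_flags=()), df)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValidationError):
            prune(flagged_table(), drop_flags=("bogus",))


class TestSummarize:
    def test_two_value_group_closed_form(self):
        df = make_objects([("p01", "A01", 1, "L1", 100.0), ("p01", "A01", 2, "L1", 200.0)])
        s = summarize(df).iloc[0]
        assert s["n"] == 2
        assert s["mean_length"] == 150.0
        assert s["var_length"] == 5000.0  # ((100-150)^2 + (200-150)^2) / 1
        assert (s["min_length"], s["max_length"], s["q50"]) == (100.0, 200.0, 150.0)

    def test_singleton_group_has_missing_variance(self):
        df = make_objects([("p01", "A01", 1, "L1", 250.0)])
        s = summarize(df).iloc[0]
        assert s["n"] == 1 and s["mean_length"] == 250.0
        assert np.isnan(s["var_length"])

    def test_quantiles_are_ordered(self, flagged_small_sim):
        s = summarize(flagged_small_sim)
        for cols in (["min_length", "q10", "q25", "q50", "q75", "q90", "max_length"],):
            vals = s[cols].to_numpy()
            assert (np.diff(vals, axis=1) >= -1e-12).all()

    def test_grouping_partitions_rows(self, small_sim):
        _, objects, design, _ = small_sim
        joined = join_design(objects, design)
        s = summarize(joined, ["Metadata_Plate", "Metadata_Well", "strain"])
        assert s["n"].sum() == len(joined)

    def test_brute_force_per_group(self, flagged_small_sim):
        s = summarize(flagged_small_sim).set_index(["Metadata_Plate", "Metadata_Well"])
        for key, sub in flagged_small_sim.groupby(["Metadata_Plate", "Metadata_Well"]):
            arr = sub["worm_length"].to_numpy()
            row = s.loc[key]
            assert row["mean_length"] == pytest.approx(arr.mean())
            if len(arr) > 1:
                assert row["var_length"] == pytest.approx(arr.var(ddof=1))
            assert row["q75"] == pytest.approx(np.quantile(arr, 0.75))

    def test_empty_group_by_rejected(self, flagged_small_sim):
        with pytest.raises(ValidationError):
            summarize(flagged_small_sim, [])

    def test_extra_measurement_columns(self, flagged_small_sim):
        df = flagged_small_sim.copy()
        df["centroid_x_um"] = df["centroid_x"] * 3.2
        s = summarize(df, extra_measurements=["centroid_x_um"])
        assert "centroid_x_um_mean" in s.columns and "centroid_x_um_q50" in s.columns


class TestProcessBundle:
    def test_four_elements(self, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        assert len(bundle) == 4
        raw, processed, sraw, sproc = bundle
        assert len(processed) <= len(raw)

    def test_unflagged_input_gives_identical_elements(self):
        df = flagged_table(30, 0, 0, 0)
        bundle = process_bundle(df)
        pd.testing.assert_frame_equal(bundle.raw_data, bundle.processed_data)
        pd.testing.assert_frame_equal(bundle.summarized_raw, bundle.summarized_processed)

    def test_processed_rows_exist_in_raw(self, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        keys = ["Metadata_Plate", "Metadata_Well", "primary_object_id"]
        raw_keys = set(map(tuple, bundle.raw_data[keys].itertuples(index=False)))
        proc_keys = set(map(tuple, bundle.processed_data[keys].itertuples(index=False)))
        assert proc_keys <= raw_keys

    def test_summary_counts_monotone(self, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        keys = ["Metadata_Plate", "Metadata_Well"]
        merged = bundle.summarized_raw.merge(
            bundle.summarized_processed, on=keys, suffixes=("_raw", "_proc"), how="left"
        )
        assert (merged["n_proc"].fillna(0) <= merged["n_raw"]).all()

    def test_conservation(self, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        flags = flagged_small_sim[["cluster_flag", "well_edge_flag", "flag_outlier"]]
        dropped = flags.any(axis=1).sum()
        assert len(bundle.raw_data) == len(bundle.processed_data) + dropped

    def test_write_and_read_roundtrip(self, tmp_path, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        manifest = bundle.write(tmp_path / "run")
        assert sorted(manifest["row_counts"]) == [
            "processed.csv", "raw.csv", "summary_processed.csv", "summary_raw.csv",
        ]
        back = ProcessedBundle.read(tmp_path / "run")
        assert len(back.raw_data) == len(bundle.raw_data)
        assert len(back.summarized_processed) == len(bundle.summarized_processed)


class TestXpress:
    def test_equals_hand_chained_pipeline(self, tmp_path, small_sim):
        config, objects, design, _ = small_sim
        objects.to_csv(tmp_path / "objects.csv", index=False)
        design.to_csv(tmp_path / "design.csv", index=False)

        wrapped = xpress(tmp_path / "objects.csv", design_path=tmp_path / "design.csv")

        loaded = read_object_data([tmp_path / "objects.csv"])
        joined = join_design(loaded, read_design(tmp_path / "design.csv"))
        selected = select_models(joined, rank_models_by_frequency(joined))
        flagged = set_flags(edge_flag(selected, EdgeConfig(image_shape=(2048, 2048))))
        chained = process_bundle(flagged)

        pd.testing.assert_frame_equal(wrapped.raw_data, chained.raw_data)
        pd.testing.assert_frame_equal(wrapped.processed_data, chained.processed_data)
        pd.testing.assert_frame_equal(wrapped.summarized_processed, chained.summarized_processed)

    def test_radius_override_propagates(self, tmp_path, small_sim):
        _, objects, _, _ = small_sim
        objects.to_csv(tmp_path / "objects.csv", index=False)
        default = xpress(tmp_path / "objects.csv")
        tight = xpress(tmp_path / "objects.csv",
                       edge=EdgeConfig(radius=400, image_shape=(2048, 2048)))
        assert tight.raw_data["well_edge_flag"].sum() > default.raw_data["well_edge_flag"].sum()

    def test_design_is_optional(self, tmp_path, small_sim):
        _, objects, _, _ = small_sim
        objects.to_csv(tmp_path / "objects.csv", index=False)
        bundle = xpress(tmp_path / "objects.csv")
        assert "strain" not in bundle.raw_data.columns
        assert len(bundle) == 4
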