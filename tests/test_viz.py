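"""Plate heatmaps, well overlays and dose panels."""

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

from wormwell import (
    EdgeConfig,
    ValidationError,
    process_bundle,
    view_dose,
    view_plate,
    view_well,
)
from wormwell.viz import ALL_WELLS, representative_well


def _summary(wells, plate="p01"):
    return pd.DataFrame(
        {
            "Metadata_Plate": plate,
            "Metadata_Well": wells,
            "n": np.arange(1, len(wells) + 1),
            "mean_length": np.linspace(200, 1000, len(wells)),
        }
    )


class TestViewPlate:
    def test_full_plate_populates_96_cells(self):
        fig = view_plate(_summary(ALL_WELLS), "p01")
        assert len(fig.cells) == 96
        assert all(v is not None for v in fig.cells.values())

    def test_missing_wells_render_empty(self):
        fig = view_plate(_summary(ALL_WELLS[:90]), "p01")
        empty = [w for w, v in fig.cells.items() if v is None]
        assert len(empty) == 6
        assert set(empty) == set(ALL_WELLS[90:])

    def test_grid_is_complete_and_row_major(self):
        fig = view_plate(_summary(ALL_WELLS[:5]), "p01")
        assert sorted(fig.cells) == sorted(ALL_WELLS)
        assert ALL_WELLS[0] == "A01" and ALL_WELLS[-1] == "H12"
        assert ALL_WELLS[12] == "B01"

    def test_hover_payload_embedded_in_html(self, tmp_path):
        summary = _summary(["C05"])
        summary.loc[0, ["n", "mean_length"]] = [12, 512.3]
        fig = view_plate(summary, "p01")
        out = tmp_path / "plate.html"
        fig.to_html(out)
        html = out.read_text()
        assert "C05: n=12, mean=512.3" in html
        assert "<svg" in html and "script src" not in html  # self-contained

    def test_png_export(self, tmp_path):
        view_plate(_summary(ALL_WELLS), "p01").to_png(tmp_path / "plate.png")
        assert (tmp_path / "plate.png").stat().st_size > 0

    def test_absent_plate_raises(self):
        with pytest.raises(ValidationError, match="p99"):
            view_plate(_summary(ALL_WELLS), "p99")


class TestViewWell:
    def test_marker_count_equals_rows(self, flagged_small_sim):
        plate = flagged_small_sim["Metadata_Plate"].iloc[0]
        well = flagged_small_sim["Metadata_Well"].iloc[0]
        sub = flagged_small_sim[
            (flagged_small_sim["Metadata_Plate"] == plate)
            & (flagged_small_sim["Metadata_Well"] == well)
        ]
        fig = view_well(flagged_small_sim, plate, well,
                        edge=EdgeConfig(image_shape=(2048, 2048)))
        ax = fig.axes[0]
        n_markers = sum(len(c.get_offsets()) for c in ax.collections)
        assert n_markers == len(sub)
        plt.close(fig)

    def test_boxplot_toggle(self, flagged_small_sim):
        plate = flagged_small_sim["Metadata_Plate"].iloc[0]
        well = flagged_small_sim["Metadata_Well"].iloc[0]
        single = view_well(flagged_small_sim, plate, well, boxplot=False,
                           edge=EdgeConfig(image_shape=(2048, 2048)))
        double = view_well(flagged_small_sim, plate, well, boxplot=True,
                           edge=EdgeConfig(image_shape=(2048, 2048)))
        assert len(single.axes) == 1 and len(double.axes) == 2
        plt.close(single), plt.close(double)

    def test_processed_markers_subset_of_raw(self, flagged_small_sim):
        bundle = process_bundle(flagged_small_sim)
        sizes = bundle.summarized_raw.merge(
            bundle.summarized_processed,
            on=["Metadata_Plate", "Metadata_Well"], suffixes=("_r", "_p"),
        )
        row = sizes[sizes["n_p"] < sizes["n_r"]].iloc[0]
        edge = EdgeConfig(image_shape=(2048, 2048))
        raw_fig = view_well(bundle.raw_data, row["Metadata_Plate"], row["Metadata_Well"], edge=edge)
        proc_fig = view_well(bundle.processed_data, row["Metadata_Plate"], row["Metadata_Well"], edge=edge)
        count = lambda f: sum(len(c.get_offsets()) for c in f.axes[0].collections)
        assert count(proc_fig) < count(raw_fig)
        plt.close(raw_fig), plt.close(proc_fig)

    def test_absent_well_raises(self, flagged_small_sim):
        with pytest.raises(ValidationError):
            view_well(flagged_small_sim, "p99", "A01")

    def test_unreadable_image_names_path(self, flagged_small_sim, tmp_path):
        plate = flagged_small_sim["Metadata_Plate"].iloc[0]
        well = flagged_small_sim["Metadata_Well"].iloc[0]
        bad = tmp_path / "missing.tif"
        with pytest.raises(ValidationError, match="missing.tif"):
            view_well(flagged_small_sim, plate, well, image_path=bad)

    def test_image_backdrop(self, tmp_path):
        import tifffile

        from wormwell import SimulationConfig, generate_plate_set, select_models, edge_flag, set_flags

        config = SimulationConfig(
            plates=1, wells_per_plate=1, animals_per_well=8,
            image_size_px=512, well_radius_px=240.0, edge_radius_px=200.0,
        )
        objects, _, _ = generate_plate_set(config, seed=5, outdir=tmp_path, images=True)
        flagged = set_flags(edge_flag(select_models(objects), EdgeConfig(radius=200, image_shape=(512, 512))))
        fname = objects["Image_FileName_RawBF"].iloc[0]
        fig = view_well(flagged, "p01", "A01", image_path=tmp_path / fname,
                        edge=EdgeConfig(radius=200, image_shape=(512, 512)))
        assert fig.axes[0].images  # the TIFF is drawn
        plt.close(fig)


class TestRepresentativeWell:
    def test_median_of_three_means(self):
        means = pd.Series({"A01": 400.0, "B01": 500.0, "C01": 900.0})
        assert representative_well(means) == "B01"

    def test_single_well_is_its_own_representative(self):
        assert representative_well(pd.Series({"A01": 123.0})) == "A01"

    def test_even_count_uses_lower_median(self):
        means = pd.Series({"A01": 100.0, "B01": 200.0, "C01": 300.0, "D01": 400.0})
        assert representative_well(means) == "B01"


@pytest.fixture(scope="module")
def dosed():
    from wormwell import SimulationConfig, generate_plate_set, join_design, select_models, edge_flag, set_flags

    config = SimulationConfig(
        plates=1, wells_per_plate=24,
        doses_um=(0.0, 7.81, 31.25, 125.0, 500.0, 2000.0),
        stage_mixture=(0.0, 0.0, 1.0, 0.0),
    )
    objects, design, _ = generate_plate_set(config, seed=9)
    joined = join_design(objects, design)
    return set_flags(edge_flag(select_models(joined), EdgeConfig(image_shape=(2048, 2048))))


class TestViewDose:
    def test_one_panel_per_dose_ascending(self, dosed):
        panels, lengths = view_dose(dosed, "paraquat", "N2")
        assert len(panels.axes) == 6
        titles = [ax.get_title() for ax in panels.axes]
        assert titles[0].startswith("0 ") and titles[-1].startswith("2000 ")
        plt.close(panels), plt.close(lengths)

    def test_no_match_raises(self, dosed):
        with pytest.raises(ValidationError, match="no wells match"):
            view_dose(dosed, "aldicarb", "N2")

    def test_missing_design_columns_raise(self, flagged_small_sim):
        with pytest.raises(ValidationError, match="design column"):
            view_dose(flagged_small_sim, "paraquat", "N2")
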