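"""Plate, well and dose-response views.

Three plot families for exploring 96-well worm phenotype data:

* :func:`view_plate` — an 8 x 12 heatmap of mean animal length per well,
  exportable as PNG (matplotlib) or as a self-contained interactive HTML
  file (an SVG grid with native hover tooltips reporting well id, object
  count and mean length; all data is embedded in the file).
* :func:`view_well` — objects of one well drawn at their centroid pixel
  coordinates over the brightfield image (16-bit TIFF, contrast-stretched
  to the 1st-99th intensity percentiles) or over a blank circle when no
  image is available, colored by object class, with the even-illumination
  radius in red and an optional side boxplot of lengths.
* :func:`view_dose` — one representative well per concentration of a
  drug/strain combination (the well whose mean length is the median of
  that dose's well means), plus a companion per-dose length distribution.

Markers sit exactly at centroid coordinates (no jitter) so overlays can be
checked against the table.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps, colors

from .errors import ValidationError
from .flags import EdgeConfig

ROWS = "ABCDEFGH"
COLS = range(1, 13)
ALL_WELLS = [f"{r}{c:02d}" for r in ROWS for c in COLS]

#: Marker colors by object class; model classes cycle through tab10.
_FLAG_COLORS = {"cluster": "#ff7f0e", "well_edge": "#d62728", "outlier": "#9467bd"}


def _object_class(row: pd.Series) -> str:
    """Class label used for marker coloring: flags outrank the model label."""
    if row.get("flag_outlier", False):
        return "outlier"
    if row.get("well_edge_flag", False):
        return "well_edge"
    if row.get("cluster_flag", False):
        return "cluster"
    return str(row.get("model_select", row.get("model_name", "object")))


@dataclass
class PlateFigure:
    """8 x 12 grid of per-well mean length with hover payloads.

    ``cells`` maps every well id A01..H12 to ``(n, mean_length)`` or to
    ``None`` for wells absent from the summary.
    """

    plate: str
    cells: dict[str, tuple[int, float] | None]

    def __post_init__(self) -> None:
        missing = set(ALL_WELLS) - set(self.cells)
        for w in missing:
            self.cells[w] = None

    def _color_scale(self):
        vals = [v[1] for v in self.cells.values() if v is not None]
        vmin, vmax = (min(vals), max(vals)) if vals else (0.0, 1.0)
        if vmin == vmax:
            vmax = vmin + 1.0
        return colormaps["viridis"], colors.Normalize(vmin, vmax)

    def to_png(self, path: str | PathLike) -> None:
        """Render the plate as a static matplotlib heatmap."""
        grid = np.full((8, 12), np.nan)
        for w, v in self.cells.items():
            if v is not None:
                grid[ROWS.index(w[0]), int(w[1:]) - 1] = v[1]
        fig, ax = plt.subplots(figsize=(8, 5))
        cmap = colormaps["viridis"].copy()
        cmap.set_bad("#eeeeee")
        im = ax.imshow(grid, cmap=cmap, aspect="auto")
        ax.set_xticks(range(12), [str(c) for c in COLS])
        ax.set_yticks(range(8), list(ROWS))
        ax.set_title(f"Plate {self.plate}: mean animal length (µm)")
        fig.colorbar(im, ax=ax, label="mean length (µm)")
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)

    def to_html(self, path: str | PathLike) -> None:
        """Write a self-contained interactive SVG/HTML plate view.

        Hovering a well shows its id, object count and mean length via the
        browser-native SVG tooltip; the numbers are embedded in the file.
        """
        cmap, norm = self._color_scale()
        cell, pad = 54, 36
        width, height = pad + 12 * cell + 10, pad + 8 * cell + 10
        parts = [
            "<!DOCTYPE html><html><head><meta charset='utf-8'>",
            f"<title>Plate {html.escape(self.plate)}</title></head><body>",
            f"<h2>Plate {html.escape(self.plate)} — mean animal length (&#181;m)</h2>",
            f"<svg width='{width}' height='{height}' font-family='sans-serif' font-size='12'>",
        ]
        for j, c in enumerate(COLS):
            parts.append(f"<text x='{pad + j * cell + cell / 2}' y='{pad - 10}' text-anchor='middle'>{c}</text>")
        for i, r in enumerate(ROWS):
            parts.append(f"<text x='{pad - 14}' y='{pad + i * cell + cell / 2 + 4}' text-anchor='middle'>{r}</text>")
        for well in ALL_WELLS:
            i, j = ROWS.index(well[0]), int(well[1:]) - 1
            x, y = pad + j * cell, pad + i * cell
            v = self.cells[well]
            if v is None:
                fill, tip = "#eeeeee", f"{well}: no data"
            else:
                n, mean = v
                fill = colors.to_hex(cmap(norm(mean)))
                tip = f"{well}: n={n}, mean={mean:.1f} µm"
            parts.append(
                f"<rect x='{x}' y='{y}' width='{cell - 4}' height='{cell - 4}' rx='6' "
                f"fill='{fill}' stroke='#666'><title>{html.escape(tip)}</title></rect>"
            )
        parts.append("</svg></body></html>")
        Path(path).write_text("\n".join(parts))


def view_plate(summary: pd.DataFrame, plate: str) -> PlateFigure:
    """Build the plate heatmap from a per-well summary (raw or processed)."""
    for col in ("Metadata_Plate", "Metadata_Well", "mean_length", "n"):
        if col not in summary.columns:
            raise ValidationError(f"summary table lacks column {col!r}")
    sub = summary[summary["Metadata_Plate"] == plate]
    if sub.empty:
        raise ValidationError(f"plate {plate!r} absent from summary")
    cells: dict[str, tuple[int, float] | None] = {
        row.Metadata_Well: (int(row.n), float(row.mean_length))
        for row in sub.itertuples(index=False)
    }
    return PlateFigure(plate=plate, cells=cells)


def _load_image(path: str | PathLike) -> np.ndarray:
    """Read a 16-bit TIFF and contrast-stretch to the 1st-99th percentiles."""
    import tifffile

    try:
        img = tifffile.imread(path)
    except (FileNotFoundError, OSError, ValueError) as exc:
        raise ValidationError(f"cannot read well image {path}: {exc}") from exc
    img = img.astype(float)
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        hi = lo + 1
    return np.clip((img - lo) / (hi - lo), 0, 1)


def _draw_well_axis(ax, sub: pd.DataFrame, image, edge: EdgeConfig, extent: float) -> None:
    if image is not None:
        ax.imshow(image, cmap="gray", vmin=0, vmax=1)
        cx, cy = (
            edge.resolved_center()
            if (edge.center or edge.image_shape)
            else (image.shape[1] / 2.0, image.shape[0] / 2.0)
        )
    else:
        cx = cy = extent / 2.0
        ax.add_patch(plt.Circle((cx, cy), extent / 2.0, fill=False, color="#999"))
        ax.set_xlim(0, extent)
        ax.set_ylim(extent, 0)  # image convention: y grows downward
        ax.set_aspect("equal")
    ax.add_patch(plt.Circle((cx, cy), edge.radius, fill=False, color="red", lw=1.5))
    classes = sub.apply(_object_class, axis=1) if len(sub) else pd.Series(dtype=object)
    palette = dict(_FLAG_COLORS)
    tab = colormaps["tab10"]
    for i, cls in enumerate(c for c in pd.unique(classes) if c not in palette):
        palette[cls] = colors.to_hex(tab(i % 10))
    for cls in pd.unique(classes):
        pts = sub[classes == cls]
        ax.scatter(pts["centroid_x"], pts["centroid_y"], s=36, facecolors="none",
                   edgecolors=palette[cls], label=str(cls), linewidths=1.5)
    ax.set_xticks([])
    ax.set_yticks([])


def view_well(
    objects: pd.DataFrame,
    plate: str,
    well: str,
    image_path: str | PathLike | None = None,
    boxplot: bool = True,
    edge: EdgeConfig | None = None,
):
    """Plot one well's objects at their centroids, colored by class.

    Works on the flagged (raw) or processed table; pass ``image_path`` to
    draw over the brightfield TIFF, else a blank circle of the configured
    radius is used.  Returns the matplotlib figure.
    """
    edge = edge or EdgeConfig()
    sub = objects[(objects["Metadata_Plate"] == plate) & (objects["Metadata_Well"] == well)]
    if sub.empty:
        raise ValidationError(f"well ({plate}, {well}) absent from table")
    image = _load_image(image_path) if image_path is not None else None
    extent = image.shape[0] if image is not None else 2 * edge.radius * 1.2

    ncols = 2 if boxplot else 1
    fig, axes = plt.subplots(1, ncols, figsize=(6 * ncols, 6),
                             gridspec_kw={"width_ratios": [3, 1]} if boxplot else None)
    ax = axes[0] if boxplot else axes
    _draw_well_axis(ax, sub, image, edge, extent)
    ax.legend(loc="upper left", bbox_to_anchor=(0, -0.02), ncol=3, fontsize=8, frameon=False)
    ax.set_title(f"{plate} {well} ({len(sub)} objects)")
    if boxplot:
        axes[1].boxplot(sub["worm_length"], widths=0.5)
        axes[1].scatter(np.ones(len(sub)), sub["worm_length"], s=12, alpha=0.6)
        axes[1].set_ylabel("worm length (µm)")
        axes[1].set_xticks([])
    fig.tight_layout()
    return fig


def representative_well(well_means: pd.Series) -> str:
    """The well whose mean is the median of the given well means.

    With an even number of wells the lower median is used so that the
    returned well always exists in the data.
    """
    if well_means.empty:
        raise ValidationError("no wells to choose a representative from")
    order = well_means.sort_values(kind="mergesort")
    return order.index[(len(order) - 1) // 2]


def view_dose(
    objects: pd.DataFrame,
    drug: str,
    strain: str,
    image_dir: str | PathLike | None = None,
    edge: EdgeConfig | None = None,
):
    """Dose panels for one drug/strain: representative well per concentration.

    ``objects`` must carry the design columns ``drug``, ``strain`` and
    ``concentration_um``.  Returns ``(panel_fig, length_fig)``: one well
    panel per concentration in ascending order, and a companion boxplot of
    length distributions per dose.  Well images are located through the
    ``Image_PathName_RawBF``/``Image_FileName_RawBF`` columns; pass
    ``image_dir`` to remap stale paths, or images are skipped when absent.
    """
    edge = edge or EdgeConfig()
    for col in ("drug", "strain", "concentration_um"):
        if col not in objects.columns:
            raise ValidationError(f"design column {col!r} missing; join a design file first")
    sub = objects[(objects["drug"] == drug) & (objects["strain"] == strain)]
    if sub.empty:
        raise ValidationError(f"no wells match drug={drug!r}, strain={strain!r}")
    doses = sorted(sub["concentration_um"].unique())

    panel_fig, axes = plt.subplots(1, len(doses), figsize=(3.2 * len(doses), 3.6), squeeze=False)
    per_dose_lengths = []
    for ax, dose in zip(axes[0], doses):
        at_dose = sub[sub["concentration_um"] == dose]
        means = at_dose.groupby(["Metadata_Plate", "Metadata_Well"])["worm_length"].mean()
        plate, well = representative_well(means)
        shown = at_dose[(at_dose["Metadata_Plate"] == plate) & (at_dose["Metadata_Well"] == well)]
        image = None
        fname = shown["Image_FileName_RawBF"].iloc[0]
        base = Path(image_dir) if image_dir else Path(shown["Image_PathName_RawBF"].iloc[0])
        if (base / fname).exists():
            image = _load_image(base / fname)
        extent = image.shape[0] if image is not None else 2 * edge.radius * 1.2
        _draw_well_axis(ax, shown, image, edge, extent)
        ax.set_title(f"{dose:g} µM\n{plate} {well}", fontsize=9)
        per_dose_lengths.append(at_dose["worm_length"].to_numpy())
    panel_fig.suptitle(f"{strain} · {drug}: representative wells by dose")
    panel_fig.tight_layout()

    length_fig, lax = plt.subplots(figsize=(1.2 * len(doses) + 2, 4))
    lax.boxplot(per_dose_lengths, tick_labels=[f"{d:g}" for d in doses])
    lax.set_xlabel(f"{drug} concentration (µM)")
    lax.set_ylabel("worm length (µm)")
    lax.set_title(f"{strain}: length by dose")
    length_fig.tight_layout()
    return panel_fig, length_fig
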