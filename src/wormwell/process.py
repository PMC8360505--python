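"""Pruning, summarization and the one-call pipeline wrapper.

After flagging, objects carrying cluster / well-edge / outlier flags are
dropped (configurably) and animal length is summarized per experimental
unit — per well by default, or by any design columns.  Results travel as a
:class:`ProcessedBundle` of four elements: the raw (flagged) table, the
processed (pruned) table, and per-group summaries of both.

:func:`xpress` chains the whole pipeline — read, join design, rank and
select models, edge flag, outlier flag, prune, summarize — with defaults
that can be overridden per step.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .flags import FLAG_COLUMNS, EdgeConfig, OutlierConfig, edge_flag, set_flags
from .io import join_design, read_design, read_object_data
from .models import rank_models_by_frequency, select_models

DEFAULT_GROUP_BY = ("Metadata_Plate", "Metadata_Well")
DEFAULT_DROP_FLAGS = ("cluster", "well_edge", "outlier")
SUMMARY_QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)


def prune(objects: pd.DataFrame, drop_flags: Sequence[str] = DEFAULT_DROP_FLAGS) -> pd.DataFrame:
    """Remove rows carrying any flag named in ``drop_flags``.

    By default all three flag families are dropped.  Flags the user chose
    to retain upstream simply stay in the processed output.
    """
    unknown = set(drop_flags) - set(FLAG_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown flag names: {sorted(unknown)}")
    mask = pd.Series(False, index=objects.index)
    for fam in drop_flags:
        col = FLAG_COLUMNS[fam]
        if col not in objects.columns:
            raise ValidationError(f"flag column {col!r} missing; run flagging first")
        mask |= objects[col].astype(bool)
    return objects.loc[~mask].copy()


def summarize(
    objects: pd.DataFrame,
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
    measurement: str = "worm_length",
    extra_measurements: Sequence[str] = (),
) -> pd.DataFrame:
    """Summarize a measurement per group (per well by default).

    For every group the output reports ``n``, mean, sample variance
    (missing when n = 1), min, max and the 10/25/50/75/90% quantiles of the
    measurement.  ``extra_measurements`` names further columns summarized
    identically with a column-name prefix.  Groups with zero rows do not
    appear.
    """
    group_by = list(group_by)
    if not group_by:
        raise ValidationError("group_by must name at least one column")
    missing = [c for c in group_by + [measurement, *extra_measurements] if c not in objects.columns]
    if missing:
        raise ValidationError(f"columns not in table: {missing}")

    def _stats(values: pd.Series, names: dict[str, str]) -> dict[str, float]:
        arr = values.to_numpy(dtype=float)
        out = {
            names["mean"]: arr.mean(),
            names["var"]: arr.var(ddof=1) if len(arr) > 1 else np.nan,
            names["min"]: arr.min(),
            names["max"]: arr.max(),
        }
        for p, q in zip(SUMMARY_QUANTILES, np.quantile(arr, SUMMARY_QUANTILES)):
            out[f"{names['q']}{int(p * 100)}"] = q
        return out

    primary_names = {"mean": "mean_length", "var": "var_length",
                     "min": "min_length", "max": "max_length", "q": "q"}
    rows = []
    for key, sub in objects.groupby(group_by, sort=True, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(group_by, key))
        row["n"] = len(sub)
        row.update(_stats(sub[measurement], primary_names))
        for extra in extra_measurements:
            names = {s: f"{extra}_{s}" for s in ("mean", "var", "min", "max")}
            names["q"] = f"{extra}_q"
            row.update(_stats(sub[extra], names))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ProcessedBundle:
    """Four-element pipeline result.

    ``raw_data`` is the selected + flagged table; ``processed_data`` the
    pruned one; the two summaries are per-group tables of each.
    """

    raw_data: pd.DataFrame
    processed_data: pd.DataFrame
    summarized_raw: pd.DataFrame
    summarized_processed: pd.DataFrame

    def __iter__(self):
        return iter((self.raw_data, self.processed_data, self.summarized_raw, self.summarized_processed))

    def __len__(self) -> int:
        return 4

    def write(self, outdir: str | PathLike, manifest_extra: dict | None = None) -> dict:
        """Write raw/processed/summary CSVs plus a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "raw.csv": self.raw_data,
            "processed.csv": self.processed_data,
            "summary_raw.csv": self.summarized_raw,
            "summary_processed.csv": self.summarized_processed,
        }
        for name, df in files.items():
            df.to_csv(outdir / name, index=False)
        manifest = {
            "row_counts": {name: len(df) for name, df in files.items()},
            "outputs": sorted(files),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        if manifest_extra:
            manifest.update(manifest_extra)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return manifest

    @classmethod
    def read(cls, outdir: str | PathLike) -> "ProcessedBundle":
        outdir = Path(outdir)
        return cls(
            raw_data=pd.read_csv(outdir / "raw.csv"),
            processed_data=pd.read_csv(outdir / "processed.csv"),
            summarized_raw=pd.read_csv(outdir / "summary_raw.csv"),
            summarized_processed=pd.read_csv(outdir / "summary_processed.csv"),
        )


def process_bundle(
    objects: pd.DataFrame,
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
    drop_flags: Sequence[str] = DEFAULT_DROP_FLAGS,
    extra_measurements: Sequence[str] = (),
) -> ProcessedBundle:
    """Assemble the four-element bundle from a fully flagged table."""
    processed = prune(objects, drop_flags)
    return ProcessedBundle(
        raw_data=objects.reset_index(drop=True),
        processed_data=processed.reset_index(drop=True),
        summarized_raw=summarize(objects, group_by, extra_measurements=extra_measurements),
        summarized_processed=summarize(processed, group_by, extra_measurements=extra_measurements)
        if len(processed)
        else pd.DataFrame(columns=list(group_by)),
    )


def xpress(
    data_paths: Iterable[str | PathLike] | str | PathLike,
    design_path: str | PathLike | None = None,
    edge: EdgeConfig | None = None,
    outlier: OutlierConfig | None = None,
    group_by: Sequence[str] = DEFAULT_GROUP_BY,
    drop_flags: Sequence[str] = DEFAULT_DROP_FLAGS,
    column_map=None,
) -> ProcessedBundle:
    """Run the whole pipeline with defaults, honoring any overridden step.

    Equivalent to read_object_data -> join_design -> rank/select models ->
    edge_flag -> set_flags -> process_bundle.  With no ``edge`` config the
    well center defaults to the middle of a 2048 x 2048 px image — the
    geometry the synthetic generator uses; supply an explicit
    :class:`EdgeConfig` for other cameras.
    """
    if isinstance(data_paths, (str, PathLike)):
        data_paths = [data_paths]
    objects = read_object_data(data_paths, column_map=column_map)
    if design_path is not None:
        objects = join_design(objects, read_design(design_path))
    ranking = rank_models_by_frequency(objects)
    selected = select_models(objects, ranking)
    edge = edge or EdgeConfig(image_shape=(2048, 2048))
    flagged = set_flags(edge_flag(selected, edge), outlier)
    return process_bundle(flagged, group_by=group_by, drop_flags=drop_flags)
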