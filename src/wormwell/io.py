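"""Reading CellProfiler per-object exports and experimental design files.

CellProfiler's WormToolbox exports one row per *model object* — one fit of a
worm shape model (e.g. L1, L2L3, L4, Adult) to a detected animal (the
"primary object").  Because several models are run per image ("soft
matching"), a single animal usually produces several rows.  This module
reads those CSV exports into a single canonical :class:`pandas.DataFrame`
with validated metadata columns, and left-joins an optional design table
mapping (plate, well) to experimental conditions.

Canonical columns
-----------------
Metadata columns keep their CellProfiler names (``Metadata_Plate``,
``Metadata_Well``, ``Metadata_Date``, ``Metadata_Experiment``,
``Metadata_Magnification``, ``Image_FileName_RawBF``,
``Image_PathName_RawBF``).  Measurement columns are normalized to

* ``primary_object_id`` — integer id of the detected animal within its well
* ``model_name``       — worm-model label of this fit
* ``centroid_x``, ``centroid_y`` — object centroid in pixels (origin top-left)
* ``worm_length``      — animal length in micrometres, strictly positive

Unrecognized measurement columns are carried through untouched.
"""

from __future__ import annotations

import logging
import re
from os import PathLike
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FilenameParseError, ValidationError

logger = logging.getLogger(__name__)

#: Metadata columns every object table must carry.
REQUIRED_METADATA = ("Metadata_Plate", "Metadata_Well")

#: Measurement columns of the canonical table.
MEASUREMENT_COLUMNS = (
    "primary_object_id",
    "model_name",
    "centroid_x",
    "centroid_y",
    "worm_length",
)

#: Default aliases accepted for each canonical measurement column.  The
#: exact export names vary with how models were named inside CellProfiler,
#: so the reader accepts a user-supplied ``column_map`` overriding these.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "primary_object_id": ("primary_object_id", "Parent_WormObjects", "ObjectNumber"),
    "model_name": ("model_name", "model", "Model"),
    "centroid_x": ("centroid_x", "AreaShape_Center_X", "Location_Center_X"),
    "centroid_y": ("centroid_y", "AreaShape_Center_Y", "Location_Center_Y"),
    "worm_length": ("worm_length", "Worm_Length", "AreaShape_Length"),
}

_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")
_FILENAME_RE = re.compile(
    r"^(?P<date>[^-]+)-(?P<experiment>[^-]+)-(?P<plate>[^-]+)-"
    r"(?P<magnification>[^_]+)_(?P<well>[A-Ha-h]\d{1,2})\.(?P<ext>[A-Za-z0-9]+)$"
)
_WIDE_LENGTH_RE = re.compile(r"^Worm_Length_(?P<model>.+)$")


def normalize_well(well: str) -> str:
    """Normalize a well token to row letter + zero-padded column ("C3" -> "C03").

    Raises :class:`ValidationError` if the token is not a well of an 8x12
    (A-H x 01-12) plate.  Idempotent.
    """
    token = str(well).strip().upper()
    m = re.match(r"^([A-H])0*(\d{1,2})$", token)
    if m:
        token = f"{m.group(1)}{int(m.group(2)):02d}"
    if not _WELL_RE.match(token):
        raise ValidationError(f"not a valid 96-well identifier: {well!r}")
    return token


def parse_filename_metadata(filename: str) -> dict[str, str]:
    """Parse an image filename into its five metadata tokens.

    Filenames follow ``{date}-{experiment}-{plate}-{magnification}_{well}.{ext}``,
    e.g. ``20191119-growth-p05-m2X_C03.TIF``.  The well token is normalized
    to zero-padded form.

    Returns a dict with keys ``date``, ``experiment``, ``plate``,
    ``magnification``, ``well``.  Raises :class:`FilenameParseError` naming
    the offending filename when the pattern does not match.
    """
    if not filename:
        raise FilenameParseError("empty filename")
    name = Path(str(filename)).name
    m = _FILENAME_RE.match(name)
    if m is None:
        raise FilenameParseError(
            f"filename {filename!r} does not match "
            "{date}-{experiment}-{plate}-{magnification}_{well}.{ext}"
        )
    return {
        "date": m.group("date"),
        "experiment": m.group("experiment"),
        "plate": m.group("plate"),
        "magnification": m.group("magnification"),
        "well": normalize_well(m.group("well")),
    }


def _resolve_measurement_columns(
    df: pd.DataFrame, column_map: Mapping[str, Sequence[str] | str] | None
) -> pd.DataFrame:
    """Rename aliased measurement columns to their canonical names.

    If no model-name column exists but wide per-model length columns
    (``Worm_Length_<Model>``) do, the table is melted to long form with one
    row per model fit; the chosen source is logged.
    """
    aliases = {k: tuple(v) if not isinstance(v, str) else (v,) for k, v in DEFAULT_COLUMN_MAP.items()}
    if column_map:
        for canon, src in column_map.items():
            if canon not in aliases:
                raise ValidationError(f"unknown canonical column in column_map: {canon!r}")
            aliases[canon] = (src,) if isinstance(src, str) else tuple(src)

    renames: dict[str, str] = {}
    for canon, candidates in aliases.items():
        for cand in candidates:
            if cand in df.columns:
                if cand != canon:
                    renames[cand] = canon
                break
    df = df.rename(columns=renames)

    if "model_name" not in df.columns:
        wide = {c: _WIDE_LENGTH_RE.match(c) for c in df.columns}
        wide_cols = {c: m.group("model") for c, m in wide.items() if m}
        if wide_cols:
            logger.info("model names parsed from wide columns: %s", sorted(wide_cols.values()))
            id_cols = [c for c in df.columns if c not in wide_cols]
            df = df.melt(
                id_vars=id_cols,
                value_vars=list(wide_cols),
                var_name="model_name",
                value_name="worm_length",
            )
            df["model_name"] = df["model_name"].map(wide_cols)
            df = df.dropna(subset=["worm_length"]).reset_index(drop=True)
        else:
            logger.info("model names taken from 'model_name' column")
    return df


def _validate_objects(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    missing += [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"object table is missing required columns: {missing}")
    df = df.copy()
    # metadata tokens are labels, not numbers, even when they look numeric
    for col in ("Metadata_Plate", "Metadata_Date", "Metadata_Experiment", "Metadata_Magnification"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    df["Metadata_Well"] = df["Metadata_Well"].map(normalize_well)
    df["primary_object_id"] = df["primary_object_id"].astype(int)
    for col in ("centroid_x", "centroid_y", "worm_length"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["worm_length"] <= 0).any():
        bad = int((df["worm_length"] <= 0).sum())
        raise ValidationError(f"{bad} rows have non-positive worm_length")
    if (df[["centroid_x", "centroid_y"]] < 0).any().any():
        raise ValidationError("negative centroid coordinates")
    return df


def read_object_data(
    paths: Iterable[str | PathLike],
    column_map: Mapping[str, Sequence[str] | str] | None = None,
) -> pd.DataFrame:
    """Read one or more CellProfiler per-object CSV exports into one table.

    Files are concatenated in input order, measurement columns are renamed
    to canonical form (see :data:`DEFAULT_COLUMN_MAP`; override with
    ``column_map``), well identifiers are zero-padded, and the result is
    validated.  Extra columns pass through untouched.

    Raises :class:`ValidationError` for an empty path list or a file missing
    required columns.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("no input files given")
    frames = []
    for p in paths:
        if not p.exists():
            raise ValidationError(f"input file does not exist: {p}")
        frames.append(pd.read_csv(p))
    df = pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]
    df = _resolve_measurement_columns(df, column_map)
    return _validate_objects(df)


def read_design(path: str | PathLike) -> pd.DataFrame:
    """Read a design file mapping (plate, well) to experimental conditions."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise ValidationError(f"design file is missing required columns: {missing}")
    df = df.copy()
    df["Metadata_Well"] = df["Metadata_Well"].map(normalize_well)
    return df


def join_design(objects: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Left-join design columns onto the object table by (plate, well).

    Object rows without a design match keep missing values in the design
    columns; the object row count never changes.  A duplicated
    (plate, well) pair in the design is an error (the join would be
    ambiguous).
    """
    keys = list(REQUIRED_METADATA)
    for t, name in ((objects, "object"), (design, "design")):
        missing = [c for c in keys if c not in t.columns]
        if missing:
            raise ValidationError(f"{name} table is missing join columns: {missing}")
    dup = design.duplicated(subset=keys)
    if dup.any():
        pairs = design.loc[dup, keys].drop_duplicates().itertuples(index=False)
        raise ValidationError(
            "duplicate (plate, well) in design file: "
            + ", ".join(f"({p}, {w})" for p, w in pairs)
        )
    merged = objects.merge(design, on=keys, how="left", sort=False)
    assert len(merged) == len(objects)
    return merged
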