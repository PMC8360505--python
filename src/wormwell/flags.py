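"""Well-edge and outlier flagging of selected objects.

Two QC flags are added to the one-row-per-animal table produced by model
selection:

* ``well_edge_flag`` — the object's centroid lies beyond the radius of even
  illumination from the image center.  Near the periphery of a circular
  well, background correction degrades and segmentation gets noisy, so
  measurements there are suspect.  The default radius is 825 px.
* ``flag_outlier`` — the object's length falls outside Tukey's fences
  [Q1 - k*IQR, Q3 + k*IQR] computed over its well.  By default the fences
  are computed after excluding objects already flagged as clusters or edge
  cases, so that corrupted measurements do not distort the fences; which
  flags to exclude is configurable.

Quartiles use linear interpolation between order statistics at position
(n-1)*p — the dominant convention in the scientific Python ecosystem —
and all comparisons are strict, so boundary points are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

WELL_KEYS = ("Metadata_Plate", "Metadata_Well")

#: Flag-family name -> column carrying it.
FLAG_COLUMNS = {
    "cluster": "cluster_flag",
    "well_edge": "well_edge_flag",
    "outlier": "flag_outlier",
}

DEFAULT_EDGE_RADIUS_PX = 825.0


@dataclass(frozen=True)
class EdgeConfig:
    """Geometry of the even-illumination disc.

    ``radius`` defaults to 825 px.  The center is taken from ``center``
    when given, else derived as half of ``image_shape`` (width, height);
    if neither is available the configuration refuses to guess and raises.
    """

    radius: float = DEFAULT_EDGE_RADIUS_PX
    center: tuple[float, float] | None = None
    image_shape: tuple[int, int] | None = None  # (width, height) in px

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"edge radius must be positive, got {self.radius}")
        if self.center is not None and (self.center[0] < 0 or self.center[1] < 0):
            raise ValidationError("edge center coordinates must be non-negative")

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return (float(self.center[0]), float(self.center[1]))
        if self.image_shape is not None:
            return (self.image_shape[0] / 2.0, self.image_shape[1] / 2.0)
        raise ValidationError(
            "well center unknown: supply EdgeConfig.center or EdgeConfig.image_shape"
        )


@dataclass(frozen=True)
class OutlierConfig:
    """Tukey's-fences configuration for within-well outlier flagging."""

    k: float = 1.5
    min_n: int = 3
    exclude_flags: tuple[str, ...] = ("cluster", "well_edge")

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValidationError("Tukey multiplier k must be >= 0")
        if self.min_n < 2:
            raise ValidationError("min_n must be >= 2")
        unknown = set(self.exclude_flags) - {"cluster", "well_edge"}
        if unknown:
            raise ValidationError(f"unknown flag names in exclude_flags: {sorted(unknown)}")


@dataclass(frozen=True)
class Fences:
    """Tukey's fences of one sample of lengths."""

    q1: float
    q3: float
    k: float

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - self.k * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + self.k * self.iqr

    def outside(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values strictly outside the fences."""
        values = np.asarray(values, dtype=float)
        return (values < self.lower) | (values > self.upper)


def tukey_fences(values, k: float = 1.5) -> Fences:
    """Compute Tukey's fences of a sample.

    Quartiles are linearly interpolated order statistics (position
    (n-1)*p).  At least two finite values are required.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValidationError(f"need >= 2 finite values for fences, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    return Fences(q1=float(q1), q3=float(q3), k=float(k))


def edge_flag(objects: pd.DataFrame, config: EdgeConfig | None = None) -> pd.DataFrame:
    """Flag objects whose centroid lies strictly beyond the illumination radius.

    Adds a boolean ``well_edge_flag`` column; all rows are retained.
    """
    config = config or EdgeConfig()
    cx, cy = config.resolved_center()
    out = objects.copy()
    dist = np.hypot(out["centroid_x"] - cx, out["centroid_y"] - cy)
    out["well_edge_flag"] = (dist > config.radius).to_numpy()
    return out


def set_flags(objects: pd.DataFrame, config: OutlierConfig | None = None) -> pd.DataFrame:
    """Flag within-well length outliers by Tukey's fences.

    Per well, fences are computed over ``worm_length`` of rows not carrying
    any flag named in ``config.exclude_flags``; only those eligible rows
    can receive ``flag_outlier`` (already-flagged rows keep ``False``).
    Wells with fewer than ``config.min_n`` eligible rows are left entirely
    unflagged.
    """
    config = config or OutlierConfig()
    for fam in ("cluster", "well_edge"):
        col = FLAG_COLUMNS[fam]
        if col not in objects.columns:
            raise ValidationError(f"set_flags requires the {col!r} column; run the earlier steps")

    out = objects.copy()
    eligible = pd.Series(True, index=out.index)
    for fam in config.exclude_flags:
        eligible &= ~out[FLAG_COLUMNS[fam]].astype(bool)

    flag = np.zeros(len(out), dtype=bool)
    for _, idx in out.groupby(list(WELL_KEYS), sort=False).groups.items():
        elig_idx = [i for i in idx if eligible[i]]
        if len(elig_idx) < config.min_n:
            continue
        fences = tukey_fences(out.loc[elig_idx, "worm_length"], k=config.k)
        pos = out.index.get_indexer(elig_idx)
        flag[pos] = fences.outside(out.loc[elig_idx, "worm_length"].to_numpy())
    out["flag_outlier"] = flag
    return out
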