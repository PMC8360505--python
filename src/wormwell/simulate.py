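"""Synthetic WormToolbox-style plates with ground truth.

The generator emulates the per-object output of CellProfiler's WormToolbox
on a 96-well *C. elegans* assay, so that every pipeline stage is testable
without real images:

* **soft matching** — each simulated animal emits a model-object row for
  its own developmental stage plus 1-3 rows for every smaller worm model
  (partial fits covering parts of the body), reproducing the one-to-many
  model/animal structure;
* **clusters** — a configurable fraction of animals (overlapping worms)
  have their largest model fitted 2-3 times with distorted lengths;
* **edge objects** — a configurable fraction of animals sit beyond the
  even-illumination radius, with extra measurement noise;
* **debris** — non-animal objects (bacteria clumps, shadows) appear as a
  single short fit of the smallest model.

Wells are bleach-synchronized: each well holds animals of one nominal
developmental stage (drawn from ``stage_mixture``), as in a real
high-throughput growth assay.  Per-stage true lengths are normal draws;
the default stage distributions (L1 ~ N(250, 25), L2L3 ~ N(450, 50),
L4 ~ N(700, 60), Adult ~ N(1000, 80) micrometres) are this package's own
fixtures and are configurable.

A truth table (one row per simulated primary object, joinable by plate /
well / primary_object_id) records class, stage, true length and
constructed edge / cluster / outlier labels, and
:func:`evaluate_against_truth` scores pipeline output against it.

Reproducibility: one RNG stream per plate is spawned from the master seed,
so a fixed seed yields byte-identical tables regardless of how plates are
iterated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .process import ProcessedBundle

STAGE_ORDER = ("L1", "L2L3", "L4", "Adult")

DEFAULT_STAGE_LENGTHS: dict[str, tuple[float, float]] = {
    "L1": (250.0, 25.0),
    "L2L3": (450.0, 50.0),
    "L4": (700.0, 60.0),
    "Adult": (1000.0, 80.0),
}

TRUTH_KEYS = ("Metadata_Plate", "Metadata_Well", "primary_object_id")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated experiment.

    Fractions are per animal; ``debris_rate`` is the expected number of
    debris objects per animal (Poisson per well).  ``stage_mixture`` gives
    the probability that a well is synchronized to each stage and must sum
    to 1.
    """

    plates: int = 1
    wells_per_plate: int = 96
    animals_per_well: int = 30
    stage_mixture: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    stage_lengths: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_LENGTHS)
    )
    image_size_px: int = 2048
    well_radius_px: float = 1000.0
    edge_radius_px: float = 825.0
    edge_fraction: float = 0.1
    cluster_fraction: float = 0.05
    debris_rate: float = 0.1
    debris_length: tuple[float, float] = (80.0, 20.0)
    measurement_cv: float = 0.02
    image_pathname: str = "raw_images"
    date: str = "20210601"
    experiment: str = "sim"
    magnification: str = "m2X"
    doses_um: tuple[float, ...] | None = None
    drug: str = "paraquat"
    strain: str = "N2"

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.stage_mixture), 1.0):
            raise ValidationError("stage_mixture must sum to 1")
        for name, frac in (
            ("edge_fraction", self.edge_fraction),
            ("cluster_fraction", self.cluster_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {frac}")
        if self.debris_rate < 0:
            raise ValidationError("debris_rate must be >= 0")
        if len(self.stage_mixture) != len(STAGE_ORDER):
            raise ValidationError(
                f"stage_mixture needs {len(STAGE_ORDER)} entries (one per stage)"
            )
        if not self.edge_radius_px < self.well_radius_px:
            raise ValidationError("edge_radius_px must be smaller than well_radius_px")


def _well_ids(n: int) -> list[str]:
    ids = [f"{r}{c:02d}" for r in "ABCDEFGH" for c in range(1, 13)]
    if n > len(ids):
        raise ValidationError(f"at most 96 wells per plate, got {n}")
    return ids[:n]


def _dose_effect(concentration: float, ec50: float = 250.0, max_inhibition: float = 0.5) -> float:
    """Fractional growth retained under a drug dose (simple Emax curve)."""
    return 1.0 - max_inhibition * concentration / (concentration + ec50)


def _position(rng: np.random.Generator, r_min: float, r_max: float, center: float) -> tuple[float, float]:
    """Uniform point in the annulus (or disc when r_min = 0) around the image center."""
    r = np.sqrt(rng.uniform(r_min**2, r_max**2))
    theta = rng.uniform(0, 2 * np.pi)
    return center + r * np.cos(theta), center + r * np.sin(theta)


def generate_plate_set(
    config: SimulationConfig | None = None,
    seed: int = 0,
    outdir: str | PathLike | None = None,
    images: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate per-object tables, a design table and a truth table.

    Returns ``(objects, design, truth)``.  When ``outdir`` is given the
    three tables are written there as ``objects.csv``, ``design.csv`` and
    ``truth.csv`` (and, with ``images=True``, one 16-bit TIFF per well).
    """
    config = config or SimulationConfig()
    children = np.random.SeedSequence(seed).spawn(config.plates)
    center = config.image_size_px / 2.0
    stage_means = {s: config.stage_lengths[s][0] for s in STAGE_ORDER}

    obj_rows: list[dict] = []
    truth_rows: list[dict] = []
    design_rows: list[dict] = []

    for p in range(config.plates):
        rng = np.random.default_rng(children[p])
        plate = f"p{p + 1:02d}"
        for w, well in enumerate(_well_ids(config.wells_per_plate)):
            fname = (
                f"{config.date}-{config.experiment}-{plate}-"
                f"{config.magnification}_{well}.TIF"
            )
            meta = {
                "Image_FileName_RawBF": fname,
                "Image_PathName_RawBF": config.image_pathname,
                "Metadata_Date": config.date,
                "Metadata_Experiment": config.experiment,
                "Metadata_Plate": plate,
                "Metadata_Magnification": config.magnification,
                "Metadata_Well": well,
            }
            conc = None
            if config.doses_um is not None:
                conc = config.doses_um[w % len(config.doses_um)]
            design_rows.append(
                {
                    "Metadata_Plate": plate,
                    "Metadata_Well": well,
                    "strain": config.strain,
                    "drug": config.drug if conc is not None else "none",
                    "concentration_um": conc if conc is not None else 0.0,
                }
            )
            stage_idx = rng.choice(len(STAGE_ORDER), p=config.stage_mixture)
            stage = STAGE_ORDER[stage_idx]
            mu, sd = config.stage_lengths[stage]
            growth = _dose_effect(conc) if conc else 1.0

            oid = 0
            for _ in range(config.animals_per_well):
                oid += 1
                true_len = max(50.0, rng.normal(mu * growth, sd * growth))
                is_edge = rng.random() < config.edge_fraction
                is_cluster = rng.random() < config.cluster_fraction
                if is_edge:
                    x, y = _position(rng, config.edge_radius_px + 5, config.well_radius_px, center)
                else:
                    x, y = _position(rng, 0.0, config.edge_radius_px - 5, center)

                def emit(model: str, length: float) -> None:
                    obj_rows.append(
                        {
                            **meta,
                            "primary_object_id": oid,
                            "model_name": model,
                            "centroid_x": x,
                            "centroid_y": y,
                            "worm_length": max(10.0, length),
                        }
                    )

                # partial fits of every smaller model (soft matching)
                for smaller in STAGE_ORDER[:stage_idx]:
                    for _ in range(int(rng.integers(1, 4))):
                        emit(smaller, true_len * rng.uniform(0.2, 0.7)
                             * stage_means[smaller] / stage_means[stage])
                noise = rng.normal(1.0, config.measurement_cv)
                if is_edge:
                    noise *= rng.uniform(0.5, 1.5)  # degraded segmentation at the rim
                if is_cluster:
                    for _ in range(int(rng.integers(2, 4))):
                        emit(stage, true_len * rng.uniform(0.5, 0.9) * noise)
                else:
                    emit(stage, true_len * noise)
                truth_rows.append(
                    {
                        "Metadata_Plate": plate,
                        "Metadata_Well": well,
                        "primary_object_id": oid,
                        "true_class": "animal",
                        "true_stage": stage,
                        "true_length_um": true_len,
                        "is_edge": is_edge,
                        "is_cluster": is_cluster,
                        "is_outlier": False,
                    }
                )

            for _ in range(rng.poisson(config.debris_rate * config.animals_per_well)):
                oid += 1
                x, y = _position(rng, 0.0, config.edge_radius_px - 5, center)
                d_mu, d_sd = config.debris_length
                length = max(10.0, rng.normal(d_mu, d_sd))
                obj_rows.append(
                    {
                        **meta,
                        "primary_object_id": oid,
                        "model_name": STAGE_ORDER[0],
                        "centroid_x": x,
                        "centroid_y": y,
                        "worm_length": length,
                    }
                )
                truth_rows.append(
                    {
                        "Metadata_Plate": plate,
                        "Metadata_Well": well,
                        "primary_object_id": oid,
                        "true_class": "debris",
                        "true_stage": "",
                        "true_length_um": length,
                        "is_edge": False,
                        "is_cluster": False,
                        "is_outlier": True,
                    }
                )

    objects = pd.DataFrame(obj_rows)
    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(truth_rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        objects.to_csv(outdir / "objects.csv", index=False)
        design.to_csv(outdir / "design.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
        if images:
            _render_well_images(objects, config, outdir)
    return objects, design, truth


def _render_well_images(objects: pd.DataFrame, config: SimulationConfig, outdir: Path) -> None:
    """Draw crude 16-bit brightfield analogs: bright vignetted well, dark worms.

    Visual fidelity only — dark elongated strokes at each object centroid on
    a bright circular well whose intensity falls off radially (the uneven
    illumination artifact that motivates edge flagging).
    """
    import zlib

    import tifffile

    n = config.image_size_px
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    c = n / 2.0
    r = np.hypot(xx - c, yy - c)
    base = np.where(r <= config.well_radius_px, 45000.0 * (1.0 - 0.5 * (r / config.well_radius_px) ** 2), 8000.0)
    for (fname, _), sub in objects.groupby(["Image_FileName_RawBF", "Metadata_Well"], sort=False):
        img = base.copy()
        rng = np.random.default_rng(zlib.crc32(fname.encode()))
        for row in sub.itertuples(index=False):
            # a short dark stroke, length scaled down to px, random direction
            L = min(row.worm_length / 3.0, 200.0)
            theta = rng.uniform(0, np.pi)
            t = np.linspace(-L / 2, L / 2, max(int(L), 2))
            px = np.clip(row.centroid_x + t * np.cos(theta), 0, n - 1).astype(int)
            py = np.clip(row.centroid_y + t * np.sin(theta), 0, n - 1).astype(int)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    img[np.clip(py + dy, 0, n - 1), np.clip(px + dx, 0, n - 1)] = 12000.0
        tifffile.imwrite(outdir / fname, img.astype(np.uint16))


@dataclass(frozen=True)
class FlagScore:
    """Precision/recall of one flag family against constructed truth."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


@dataclass
class EvaluationReport:
    """Pipeline-vs-truth scorecard.

    Flag precision/recall per family, per-well absolute/relative errors of
    the processed and raw mean lengths against the true animal mean, and
    model-selection accuracy on unflagged animals.
    """

    flag_scores: dict[str, FlagScore]
    well_errors: pd.DataFrame
    model_accuracy: float

    @property
    def fraction_wells_within(self) -> float:
        """Fraction of wells with processed mean within 5% of the true mean."""
        return float((self.well_errors["processed_rel_err"] <= 0.05).mean())

    @property
    def fraction_processed_closer(self) -> float:
        """Fraction of wells where the processed mean beats the raw mean."""
        e = self.well_errors
        return float((e["processed_abs_err"] < e["raw_abs_err"]).mean())

    def to_dict(self) -> dict:
        d: dict = {"model_selection_accuracy": self.model_accuracy}
        for fam, s in self.flag_scores.items():
            d[f"{fam}_precision"] = s.precision
            d[f"{fam}_recall"] = s.recall
        d["fraction_wells_within_5pct"] = self.fraction_wells_within
        d["fraction_processed_closer_than_raw"] = self.fraction_processed_closer
        d["n_wells"] = int(len(self.well_errors))
        return d


def evaluate_against_truth(bundle: ProcessedBundle, truth: pd.DataFrame) -> EvaluationReport:
    """Score a processed bundle against the simulator's ground truth.

    The bundle's raw table and the truth table must be in bijection on
    (plate, well, primary_object_id).
    """
    keys = list(TRUTH_KEYS)
    raw = bundle.raw_data
    merged = raw.merge(truth, on=keys, how="outer", indicator=True, suffixes=("", "_truth"))
    if (merged["_merge"] != "both").any():
        n_bad = int((merged["_merge"] != "both").sum())
        raise ValidationError(f"{n_bad} objects do not match between pipeline output and truth")

    pairs = {"cluster": "is_cluster", "well_edge": "is_edge", "outlier": "is_outlier"}
    pred_cols = {"cluster": "cluster_flag", "well_edge": "well_edge_flag", "outlier": "flag_outlier"}
    scores = {}
    for fam, truth_col in pairs.items():
        pred = merged[pred_cols[fam]].astype(bool)
        true = merged[truth_col].astype(bool)
        scores[fam] = FlagScore(
            tp=int((pred & true).sum()),
            fp=int((pred & ~true).sum()),
            fn=int((~pred & true).sum()),
        )

    animals = truth[truth["true_class"] == "animal"]
    true_means = animals.groupby(keys[:2])["true_length_um"].mean().rename("true_mean")
    well_keys = keys[:2]

    def _well_means(summary: pd.DataFrame, name: str) -> pd.Series:
        return summary.set_index(well_keys)["mean_length"].rename(name)

    errs = pd.concat(
        [
            true_means,
            _well_means(bundle.summarized_processed, "processed_mean"),
            _well_means(bundle.summarized_raw, "raw_mean"),
        ],
        axis=1,
    ).dropna(subset=["true_mean", "processed_mean"])
    errs["processed_abs_err"] = (errs["processed_mean"] - errs["true_mean"]).abs()
    errs["raw_abs_err"] = (errs["raw_mean"] - errs["true_mean"]).abs()
    errs["processed_rel_err"] = errs["processed_abs_err"] / errs["true_mean"]
    errs["raw_rel_err"] = errs["raw_abs_err"] / errs["true_mean"]

    clean = merged[
        (merged["true_class"] == "animal")
        & ~merged[["is_edge", "is_cluster", "is_outlier"]].any(axis=1)
    ]
    accuracy = float((clean["model_select"] == clean["true_stage"]).mean())
    return EvaluationReport(flag_scores=scores, well_errors=errs.reset_index(), model_accuracy=accuracy)
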