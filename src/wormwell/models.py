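"""Frequency-ranked worm-model selection.

Soft matching — running several worm shape models over the same image so
that animals of slightly different sizes are still detected — leaves a
one-to-many relationship between real animals (primary objects) and model
objects.  This module resolves it: worm models are ranked by how often they
occur in the whole dataset (the smallest model is fitted most often, since
it matches fragments of every larger animal; the largest is fitted least
often), and for every primary object the largest-ranked model present is
selected as the best fit.  If that selected model was fitted more than once
to the same primary object the animal is flagged as a *cluster* —
typically overlapping animals whose measurements are unreliable.

The output has exactly one row per (plate, well, primary object), carrying
``model_select`` and ``cluster_flag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

#: Grouping key identifying one real animal.
GROUP_KEYS = ("Metadata_Plate", "Metadata_Well", "primary_object_id")


@dataclass(frozen=True)
class ModelRanking:
    """Dataset-wide ordering of worm models from smallest to largest.

    ``table`` has one row per model with columns ``model_name``,
    ``frequency``, ``mean_length`` and ``rank``; rank 1 is the most
    frequent (smallest) model.  Exact frequency ties are broken by
    ascending mean worm length — length is the direct size measure for
    which frequency is only a proxy.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ranks = sorted(self.table["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError("ranks must be a permutation of 1..K")

    @property
    def models(self) -> list[str]:
        """Model names ordered smallest (rank 1) to largest."""
        return list(self.table.sort_values("rank")["model_name"])

    def rank_of(self, model: str) -> int:
        row = self.table.loc[self.table["model_name"] == model, "rank"]
        if row.empty:
            raise ValidationError(f"model {model!r} not present in ranking")
        return int(row.iloc[0])


def rank_models_by_frequency(objects: pd.DataFrame) -> ModelRanking:
    """Rank worm models by descending dataset frequency (rank 1 = most frequent).

    Frequency is counted over the whole table — all plates read together —
    and exact ties are broken by ascending mean ``worm_length``.
    """
    if objects is None or len(objects) == 0:
        raise ValidationError("cannot rank models of an empty table")
    stats = (
        objects.groupby("model_name", sort=False)
        .agg(frequency=("model_name", "size"), mean_length=("worm_length", "mean"))
        .reset_index()
    )
    stats = stats.sort_values(
        ["frequency", "mean_length", "model_name"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    stats["rank"] = stats.index + 1
    return ModelRanking(stats)


def select_models(objects: pd.DataFrame, ranking: ModelRanking | None = None) -> pd.DataFrame:
    """Pick one best-fitting model row per primary object and flag clusters.

    For each (plate, well, primary_object_id) group the largest-ranked
    model present is selected; ``cluster_flag`` is set when that model was
    fitted to the group more than once.  The representative row kept for a
    cluster is the selected model's instance with maximal ``worm_length``
    (the instance that best approximates the whole animal; cluster
    measurements are dropped downstream by default anyway).

    Parameters
    ----------
    objects
        Canonical object table (see :mod:`wormwell.io`).
    ranking
        Precomputed :class:`ModelRanking`; computed from ``objects`` when
        omitted.  Every model in ``objects`` must appear in it.

    Returns
    -------
    DataFrame with all input columns plus ``model_select`` and
    ``cluster_flag``, exactly one row per group.
    """
    if ranking is None:
        ranking = rank_models_by_frequency(objects)
    rank_map = dict(zip(ranking.table["model_name"], ranking.table["rank"]))
    unknown = set(objects["model_name"]) - set(rank_map)
    if unknown:
        raise ValidationError(f"models absent from ranking: {sorted(unknown)}")

    df = objects.copy()
    keys = list(GROUP_KEYS)
    df["_rank"] = df["model_name"].map(rank_map)
    grouped = df.groupby(keys, sort=False)
    best_rank = grouped["_rank"].transform("max")
    best = df[df["_rank"] == best_rank]
    multiplicity = best.groupby(keys, sort=False)["_rank"].transform("size")
    # idxmax keeps the first maximal-length instance, a deterministic tie-break
    rep_idx = best.groupby(keys, sort=False)["worm_length"].idxmax()
    out = df.loc[sorted(rep_idx)].copy()
    out["model_select"] = out["model_name"]
    out["cluster_flag"] = (multiplicity.loc[out.index] > 1).to_numpy()
    return out.drop(columns="_rank").reset_index(drop=True)
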