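"""Score fusion by resampled nominal groups.

The fusion analysis models collective face-identification decisions: draw a
small nominal group (e.g. two super-recognizers, or a super-recognizer plus
a named DNN), average the members' per-item ratings into a single fused
rating vector, and score the fused vector with rating-scale AUC.  Repeating
the draw many times yields an AUC distribution per composition, summarized
by its median and range.

Human ratings already share the -5..+5 scale; DNN similarity scores are
first min-max rescaled onto that range (once per DNN over the analyzed
items, so member scores do not depend on the draw).  Averaging is plain
arithmetic — no weighting or vote — and missing cells are averaged over
the members that responded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import ItemKey, RatingMatrix, rescale_scores_to_rating_range
from .errors import SamplingError, ValidationError
from .roc import rating_auc

__all__ = ["FusionConfig", "FusionResult", "fuse_ratings", "run_fusion",
           "fusion_report"]


@dataclass(frozen=True)
class FusionConfig:
    """One fusion composition.

    ``composition`` maps a group name (members drawn at random, distinct
    within a draw) or a specific observer_id (fixed named member, as when
    fusing the top DNNs) to a member count.
    """

    composition: Mapping[str, int]
    n_samples: int = 1000
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        total = sum(self.composition.values())
        if total < 1 or any(c < 1 for c in self.composition.values()):
            raise ValidationError("composition needs at least one member per entry")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return "+".join(f"{k}x{v}" if v > 1 else k
                        for k, v in sorted(self.composition.items()))


@dataclass
class FusionResult:
    config: FusionConfig
    auc_samples: np.ndarray
    median_auc: float = field(init=False)
    min_auc: float = field(init=False)
    max_auc: float = field(init=False)

    def __post_init__(self) -> None:
        self.auc_samples = np.asarray(self.auc_samples, dtype=float)
        self.median_auc = float(np.median(self.auc_samples))
        self.min_auc = float(self.auc_samples.min())
        self.max_auc = float(self.auc_samples.max())


def fuse_ratings(member_rows: Sequence[pd.Series | np.ndarray]) -> np.ndarray:
    """Element-wise mean of member rating vectors on a common scale.

    Cells missing for some members are averaged over the members that
    responded; a cell with no member value stays missing.
    """
    if not member_rows:
        raise ValidationError("need at least one member row")
    arr = np.vstack([np.asarray(r, dtype=float) for r in member_rows])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        out = np.nanmean(arr, axis=0)
    return out


def _member_scores(matrix: RatingMatrix) -> pd.DataFrame:
    """Per-observer score rows on the common -5..+5 scale.

    DNN rows (and any raw-score matrix) are min-max rescaled per observer;
    ordinal human rows pass through unchanged.
    """
    vals = matrix.values.copy()
    groups = matrix.groups
    for oid in matrix.observer_ids:
        if groups[oid] == "dnn" or matrix.value_kind == "raw_score":
            vals.loc[oid] = rescale_scores_to_rating_range(vals.loc[oid].to_numpy())
    return vals


def run_fusion(matrix: RatingMatrix, key: Sequence[ItemKey],
               config: FusionConfig) -> FusionResult:
    """Monte-Carlo AUC distribution for one composition.

    Each of ``n_samples`` draws picks distinct observers per composition
    entry (without replacement within the draw; independently across
    draws), fuses their score rows, and computes the rating AUC of the
    fused vector.  Bit-reproducible for a given seed.
    """
    scores = _member_scores(matrix)
    pools: list[tuple[list[str], int]] = []
    all_ids = set(matrix.observer_ids)
    for entry, count in sorted(config.composition.items()):
        if entry in all_ids:
            pool = [entry]
        else:
            pool = matrix.observers_in_group(entry)
            if not pool:
                raise SamplingError(f"composition entry {entry!r} names no "
                                    f"observer or non-empty group")
        if count > len(pool):
            raise SamplingError(
                f"cannot draw {count} distinct members from {entry!r} "
                f"(pool size {len(pool)})")
        pools.append((pool, count))

    rng = np.random.default_rng(config.seed)
    aucs = np.empty(config.n_samples)
    for s in range(config.n_samples):
        members: list[str] = []
        for pool, count in pools:
            if count == len(pool):
                members.extend(pool)
            else:
                members.extend(rng.choice(pool, size=count, replace=False))
        fused = fuse_ratings([scores.loc[m] for m in members])
        aucs[s] = rating_auc(pd.Series(fused, index=scores.columns), key)
    return FusionResult(config=config, auc_samples=aucs)


def fusion_report(results: Sequence[FusionResult]) -> pd.DataFrame:
    """Comparison table over compositions, best (highest median) first.

    Reports the median and the min-max range of the resampled AUCs, plus
    the range of composition medians across the table, so either reading
    of a "fused AUC range" can be checked.
    """
    if not results:
        raise ValidationError("need at least one fusion result")
    rows = [{"composition": r.config.name,
             "n_members": sum(r.config.composition.values()),
             "n_samples": len(r.auc_samples),
             "median_auc": r.median_auc,
             "min_auc": r.min_auc,
             "max_auc": r.max_auc,
             "seed": r.config.seed}
            for r in results]
    table = pd.DataFrame(rows).sort_values(
        "median_auc", ascending=False, kind="mergesort").reset_index(drop=True)
    table["best"] = False
    table.loc[0, "best"] = True
    return table
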