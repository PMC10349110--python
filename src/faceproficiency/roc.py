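"""Rating-scale ROC accuracy.

Per-observer accuracy on the proficiency test is the area under the ROC
curve traced by sweeping a decision threshold across the ordinal rating
scale (or across raw similarity scores; AUC is rank-invariant, so the two
are interchangeable for machine observers).  AUC equals the probability
that a randomly chosen same-person item receives a higher rating than a
randomly chosen different-people item, with tied pairs counted 1/2 — the
normalized Mann-Whitney U statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .datamodel import ItemKey, RatingMatrix, truth_labels
from .errors import UndefinedStatisticError

log = logging.getLogger(__name__)


def _aligned(ratings: pd.Series | Sequence[float],
             key: Sequence[ItemKey]) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, is_same) over non-missing items, aligned to the key.

    ``ratings`` may be a Series indexed by item_id (aligned by label) or a
    plain sequence in key order.
    """
    truths = truth_labels(key)
    if isinstance(ratings, pd.Series):
        vals = ratings.reindex(truths.index).to_numpy(dtype=float)
    else:
        vals = np.asarray(ratings, dtype=float)
        if vals.shape[0] != len(key):
            raise ValueError("ratings length does not match key length")
    is_same = (truths.to_numpy() == "same")
    mask = np.isfinite(vals)
    return vals[mask], is_same[mask]


def rating_auc(ratings: pd.Series | Sequence[float],
               key: Sequence[ItemKey]) -> float:
    """Tie-corrected rank AUC for one observer.

    AUC = [#(same, different) pairs won + 0.5 * #ties] / (n_same * n_diff),
    computed via mid-ranks.  Missing ratings drop the item for this
    observer.  Raises :class:`UndefinedStatisticError` when either truth
    class has no non-missing rating.
    """
    vals, is_same = _aligned(ratings, key)
    n_s, n_d = int(is_same.sum()), int((~is_same).sum())
    if n_s == 0 or n_d == 0:
        raise UndefinedStatisticError(
            f"AUC undefined: {n_s} same and {n_d} different items with responses")
    ranks = rankdata(vals)  # mid-ranks handle ties
    u = ranks[is_same].sum() - n_s * (n_s + 1) / 2
    return float(u / (n_s * n_d))


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_points(ratings: pd.Series | Sequence[float],
               key: Sequence[ItemKey]) -> RocCurve:
    """Explicit ROC curve (one point per distinct rating cutoff plus
    endpoints) with trapezoidal area.

    The trapezoidal area agrees with :func:`rating_auc` to numerical
    precision; both are exposed so each can serve as a check on the other.
    """
    vals, is_same = _aligned(ratings, key)
    if is_same.all() or (~is_same).all():
        raise UndefinedStatisticError("ROC undefined with a single truth class")
    fpr, tpr, thr = roc_curve(is_same.astype(int), vals, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=area)


@dataclass
class GroupAccuracy:
    group: str
    n: int
    mean_auc: float
    sd_auc: float
    per_observer_auc: pd.Series  # observer_id -> AUC


def observer_auc_table(matrix: RatingMatrix, key: Sequence[ItemKey]) -> pd.DataFrame:
    """Per-observer AUC table: observer_id, group, auc."""
    rows = []
    for obs in matrix.observers:
        try:
            auc = rating_auc(matrix.row(obs.observer_id), key)
        except UndefinedStatisticError as e:
            log.warning("observer %s skipped: %s", obs.observer_id, e)
            continue
        rows.append({"observer_id": obs.observer_id, "group": obs.group, "auc": auc})
    return pd.DataFrame(rows, columns=["observer_id", "group", "auc"])


def group_auc_summary(matrix: RatingMatrix,
                      key: Sequence[ItemKey]) -> list[GroupAccuracy]:
    """Mean AUC per observer group, sorted by mean descending.

    Groups with no scorable observer are omitted with a warning.  Raw DNN
    scores need no rescaling here: AUC depends only on within-observer
    rank order.
    """
    table = observer_auc_table(matrix, key)
    out = []
    for group, sub in table.groupby("group"):
        per = sub.set_index("observer_id")["auc"]
        out.append(GroupAccuracy(
            group=str(group), n=len(per),
            mean_auc=float(per.mean()),
            sd_auc=float(per.std(ddof=1)) if len(per) > 1 else 0.0,
            per_observer_auc=per))
    present = {g.group for g in out}
    for group in matrix.groups.unique():
        if group not in present:
            log.warning("group %s omitted: no scorable observers", group)
    return sorted(out, key=lambda g: g.mean_auc, reverse=True)


def group_summary_frame(summaries: Sequence[GroupAccuracy]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"group": g.group, "n": g.n, "mean_auc": g.mean_auc, "sd_auc": g.sd_auc}
         for g in summaries])
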