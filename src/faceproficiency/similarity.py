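"""Inter-observer similarity structure.

For each trial type (same-person pairs, different-people pairs) the
pipeline computes the observer x observer Spearman rank correlation of
responses over that trial type's items.  With only 11 possible human
values over at most 13 items, ties are heavy, so the tie-aware mid-rank
definition (Pearson correlation of mid-ranks) is used throughout.

Observers whose responses for a trial type are degenerate — fewer than two
non-missing values, or a single distinct value — have no defined rank
order there and are excluded, with the reason logged in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .datamodel import GROUPS, ItemKey, RatingMatrix, truth_labels
from .errors import EmptyMatrixError, UndefinedStatisticError

log = logging.getLogger(__name__)

TrialType = Literal["same", "different"]


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-aware Spearman correlation of two response vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise UndefinedStatisticError("need two equal-length vectors of length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    rho = spearmanr(x, y).statistic
    return float(rho)


@dataclass
class CorrelationMatrix:
    observer_ids: list[str]
    rho: pd.DataFrame            # square, symmetric, unit diagonal
    trial_type: str
    excluded: list[tuple[str, str]]   # (observer_id, reason)


def correlation_matrix(matrix: RatingMatrix, key: Sequence[ItemKey],
                       trial_type: TrialType) -> CorrelationMatrix:
    """Pairwise Spearman rho over one trial type's items.

    Pairwise complete observations: each pair is correlated over the items
    both observers answered.  A pair that ends up degenerate (fewer than 2
    shared items, or zero variance on the shared set) gets NaN.
    """
    truths = truth_labels(key)
    cols = [c for c in matrix.item_ids
            if c in truths.index and truths[c] == trial_type]
    if not cols:
        raise EmptyMatrixError(f"no items of trial type {trial_type!r}")
    vals = matrix.values[cols]

    excluded: list[tuple[str, str]] = []
    eligible: list[str] = []
    for oid in matrix.observer_ids:
        row = vals.loc[oid].dropna()
        if len(row) < 2:
            excluded.append((oid, "fewer than 2 responses for this trial type"))
        elif row.nunique() < 2:
            excluded.append((oid, "degenerate responses (single distinct value)"))
        else:
            eligible.append(oid)
    for oid, reason in excluded:
        log.info("excluded %s from %s-pairs correlation: %s", oid, trial_type, reason)
    if len(eligible) < 2:
        raise EmptyMatrixError(
            f"fewer than 2 eligible observers for trial type {trial_type!r}")

    sub = vals.loc[eligible]
    n = len(eligible)
    arr = sub.to_numpy(dtype=float)
    if np.isfinite(arr).all():
        # complete data: mid-rank each row once, then one correlation pass
        from scipy.stats import rankdata
        ranks = rankdata(arr, axis=1)
        rho = np.corrcoef(ranks)
        np.fill_diagonal(rho, 1.0)
    else:
        rho = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                both = np.isfinite(arr[i]) & np.isfinite(arr[j])
                xi, yj = arr[i, both], arr[j, both]
                if both.sum() < 2 or np.unique(xi).size < 2 or np.unique(yj).size < 2:
                    r = np.nan
                else:
                    r = spearmanr(xi, yj).statistic
                rho[i, j] = rho[j, i] = r
    frame = pd.DataFrame(rho, index=eligible, columns=eligible)
    return CorrelationMatrix(eligible, frame, trial_type, excluded)


@dataclass
class BlockAgreement:
    group_a: str
    group_b: str
    trial_type: str
    mean_rho: float
    n_pairs: int


def block_agreement(corr: CorrelationMatrix,
                    groups: Mapping[str, str] | pd.Series,
                    pairs: Sequence[tuple[str, str]] | None = None,
                    ) -> list[BlockAgreement]:
    """Plain average of rho over every group-pair block.

    Cross-group blocks average all entries; within-group blocks average
    the off-diagonal upper triangle.  ``groups`` maps observer_id to group
    label; labels may also be coarser aggregates (e.g. 'human').  ``pairs``
    restricts the output; by default every unordered pair of present
    groups is reported.  Absent groups are omitted with a warning.
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    members: dict[str, list[str]] = {}
    for oid in corr.observer_ids:
        g = groups.get(oid)
        if g is None:
            continue
        members.setdefault(str(g), []).append(oid)
    present = sorted(members)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(present) for b in present[i:]]
    out = []
    for a, b in pairs:
        if a not in members or b not in members:
            log.warning("block %s x %s omitted: group absent from matrix", a, b)
            continue
        block = corr.rho.loc[members[a], members[b]].to_numpy(dtype=float)
        if a == b:
            iu = np.triu_indices(block.shape[0], k=1)
            entries = block[iu]
        else:
            entries = block.ravel()
        entries = entries[np.isfinite(entries)]
        if entries.size == 0:
            log.warning("block %s x %s omitted: no finite entries", a, b)
            continue
        out.append(BlockAgreement(a, b, corr.trial_type,
                                  float(entries.mean()), int(entries.size)))
    return out


def block_agreement_frame(blocks: Sequence[BlockAgreement]) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in blocks])


def heatmap_export(corr: CorrelationMatrix, path: str | Path,
                   groups: Mapping[str, str] | pd.Series | None = None) -> Path:
    """Write a diverging red/yellow/blue correlation heatmap.

    Axes are ordered by group (study group order, DNNs last) when group
    labels are given, else by the matrix's own order.  Red is positive
    rho, yellow zero, blue negative.  Deterministic for a given matrix.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = list(corr.observer_ids)
    if groups is not None:
        groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        rank = {g: i for i, g in enumerate(GROUPS)}
        order = sorted(order, key=lambda o: (rank.get(groups.get(o, ""), 99), o))
    mat = corr.rho.loc[order, order].to_numpy(dtype=float)

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(mat, cmap="RdYlBu_r", vmin=-1, vmax=1, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"Spearman correlation, {corr.trial_type}-pairs "
                 f"({len(order)} observers)")
    fig.colorbar(im, ax=ax, label="Spearman rho")
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
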