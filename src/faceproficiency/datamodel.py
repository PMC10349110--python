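"""Data model and tabular I/O for 1-to-1 face-comparison proficiency tests.

The central objects are an item key (which comparisons show the same person
and which show different people) and a rating matrix (observers x items).
Human observers respond on an 11-point ordinal scale from -5 (extremely
strong support for "different people") to +5 (extremely strong support for
"same person"), with 0 meaning the comparison is inconclusive.  Machine
observers (face-recognition DNNs) contribute one real-valued similarity
score per item instead.

Files are plain comma-separated text: one observer per row with
``observer_id``, ``group`` and ``mode`` columns followed by one column per
item; missing responses are empty cells.  The item key is a second CSV with
``item_id``, ``truth`` and an optional ``gap_category`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, FormatError, ValidationError

RATING_LO = -5
RATING_HI = 5

GROUPS = ("novice", "super_recognizer", "forensic_examiner",
          "forensic_laboratory", "dnn")
MODES = ("offline", "online", "not_applicable")
TRUTHS = ("same", "different")
GAP_CATEGORIES = ("0-2y", "2-8y", "8+y")
VALUE_KINDS = ("ordinal_11pt", "raw_score")

#: column names that precede the per-item rating columns in a ratings CSV
META_COLUMNS = ("observer_id", "group", "mode")


@dataclass(frozen=True)
class ItemKey:
    """Ground truth for one 1-to-1 comparison."""

    item_id: str
    truth: str                      # "same" or "different"
    gap_category: str | None = None  # "0-2y", "2-8y", "8+y"

    def __post_init__(self) -> None:
        if self.truth not in TRUTHS:
            raise ValidationError(
                f"item {self.item_id!r}: truth must be one of {TRUTHS}, "
                f"got {self.truth!r}")
        if self.gap_category is not None and self.gap_category not in GAP_CATEGORIES:
            raise ValidationError(
                f"item {self.item_id!r}: gap_category must be one of "
                f"{GAP_CATEGORIES}, got {self.gap_category!r}")


@dataclass(frozen=True)
class Observer:
    observer_id: str
    group: str
    mode: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"observer {self.observer_id!r}: group must be one of "
                f"{GROUPS}, got {self.group!r}")
        if self.mode not in MODES:
            raise ValidationError(
                f"observer {self.observer_id!r}: mode must be one of "
                f"{MODES}, got {self.mode!r}")


@dataclass
class RatingMatrix:
    """Observers x items response table.

    ``values`` is a float DataFrame indexed by observer_id with one column
    per item id; missing responses are NaN.  ``value_kind`` declares whether
    entries are constrained to the 11-point ordinal scale or are raw scores.
    """

    observers: list[Observer]
    item_ids: list[str]
    values: pd.DataFrame
    value_kind: str = "ordinal_11pt"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if len(self.item_ids) == 0:
            raise ValidationError("a rating matrix needs at least one item")
        if len(self.observers) == 0:
            raise ValidationError("a rating matrix needs at least one observer")
        ids = [o.observer_id for o in self.observers]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate observer_id")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError("duplicate item_id")
        self.values = self.values.astype(float)
        if list(self.values.index) != ids or list(self.values.columns) != self.item_ids:
            raise ValidationError("values index/columns must match observers/item_ids")
        if self.value_kind == "ordinal_11pt":
            self._check_ordinal()

    def _check_ordinal(self) -> None:
        arr = self.values.to_numpy()
        finite = np.isfinite(arr)
        bad = finite & ((arr < RATING_LO) | (arr > RATING_HI) | (arr != np.round(arr)))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-integer or out-of-range ordinal rating "
                f"{arr[i, j]!r} at observer {self.values.index[i]!r}, "
                f"item {self.values.columns[j]!r}")

    # -- convenience accessors -------------------------------------------------

    @property
    def observer_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({o.observer_id: o.group for o in self.observers},
                         name="group").reindex(self.values.index)

    def observers_in_group(self, group: str) -> list[str]:
        return [o.observer_id for o in self.observers if o.group == group]

    def row(self, observer_id: str) -> pd.Series:
        return self.values.loc[observer_id]

    def subset(self, observer_ids: Sequence[str]) -> "RatingMatrix":
        keep = set(observer_ids)
        obs = [o for o in self.observers if o.observer_id in keep]
        order = [o.observer_id for o in obs]
        return RatingMatrix(obs, list(self.item_ids),
                            self.values.loc[order], self.value_kind)

    def equals(self, other: "RatingMatrix") -> bool:
        return (self.observers == other.observers
                and self.item_ids == other.item_ids
                and self.value_kind == other.value_kind
                and self.values.equals(other.values))


# ---------------------------------------------------------------------------
# item key I/O

def load_item_key(path: str | Path) -> list[ItemKey]:
    df = pd.read_csv(path, dtype=str)
    required = {"item_id", "truth"}
    if not required.issubset(df.columns):
        raise FormatError(f"item key must have columns {sorted(required)}, "
                          f"found {list(df.columns)}")
    keys = []
    for _, r in df.iterrows():
        gap = r.get("gap_category")
        if isinstance(gap, float) and np.isnan(gap):
            gap = None
        keys.append(ItemKey(str(r["item_id"]), str(r["truth"]),
                            None if gap in (None, "") else str(gap)))
    if len({k.item_id for k in keys}) != len(keys):
        raise ValidationError("duplicate item_id in key")
    return keys


def write_item_key(keys: Sequence[ItemKey], path: str | Path) -> None:
    pd.DataFrame(
        {"item_id": [k.item_id for k in keys],
         "truth": [k.truth for k in keys],
         "gap_category": [k.gap_category or "" for k in keys]}
    ).to_csv(path, index=False)


def truth_labels(keys: Sequence[ItemKey]) -> pd.Series:
    """Series item_id -> truth ('same'/'different')."""
    return pd.Series({k.item_id: k.truth for k in keys}, name="truth")


# ---------------------------------------------------------------------------
# rating matrix I/O

def load_ratings(path: str | Path, value_kind: str = "ordinal_11pt") -> RatingMatrix:
    """Read a ratings CSV into a validated :class:`RatingMatrix`.

    The header must start with ``observer_id,group,mode`` followed by item
    ids; each subsequent row is one observer.  Empty cells mark missing
    responses.  Ordinal files are checked cell-by-cell: any non-integer or
    out-of-range value raises :class:`ValidationError` naming the offending
    observer and item.
    """
    df = pd.read_csv(path, dtype={0: str, 1: str, 2: str})
    if list(df.columns[:3]) != list(META_COLUMNS):
        raise FormatError(
            f"ratings file must begin with columns {META_COLUMNS}, "
            f"found {list(df.columns[:3])}")
    item_ids = [str(c) for c in df.columns[3:]]
    if not item_ids:
        raise FormatError("ratings file declares no item columns")
    observers = [Observer(str(r.observer_id), str(r.group), str(r.mode))
                 for r in df.itertuples(index=False)]
    values = df[df.columns[3:]].apply(pd.to_numeric, errors="coerce")
    raw = df[df.columns[3:]]
    # a cell that is non-empty text but fails numeric conversion is a format
    # problem, not a missing value (empty cells parse as NaN in `raw` too)
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = map(int, np.argwhere(bad.to_numpy())[0])
        raise ValidationError(
            f"non-numeric value {raw.iat[i, j]!r} at observer "
            f"{observers[i].observer_id!r}, item {item_ids[j]!r}")
    values.index = pd.Index([o.observer_id for o in observers])
    values.columns = pd.Index(item_ids)
    return RatingMatrix(observers, item_ids, values, value_kind)


def write_ratings(matrix: RatingMatrix, path: str | Path) -> None:
    """Write a matrix to CSV so that :func:`load_ratings` round-trips it."""
    out = matrix.values.copy()
    if matrix.value_kind == "ordinal_11pt":
        # keep integers readable (no trailing .0) while preserving NaN
        out = out.astype("Int64")
    meta = pd.DataFrame(
        {"observer_id": [o.observer_id for o in matrix.observers],
         "group": [o.group for o in matrix.observers],
         "mode": [o.mode for o in matrix.observers]})
    body = out.reset_index(drop=True)
    pd.concat([meta, body], axis=1).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# score rescaling

def rescale_scores_to_rating_range(scores: Iterable[float],
                                   lo: float = RATING_LO,
                                   hi: float = RATING_HI) -> np.ndarray:
    """Linearly map an observer's raw similarity scores onto [lo, hi].

    Min-max rescaling per observer: the observer's smallest score maps to
    ``lo``, the largest to ``hi``, everything in between affinely.  Order
    (and hence every rank statistic) is preserved exactly; NaNs pass
    through.  Raises :class:`DegenerateScaleError` when all finite scores
    are identical, since such a vector carries no rank information.
    """
    arr = np.asarray(list(scores) if not isinstance(scores, np.ndarray) else scores,
                     dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2 or finite.min() == finite.max():
        raise DegenerateScaleError(
            "need at least two distinct finite scores to rescale")
    lo_s, hi_s = finite.min(), finite.max()
    return lo + (arr - lo_s) * (hi - lo) / (hi_s - lo_s)


# ---------------------------------------------------------------------------
# study validation report

@dataclass
class StudyReport:
    n_items_matrix: int
    n_items_key: int
    items_missing_from_key: list[str]
    items_missing_from_matrix: list[str]
    truth_counts: dict[str, int]
    group_sizes: dict[str, int]
    missing_per_observer: dict[str, int]
    empty_observers: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.items_missing_from_key or self.items_missing_from_matrix
                    or self.empty_observers)

    def __str__(self) -> str:  # human-readable summary for the CLI
        lines = [
            f"items: {self.n_items_matrix} in matrix, {self.n_items_key} in key",
            "truth counts: " + ", ".join(f"{k}={v}" for k, v in self.truth_counts.items()),
            "group sizes: " + ", ".join(f"{k}={v}" for k, v in sorted(self.group_sizes.items())),
        ]
        if self.items_missing_from_key:
            lines.append("items absent from key: " + ", ".join(self.items_missing_from_key))
        if self.items_missing_from_matrix:
            lines.append("key items absent from matrix: " + ", ".join(self.items_missing_from_matrix))
        if self.empty_observers:
            lines.append("observers with no responses: " + ", ".join(self.empty_observers))
        n_missing = sum(self.missing_per_observer.values())
        lines.append(f"missing cells: {n_missing}")
        return "\n".join(lines)


def validate_study(matrix: RatingMatrix, key: Sequence[ItemKey]) -> StudyReport:
    """Cross-check a rating matrix against its item key (report-only)."""
    key_ids = [k.item_id for k in key]
    truth_counts: dict[str, int] = {t: 0 for t in TRUTHS}
    for k in key:
        truth_counts[k.truth] += 1
    missing_per_obs = matrix.values.isna().sum(axis=1).astype(int).to_dict()
    empty = [oid for oid, n in missing_per_obs.items() if n == len(matrix.item_ids)]
    groups = matrix.groups
    return StudyReport(
        n_items_matrix=len(matrix.item_ids),
        n_items_key=len(key),
        items_missing_from_key=[i for i in matrix.item_ids if i not in set(key_ids)],
        items_missing_from_matrix=[i for i in key_ids if i not in set(matrix.item_ids)],
        truth_counts=truth_counts,
        group_sizes=groups.value_counts().to_dict(),
        missing_per_observer=missing_per_obs,
        empty_observers=empty,
    )
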