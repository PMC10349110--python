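import numpy as np
import pandas as pd
import pytest

from faceproficiency.datamodel import ItemKey, Observer, RatingMatrix


@pytest.fixture
def tiny_key() -> list[ItemKey]:
    """Four items: two same-person, two different-people."""
    return [
        ItemKey("i1", "same"), ItemKey("i2", "same"),
        ItemKey("i3", "different"), ItemKey("i4", "different"),
    ]


@pytest.fixture
def enfsi_key() -> list[ItemKey]:
    """A 20-item key with the proficiency test's 13:7 truth split."""
    truths = ["same"] * 13 + ["different"] * 7
    return [ItemKey(f"it{i:02d}", t) for i, t in enumerate(truths, 1)]


def make_matrix(rows: dict[str, list[float]], item_ids: list[str],
                groups: dict[str, str] | None = None,
                value_kind: str = "ordinal_11pt") -> RatingMatrix:
    groups = groups or {}
    observers = [Observer(oid, groups.get(oid, "novice")) for oid in rows]
    values = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    values.columns = pd.Index(item_ids)
    return RatingMatrix(observers, item_ids, values, value_kind)


@pytest.fixture
def tiny_matrix(tiny_key) -> RatingMatrix:
    return make_matrix(
        {"a": [3, 5, -2, 3], "b": [5, 5, -5, -5]},
        [k.item_id for k in tiny_key],
        groups={"a": "novice", "b": "super_recognizer"},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
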