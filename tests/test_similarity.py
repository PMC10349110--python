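"""Spearman correlation structure, exclusions, block agreement, heatmap."""

import numpy as np
import pytest

from faceproficiency.errors import EmptyMatrixError, UndefinedStatisticError
from faceproficiency.similarity import (block_agreement, correlation_matrix,
                                        heatmap_export, spearman_rho)

from conftest import make_matrix


def rank_then_pearson(x, y):
    """Independent oracle: mid-rank both vectors, then plain Pearson."""
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 3], [2, 4, 9]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        x, y = [1, 2, 2, 4], [2, 1, 3, 4]
        assert spearman_rho(x, y) == pytest.approx(rank_then_pearson(x, y))
        for _ in range(25):
            a = rng.integers(-5, 6, size=12)
            b = rng.integers(-5, 6, size=12)
            if np.unique(a).size < 2 or np.unique(b).size < 2:
                continue
            assert spearman_rho(a, b) == pytest.approx(rank_then_pearson(a, b))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])


@pytest.fixture
def small_study(enfsi_key):
    ids = [k.item_id for k in enfsi_key]
    rows = {
        "h1": list(range(-5, 5)) + [1] * 10,
        "h2": list(range(-5, 5)) + [2, 1] * 5,
        "flat": [5] * 13 + list(range(-5, 2)),   # constant on same items
        "sparse": [1] + [np.nan] * 19,           # one response only
    }
    return make_matrix(rows, ids, groups={"h1": "novice", "h2": "novice",
                                          "flat": "super_recognizer",
                                          "sparse": "super_recognizer"})


class TestCorrelationMatrix:
    def test_shape_and_symmetry(self, small_study, enfsi_key):
        corr = correlation_matrix(small_study, enfsi_key, "same")
        rho = corr.rho.to_numpy()
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)
        assert np.nanmax(np.abs(rho)) <= 1.0 + 1e-12

    def test_degenerate_observers_excluded_with_reason(self, small_study, enfsi_key):
        corr = correlation_matrix(small_study, enfsi_key, "same")
        reasons = dict(corr.excluded)
        assert "degenerate" in reasons["flat"]
        assert "fewer than 2" in reasons["sparse"]
        assert "flat" not in corr.observer_ids
        # the same observer is fine on different-people items
        corr_d = correlation_matrix(small_study, enfsi_key, "different")
        assert "flat" in corr_d.observer_ids

    def test_identical_observers_correlate_perfectly(self, enfsi_key):
        ids = [k.item_id for k in enfsi_key]
        row = list(range(-5, 5)) + [1] * 10
        m = make_matrix({"a": row, "b": row}, ids)
        corr = correlation_matrix(m, enfsi_key, "same")
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_permutation_equivariance(self, enfsi_key, rng):
        ids = [k.item_id for k in enfsi_key]
        rows = {f"o{i}": rng.integers(-5, 6, size=20).tolist() for i in range(6)}
        m1 = make_matrix(rows, ids)
        shuffled = dict(reversed(list(rows.items())))
        m2 = make_matrix(shuffled, ids)
        c1 = correlation_matrix(m1, enfsi_key, "different")
        c2 = correlation_matrix(m2, enfsi_key, "different")
        common = sorted(set(c1.observer_ids) & set(c2.observer_ids))
        assert np.allclose(c1.rho.loc[common, common],
                           c2.rho.loc[common, common], equal_nan=True)

    def test_too_few_eligible_observers(self, enfsi_key):
        ids = [k.item_id for k in enfsi_key]
        m = make_matrix({"a": [5] * 13 + [1] * 7, "b": [4] * 13 + [2] * 7}, ids)
        with pytest.raises(EmptyMatrixError):
            correlation_matrix(m, enfsi_key, "same")


class TestBlockAgreement:
    def test_identical_block_means_one(self, enfsi_key):
        ids = [k.item_id for k in enfsi_key]
        row = list(range(-5, 5)) + [1] * 10
        m = make_matrix({"a": row, "b": row, "c": row}, ids)
        corr = correlation_matrix(m, enfsi_key, "same")
        blocks = block_agreement(corr, {"a": "g", "b": "g", "c": "g"})
        assert len(blocks) == 1
        assert blocks[0].mean_rho == pytest.approx(1.0)
        assert blocks[0].n_pairs == 3  # off-diagonal upper triangle

    def test_cross_block_average(self, enfsi_key):
        ids = [k.item_id for k in enfsi_key]
        ramp = list(range(-5, 6)) + [5, 5]          # 13 same-item values
        up = ramp + [0] * 7
        down = ramp[::-1] + [0] * 7
        m = make_matrix({"a": up, "b": down}, ids,
                        groups={"a": "novice", "b": "dnn"})
        corr = correlation_matrix(m, enfsi_key, "same")
        blocks = block_agreement(corr, m.groups, pairs=[("dnn", "novice")])
        # a 1x1 cross block is just the pairwise correlation
        assert blocks[0].mean_rho == pytest.approx(spearman_rho(ramp, ramp[::-1]))
        assert blocks[0].mean_rho < -0.95
        assert blocks[0].n_pairs == 1

    def test_absent_group_omitted(self, enfsi_key):
        ids = [k.item_id for k in enfsi_key]
        row = list(range(-5, 5)) + [1] * 10
        m = make_matrix({"a": row, "b": row}, ids)
        corr = correlation_matrix(m, enfsi_key, "same")
        blocks = block_agreement(corr, m.groups, pairs=[("dnn", "novice")])
        assert blocks == []


def test_heatmap_written_deterministically(tmp_path, enfsi_key, rng):
    ids = [k.item_id for k in enfsi_key]
    rows = {f"o{i}": rng.integers(-5, 6, size=20).tolist() for i in range(5)}
    m = make_matrix(rows, ids)
    corr = correlation_matrix(m, enfsi_key, "different")
    p1 = heatmap_export(corr, tmp_path / "a.png", m.groups)
    p2 = heatmap_export(corr, tmp_path / "b.png", m.groups)
    assert p1.exists() and p1.stat().st_size > 0
    assert p1.read_bytes() == p2.read_bytes()
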