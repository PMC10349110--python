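"""Signal-detection and response-scale profiling.

Ordinal ratings are binarized by sign: positive ratings are "same person"
decisions, negative ratings "different people", and 0 is an inconclusive
non-decision.  Hit and false-alarm rates are computed over decisive
responses only (the default; a sensitivity toggle instead folds 0 into
"different people").  Sensitivity d' and response criterion c follow the
equal-variance Gaussian model:

    d' = z(H) - z(F)        c = -(z(H) + z(F)) / 2

with z the inverse standard-normal CDF.  Negative c is a liberal bias
toward responding "same person".  Boundary rates (0 or 1) are handled by
the log-linear correction: add 0.5 to every response-category count and 1
to each denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import ItemKey, RatingMatrix, truth_labels
from .errors import UndefinedStatisticError, ValidationError

SCALE_POINTS = tuple(range(-5, 6))

InconclusivePolicy = Literal["exclude", "as_different"]
CorrectionRule = Literal["loglinear", "clamp"]


def binarize(rating: int) -> str:
    """Map one ordinal rating to {'same', 'different', 'inconclusive'}."""
    r = int(rating)
    if r != rating or not -5 <= r <= 5:
        raise ValidationError(f"rating must be an integer in [-5, 5], got {rating!r}")
    if r > 0:
        return "same"
    if r < 0:
        return "different"
    return "inconclusive"


@dataclass
class SdtSummary:
    observer_id: str
    hit_rate: float
    false_alarm_rate: float
    d_prime: float
    criterion_c: float
    correction_applied: bool
    n_decisive_same: int
    n_decisive_diff: int


def hit_fa_rates(ratings: pd.Series | Sequence[float],
                 key: Sequence[ItemKey],
                 inconclusive: InconclusivePolicy = "exclude",
                 correction: CorrectionRule = "loglinear",
                 ) -> tuple[float, float, bool, int, int]:
    """Hit and false-alarm rates for one observer.

    Returns (H, F, correction_applied, n_decisive_same, n_decisive_diff).
    H is the probability of a "same" decision on same-person items, F on
    different-people items.  Under the default policy inconclusive (0)
    responses are non-decisions and leave the denominators; under
    ``as_different`` they count as "different people" decisions.

    When a raw rate is 0 or 1, ``loglinear`` adds 0.5 to each cell and 1
    to each denominator (both classes, so H and F stay comparable);
    ``clamp`` replaces the boundary rate with 1/(2N) or 1 - 1/(2N).
    """
    truths = truth_labels(key)
    if isinstance(ratings, pd.Series):
        vals = ratings.reindex(truths.index).to_numpy(dtype=float)
    else:
        vals = np.asarray(ratings, dtype=float)
        if vals.shape[0] != len(key):
            raise ValueError("ratings length does not match key length")
    is_same_item = truths.to_numpy() == "same"
    present = np.isfinite(vals)

    if inconclusive == "exclude":
        decisive = present & (vals != 0)
    elif inconclusive == "as_different":
        decisive = present
    else:
        raise ValidationError(f"unknown inconclusive policy {inconclusive!r}")

    said_same = decisive & (vals > 0)
    n_s = int((decisive & is_same_item).sum())
    n_d = int((decisive & ~is_same_item).sum())
    if n_s == 0 or n_d == 0:
        raise UndefinedStatisticError(
            f"rates undefined: {n_s} decisive same and {n_d} decisive "
            f"different responses")
    hits = int((said_same & is_same_item).sum())
    fas = int((said_same & ~is_same_item).sum())

    h_raw, f_raw = hits / n_s, fas / n_d
    boundary = h_raw in (0.0, 1.0) or f_raw in (0.0, 1.0)
    if not boundary:
        return h_raw, f_raw, False, n_s, n_d
    if correction == "loglinear":
        h = (hits + 0.5) / (n_s + 1)
        f = (fas + 0.5) / (n_d + 1)
    elif correction == "clamp":
        h = min(max(h_raw, 1 / (2 * n_s)), 1 - 1 / (2 * n_s))
        f = min(max(f_raw, 1 / (2 * n_d)), 1 - 1 / (2 * n_d))
    else:
        raise ValidationError(f"unknown correction rule {correction!r}")
    return h, f, True, n_s, n_d


def _check_open_interval(h: float, f: float) -> None:
    if not (0.0 < h < 1.0 and 0.0 < f < 1.0):
        raise UndefinedStatisticError(
            f"rates must lie strictly inside (0, 1); got H={h}, F={f} — "
            f"apply a boundary correction first")


def criterion_c(h: float, f: float) -> float:
    """Response criterion c = -(z(H) + z(F))/2; c < 0 is liberal toward 'same'."""
    _check_open_interval(h, f)
    return float(-0.5 * (norm.ppf(h) + norm.ppf(f)))


def d_prime(h: float, f: float) -> float:
    """Sensitivity d' = z(H) - z(F)."""
    _check_open_interval(h, f)
    return float(norm.ppf(h) - norm.ppf(f))


def sdt_summary(matrix: RatingMatrix, key: Sequence[ItemKey],
                inconclusive: InconclusivePolicy = "exclude",
                correction: CorrectionRule = "loglinear") -> list[SdtSummary]:
    """Per-observer SDT summaries; observers with an undefined rate are
    skipped (they carry no decisive response in some truth class)."""
    out = []
    for obs in matrix.observers:
        try:
            h, f, corr, n_s, n_d = hit_fa_rates(
                matrix.row(obs.observer_id), key, inconclusive, correction)
        except UndefinedStatisticError:
            continue
        out.append(SdtSummary(obs.observer_id, h, f,
                              d_prime(h, f), criterion_c(h, f),
                              corr, n_s, n_d))
    return out


def sdt_summary_frame(summaries: Sequence[SdtSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass
class ResponseProfile:
    """How one observer or group spreads responses over the 11-point scale.

    ``usage`` and ``error_distribution`` are indexed by scale point -5..5.
    An error is a decisive response on the wrong side of the truth: a
    positive rating on a different-people item or a negative rating on a
    same-person item; 0 is never an error.  ``high_conf_same_error_share``
    is the share of all errors that are +4/+5 responses on different-people
    items (the high-confidence misidentifications).
    """

    profile_id: str
    n_observers: int
    n_responses: int
    usage: pd.Series
    error_distribution: pd.Series
    n_errors: int
    inconclusive_rate: float
    high_conf_same_error_share: float


def _profile(profile_id: str, sub: pd.DataFrame,
             is_same_item: np.ndarray) -> ResponseProfile | None:
    vals = sub.to_numpy(dtype=float)
    present = np.isfinite(vals)
    n_resp = int(present.sum())
    if n_resp == 0:
        return None
    flat = vals[present].astype(int)
    usage = pd.Series(0.0, index=list(SCALE_POINTS))
    counts = pd.Series(flat).value_counts()
    usage.loc[counts.index] = counts.to_numpy() / n_resp

    same_grid = np.broadcast_to(is_same_item, vals.shape)
    err_mask = present & (((vals > 0) & ~same_grid) | ((vals < 0) & same_grid))
    errors = vals[err_mask].astype(int)
    err_dist = pd.Series(0.0, index=list(SCALE_POINTS))
    if errors.size:
        ec = pd.Series(errors).value_counts()
        err_dist.loc[ec.index] = ec.to_numpy() / errors.size
    high_conf = int(((errors == 4) | (errors == 5)).sum())
    return ResponseProfile(
        profile_id=profile_id,
        n_observers=sub.shape[0],
        n_responses=n_resp,
        usage=usage,
        error_distribution=err_dist,
        n_errors=int(errors.size),
        inconclusive_rate=float((flat == 0).mean()),
        high_conf_same_error_share=(high_conf / errors.size) if errors.size else 0.0,
    )


def response_profile(matrix: RatingMatrix, key: Sequence[ItemKey],
                     by: Literal["observer", "group"] = "group",
                     ) -> list[ResponseProfile]:
    """Scale-usage and error profiles, pooled per group or per observer."""
    if matrix.value_kind != "ordinal_11pt":
        raise ValidationError("response profiles require ordinal ratings")
    truths = truth_labels(key)
    cols = [c for c in matrix.item_ids if c in truths.index]
    vals = matrix.values[cols]
    is_same = (truths.reindex(cols).to_numpy() == "same")
    out = []
    if by == "group":
        for group in sorted(matrix.groups.unique()):
            ids = matrix.observers_in_group(group)
            p = _profile(group, vals.loc[ids], is_same)
            if p is not None:
                out.append(p)
    elif by == "observer":
        for oid in matrix.observer_ids:
            p = _profile(oid, vals.loc[[oid]], is_same)
            if p is not None:
                out.append(p)
    else:
        raise ValidationError(f"unknown grouping {by!r}")
    return out


def profile_frame(profiles: Sequence[ResponseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"profile_id": p.profile_id, "n_observers": p.n_observers,
               "n_responses": p.n_responses, "n_errors": p.n_errors,
               "inconclusive_rate": p.inconclusive_rate,
               "high_conf_same_error_share": p.high_conf_same_error_share}
        row.update({f"usage_{k}": v for k, v in p.usage.items()})
        row.update({f"err_{k}": v for k, v in p.error_distribution.items()})
        rows.append(row)
    return pd.DataFrame(rows)
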