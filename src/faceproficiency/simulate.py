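"""Synthetic observer generator.

Generates proficiency-test studies with the statistical structure the
analysis pipeline assumes, so every stage can be verified end to end
without access to any real response data.

The generative core is equal-variance Gaussian signal detection.  Each
item i carries latent evidence; for human observer j,

    e_ij = d*_j . [item is same-person] + lambda_j . u_i
           + sqrt(1 - lambda_j^2) . eps_ij

where u_i ~ N(0,1) is an item component shared by all humans (it induces
inter-observer rank correlation) and eps_ij is idiosyncratic, so marginal
evidence has unit variance in both truth classes and the observer's
expected rating AUC has the closed form Phi(d*/sqrt(2)).

Evidence is mapped to the 11-point scale through a response boundary at
k_j = d*_j/2 + c*_j (so the measured SDT criterion recovers c*_j) and four
confidence cutoffs on each side of it.  Cutoff increments shrink
geometrically with the extremeness gain kappa_j: kappa > 1 piles mass on
the scale ends (+/-4, +/-5), kappa < 1 spreads it over the midscale.
When evidence lands in the innermost band around the boundary, the
observer emits the inconclusive response 0 with probability
p_inconclusive_j.

DNN-like scorers return real-valued similarity scores

    s_ij = d*_j . [same] + a . u_i . [same] + (a - nu_j) . u_i . [different]
           + noise_sd_j . eps_ij

with alignment a > 0.  At nu = 0 the scorer is human-aligned on both trial
types; as nu grows past a, its different-pair scores progressively
anti-correlate with human ratings while same-pair agreement is untouched —
the divergence signature the similarity analysis is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datamodel import ItemKey, Observer, RatingMatrix
from .errors import ValidationError
from .roc import observer_auc_table
from .sdt import sdt_summary
from .similarity import block_agreement, correlation_matrix

#: base width (in evidence z-units) of the innermost confidence band
BIN_BASE_WIDTH = 0.5


@dataclass(frozen=True)
class ObserverParams:
    """Generating parameters for one human-like observer."""

    d_star: float                 # sensitivity, z-units; >= 0
    c_star: float = 0.0           # criterion; < 0 = liberal toward "same"
    kappa: float = 1.0            # confidence extremeness gain, > 0
    p_inconclusive: float = 0.0   # P(respond 0 | evidence in innermost band)
    lambda_shared: float = 0.5    # loading on the shared item component

    def __post_init__(self) -> None:
        if self.d_star < 0:
            raise ValidationError("d_star must be >= 0")
        if self.kappa <= 0:
            raise ValidationError("kappa must be > 0")
        if not 0 <= self.p_inconclusive < 1:
            raise ValidationError("p_inconclusive must be in [0, 1)")
        if not 0 <= self.lambda_shared < 1:
            raise ValidationError("lambda_shared must be in [0, 1)")


@dataclass(frozen=True)
class DnnParams:
    """Generating parameters for one DNN-like scorer."""

    d_star: float
    nu: float = 0.0               # divergence loading on different-people items
    noise_sd: float = 0.6
    alignment: float = 0.3        # shared-component loading when aligned

    def __post_init__(self) -> None:
        if self.d_star < 0:
            raise ValidationError("d_star must be >= 0")
        if self.nu < 0:
            raise ValidationError("nu must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


AnyParams = Union[ObserverParams, DnnParams]


@dataclass
class SyntheticConfig:
    n_items: int
    n_same: int
    groups: dict[str, list[AnyParams]]
    seed: int = 0
    modes: dict[str, str] = field(default_factory=dict)  # group -> mode

    def __post_init__(self) -> None:
        if not 0 < self.n_same < self.n_items:
            raise ValidationError("need 0 < n_same < n_items")
        if not self.groups or not any(self.groups.values()):
            raise ValidationError("need at least one observer")
        for g, roster in self.groups.items():
            want_dnn = (g == "dnn")
            for p in roster:
                if isinstance(p, DnnParams) != want_dnn:
                    raise ValidationError(
                        f"group {g!r} roster holds the wrong parameter kind")


# ---------------------------------------------------------------------------
# closed forms

def closed_form_auc(d_star: float) -> float:
    """Expected rating AUC of a unit-variance observer: Phi(d*/sqrt(2))."""
    return float(norm.cdf(d_star / np.sqrt(2.0)))


def dnn_expected_auc(p: DnnParams) -> float:
    """Expected AUC of a DNN scorer given its class-conditional variances."""
    var_same = p.alignment ** 2 + p.noise_sd ** 2
    var_diff = (p.alignment - p.nu) ** 2 + p.noise_sd ** 2
    return float(norm.cdf(p.d_star / np.sqrt(var_same + var_diff)))


def d_star_for_auc(auc: float) -> float:
    """Invert the unit-variance closed form: d* = sqrt(2) z(AUC)."""
    return float(np.sqrt(2.0) * norm.ppf(auc))


def rating_bin_probabilities(p: ObserverParams) -> tuple[np.ndarray, np.ndarray]:
    """Exact response-category probabilities (-5..+5) per truth class.

    Evidence is N(d*, 1) on same-person items and N(0, 1) on
    different-people items; the category boundaries are the response
    boundary k = d*/2 + c* plus the four confidence cutoffs on each side,
    and the innermost band loses mass p_inconclusive to the 0 response.
    """
    delta = _cutoffs(p.kappa)
    k = p.d_star / 2 + p.c_star
    edges = np.concatenate([[-np.inf], k - delta[::-1], [k], k + delta, [np.inf]])
    out = []
    for mu in (p.d_star, 0.0):  # same, different
        cdf = norm.cdf(edges - mu)
        mass = np.diff(cdf)  # categories -5..-1, +1..+5 (10 bands)
        probs = np.empty(11)
        probs[:5] = mass[:5]          # -5..-1
        probs[6:] = mass[5:]          # +1..+5
        inner = mass[4] + mass[5]     # the +/-1 band around the boundary
        probs[5] = p.p_inconclusive * inner
        probs[4] *= 1 - p.p_inconclusive
        probs[6] *= 1 - p.p_inconclusive
        out.append(probs)
    return out[0], out[1]


def expected_rating_auc(p: ObserverParams) -> float:
    """Expected rating AUC of a discretized observer (exact).

    AUC is a U-statistic over (same, different) item pairs, so its
    expectation is sum_r sum_{r'<r} P_s(r) P_d(r') + 0.5 sum_r P_s(r) P_d(r)
    over the category distributions — the discretization attenuates it
    below the latent Phi(d*/sqrt(2))."""
    ps, pd_ = rating_bin_probabilities(p)
    cum_d = np.concatenate([[0.0], np.cumsum(pd_)])[:-1]  # P(diff < category r)
    return float(np.sum(ps * cum_d) + 0.5 * np.sum(ps * pd_))


def d_star_for_rating_auc(auc: float, c_star: float = 0.0, kappa: float = 1.0,
                          p_inconclusive: float = 0.0,
                          lambda_shared: float = 0.5) -> float:
    """Sensitivity whose *rating* AUC (after discretization) equals ``auc``."""
    from scipy.optimize import brentq

    def f(d: float) -> float:
        return expected_rating_auc(ObserverParams(
            d, c_star, kappa, p_inconclusive, lambda_shared)) - auc

    return float(brentq(f, 0.0, 15.0, xtol=1e-10))


def expected_inconclusive_rate(p: ObserverParams, n_same: int,
                               n_diff: int) -> float:
    """Expected share of 0 responses over an n_same:n_diff item mix."""
    ps, pd_ = rating_bin_probabilities(p)
    return float((n_same * ps[5] + n_diff * pd_[5]) / (n_same + n_diff))


def solve_observer_params(auc: float, c_star: float, kappa: float,
                          inconclusive_rate: float = 0.0,
                          lambda_shared: float = 0.5,
                          n_same: int = 13, n_diff: int = 7) -> ObserverParams:
    """Observer parameters whose expected rating AUC and expected
    inconclusive rate both equal the given targets.

    d* and p_inconclusive interact through the response-category
    probabilities, so they are solved jointly by fixed-point iteration
    (the map contracts quickly; 40 rounds reach float precision).
    """
    p_inc = 0.0
    d = d_star_for_rating_auc(auc, c_star, kappa, p_inc, lambda_shared)
    for _ in range(40):
        if inconclusive_rate > 0:
            probe = ObserverParams(d, c_star, kappa, 0.5, lambda_shared)
            inner = 2 * expected_inconclusive_rate(probe, n_same, n_diff)
            p_inc = min(inconclusive_rate / inner, 0.99)
        d = d_star_for_rating_auc(auc, c_star, kappa, p_inc, lambda_shared)
    return ObserverParams(d, c_star, kappa, p_inc, lambda_shared)


def dnn_d_star_for_auc(auc: float, nu: float = 0.0, noise_sd: float = 0.6,
                       alignment: float = 0.3) -> float:
    var_same = alignment ** 2 + noise_sd ** 2
    var_diff = (alignment - nu) ** 2 + noise_sd ** 2
    return float(np.sqrt(var_same + var_diff) * norm.ppf(auc))


# ---------------------------------------------------------------------------
# discretization

def _cutoffs(kappa: float) -> np.ndarray:
    """Cumulative confidence-band offsets delta_1..delta_4 from the boundary."""
    inc = BIN_BASE_WIDTH * kappa ** -np.arange(4, dtype=float)
    return np.cumsum(inc)


def discretize_evidence(e: np.ndarray, boundary: float, kappa: float,
                        p_inconclusive: float, rng: np.random.Generator,
                        ) -> np.ndarray:
    """Map latent evidence to integer ratings in [-5, 5]."""
    delta = _cutoffs(kappa)
    dist = np.abs(e - boundary)
    mag = 1 + np.searchsorted(delta, dist, side="right")  # 1..5
    mag = np.minimum(mag, 5)
    rating = np.sign(e - boundary).astype(int) * mag
    rating[rating == 0] = 1  # sign exactly 0 has measure zero; break toward "same"
    if p_inconclusive > 0:
        inner = dist < delta[0]
        emit0 = inner & (rng.random(e.shape) < p_inconclusive)
        rating[emit0] = 0
    return rating


# ---------------------------------------------------------------------------
# study generation

def _gap_categories(n_items: int, rng: np.random.Generator) -> list[str | None]:
    # the 20-item proficiency test's mix: 3 recent, 13 medium, 4 long gaps
    if n_items == 20:
        cats = ["0-2y"] * 3 + ["2-8y"] * 13 + ["8+y"] * 4
        rng.shuffle(cats)
        return cats
    return [None] * n_items


def generate_study(config: SyntheticConfig,
                   ) -> tuple[RatingMatrix, list[ItemKey], pd.DataFrame]:
    """Simulate one study.

    Returns the rating matrix (ordinal humans and raw-score DNNs share one
    table; the DNN rows are real-valued, so the matrix is tagged
    ``raw_score`` whenever DNNs are present and callers binarize/profile on
    the human subset), the item key, and a truth record holding every
    generating parameter plus each observer's closed-form expected AUC.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n, n_same = config.n_items, config.n_same
    width = len(str(n))
    item_ids = [f"item{str(i + 1).zfill(width)}" for i in range(n)]
    is_same = np.zeros(n, dtype=bool)
    is_same[:n_same] = True
    gaps = _gap_categories(n, rng)
    keys = [ItemKey(iid, "same" if s else "different", gap)
            for iid, s, gap in zip(item_ids, is_same, gaps)]

    u = rng.standard_normal(n)             # shared item component

    observers: list[Observer] = []
    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    any_dnn = False
    counter = 0
    for group in sorted(config.groups):
        mode = config.modes.get(group,
                                "not_applicable" if group == "dnn" else "online")
        for p in config.groups[group]:
            counter += 1
            oid = f"{group}_{counter:03d}"
            observers.append(Observer(oid, group, mode))
            if isinstance(p, DnnParams):
                any_dnn = True
                load = np.where(is_same, p.alignment,
                                p.alignment - p.nu)
                score = (p.d_star * is_same + load * u
                         + p.noise_sd * rng.standard_normal(n))
                rows.append(score)
                expected = dnn_expected_auc(p)
                truth_rows.append({"observer_id": oid, "group": group,
                                   "kind": "dnn", "d_star": p.d_star,
                                   "c_star": np.nan, "kappa": np.nan,
                                   "p_inconclusive": np.nan,
                                   "lambda_shared": np.nan, "nu": p.nu,
                                   "noise_sd": p.noise_sd,
                                   "alignment": p.alignment,
                                   "expected_auc": expected})
            else:
                lam = p.lambda_shared
                e = (p.d_star * is_same + lam * u
                     + np.sqrt(1 - lam ** 2) * rng.standard_normal(n))
                boundary = p.d_star / 2 + p.c_star
                rating = discretize_evidence(e, boundary, p.kappa,
                                             p.p_inconclusive, rng)
                rows.append(rating.astype(float))
                truth_rows.append({"observer_id": oid, "group": group,
                                   "kind": "human", "d_star": p.d_star,
                                   "c_star": p.c_star, "kappa": p.kappa,
                                   "p_inconclusive": p.p_inconclusive,
                                   "lambda_shared": lam, "nu": np.nan,
                                   "noise_sd": np.nan, "alignment": np.nan,
                                   "expected_auc": expected_rating_auc(p)})
    values = pd.DataFrame(np.vstack(rows),
                          index=[o.observer_id for o in observers],
                          columns=item_ids)
    kind = "raw_score" if any_dnn else "ordinal_11pt"
    matrix = RatingMatrix(observers, item_ids, values, kind)
    truth = pd.DataFrame(truth_rows).set_index("observer_id")
    return matrix, keys, truth


def human_subset(matrix: RatingMatrix) -> RatingMatrix:
    """The human rows of a mixed study, re-tagged as ordinal."""
    ids = [o.observer_id for o in matrix.observers if o.group != "dnn"]
    sub = matrix.subset(ids)
    return RatingMatrix(sub.observers, sub.item_ids, sub.values, "ordinal_11pt")


# ---------------------------------------------------------------------------
# the study-conditions cohort

#: group mean AUCs on the proficiency test that the default cohort is built
#: to reproduce in expectation (proportions)
COHORT_TARGET_AUC = {
    "forensic_examiner": 0.910,
    "super_recognizer": 0.880,
    "dnn": 0.876,
    "novice": 0.762,
    "forensic_laboratory": 0.974,
}

#: group sizes of the proficiency-test cohort
COHORT_SIZES = {
    "novice": 106,
    "super_recognizer": 37,
    "forensic_examiner": 16,
    "forensic_laboratory": 19,
    "dnn": 10,
}


#: observed group inconclusive-response rates the cohort reproduces in
#: expectation (share of all responses that are 0)
COHORT_TARGET_INCONCLUSIVE = {
    "forensic_examiner": 0.091,
    "super_recognizer": 0.003,
}

#: shared-component loadings for the default cohort.  Expert lambda = 0.6
#: puts the expected expert-expert evidence correlation at lambda^2 = 0.36
#: (~0.25 after rank/discretization attenuation); DNN alignment 0.55 and
#: divergence nu = 0.8 put the human x DNN evidence correlation at
#: +0.40 on same-person items and -0.24 on different-people items,
#: matching the observed agree-on-same / disagree-on-different signature.
COHORT_LAMBDA_EXPERT = 0.6
COHORT_LAMBDA_NOVICE = 0.45
COHORT_DNN_ALIGNMENT = 0.55
COHORT_DNN_NU = 0.8


def study_cohort_config(seed: int = 0,
                        sizes: dict[str, int] | None = None,
                        dnn_nu: float = COHORT_DNN_NU) -> SyntheticConfig:
    """Default cohort emulating the proficiency-test study conditions.

    20 items (13 same-person, 7 different-people); five observer groups
    with sensitivities and inconclusive propensities solved so each
    group's expected AUC — and, for the expert groups, expected
    inconclusive rate — equals its observed value; criteria of -1.08
    (super-recognizers, strongly liberal) and -0.10 (examiners, near
    neutral); extremeness gains that pile super-recognizer responses on
    the scale ends while examiners stay midscale; and DNN scorers whose
    different-pair rank order anti-correlates with the humans'
    (nu > alignment).
    """
    sizes = dict(COHORT_SIZES if sizes is None else sizes)
    style = {
        "super_recognizer": dict(c_star=-1.08, kappa=2.0,
                                 lambda_shared=COHORT_LAMBDA_EXPERT),
        "forensic_examiner": dict(c_star=-0.10, kappa=0.75,
                                  lambda_shared=COHORT_LAMBDA_EXPERT),
        "forensic_laboratory": dict(c_star=-0.10, kappa=0.75,
                                    lambda_shared=COHORT_LAMBDA_EXPERT),
        "novice": dict(c_star=-0.30, kappa=1.0,
                       lambda_shared=COHORT_LAMBDA_NOVICE),
    }
    # laboratories and novices have no reported inconclusive rate; they get
    # examiner-like and midway propensities respectively
    inc_target = dict(COHORT_TARGET_INCONCLUSIVE,
                      forensic_laboratory=0.075, novice=0.04)
    human_params = {
        g: solve_observer_params(COHORT_TARGET_AUC[g],
                                 inconclusive_rate=inc_target[g], **s)
        for g, s in style.items()
    }
    groups: dict[str, list[AnyParams]] = {
        g: [human_params[g]] * n for g, n in sizes.items() if g != "dnn"
    }
    if sizes.get("dnn", 0):
        dstar = dnn_d_star_for_auc(COHORT_TARGET_AUC["dnn"], nu=dnn_nu,
                                   alignment=COHORT_DNN_ALIGNMENT)
        groups["dnn"] = [DnnParams(dstar, nu=dnn_nu,
                                   alignment=COHORT_DNN_ALIGNMENT)] * sizes["dnn"]
    modes = {"forensic_examiner": "offline", "forensic_laboratory": "offline",
             "novice": "online", "super_recognizer": "online",
             "dnn": "not_applicable"}
    return SyntheticConfig(n_items=20, n_same=13, groups=groups,
                           seed=seed, modes=modes)


# ---------------------------------------------------------------------------
# recovery harness

@dataclass
class RecoveryReport:
    per_observer: pd.DataFrame   # estimates joined with generating truth
    mae_c: float
    mae_d: float
    mean_abs_auc_error: float
    block_rho: pd.DataFrame | None  # human x dnn block means per trial type


def recovery_suite(config: SyntheticConfig) -> RecoveryReport:
    """Generate a study and measure how well the pipeline recovers the
    generating parameters (criterion, sensitivity, AUC, block-correlation
    signs)."""
    matrix, keys, truth = generate_study(config)
    humans = human_subset(matrix) if "dnn" in matrix.groups.values else matrix

    auc = observer_auc_table(matrix, keys).set_index("observer_id")["auc"]
    est = truth.join(auc.rename("auc_hat"))
    est["auc_err"] = est["auc_hat"] - est["expected_auc"]

    sdt = pd.DataFrame([s.__dict__ for s in sdt_summary(humans, keys)])
    if not sdt.empty:
        sdt = sdt.set_index("observer_id")[["d_prime", "criterion_c"]]
        est = est.join(sdt)
        hmask = est["kind"] == "human"
        mae_c = float((est.loc[hmask, "criterion_c"] - est.loc[hmask, "c_star"])
                      .abs().mean())
        mae_d = float((est.loc[hmask, "d_prime"] - est.loc[hmask, "d_star"])
                      .abs().mean())
    else:
        mae_c = mae_d = float("nan")

    block = None
    if "dnn" in matrix.groups.values:
        coarse = matrix.groups.map(lambda g: "dnn" if g == "dnn" else "human")
        rows = []
        for tt in ("same", "different"):
            corr = correlation_matrix(matrix, keys, tt)
            for b in block_agreement(corr, coarse, pairs=[("dnn", "human")]):
                rows.append({"trial_type": tt, "mean_rho": b.mean_rho,
                             "n_pairs": b.n_pairs})
        block = pd.DataFrame(rows)

    return RecoveryReport(
        per_observer=est,
        mae_c=mae_c,
        mae_d=mae_d,
        mean_abs_auc_error=float(est["auc_err"].abs().mean()),
        block_rho=block,
    )
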