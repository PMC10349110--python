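"""Synthetic observer generator: determinism, closed forms, monotonicity,
parameter recovery."""

import itertools

import numpy as np
import pytest
from scipy.stats import ks_2samp, norm

from faceproficiency.errors import ValidationError
from faceproficiency.roc import observer_auc_table, rating_auc
from faceproficiency.sdt import response_profile
from faceproficiency.similarity import block_agreement, correlation_matrix
from faceproficiency.simulate import (DnnParams, ObserverParams,
                                      SyntheticConfig, closed_form_auc,
                                      dnn_expected_auc, expected_rating_auc,
                                      expected_inconclusive_rate,
                                      generate_study, human_subset,
                                      rating_bin_probabilities,
                                      recovery_suite, solve_observer_params,
                                      study_cohort_config)


def simple_cfg(seed=0, n=40, n_items=100, **kw):
    p = ObserverParams(kw.pop("d_star", 1.5), **kw)
    return SyntheticConfig(n_items=n_items, n_same=n_items * 13 // 20,
                           groups={"novice": [p] * n}, seed=seed)


class TestConfigValidation:
    def test_needs_both_truth_classes(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(10, 10, {"novice": [ObserverParams(1.0)]})

    def test_dnn_group_needs_dnn_params(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(10, 5, {"dnn": [ObserverParams(1.0)]})

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValidationError):
            ObserverParams(-0.5)


class TestDeterminism:
    def test_same_seed_same_study(self):
        m1, k1, t1 = generate_study(simple_cfg(seed=7, n=5))
        m2, k2, t2 = generate_study(simple_cfg(seed=7, n=5))
        assert m1.values.equals(m2.values)
        assert k1 == k2
        assert t1.equals(t2)

    def test_different_seeds_differ_but_match_in_distribution(self):
        """Distinct seeds give different draws whose per-observer AUC
        distributions are statistically indistinguishable."""
        m1, key, _ = generate_study(simple_cfg(seed=1, n=60))
        m2, _, _ = generate_study(simple_cfg(seed=2, n=60))
        assert not m1.values.equals(m2.values)
        a1 = observer_auc_table(m1, key)["auc"]
        a2 = observer_auc_table(m2, key)["auc"]
        assert ks_2samp(a1, a2).pvalue > 1e-3


class TestClosedForms:
    def test_bin_probabilities_sum_to_one(self):
        for p in (ObserverParams(1.5, -1.08, 2.0, 0.3),
                  ObserverParams(0.5, 0.4, 0.75, 0.0)):
            ps, pd_ = rating_bin_probabilities(p)
            assert ps.sum() == pytest.approx(1.0)
            assert pd_.sum() == pytest.approx(1.0)
            assert (ps >= 0).all() and (pd_ >= 0).all()

    def test_simulated_category_frequencies_match_analytic(self):
        p = ObserverParams(1.8, -0.4, 1.3, 0.25, lambda_shared=0.0)
        cfg = SyntheticConfig(40000, 20000, {"novice": [p]}, seed=13)
        matrix, keys, _ = generate_study(cfg)
        truths = np.array([k.truth for k in keys])
        vals = matrix.values.to_numpy().ravel()
        ps, pd_ = rating_bin_probabilities(p)
        for cls, expected in (("same", ps), ("different", pd_)):
            v = vals[truths == cls]
            freq = np.array([(v == r).mean() for r in range(-5, 6)])
            assert np.abs(freq - expected).max() < 0.01

    def test_no_signal_means_chance_auc(self):
        matrix, keys, _ = generate_study(simple_cfg(d_star=0.0, n=60, seed=3))
        aucs = observer_auc_table(matrix, keys)["auc"]
        assert aucs.mean() == pytest.approx(0.5, abs=0.02)

    def test_huge_sensitivity_means_perfect_observers(self):
        matrix, keys, _ = generate_study(simple_cfg(d_star=12.0, n=10, seed=4))
        aucs = observer_auc_table(matrix, keys)["auc"]
        assert (aucs == 1.0).all()
        profiles = response_profile(matrix, keys, by="group")
        assert profiles[0].n_errors == 0

    def test_single_observer_auc_matches_gaussian_closed_form(self):
        """An independent observer's simulated rating AUC agrees with the
        equal-variance prediction Phi(d*/sqrt(2)) within Monte-Carlo error
        (the exact discretized expectation is tighter still)."""
        d = 1.5
        p = ObserverParams(d, lambda_shared=0.0)
        cfg = SyntheticConfig(2000, 1300, {"novice": [p]}, seed=21)
        matrix, keys, _ = generate_study(cfg)
        auc = rating_auc(matrix.values.iloc[0], keys)
        a = closed_form_auc(d)
        # Hanley-McNeil standard error of an AUC estimate
        q1, q2 = a / (2 - a), 2 * a ** 2 / (1 + a)
        n1, n2 = 1300, 700
        se = np.sqrt((a * (1 - a) + (n1 - 1) * (q1 - a ** 2)
                      + (n2 - 1) * (q2 - a ** 2)) / (n1 * n2))
        assert abs(auc - expected_rating_auc(p)) < 3 * se
        assert abs(auc - a) < 3 * se + abs(expected_rating_auc(p) - a)
        assert abs(expected_rating_auc(p) - a) < 0.01  # small attenuation

    def test_solver_hits_auc_and_inconclusive_targets(self):
        p = solve_observer_params(0.91, c_star=-0.1, kappa=0.75,
                                  inconclusive_rate=0.091, lambda_shared=0.6)
        assert expected_rating_auc(p) == pytest.approx(0.91, abs=1e-9)
        assert expected_inconclusive_rate(p, 13, 7) == pytest.approx(0.091, abs=1e-9)

    def test_dnn_expected_auc_matches_simulation(self):
        p = DnnParams(d_star=1.2, nu=0.8, noise_sd=0.6, alignment=0.55)
        cfg = SyntheticConfig(4000, 2600, {"dnn": [p]}, seed=17)
        matrix, keys, _ = generate_study(cfg)
        auc = rating_auc(matrix.values.iloc[0], keys)
        assert auc == pytest.approx(dnn_expected_auc(p), abs=0.03)


class TestMonotonicity:
    def test_auc_increases_with_sensitivity(self):
        analytic = [expected_rating_auc(ObserverParams(d)) for d in (0.5, 1.0, 2.0)]
        assert analytic == sorted(analytic)
        means = []
        for d in (0.5, 1.0, 2.0):
            m, keys, _ = generate_study(simple_cfg(d_star=d, n=25, seed=8))
            means.append(observer_auc_table(m, keys)["auc"].mean())
        assert means == sorted(means)

    def test_inconclusive_rate_increases_with_propensity(self):
        rates = []
        for pi in (0.0, 0.2, 0.6):
            m, keys, _ = generate_study(
                simple_cfg(p_inconclusive=pi, n=25, seed=9))
            (prof,) = response_profile(m, keys, by="group")
            rates.append(prof.inconclusive_rate)
        assert rates[0] == 0.0
        assert rates == sorted(rates)

    def test_extremeness_gain_piles_mass_on_scale_ends(self):
        def extreme_mass(kappa):
            ps, pd_ = rating_bin_probabilities(ObserverParams(1.5, kappa=kappa))
            mix = (13 * ps + 7 * pd_) / 20
            return mix[0] + mix[1] + mix[-2] + mix[-1]  # -5,-4,+4,+5
        assert extreme_mass(2.0) > extreme_mass(1.0) > extreme_mass(0.75)

    def test_dnn_divergence_flips_different_pair_agreement(self):
        """As nu grows, the human x DNN block correlation on
        different-people items falls below zero while same-person
        agreement stays positive."""
        diff_rho, same_rho = [], []
        for nu in (0.0, 0.55, 1.1):
            human = ObserverParams(1.7, lambda_shared=0.6)
            dnn = DnnParams(1.3, nu=nu, alignment=0.55)
            cfg = SyntheticConfig(60, 39, {"novice": [human] * 25,
                                           "dnn": [dnn] * 8}, seed=31)
            matrix, keys, _ = generate_study(cfg)
            coarse = matrix.groups.map(lambda g: "dnn" if g == "dnn" else "human")
            for tt, acc in (("different", diff_rho), ("same", same_rho)):
                corr = correlation_matrix(matrix, keys, tt)
                (b,) = block_agreement(corr, coarse, pairs=[("dnn", "human")])
                acc.append(b.mean_rho)
        assert diff_rho == sorted(diff_rho, reverse=True)
        assert diff_rho[0] > 0 > diff_rho[2]
        assert all(r > 0 for r in same_rho)


def recovery_config(seed, n_items=200):
    """40 observers spanning moderate criteria, sensitivities, extremeness
    gains and inconclusive propensities — the regime where 130/70 decisive
    trials can still resolve H and F off the boundaries."""
    params = [ObserverParams(d, c, kap, pi, 0.4)
              for c, d, kap, pi in itertools.product(
                  (-0.8, -0.3, 0.0, 0.3, 0.8), (0.8, 1.4, 2.0),
                  (0.8, 1.5), (0.0, 0.2))][:40]
    return SyntheticConfig(n_items=n_items, n_same=n_items * 13 // 20,
                           groups={"novice": params}, seed=seed)


class TestRecovery:
    def test_criterion_and_sensitivity_recovered(self):
        reports = [recovery_suite(recovery_config(seed)) for seed in (0, 1, 2)]
        assert np.mean([r.mae_c for r in reports]) <= 0.1
        assert np.mean([r.mae_d for r in reports]) <= 0.3
        assert np.mean([r.mean_abs_auc_error for r in reports]) <= 0.05

    def test_aligned_dnns_agree_with_humans_on_both_trial_types(self):
        human = ObserverParams(1.7, lambda_shared=0.6)
        dnn = DnnParams(1.3, nu=0.0, alignment=0.55)
        cfg = SyntheticConfig(60, 39, {"novice": [human] * 20,
                                       "dnn": [dnn] * 6}, seed=12)
        rep = recovery_suite(cfg)
        assert (rep.block_rho["mean_rho"] > 0).all()


class TestStudyCohort:
    def test_census_matches_study(self):
        matrix, keys, truth = generate_study(study_cohort_config(seed=0))
        assert len(keys) == 20
        assert sum(k.truth == "same" for k in keys) == 13
        sizes = matrix.groups.value_counts()
        assert sizes["novice"] == 106 and sizes["super_recognizer"] == 37
        assert sizes["forensic_examiner"] == 16
        assert sizes["forensic_laboratory"] == 19 and sizes["dnn"] == 10
        gaps = [k.gap_category for k in keys]
        assert (gaps.count("0-2y"), gaps.count("2-8y"), gaps.count("8+y")) == (3, 13, 4)

    def test_human_rows_ordinal_dnn_rows_real(self):
        matrix, _, _ = generate_study(study_cohort_config(seed=0))
        hum = human_subset(matrix)
        v = hum.values.to_numpy()
        assert np.all(v == np.round(v))
        dnn_rows = matrix.values.loc[matrix.groups == "dnn"].to_numpy()
        assert not np.all(dnn_rows == np.round(dnn_rows))

    def test_extremeness_contrast_between_expert_groups(self):
        matrix, keys, _ = generate_study(study_cohort_config(seed=0))
        profs = {p.profile_id: p
                 for p in response_profile(human_subset(matrix), keys)}
        sr, ex = profs["super_recognizer"], profs["forensic_examiner"]
        ends = [-5, 4, 5]
        assert sr.usage[ends].sum() > ex.usage[ends].sum()
        assert ex.inconclusive_rate > sr.inconclusive_rate
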