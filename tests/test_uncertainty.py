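"""Uncertainty measures vs brute-force oracles, threshold, evaluation."""

import numpy as np
import pytest
from scipy import stats

from bciuq import (
    PredictiveDistribution,
    bhattacharyya_distance,
    decide,
    evaluate_uncertainty,
    margin_of_confidence,
    margin_threshold,
    measure_separation,
    mutual_information,
    predictive_entropy,
    sweep_threshold_multiplier,
    total_variance,
    variation_ratio,
)
from bciuq.uncertainty import CertaintyDecision
from oracles import db_oracle, margin_oracle, mi_oracle, vr_oracle, vtot_oracle, entropy_oracle


def make_pd(P):
    P = np.asarray(P, dtype=np.float64)
    return PredictiveDistribution(P, P.mean(axis=0), P.shape[0])


def random_pds(n, rng, T_max=10, C_max=5):
    out = []
    for _ in range(n):
        T = int(rng.integers(1, T_max + 1))
        C = int(rng.integers(2, C_max + 1))
        P = rng.dirichlet(np.ones(C) * rng.uniform(0.3, 3.0), size=T)
        out.append(make_pd(P))
    return out


class TestMeasuresAgainstOracles:
    def test_all_measures_match_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for pd_ in random_pds(300, rng):
            P = pd_.P.tolist()
            assert variation_ratio(pd_) == pytest.approx(vr_oracle(P), abs=1e-9)
            H, Hn = predictive_entropy(pd_)
            assert H == pytest.approx(entropy_oracle(pd_.p_star.tolist()), abs=1e-9)
            assert Hn == pytest.approx(H / np.log2(pd_.n_classes), abs=1e-12)
            assert mutual_information(pd_) == pytest.approx(mi_oracle(P), abs=1e-9)
            assert total_variance(pd_) == pytest.approx(vtot_oracle(P), abs=1e-9)
            M, sd, d = margin_of_confidence(pd_)
            Mo, sdo, do = margin_oracle(P)
            assert M == pytest.approx(Mo, abs=1e-9)
            assert sd == pytest.approx(sdo, abs=1e-9)
            np.testing.assert_allclose(d, do, atol=1e-9)

    def test_mutual_information_non_negative(self):
        rng = np.random.default_rng(7)
        for pd_ in random_pds(200, rng):
            assert mutual_information(pd_) >= 0.0


class TestVariationRatio:
    def test_unanimous_passes_give_zero(self):
        assert variation_ratio(make_pd([[0.1, 0.1, 0.8]] * 5)) == 0.0

    def test_mode_frequency_two_of_four(self):
        P = [[0.9, 0.05, 0.05], [0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
        assert variation_ratio(make_pd(P)) == pytest.approx(0.5)

    def test_even_binary_split_gives_half(self):
        P = [[0.9, 0.1]] * 25 + [[0.1, 0.9]] * 25
        assert variation_ratio(make_pd(P)) == pytest.approx(0.5)

    def test_upper_bound_is_one_minus_one_over_C(self):
        # maximally dispersed per-pass modes over C=4 classes
        P = np.eye(4) * 0.7 + 0.075
        assert variation_ratio(make_pd(P)) == pytest.approx(1 - 1 / 4)


class TestEntropy:
    def test_one_hot_zero(self):
        H, Hn = predictive_entropy(make_pd([[1.0, 0.0, 0.0, 0.0]]))
        assert H == 0.0 and Hn == 0.0

    def test_uniform_is_maximal(self):
        H, Hn = predictive_entropy(make_pd([[0.25] * 4]))
        assert H == pytest.approx(2.0)
        assert Hn == pytest.approx(1.0)

    def test_binary_half(self):
        H, _ = predictive_entropy(make_pd([[0.5, 0.5]]))
        assert H == pytest.approx(1.0)


class TestMutualInformation:
    def test_identical_rows_zero(self):
        assert mutual_information(make_pd([[0.3, 0.7]] * 6)) == 0.0

    def test_fully_disagreeing_one_hot_rows_give_one_bit(self):
        assert mutual_information(make_pd([[1.0, 0.0], [0.0, 1.0]])) == pytest.approx(1.0)


class TestTotalVariance:
    def test_identical_rows_zero(self):
        assert total_variance(make_pd([[0.2, 0.8]] * 4)) == 0.0

    def test_hand_value_and_column_permutation_symmetry(self):
        pd_ = make_pd([[1.0, 0.0], [0.0, 1.0]])
        assert total_variance(pd_) == pytest.approx(0.5)
        pd_perm = make_pd([[0.0, 1.0], [1.0, 0.0]])
        assert total_variance(pd_perm) == pytest.approx(total_variance(pd_))


class TestMargin:
    def test_unanimous_one_hot(self):
        M, sd, _ = margin_of_confidence(make_pd([[0.0, 1.0]] * 5))
        assert M == 1.0 and sd == 0.0

    def test_uniform_rows_zero_margin(self):
        M, _, d = margin_of_confidence(make_pd([[0.5, 0.5]] * 4))
        assert M == 0.0
        assert np.all(d == 0.0)

    def test_negative_per_pass_margin(self):
        pd_ = make_pd([[0.6, 0.4], [0.2, 0.8]])
        M, sd, d = margin_of_confidence(pd_)
        assert pd_.predicted_class == 1
        np.testing.assert_allclose(d, [-0.2, 0.6], atol=1e-12)
        assert M == pytest.approx(0.2)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            margin_of_confidence(make_pd([[1.0]]))


class TestBhattacharyya:
    def test_identical_histograms_zero(self):
        h = np.array([0.2, 0.3, 0.5])
        assert bhattacharyya_distance(h, h) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value(self):
        assert bhattacharyya_distance([1.0, 0.0], [0.5, 0.5]) == pytest.approx(
            -np.log(np.sqrt(0.5)), abs=1e-9
        )

    def test_symmetry_on_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(10))
            q = rng.dirichlet(np.ones(10))
            assert bhattacharyya_distance(p, q) == pytest.approx(
                bhattacharyya_distance(q, p), abs=1e-12
            )
            assert db_oracle(p.tolist(), q.tolist()) == pytest.approx(
                bhattacharyya_distance(p, q), abs=1e-9
            )

    def test_mismatched_binning_errors(self):
        with pytest.raises(ValueError):
            bhattacharyya_distance([0.5, 0.5], [0.3, 0.3, 0.4])


class TestMeasureSeparation:
    def test_same_samples_give_zero(self):
        v = np.linspace(0, 1, 100)
        assert measure_separation(v, v) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_is_large(self):
        assert measure_separation(np.zeros(50), np.ones(50) + 9) > 13.0

    def test_gaussian_closed_form(self):
        # N(0,1) vs N(3,1): DB = mu_diff^2/8 = 9/8 for equal variances
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 100_000)
        b = rng.normal(3, 1, 100_000)
        assert measure_separation(a, b, n_bins=50) == pytest.approx(9 / 8, abs=0.1)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            measure_separation(np.array([]), np.ones(3))


class TestThreshold:
    def test_consistent_model_never_rejected(self):
        assert margin_threshold(0.0, 50) == 0.0

    def test_normal_quantile_value(self):
        assert margin_threshold(0.1, 50, 0.05) == pytest.approx(
            0.1 * 1.959964 / np.sqrt(50), abs=1e-6
        )

    def test_alpha_to_one_limit(self):
        assert margin_threshold(0.5, 50, 0.999999) == pytest.approx(0.0, abs=1e-5)

    def test_invalid_alpha_errors(self):
        with pytest.raises(ValueError):
            margin_threshold(0.1, 50, 1.5)


class TestDecide:
    def test_unanimous_one_hot_is_certain(self):
        dec = decide(make_pd([[0.0, 1.0]] * 5))
        assert dec.certain and dec.M == 1.0

    def test_uniform_boundary_is_uncertain(self):
        dec = decide(make_pd([[0.5, 0.5]] * 4))
        assert dec.M == 0.0 and dec.threshold == 0.0
        assert not dec.certain  # M <= M_hat counts as uncertain

    def test_full_path_against_threshold_oracle(self):
        pd_ = make_pd([[0.6, 0.4], [0.2, 0.8]])
        dec = decide(pd_, alpha=0.05)
        sd = np.std([-0.2, 0.6], ddof=1)
        th = sd * stats.norm.ppf(0.975) / np.sqrt(2)
        assert dec.threshold == pytest.approx(th, abs=1e-12)
        assert dec.certain == (0.2 > th)


class TestEvaluate:
    def _dec(self, c, certain):
        return CertaintyDecision(c, 0.5, 0.1, 0.01, 0.05, certain)

    def test_all_correct_certain(self):
        decs = [self._dec(1, True)] * 4
        r = evaluate_uncertainty(decs, [1, 1, 1, 1])
        assert r.Rc == 1.0 and r.Rcc == 1.0 and r.UA == 1.0
        assert np.isnan(r.Riu)

    def test_hand_counts(self):
        decs = (
            [self._dec(1, True)] * 6  # correct certain
            + [self._dec(0, True)]  # incorrect certain
            + [self._dec(1, False)] * 2  # correct uncertain
            + [self._dec(0, False)]  # incorrect uncertain
        )
        labels = [1] * 6 + [1] + [1] * 2 + [1]
        r = evaluate_uncertainty(decs, labels)
        assert (r.N_cc, r.N_ic, r.N_cu, r.N_iu) == (6, 1, 2, 1)
        assert r.Rc == pytest.approx(0.7)
        assert r.Rcc == pytest.approx(6 / 7)
        assert r.Riu == pytest.approx(0.5)
        assert r.UA == pytest.approx(0.7)
        # the two UA forms agree exactly
        assert r.UA == pytest.approx(1 - (r.N_ic + r.N_cu) / r.N)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            evaluate_uncertainty([self._dec(0, True)], [0, 1])


class TestSweep:
    def _pds_and_labels(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pds, labels = [], []
        for _ in range(n):
            strength = rng.uniform(0.5, 5.0)
            P = rng.dirichlet([strength, 1.0], size=20)
            pd_ = make_pd(P)
            pds.append(pd_)
            # true label agrees with the prediction 80% of the time
            flip = rng.random() > 0.8
            labels.append(pd_.predicted_class ^ flip)
        return pds, np.array(labels, dtype=int)

    def test_ua_never_exceeds_optimum_and_rc_monotone(self):
        pds, labels = self._pds_and_labels()
        curve, summary = sweep_threshold_multiplier(pds, labels)
        assert np.all(curve["UA"] <= summary["UA_star"] + 1e-12)
        rc = curve["Rc"].to_numpy()
        assert np.all(np.diff(rc) <= 1e-12)  # larger z rejects weakly more

    def test_reference_multipliers_reported(self):
        pds, labels = self._pds_and_labels(seed=3)
        _, summary = sweep_threshold_multiplier(pds, labels)
        assert 0.0 <= summary["UA_at_0.95"] <= 1.0
        assert 0.0 <= summary["UA_at_0.99"] <= 1.0
        assert summary["UA_at_0.95"] <= summary["UA_star"] + 1e-12

    def test_empty_grid_errors(self):
        pds, labels = self._pds_and_labels(n=5)
        with pytest.raises(ValueError):
            sweep_threshold_multiplier(pds, labels, z_grid=np.array([]))


def test_threshold_coverage_under_null_margins():
    """For d_t iid N(0, s^2), T=50, alpha=0.05 the certain fraction matches
    alpha/2 within 3 Monte-Carlo standard errors (10,000 replicates)."""
    rng = np.random.default_rng(2024)
    T, alpha, n_rep = 50, 0.05, 10_000
    d = rng.normal(0.0, 0.3, size=(n_rep, T))
    M = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    z = stats.norm.ppf(1 - alpha / 2)
    frac = np.mean(M > sd * z / np.sqrt(T))
    target = alpha / 2
    se = np.sqrt(target * (1 - target) / n_rep)
    assert abs(frac - target) <= 3 * se


def test_misclassified_predictions_carry_higher_entropy(overlap_data):
    """On overlapping synthetic classes, mean normalized entropy of the
    misclassified trials exceeds that of correct trials."""
    from conftest import fit_one
    from bciuq.experiment import _crop, evaluate_trials

    tr, te = overlap_data
    m, ecfg = fit_one(tr, seed=1)
    crops_te = _crop(te, ecfg)
    labels = np.array([te.labels[i] for i in np.unique(crops_te.trial_index)])
    acc, pds, decs, rep, table = evaluate_trials(m, crops_te, labels, T=50, seed=1)
    wrong = table["c"] != table["true"]
    assert wrong.any() and (~wrong).any()
    assert table.loc[wrong, "Hn"].mean() > table.loc[~wrong, "Hn"].mean()
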