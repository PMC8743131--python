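"""Univariable estimators: closed-form oracles, invariants, sensitivity logic."""

import numpy as np
import pytest

from mrpipe.errors import ConfigurationError, DataError
from mrpipe.harmonize import HarmonizedSet
from mrpipe.uvmr import (egger, egger_simex, ivw, mr_raps, per_snp_f,
                         steiger_filter, weighted_median, weighted_mode)

from conftest import proportional_set


def _hset(bx, by, sy=0.01, sx=1e-8):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    return HarmonizedSet.from_arrays(bx, np.full_like(bx, sx), by,
                                     np.full_like(by, sy))


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        est = ivw(_hset([0.1], [0.05]))
        assert est.beta == pytest.approx(0.05 / 0.1)

    def test_two_snp_closed_form(self):
        # hand-derived: equal weights, by = 0.5 bx exactly -> beta 0.5, Q 0
        est = ivw(_hset([0.1, 0.2], [0.05, 0.10]))
        assert est.beta == pytest.approx(0.5)
        assert est.het.Q == pytest.approx(0.0, abs=1e-20)

    def test_exact_proportionality_limit(self, noiseless):
        fixed = ivw(noiseless, variance_model="fixed")
        random = ivw(noiseless, variance_model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.5)
        assert random.beta == pytest.approx(0.5)
        # Q = 0 -> no inflation -> identical SEs
        assert fixed.se == pytest.approx(random.se)

    def test_random_effects_inflates_under_heterogeneity(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.05, 0.2, 30)
        by = 0.5 * bx + rng.normal(0, 0.05, 30)  # gross overdispersion vs sy = 0.01
        h = _hset(bx, by)
        assert ivw(h).se > ivw(h, variance_model="fixed").se

    def test_q_invariant_to_row_permutation(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.5 * bx + rng.normal(0, 0.01, 20)
        h = _hset(bx, by)
        perm = rng.permutation(20)
        hp = _hset(bx[perm], by[perm])
        assert ivw(h).het.Q == pytest.approx(ivw(hp).het.Q)
        assert ivw(h).beta == pytest.approx(ivw(hp).beta)

    def test_empty_set_rejected(self):
        empty = HarmonizedSet.from_arrays(np.empty((0, 1)), np.empty((0, 1)),
                                          np.empty(0), np.empty(0))
        with pytest.raises(DataError):
            ivw(empty)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        est = egger(_hset(bx, 0.02 + 0.5 * bx))
        assert est.beta == pytest.approx(0.5)
        assert est.intercept[0] == pytest.approx(0.02)

    def test_null_intercept_when_no_pleiotropy(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        est = egger(_hset(bx, 0.5 * bx))
        assert est.intercept[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_invariance_after_reorientation(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.2, 10)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.005, 10)
        flip = rng.choice([-1.0, 1.0], 10)
        a = egger(_hset(bx, by))
        b = egger(_hset(bx * flip, by * flip))
        assert a.beta == pytest.approx(b.beta)
        assert a.intercept[0] == pytest.approx(b.intercept[0])

    def test_requires_three_instruments(self):
        with pytest.raises(DataError):
            egger(_hset([0.1, 0.2], [0.05, 0.1]))


class TestEggerSIMEX:
    def test_no_measurement_error_equals_plain_egger(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.01 + 0.5 * bx + rng.normal(0, 0.003, 8)
        h = _hset(bx, by, sx=1e-12)
        sim = egger_simex(h, reps=100, seed=0)
        assert sim.beta == pytest.approx(egger(h).beta, abs=1e-6)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.2, 8)
        by = 0.5 * bx + rng.normal(0, 0.003, 8)
        h = HarmonizedSet.from_arrays(bx, np.full(8, 0.02), by, np.full(8, 0.01))
        a = egger_simex(h, reps=100, seed=42)
        b = egger_simex(h, reps=100, seed=42)
        assert a.beta == b.beta and a.se == b.se

    def test_degenerate_lambda_grid_rejected(self):
        h = proportional_set(n=5)
        with pytest.raises(ConfigurationError):
            egger_simex(h, lambdas=(0.0, 1.0), reps=100)

    def test_corrects_dilution_toward_truth(self):
        """Mean SIMEX slope closer to truth than naive Egger under dilution."""
        theta = 0.5
        wins = 0
        n_sims = 40
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            n = 40
            bx_true = rng.uniform(0.05, 0.2, n)
            sx = np.full(n, 0.04)  # heavy measurement error -> dilution
            bx_obs = bx_true + rng.normal(0, sx)
            by = theta * bx_true + rng.normal(0, 0.01, n)
            h = HarmonizedSet.from_arrays(bx_obs, sx, by, np.full(n, 0.01))
            naive = abs(egger(h).beta - theta)
            simex = abs(egger_simex(h, reps=100, seed=s).beta - theta)
            wins += simex < naive
        assert wins / n_sims >= 0.8


class TestWeightedMedian:
    def test_unweighted_median_of_equal_weights(self):
        est = weighted_median(_hset([1, 1, 1], [0.4, 0.5, 0.6]), boot_reps=100, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_hand_evaluated_interpolation(self):
        # ratios {0.1, 0.5, 0.9}, normalized weights {0.98, 0.01, 0.01}:
        # cumulative-minus-half-weight = {0.49, 0.985, 0.995}; 0.5 falls
        # between the first two -> 0.1 + (0.5-0.49)/(0.985-0.49) * 0.4
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        sy = 1.0 / np.sqrt(np.array([0.98, 0.01, 0.01]))
        h = HarmonizedSet.from_arrays(bx, np.full(3, 1e-8), by, sy)
        est = weighted_median(h, boot_reps=100, seed=0)
        assert est.beta == pytest.approx(0.1 + 0.01 / 0.495 * (0.5 - 0.1), rel=1e-9)

    def test_degenerate_consensus_and_shrinking_se(self):
        h_tight = proportional_set(theta=0.7, n=10, sy=1e-5)
        h_loose = proportional_set(theta=0.7, n=10, sy=1e-2)
        tight = weighted_median(h_tight, boot_reps=200, seed=1)
        loose = weighted_median(h_loose, boot_reps=200, seed=1)
        assert tight.beta == pytest.approx(0.7, abs=1e-4)
        assert tight.se < loose.se

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DataError, match="rs2"):
            weighted_median(_hset([0.1, 0.0, 0.2], [0.05, 0.0, 0.1]),
                            boot_reps=100, seed=0)


class TestWeightedMode:
    def test_majority_cluster_wins(self):
        est = weighted_mode(_hset([1, 1, 1, 1], [0.5, 0.5, 0.5, 5.0]),
                            boot_reps=100, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.1)

    def test_unimodal_limit_recovers_center(self):
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.1, 0.2, 10)
        by = 0.3 * bx * (1 + rng.normal(0, 0.01, 10))
        est = weighted_mode(_hset(bx, by), boot_reps=100, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_bandwidth_sensitivity_is_smooth(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.2, 15)
        by = 0.3 * bx + rng.normal(0, 0.002, 15)
        h = _hset(bx, by)
        est1 = weighted_mode(h, bandwidth_factor=1.0, boot_reps=100, seed=0)
        est2 = weighted_mode(h, bandwidth_factor=2.0, boot_reps=100, seed=0)
        assert abs(est1.beta - est2.beta) < 0.05


class TestMRRaps:
    def test_reduces_to_ivw_without_exposure_noise(self):
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.05, 0.2, 20)
        by = 0.5 * bx + rng.normal(0, 0.01, 20)
        h = HarmonizedSet.from_arrays(bx, np.full(20, 1e-10), by, np.full(20, 0.01))
        raps = mr_raps(h, loss="l2", overdispersion=False)
        fixed = ivw(h, variance_model="fixed")
        assert raps.beta == pytest.approx(fixed.beta, abs=1e-8)

    @pytest.mark.parametrize("loss,overdispersion", [("l2", False), ("l2", True),
                                                     ("huber", False), ("huber", True)])
    def test_noiseless_recovery(self, loss, overdispersion):
        h = proportional_set(theta=0.42, n=12, sy=1e-4, sx=1e-6)
        est = mr_raps(h, loss=loss, overdispersion=overdispersion)
        assert est.beta == pytest.approx(0.42, abs=1e-4)

    def test_unknown_loss_rejected(self, noiseless):
        with pytest.raises(ConfigurationError):
            mr_raps(noiseless, loss="l1")


class TestPerSnpF:
    def test_direct_formula(self):
        h = HarmonizedSet.from_arrays([0.05], [0.01], [0.01], [0.01])
        strength = per_snp_f(h)
        assert strength.per_snp_f["rs1"] == pytest.approx(25.0)
        assert strength.min_f == strength.max_f == pytest.approx(25.0)

    def test_weak_instrument_below_threshold(self):
        h = HarmonizedSet.from_arrays([0.01], [0.01], [0.01], [0.01])
        assert per_snp_f(h).mean_f == pytest.approx(1.0)
        assert per_snp_f(h).mean_f < 10


class TestSteigerFilter:
    def _set(self, bx, sx, by, sy):
        return HarmonizedSet.from_arrays(np.asarray(bx, float), np.asarray(sx, float),
                                         np.asarray(by, float), np.asarray(sy, float))

    def test_forward_variant_retained(self):
        # r2_exp ~ 0.01 >> r2_out ~ 1e-4 at equal n
        h = self._set([0.1], [0.01], [0.01], [0.01])
        kept, report = steiger_filter(h, 10_000, 10_000)
        assert kept.n_snps == 1
        assert report["r2_exposure"][0] > report["r2_outcome"][0]

    def test_reverse_variant_removed(self):
        h = self._set([0.01], [0.01], [0.1], [0.01])
        kept, report = steiger_filter(h, 10_000, 10_000)
        assert kept.n_snps == 0
        assert not report["kept"][0]
        assert report["steiger_pvalue"][0] < 0.05

    def test_missing_sample_size_rejected(self, noiseless):
        with pytest.raises(ConfigurationError):
            steiger_filter(noiseless, 0, 1000)

    def test_binary_approximation_switch(self):
        h = self._set([0.1], [0.01], [0.01], [0.01])
        _, rep_z = steiger_filter(h, 10_000, 10_000, exposure_binary=True,
                                  binary_r2="z_over_sqrt_n")
        _, rep_t = steiger_filter(h, 10_000, 10_000, exposure_binary=True,
                                  binary_r2="t_statistic")
        assert rep_z["r2_exposure"][0] == pytest.approx(100.0 / 10_000)
        assert rep_t["r2_exposure"][0] == pytest.approx(100 / (100 + 9998))


class TestEstimatorConsensus:
    def test_all_estimators_equal_theta_on_noiseless_data(self):
        """Exact proportionality: every estimator returns theta."""
        h = proportional_set(theta=0.5, n=20, sy=1e-3, sx=1e-9)
        assert ivw(h).beta == pytest.approx(0.5, abs=1e-6)
        assert egger(h).beta == pytest.approx(0.5, abs=1e-6)
        assert weighted_median(h, boot_reps=100, seed=0).beta == pytest.approx(0.5, abs=1e-6)
        assert weighted_mode(h, boot_reps=100, seed=0).beta == pytest.approx(0.5, abs=1e-2)
        assert mr_raps(h).beta == pytest.approx(0.5, abs=1e-6)
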